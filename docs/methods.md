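# Methods

`denovotx` reconstructs transcripts from short, deeply sequenced, (partly)
strand-specific RNA-Seq reads without a reference genome, and scores the
resulting assembly against an annotation when one is available. This note
describes the model behind each stage, the parameters that matter, the
synthetic data the test harness uses, and the known limitations.

## Pipeline model

The pipeline is a fixed composition of stages:

```
preprocess → multi-k assembly → duplicate removal → overlap merge
          → read mapping → low-coverage split → strand split
          → orientation → consensus polish → length filter (≥ 100 bp)
```

### Read preprocessing

RNA-Seq read pools carry two artifacts that hurt de Bruijn assembly:
massive exact redundancy (PCR amplification plus very abundant
transcripts) and reads containing sequencing errors. Dereplication
collapses exactly identical reads into a representative carrying a
multiplicity count; no reverse-complement collapsing is done, because on
stranded data a read and its reverse complement are different molecules.
Reads are dereplicated within the stranded and non-stranded pools
independently so strandedness is never lost by consolidation across pools.

Error filtering is k-mer based: a *rare* k-mer is one occurring fewer than
`min_kmer_count` (default 3) times in the set of unique reads, and any
read containing a rare k-mer is removed. The counting and filtering order
is significant and both orderings are supported:

* `derep_then_filter` (default): count each unique read once — the literal
  "occurred less than three times in the set of unique reads" rule;
* `filter_then_derep`: count over the raw pool, weighted by multiplicity,
  then dereplicate.

Because weighted raw counts dominate unweighted unique counts, the second
strategy always keeps a superset of the first; the difference is exercised
by tests. The filter k defaults to 21 (mid-range of the assembly ladder)
and is exposed as `--filter-k`. Reads shorter than k carry no k-mer
evidence and pass the filter.

One intrinsic edge effect is worth knowing: after dereplication the read
containing a transcript's very first (or last) k-mer is the *only* unique
read containing it, so the `min_kmer_count − 1` outermost reads at each
transcript end always fail the filter. Assembled contigs therefore lose up
to ~2 bp per transcript end. This is invisible at the >80%/>95% coverage
thresholds the metrics use, but it means exact sequence identity with a
truth transcript should not be expected at the termini.

### Multi-k de Bruijn assembly

The internal assembler builds, for each hash length k in the ladder
(default 19, 21, …, 33 — eight runs), an edge-centric de Bruijn graph:
nodes are (k−1)-mers, edges are observed k-mers with multiplicity-weighted
occurrence counts. K-mers spanning an N are never counted. By default the
graph is double-stranded (each read and its reverse complement inserted),
since strand assignment happens downstream; `--single-strand-graph` is
available for pure sense-stranded pools.

Graph cleaning is limited to tip clipping: a dead-end branch of at most
`max_tip_len` edges (default 2k, the usual short-read convention) hanging
off a fork is removed when its mean coverage is strictly below the
strongest competing branch. Clipping iterates to a fixed point and is
idempotent. No bubble popping and no expected-coverage repeat resolution
are attempted: transcript coverage spans orders of magnitude, so
coverage-based repeat heuristics designed for uniform genomic coverage are
unreliable here, and the multi-k union plus merging recovers contiguity
instead. One consequence: a read whose error lies in its central positions
(where every k-mer of the read covers the error) leaves a short isolated
component; these fall below the 100 bp output floor and are dropped.

Unitigs — maximal non-branching paths — are then reported, discarding
those with mean edge coverage below `cov_cutoff` (default 1). Nodes are
walked in lexicographic order and each unitig of a double-stranded graph
is emitted once in its lexicographically smaller orientation, making
output deterministic and independent of any parallel execution order of
the per-k runs.

### Merging the k ladder

Small k joins more (good for low-coverage transcripts, bad for repeats);
large k resolves more (good for deeply covered transcripts). The per-k
pools are therefore complementary, and merging them recovers transcripts
no single k assembles fully.

Merging first removes duplicates: exact, reverse-complement, and contigs
contained as an exact substring of a longer contig in either orientation
(longest representative kept, ties by id). The remaining pool is merged
greedily through suffix-prefix (dovetail) overlaps of at least
`min_overlap` bp (default 40) at identity ≥ `min_identity` (default 0.94),
longest/cleanest first, in either relative orientation, until no
qualifying overlap remains. Overlapping columns take the first contig's
bases: multi-k contigs from one transcript are near-identical, so a full
multiple-alignment consensus would change almost nothing (residual
differences are fixed by polishing anyway); genuinely divergent overlaps
are outside this merger's design. Dovetail candidates are located with an
exact seed of min(16, `min_overlap`) bp at the overlap start, so an
overlap whose first seed-window bases all mismatch can be missed — again
irrelevant for near-identical inputs. The merge is idempotent by sequence
set, and a final containment pass removes redundancy created by merging.

### Read mapping

Finishing needs per-base evidence, produced by an internal
exact-seed-and-extend mapper. Seeds of `seed_k` = 11 bp at three
non-overlapping read offsets guarantee, by pigeonhole, that every
end-to-end placement with ≤ 2 mismatches is found at the default
`max_mismatches` = 2. Each read is assigned its best placement (fewest
mismatches; ties broken by contig id, then position, then '+' strand). A
read with several equally good placements is recorded as a hit for
bookkeeping but contributes nothing to coverage or base counts —
multi-mapped reads would otherwise leak strand evidence between paralogs.

Three evidence tracks accumulate per contig, weighted by read
multiplicity: total depth (all unambiguously mapped reads), fwd/rev
stranded depth (strand-specific reads only; '+' means the read sequence
matches the contig forward), and per-base A/C/G/T counts.

### Contig finishing

1. **Low-coverage split.** Maximal runs where total depth < `min_span_reads`
   (default 3) that are strictly longer than one read length are excised;
   the flanks become separate contigs. Depth counts all mapped reads, not
   only stranded ones. Concatenating fragments and gaps reconstructs the
   input exactly (tested invariant).
2. **Strand split.** Positions are classified by windowed strand purity
   (window 50 bp, purity 0.9): fwd-dominated, rev-dominated, or mixed
   (both orientations present — the signature of overlapping antisense
   transcripts). Zero-coverage positions inherit the nearest classified
   neighbor. Maximal fwd/rev segments become single-stranded contigs; a
   mixed segment is appended to its adjacent same-strand segments so each
   strand's transcript stays contiguous — the overlap region is thereby
   retained on both strands, and a contig that is mixed end-to-end is
   emitted once per strand. The transition point itself is resolved only
   to about half a smoothing window (~25 bp).
3. **Orientation.** Rev-dominated segments are reverse-complemented so all
   stranded-evidence contigs are reported in mRNA sense orientation;
   contigs with no stranded evidence keep assembly orientation and are
   flagged unoriented. Stranded reads are assumed sense-strand
   (read = mRNA); an antisense-protocol library can be handled by swapping
   the pools' interpretation.
4. **Polish.** At every position with depth ≥ `polish_min_depth` (default
   3, reusing the pipeline's evidence threshold) and a unique plurality
   base, the contig base is replaced by the plurality base; ties and
   shallow positions keep the original. Substitutions only — no indel
   realignment — so length is invariant.

Finally contigs shorter than 100 bp are dropped.

## Evaluation framework

Contigs are aligned to the reference by a spliced-lite aligner: exact
14 bp seed matches are grouped into maximal same-diagonal blocks (nearby
same-diagonal blocks merge across mismatch stretches of up to 30 bp,
counting mismatches by direct comparison), then chained colinearly
allowing target gaps up to `max_intron` (default 5,000 bp, appropriate for
intron-poor yeast-like genomes). Chained blocks may overlap by up to one
seed on the query; the successor is trimmed. Alignment score is
s = matches − mismatches, and *all* best-scoring hits per contig are kept,
so a contig matching two loci equally well counts toward both.

* **Accuracy** — % of contigs whose best hit covers > 95% of the contig
  length (aligned query bases, mismatch columns included).
* **Completeness** — % of annotated genes covered at > 80% of their length
  by the union of all contig alignment blocks.
* **Contiguity** — % of genes covered at > 80% by a single contig.
  Contiguity ≤ completeness by construction.
* **Gene fusions** — contigs whose aligned span overlaps ≥ 2 genes, each
  at > 50% of that gene's length; reported as a count and as % of contigs.

All thresholds are strict (exactly 80% is not complete) and configurable.
Gene span is the annotated interval without exon substructure. Contigs
shorter than 100 bp are excluded before evaluation.

A consequence of the fusion definition worth noting: two genuinely
overlapping antisense genes whose overlap exceeds half of one gene's
length make even a perfect single-transcript reconstruction count as a
"fusion". The metric cannot distinguish that geometry from a misassembly.

`gene_coverage_stats` summarizes per-gene mean depth with the median and
the sample variance (n−1), used to quantify how much dereplication and
filtering flatten the coverage distribution across genes.

## Synthetic data generator

The generator emulates the statistical structure of deeply sequenced
yeast-like stranded RNA-Seq: single-exon transcripts placed on a random
genome with 100–300 bp spacers; per-gene depth drawn log-uniform over
`expression_log10_range` (default 10^1.3–10^2.7 ≈ 20–500×, spanning the
orders-of-magnitude spread real libraries show); uniform fragment starts;
i.i.d. substitution errors (default 1%/base — the dominant short-read
error mode); geometric PCR duplication (default mean 1 extra copy per
fragment, errors independent per copy); 34 bp reads; 70% of reads
strand-specific, emitted in sense orientation, the rest in random
orientation; and a configurable fraction of genes (default 10%, matching
the roughly-one-in-ten rate of overlapping antisense neighbors in
well-studied yeast transcriptomes) placed as overlapping antisense pairs.
Defaults for gene count (50) and length (200–1,200 bp) are sized so a
full pipeline run completes in tens of seconds on one core while still
exercising every mechanism.

The drawn antisense overlap is capped at 40% of the shorter paired gene:
beyond 50% the fusion criterion flags even the truth transcripts (see
above), and a cap exactly at half sits on the metric's knife edge where
half-a-window of strand-split boundary blur flips the outcome, so the
generator keeps the intended "not fused" label unambiguous.

Every read carries a truth label (transcript, start, orientation,
duplicate flag, error positions) from which the read is reconstructable
byte-exactly — a tested invariant — and all output is byte-deterministic
under the config seed.

What the generator does **not** model, and hence what passing tests do
not demonstrate: introns and alternative splicing, indel errors,
quality-score profiles, paired-end structure, duplicated genomic regions
and polymorphic alleles, non-uniform fragment-start bias, and empirical
expression distributions. Results on real libraries with those features
will be worse than the harness numbers, particularly for spliced or
paralogous transcripts.

## Numerical and degenerate-input choices

* Determinism everywhere: lexicographic node order in unitig extraction,
  canonical unitig orientation, id-sorted tie-breaks in dedup/merge/
  mapping, sorted final output. Rerunning any stage on identical input is
  byte-identical, independent of scheduling.
* Accuracy of an empty contig set is an error (undefined), not 0%.
* A contig with no stranded coverage is returned whole, strand None.
* Reads shorter than the seed are unmapped; transcripts shorter than the
  read length are skipped with a warning at simulation time.
* k > read length contributes nothing to that assembly run (warned).
* Polishing requires a unique plurality; ties never rewrite.

## Problem sizes used by the test harness

The acceptance harness runs the full pipeline on: 20 genes at uniform 50×
(error-free, duplicate-free); 50 genes under the realistic defaults at
three seeds; and 5 overlapping antisense pairs at 100–200× (plus the same
input with strand splitting disabled, which must fuse pairs). Oracle
checks (k-mer tables, filtering, containment, pileup, interval metrics)
run on randomized instances up to 1,000 reads against literal brute-force
reimplementations kept in the test tree.
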