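"""Assembly evaluation: accuracy, completeness, contiguity, gene fusions.

Contigs are aligned to the reference with a spliced-lite seed-and-chain
aligner (exact seeds, colinear chaining with target gaps bounded by a
maximum intron size, alignment score s = matches - mismatches, all
best-scoring hits kept). The four quality criteria are then:

* accuracy     — fraction of contigs whose best hit aligns more than
                 ``aligned_frac`` (default 0.95) of the contig length;
* completeness — fraction of annotated genes covered at > ``gene_frac``
                 (default 0.8) of their length by the union of all contig
                 alignment blocks;
* contiguity   — fraction of genes covered at > ``gene_frac`` by a single
                 contig;
* gene fusions — contigs overlapping two or more genes, each at more than
                 ``fusion_frac`` (default 0.5) of the gene's length.

Gene span is the annotated gene interval without exon substructure, which
is adequate for intron-poor yeast-like references.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np

from .io_formats import AlignmentHit, Contig, GeneModel, revcomp

__all__ = [
    "EvaluationReport",
    "align_contigs",
    "accuracy",
    "completeness",
    "contiguity",
    "gene_fusions",
    "gene_coverage_stats",
    "evaluate_assembly",
]

#: exact seed length for the contig-vs-reference aligner
_SEED = 14
#: same-diagonal segments separated by at most this many bases are merged
#: into one block, counting mismatches in between
_MAX_MISMATCH_GAP = 30


def _union_length(intervals: Sequence[tuple[int, int]]) -> int:
    total = 0
    end = -1
    for s, e in sorted(intervals):
        if s > end:
            total += e - s
            end = e
        elif e > end:
            total += e - end
            end = e
    return total


def _chain_blocks(blocks: list, max_intron: int) -> tuple[int, list[list]]:
    """Colinear DP chaining; returns (best score, all best chains).

    Adjacent blocks may overlap by up to one seed length on the query
    (chance boundary matches extend exact segments); the successor block is
    trimmed at emission, its trimmed bases treated as matches.
    """
    if not blocks:
        return 0, []
    blocks = sorted(blocks, key=lambda b: (b["qs"], b["ts"]))
    n = len(blocks)
    score = [b["matches"] - b["mism"] for b in blocks]
    best = list(score)
    prev = [-1] * n
    trim = [0] * n
    for i in range(n):
        bi = blocks[i]
        for j in range(i):
            bj = blocks[j]
            ov = bj["qe"] - bi["qs"]
            if ov < 0:
                ov = 0
            if ov > _SEED or bi["qe"] - ov <= bi["qs"]:
                continue
            if not 0 <= (bi["ts"] + ov) - bj["te"] <= max_intron:
                continue
            cand = best[j] + score[i] - ov
            if cand > best[i] or (cand == best[i] and prev[i] == -1):
                best[i] = cand
                prev[i] = j
                trim[i] = ov
    top = max(best)
    chains = []
    used_starts = set()
    for i in range(n):
        if best[i] != top:
            continue
        chain = []
        j = i
        while j != -1:
            b = dict(blocks[j])
            if prev[j] != -1 and trim[j]:
                b["qs"] += trim[j]
                b["ts"] += trim[j]
                b["matches"] = max(0, b["matches"] - trim[j])
            chain.append(b)
            j = prev[j]
        chain.reverse()
        key = tuple((b["qs"], b["ts"]) for b in chain)
        if key not in used_starts:
            used_starts.add(key)
            chains.append(chain)
    return top, chains


def align_contigs(
    contigs: Sequence[Contig],
    reference: Mapping[str, str],
    max_intron: int = 5000,
) -> list[AlignmentHit]:
    """Align contigs to a reference genome, keeping all best-scoring hits.

    Exact seed matches are grouped into maximal same-diagonal blocks
    (nearby same-diagonal blocks merge across short mismatch stretches),
    then chained colinearly allowing target gaps up to ``max_intron``
    between blocks. Per contig, every chain achieving the maximum score
    s = matches - mismatches is returned, in either orientation.
    """
    if not reference:
        raise ValueError("reference must be non-empty")
    index: dict[str, list] = defaultdict(list)
    for chrom, seq in reference.items():
        for pos in range(len(seq) - _SEED + 1):
            kmer = seq[pos : pos + _SEED]
            if "N" not in kmer:
                index[kmer].append((chrom, pos))

    hits: list[AlignmentHit] = []
    for contig in contigs:
        per_contig: list[tuple[int, str, str, list]] = []  # (score, strand, chrom, chain)
        for strand in ("+", "-"):
            query = contig.sequence if strand == "+" else revcomp(contig.sequence)
            qlen = len(query)
            if qlen < _SEED:
                continue
            # seed hits grouped by (chrom, diagonal)
            diag_hits: dict[tuple, list[int]] = defaultdict(list)
            for qpos in range(qlen - _SEED + 1):
                for chrom, tpos in index.get(query[qpos : qpos + _SEED], ()):
                    diag_hits[(chrom, tpos - qpos)].append(qpos)
            blocks_by_chrom: dict[str, list] = defaultdict(list)
            for (chrom, diag), qstarts in diag_hits.items():
                qstarts.sort()
                tseq = reference[chrom]
                # maximal runs of consecutive seed starts -> exact segments
                segs = []
                run_s = qstarts[0]
                prev_q = qstarts[0]
                for q in qstarts[1:] + [None]:
                    if q is not None and q == prev_q + 1:
                        prev_q = q
                        continue
                    segs.append((run_s, prev_q + _SEED))
                    if q is not None:
                        run_s = prev_q = q
                # merge nearby segments on the same diagonal across mismatches
                merged = []
                for qs, qe in segs:
                    if merged and qs - merged[-1]["qe"] <= _MAX_MISMATCH_GAP:
                        blk = merged[-1]
                        gap_q = query[blk["qe"] : qs]
                        gap_t = tseq[blk["qe"] + diag : qs + diag]
                        gm = sum(1 for x, y in zip(gap_q, gap_t) if x == y)
                        blk["matches"] += gm + (qe - qs)
                        blk["mism"] += len(gap_q) - gm
                        blk["qe"] = qe
                        blk["te"] = qe + diag
                    else:
                        merged.append(
                            {
                                "qs": qs,
                                "qe": qe,
                                "ts": qs + diag,
                                "te": qe + diag,
                                "matches": qe - qs,
                                "mism": 0,
                            }
                        )
                blocks_by_chrom[chrom].extend(merged)
            for chrom, blocks in blocks_by_chrom.items():
                top, chains = _chain_blocks(blocks, max_intron)
                for chain in chains:
                    per_contig.append((top, strand, chrom, chain))
        if not per_contig:
            continue
        best_score = max(s for s, _, _, _ in per_contig)
        seen = set()
        for score, strand, chrom, chain in per_contig:
            if score != best_score:
                continue
            blocks = [(b["qs"], b["qe"], b["ts"], b["te"]) for b in chain]
            key = (strand, chrom, tuple(blocks))
            if key in seen:
                continue
            seen.add(key)
            hits.append(
                AlignmentHit(
                    query_id=contig.id,
                    target_id=chrom,
                    strand=strand,
                    matches=sum(b["matches"] for b in chain),
                    mismatches=sum(b["mism"] for b in chain),
                    blocks=blocks,
                )
            )
    return hits


def _hits_by_query(hits: Sequence[AlignmentHit]) -> dict[str, list[AlignmentHit]]:
    by_query: dict[str, list[AlignmentHit]] = defaultdict(list)
    for h in hits:
        by_query[h.query_id].append(h)
    return by_query


def accuracy(
    contigs: Sequence[Contig],
    hits: Sequence[AlignmentHit],
    aligned_frac: float = 0.95,
) -> float:
    """Percentage of contigs aligning over > ``aligned_frac`` of their length."""
    if not contigs:
        raise ValueError("accuracy is undefined for zero contigs")
    by_query = _hits_by_query(hits)
    n_accurate = 0
    for contig in contigs:
        aligned = max(
            (h.aligned_query_bases for h in by_query.get(contig.id, ())), default=0
        )
        if aligned > aligned_frac * len(contig.sequence):
            n_accurate += 1
    return 100.0 * n_accurate / len(contigs)


def _per_gene_covered(
    genes: Sequence[GeneModel], hits: Sequence[AlignmentHit], per_contig: bool
) -> dict[str, float]:
    """Covered fraction per gene, from all contigs or the best single contig."""
    by_chrom: dict[str, list[AlignmentHit]] = defaultdict(list)
    for h in hits:
        by_chrom[h.target_id].append(h)
    fractions: dict[str, float] = {}
    for gene in genes:
        glen = len(gene)
        chrom_hits = by_chrom.get(gene.chrom, ())
        if per_contig:
            best = 0
            by_query = _hits_by_query(chrom_hits)
            for qhits in by_query.values():
                ivals = [
                    (max(ts, gene.start), min(te, gene.end))
                    for h in qhits
                    for _, _, ts, te in h.blocks
                    if ts < gene.end and te > gene.start
                ]
                best = max(best, _union_length(ivals))
            fractions[gene.id] = best / glen
        else:
            ivals = [
                (max(ts, gene.start), min(te, gene.end))
                for h in chrom_hits
                for _, _, ts, te in h.blocks
                if ts < gene.end and te > gene.start
            ]
            fractions[gene.id] = _union_length(ivals) / glen
    return fractions


def completeness(
    genes: Sequence[GeneModel],
    hits: Sequence[AlignmentHit],
    gene_frac: float = 0.8,
) -> tuple[float, dict[str, float]]:
    """Percentage of genes covered at > ``gene_frac`` of their length.

    Coverage is the union of intersections between the gene interval and
    all contig alignment blocks; the threshold is strict (exactly 80% is
    not complete). Returns (percentage, per-gene covered fractions).
    """
    fractions = _per_gene_covered(genes, hits, per_contig=False)
    if not genes:
        return 0.0, fractions
    n = sum(1 for f in fractions.values() if f > gene_frac)
    return 100.0 * n / len(genes), fractions


def contiguity(
    genes: Sequence[GeneModel],
    hits: Sequence[AlignmentHit],
    gene_frac: float = 0.8,
) -> tuple[float, dict[str, float]]:
    """Percentage of genes covered at > ``gene_frac`` by a single contig."""
    fractions = _per_gene_covered(genes, hits, per_contig=True)
    if not genes:
        return 0.0, fractions
    n = sum(1 for f in fractions.values() if f > gene_frac)
    return 100.0 * n / len(genes), fractions


def gene_fusions(
    genes: Sequence[GeneModel],
    hits: Sequence[AlignmentHit],
    fusion_frac: float = 0.5,
    n_contigs: int | None = None,
) -> tuple[int, float, list[str]]:
    """Contigs overlapping >= 2 genes, each at > ``fusion_frac`` of gene length.

    Overlap is the intersection of the contig's aligned target span (union
    of its alignment blocks) with the gene interval. Returns
    (count, percentage of contigs, offending contig ids).
    """
    by_query = _hits_by_query(hits)
    genes_by_chrom: dict[str, list[GeneModel]] = defaultdict(list)
    for g in genes:
        genes_by_chrom[g.chrom].append(g)
    fused: list[str] = []
    for query_id in sorted(by_query):
        qhits = by_query[query_id]
        spans: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for h in qhits:
            spans[h.target_id].extend(h.target_intervals())
        n_over = 0
        for chrom, ivals in spans.items():
            for gene in genes_by_chrom.get(chrom, ()):
                overlap = _union_length(
                    [
                        (max(ts, gene.start), min(te, gene.end))
                        for ts, te in ivals
                        if ts < gene.end and te > gene.start
                    ]
                )
                if overlap > fusion_frac * len(gene):
                    n_over += 1
        if n_over >= 2:
            fused.append(query_id)
    denom = n_contigs if n_contigs is not None else len(by_query)
    pct = 100.0 * len(fused) / denom if denom else 0.0
    return len(fused), pct, fused


def gene_coverage_stats(per_gene_depth: Mapping[str, float]) -> dict:
    """Median and sample variance (n-1) of per-gene mean coverage."""
    depths = np.array(list(per_gene_depth.values()), dtype=float)
    if depths.size == 0:
        return {"median": 0.0, "variance": 0.0, "n_genes": 0}
    variance = float(depths.var(ddof=1)) if depths.size > 1 else 0.0
    return {
        "median": float(np.median(depths)),
        "variance": variance,
        "n_genes": int(depths.size),
    }


@dataclass
class EvaluationReport:
    """The four assembly-quality criteria plus counts."""

    accuracy_pct: float
    completeness_pct: float
    contiguity_pct: float
    fusion_count: int
    fusion_pct: float
    n_contigs: int
    n_genes: int

    def __post_init__(self) -> None:
        for name in ("accuracy_pct", "completeness_pct", "contiguity_pct", "fusion_pct"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} out of [0, 100]: {v}")
        if self.contiguity_pct > self.completeness_pct + 1e-9:
            raise ValueError("contiguity cannot exceed completeness")

    def to_dict(self) -> dict:
        return asdict(self)


def evaluate_assembly(
    contigs: Sequence[Contig],
    reference: Mapping[str, str],
    genes: Sequence[GeneModel],
    aligned_frac: float = 0.95,
    gene_frac: float = 0.8,
    fusion_frac: float = 0.5,
    max_intron: int = 5000,
    min_contig_length: int = 100,
) -> EvaluationReport:
    """Align contigs (>= ``min_contig_length`` bp) and compute all criteria."""
    kept = [c for c in contigs if len(c.sequence) >= min_contig_length]
    hits = align_contigs(kept, reference, max_intron=max_intron)
    acc = accuracy(kept, hits, aligned_frac=aligned_frac)
    comp_pct, _ = completeness(genes, hits, gene_frac=gene_frac)
    cont_pct, _ = contiguity(genes, hits, gene_frac=gene_frac)
    fus_count, fus_pct, _ = gene_fusions(
        genes, hits, fusion_frac=fusion_frac, n_contigs=len(kept)
    )
    return EvaluationReport(
        accuracy_pct=acc,
        completeness_pct=comp_pct,
        contiguity_pct=cont_pct,
        fusion_count=fus_count,
        fusion_pct=fus_pct,
        n_contigs=len(kept),
        n_genes=len(genes),
    )
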