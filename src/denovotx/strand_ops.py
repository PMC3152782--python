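"""Stranded-read post-processing of merged contigs.

Reads are aligned back to the contigs with an exact-seed-and-extend mapper;
the resulting per-base evidence drives four finishing steps, applied in
order: (i) splitting contigs at long stretches supported by fewer than
three mapped reads, (ii) splitting at strandness transition points — the
boundaries between adjacent transcripts on opposite strands, with
both-orientation (antisense overlap) regions retained on both strands,
(iii) orienting each contig to the mRNA sense strand, and (iv) polishing a
majority-vote consensus from per-base A/C/G/T counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io_formats import AlignmentHit, Contig, Read, revcomp

__all__ = [
    "StrandCoverage",
    "MappingResult",
    "map_reads",
    "split_low_coverage",
    "split_strand_transitions",
    "orient_contig",
    "polish_consensus",
    "revcomp_base_counts",
]

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}
#: row permutation that complements a 5-row (A,C,G,T,other) count matrix
_RC_ROWS = np.array([3, 2, 1, 0, 4])


@dataclass
class StrandCoverage:
    """Per-base stranded read depth on one contig.

    ``fwd`` counts stranded reads mapping in contig orientation, ``rev``
    those mapping reverse-complemented; fwd[i] + rev[i] is the total
    stranded mapped-read depth at base i.
    """

    contig_id: str
    fwd: np.ndarray
    rev: np.ndarray

    def __post_init__(self) -> None:
        if len(self.fwd) != len(self.rev):
            raise ValueError("fwd/rev coverage tracks must have equal length")


@dataclass
class MappingResult:
    """Alignments plus accumulated per-contig evidence tracks.

    ``total_depth`` counts all unambiguously mapped reads (stranded or
    not), weighted by multiplicity; ``base_counts`` is a (5, L) matrix of
    A,C,G,T,other counts per position from the same reads.
    """

    hits: list = field(default_factory=list)
    coverage: dict = field(default_factory=dict)  # contig_id -> StrandCoverage
    total_depth: dict = field(default_factory=dict)  # contig_id -> np.ndarray
    base_counts: dict = field(default_factory=dict)  # contig_id -> (5, L) np.ndarray
    n_ambiguous: int = 0
    n_unmapped: int = 0


def _count_mismatches(a: str, b: str, limit: int) -> int:
    if a == b:
        return 0
    n = 0
    for x, y in zip(a, b):
        if x != y:
            n += 1
            if n > limit:
                return n
    return n


def map_reads(
    reads: Sequence[Read],
    contigs: Sequence[Contig],
    seed_k: int = 11,
    max_mismatches: int = 2,
) -> MappingResult:
    """Map each read to its best contig position by exact-seed-and-extend.

    Non-overlapping seeds at three read offsets guarantee (pigeonhole) that
    every end-to-end placement with <= 2 mismatches is found when
    ``max_mismatches=2``. Each read is assigned to at most one position —
    best by mismatch count, ties broken by leftmost contig id then position
    then '+' strand — but reads with several equally good placements are
    ambiguous and contribute nothing to coverage or base counts. Strand '+'
    means the read sequence matches the contig forward; stranded reads
    accumulate the fwd/rev strand-coverage tracks.
    """
    result = MappingResult()
    if not contigs:
        result.n_unmapped = len(reads)
        return result
    index: dict[str, list] = {}
    contig_list = sorted(contigs, key=lambda c: c.id)
    for ci, contig in enumerate(contig_list):
        seq = contig.sequence
        for pos in range(len(seq) - seed_k + 1):
            kmer = seq[pos : pos + seed_k]
            if "N" in kmer:
                continue
            index.setdefault(kmer, []).append((ci, pos))
        L = len(seq)
        result.coverage[contig.id] = StrandCoverage(
            contig.id, np.zeros(L, dtype=np.int64), np.zeros(L, dtype=np.int64)
        )
        result.total_depth[contig.id] = np.zeros(L, dtype=np.int64)
        result.base_counts[contig.id] = np.zeros((5, L), dtype=np.int64)
    agree = {c.id: np.zeros(len(c.sequence), dtype=np.int64) for c in contig_list}

    for read in reads:
        rlen = len(read.sequence)
        if rlen < seed_k:
            result.n_unmapped += 1
            continue
        offsets = sorted({0, (rlen - seed_k) // 2, rlen - seed_k})
        candidates: dict[tuple, int] = {}
        for strand, query in (("+", read.sequence), ("-", revcomp(read.sequence))):
            for off in offsets:
                seed = query[off : off + seed_k]
                for ci, pos in index.get(seed, ()):
                    start = pos - off
                    key = (ci, start, strand)
                    if key in candidates or start < 0:
                        continue
                    cseq = contig_list[ci].sequence
                    if start + rlen > len(cseq):
                        continue
                    mism = _count_mismatches(query, cseq[start : start + rlen], max_mismatches)
                    if mism <= max_mismatches:
                        candidates[key] = mism
        if not candidates:
            result.n_unmapped += 1
            continue
        best_mism = min(candidates.values())
        best = sorted(
            (ci, start, strand)
            for (ci, start, strand), m in candidates.items()
            if m == best_mism
        )
        ci, start, strand = best[0]
        contig = contig_list[ci]
        hit = AlignmentHit(
            query_id=read.id,
            target_id=contig.id,
            strand=strand,
            matches=rlen - best_mism,
            mismatches=best_mism,
            blocks=[(0, rlen, start, start + rlen)],
        )
        result.hits.append(hit)
        if len(best) > 1:
            result.n_ambiguous += 1
            continue  # multi-mapped: no coverage contribution
        w = read.multiplicity
        end = start + rlen
        result.total_depth[contig.id][start:end] += w
        if read.stranded:
            cov = result.coverage[contig.id]
            (cov.fwd if strand == "+" else cov.rev)[start:end] += w
        agree[contig.id][start:end] += w
        if best_mism > 0:
            query = read.sequence if strand == "+" else revcomp(read.sequence)
            cseq = contig.sequence
            counts = result.base_counts[contig.id]
            for i in range(rlen):
                if query[i] != cseq[start + i]:
                    counts[_BASE_IDX.get(query[i], 4), start + i] += w
                    agree[contig.id][start + i] -= w

    # fold the "agrees with contig" depth into the base-count matrix
    for contig in contig_list:
        seq = contig.sequence
        rows = np.fromiter(
            (_BASE_IDX.get(b, 4) for b in seq), dtype=np.int64, count=len(seq)
        )
        result.base_counts[contig.id][rows, np.arange(len(seq))] += agree[contig.id]
    logger.info(
        "map_reads: %d hits, %d ambiguous, %d unmapped",
        len(result.hits),
        result.n_ambiguous,
        result.n_unmapped,
    )
    return result


def split_low_coverage(
    contig: Contig,
    depth: np.ndarray,
    min_reads: int = 3,
    read_length: int = 34,
    min_fragment_len: int = 1,
) -> list[tuple[Contig, tuple[int, int]]]:
    """Excise stretches covered by fewer than ``min_reads`` mapped reads.

    Only runs strictly longer than one read length are excised ("longer
    than" is strict: a run of exactly ``read_length`` is kept). Returns
    (fragment, (start, end)) pairs; concatenating fragments and excised
    gaps reconstructs the contig. Fragments shorter than
    ``min_fragment_len`` are dropped.
    """
    L = len(contig.sequence)
    if len(depth) != L:
        raise ValueError("depth track length must match contig length")
    low = np.asarray(depth) < min_reads
    # maximal low-coverage runs
    cuts: list[tuple[int, int]] = []
    i = 0
    while i < L:
        if low[i]:
            j = i
            while j < L and low[j]:
                j += 1
            if j - i > read_length:
                cuts.append((i, j))
            i = j
        else:
            i += 1
    if not cuts:
        return [(contig, (0, L))]
    fragments: list[tuple[Contig, tuple[int, int]]] = []
    prev = 0
    n = 0
    for s, e in cuts + [(L, L)]:
        if s - prev >= max(1, min_fragment_len):
            frag = Contig(
                id=f"{contig.id}.s{n}",
                sequence=contig.sequence[prev:s],
                provenance=contig.provenance + [("low_cov_split", (prev, s))],
                oriented=contig.oriented,
            )
            fragments.append((frag, (prev, s)))
            n += 1
        prev = e
    return fragments


def _window_sums(track: np.ndarray, window: int) -> np.ndarray:
    """Centered sliding-window sums, window truncated at the contig ends."""
    c = np.concatenate(([0], np.cumsum(track)))
    L = len(track)
    half = window // 2
    lo = np.clip(np.arange(L) - half, 0, L)
    hi = np.clip(np.arange(L) + window - half, 0, L)
    return c[hi] - c[lo]


def split_strand_transitions(
    contig: Contig,
    cov: StrandCoverage,
    window: int = 50,
    purity: float = 0.9,
) -> list[tuple[tuple[int, int], Optional[str]]]:
    """Segment a contig at strandness transition points.

    Positions are classified by windowed strand purity as fwd-dominated,
    rev-dominated or mixed (reads from both orientations: transcript
    overlap); zero-coverage positions inherit the nearest classified
    neighbor. Fwd/rev segments become single-stranded intervals; a mixed
    segment is retained on both strands by appending it to its adjacent
    same-strand segments so each strand's transcript stays contiguous. A
    contig with no stranded evidence is returned whole with strand None.
    """
    L = len(contig.sequence)
    if len(cov.fwd) != L:
        raise ValueError("coverage length must match contig length")
    wf = _window_sums(cov.fwd, window).astype(float)
    wr = _window_sums(cov.rev, window).astype(float)
    tot = wf + wr
    cls = np.zeros(L, dtype=np.int8)  # 0 unclassified, 1 fwd, 2 rev, 3 mixed
    covered = tot > 0
    if not covered.any():
        return [((0, L), None)]
    frac = np.divide(wf, tot, out=np.zeros_like(wf), where=covered)
    cls[covered & (frac >= purity)] = 1
    cls[covered & (frac <= 1.0 - purity)] = 2
    cls[covered & (cls == 0)] = 3
    # nearest-neighbor fill of unclassified positions
    idx = np.arange(L)
    known = idx[cls != 0]
    nearest = known[np.clip(np.searchsorted(known, idx), 0, len(known) - 1)]
    left = known[np.clip(np.searchsorted(known, idx) - 1, 0, len(known) - 1)]
    use_left = np.abs(idx - left) <= np.abs(nearest - idx)
    nearest = np.where(use_left, left, nearest)
    cls = cls[nearest]

    # maximal same-class runs
    runs: list[tuple[int, int, int]] = []
    s = 0
    for i in range(1, L + 1):
        if i == L or cls[i] != cls[s]:
            runs.append((s, i, int(cls[s])))
            s = i

    def collect(target_cls: int) -> list[tuple[int, int]]:
        intervals = []
        for ri, (s, e, c) in enumerate(runs):
            if c != target_cls:
                continue
            lo, hi = s, e
            if ri > 0 and runs[ri - 1][2] == 3:
                lo = runs[ri - 1][0]
            if ri + 1 < len(runs) and runs[ri + 1][2] == 3:
                hi = runs[ri + 1][1]
            intervals.append((lo, hi))
        merged: list[tuple[int, int]] = []
        for lo, hi in sorted(intervals):
            if merged and lo <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
            else:
                merged.append((lo, hi))
        return merged

    out: list[tuple[tuple[int, int], Optional[str]]] = []
    for interval in collect(1):
        out.append((interval, "+"))
    for interval in collect(2):
        out.append((interval, "-"))
    if not out:  # entirely mixed: retain both strands
        out = [((0, L), "+"), ((0, L), "-")]
    out.sort(key=lambda x: (x[0], x[1] or ""))
    return out


def orient_contig(contig: Contig, segment_strand: Optional[str]) -> Contig:
    """Set a contig to mRNA sense orientation.

    Strand '-' segments are reverse-complemented; contigs without stranded
    evidence (strand None) keep assembly orientation with oriented=False.
    """
    if segment_strand == "-":
        return Contig(
            id=contig.id,
            sequence=revcomp(contig.sequence),
            provenance=contig.provenance + [("oriented", "-")],
            oriented=True,
        )
    if segment_strand == "+":
        return Contig(
            id=contig.id,
            sequence=contig.sequence,
            provenance=contig.provenance + [("oriented", "+")],
            oriented=True,
        )
    return Contig(
        id=contig.id,
        sequence=contig.sequence,
        provenance=list(contig.provenance),
        oriented=False,
    )


def revcomp_base_counts(counts: np.ndarray) -> np.ndarray:
    """Transform a (5, L) A,C,G,T,other count matrix to the reverse strand."""
    return counts[_RC_ROWS][:, ::-1]


def polish_consensus(
    contig: Contig, base_counts: np.ndarray, min_depth: int = 3
) -> tuple[Contig, int]:
    """Majority-vote consensus polishing (substitutions only).

    At each position with depth >= ``min_depth`` and a unique plurality
    base, the contig base is replaced by that plurality base; ties and
    shallow positions keep the original. Length never changes. Returns the
    polished contig and the number of corrections.
    """
    L = len(contig.sequence)
    if base_counts.shape != (5, L):
        raise ValueError(f"base_counts must have shape (5, {L})")
    acgt = base_counts[:4]
    depth = base_counts.sum(axis=0)
    best = acgt.argmax(axis=0)
    best_count = acgt.max(axis=0)
    n_at_max = (acgt == best_count).sum(axis=0)
    seq = np.frombuffer(contig.sequence.encode(), dtype="S1").copy()
    plurality = np.frombuffer(_BASES.encode(), dtype="S1")[best]
    replace = (depth >= min_depth) & (n_at_max == 1) & (best_count > 0) & (seq != plurality)
    n_corrections = int(replace.sum())
    if n_corrections:
        seq[replace] = plurality[replace]
    polished = Contig(
        id=contig.id,
        sequence=seq.tobytes().decode(),
        provenance=contig.provenance + [("polished", n_corrections)],
        oriented=contig.oriented,
    )
    return polished, n_corrections
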