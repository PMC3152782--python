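"""Merge multi-k contig pools into one non-redundant assembly.

Duplicate and contained contigs (either orientation) are removed first;
remaining contigs are merged greedily through suffix-prefix (dovetail)
overlaps, longest and cleanest first, until no qualifying overlap remains.
All contigs form a single pool — there is no reference partition.

Overlapping multi-k contigs from the same transcript are near-identical, so
a greedy dovetail layout with the first contig's bases winning in the
overlap is adequate; highly divergent overlaps are a documented limitation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Sequence

from .io_formats import Contig, revcomp

__all__ = ["OverlapParams", "Overlap", "remove_duplicate_contigs", "find_overlaps", "merge_contigs"]

logger = logging.getLogger(__name__)


@dataclass(slots=True)
class OverlapParams:
    """Minimum dovetail length (bp) and identity fraction for merging."""

    min_overlap: int = 40
    min_identity: float = 0.94

    def __post_init__(self) -> None:
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if not 0.0 <= self.min_identity <= 1.0:
            raise ValueError("min_identity must be in [0, 1]")


class Overlap(NamedTuple):
    i: str  # contig whose suffix overlaps
    j: str  # contig whose prefix overlaps
    orientation: str  # '+' = j as given, '-' = j reverse-complemented
    overlap_len: int
    identity: float


def remove_duplicate_contigs(contigs: Sequence[Contig]) -> list[Contig]:
    """Drop exact, reverse-complement and contained duplicates.

    A contig is removed when its sequence (either orientation) occurs as an
    exact substring of a longer kept contig. The longest representative
    survives; ties are broken by lexicographic id. Deterministic.
    """
    ordered = sorted(contigs, key=lambda c: (-len(c.sequence), c.id))
    kept: list[Contig] = []
    for c in ordered:
        seq = c.sequence
        rc = revcomp(seq)
        contained = False
        for other in kept:
            if seq in other.sequence or rc in other.sequence:
                contained = True
                break
        if not contained:
            kept.append(c)
    kept.sort(key=lambda c: c.id)
    return kept


def _identity(a: str, b: str) -> float:
    matches = sum(1 for x, y in zip(a, b) if x == y)
    return matches / len(a) if a else 0.0


def _pair_overlap(a: Contig, b: Contig, orientation: str, params: OverlapParams):
    """Longest qualifying dovetail where a's suffix matches b's prefix.

    Candidate positions are located with an exact prefix seed of
    min(16, min_overlap) bp, so an overlap whose first seed-window bases
    all mismatch can be missed — acceptable for near-identical multi-k
    contigs.
    """
    bseq = b.sequence if orientation == "+" else revcomp(b.sequence)
    aseq = a.sequence
    la, lb = len(aseq), len(bseq)
    if min(la, lb) <= params.min_overlap:
        return None
    seed_len = min(16, params.min_overlap)
    seed = bseq[:seed_len]
    # longest overlap first: smallest start position p with L = la - p;
    # p >= 1 and L < lb keep this a proper dovetail, not a containment
    p = aseq.find(seed, max(1, la - lb + 1))
    while p != -1:
        overlap_len = la - p
        if overlap_len < params.min_overlap:
            return None
        if overlap_len < lb:
            ident = _identity(aseq[p:], bseq[:overlap_len])
            if ident >= params.min_identity:
                return Overlap(a.id, b.id, orientation, overlap_len, ident)
        p = aseq.find(seed, p + 1)
    return None


def find_overlaps(contigs: Sequence[Contig], params: OverlapParams) -> list[Overlap]:
    """All suffix-prefix overlaps >= min_overlap at >= min_identity.

    Both relative orientations are examined; identity = matches / overlap
    length. Only the longest qualifying overlap per (pair, orientation) is
    reported.
    """
    overlaps: list[Overlap] = []
    for a in contigs:
        for b in contigs:
            if a.id == b.id:
                continue
            for orientation in ("+", "-"):
                ovl = _pair_overlap(a, b, orientation, params)
                if ovl is not None:
                    overlaps.append(ovl)
    return overlaps


def merge_contigs(contigs: Sequence[Contig], params: OverlapParams | None = None) -> list[Contig]:
    """Greedy overlap-layout merge of a deduplicated contig pool.

    Overlaps are consumed in order of (length, identity) descending; the
    merged sequence takes the first contig's bases in the overlapping
    columns and unions provenance. Merging repeats until no qualifying
    overlap remains, then contained duplicates created by merging are
    removed. Idempotent by sequence set.
    """
    if params is None:
        params = OverlapParams()
    pool: dict[str, Contig] = {c.id: c for c in remove_duplicate_contigs(contigs)}
    overlaps = find_overlaps(list(pool.values()), params)
    attempted: set[frozenset] = set()
    n_merges = 0
    while overlaps:
        overlaps.sort(key=lambda o: (-o.overlap_len, -o.identity, o.i, o.j))
        ovl = overlaps[0]
        pair = frozenset((ovl.i, ovl.j))
        if pair in attempted or len(pair) == 1:
            overlaps.pop(0)
            continue
        attempted.add(pair)
        a, b = pool[ovl.i], pool[ovl.j]
        bseq = b.sequence if ovl.orientation == "+" else revcomp(b.sequence)
        merged_seq = a.sequence + bseq[ovl.overlap_len :]
        merged = Contig(
            id=a.id,
            sequence=merged_seq,
            provenance=a.provenance + b.provenance + [("merged_with", b.id)],
        )
        del pool[b.id]
        pool[a.id] = merged
        n_merges += 1
        overlaps = [o for o in overlaps if a.id not in (o.i, o.j) and b.id not in (o.i, o.j)]
        others = [c for c in pool.values() if c.id != merged.id]
        for other in others:
            for x, y in ((merged, other), (other, merged)):
                for orientation in ("+", "-"):
                    ovl2 = _pair_overlap(x, y, orientation, params)
                    if ovl2 is not None:
                        overlaps.append(ovl2)
    result = remove_duplicate_contigs(list(pool.values()))
    logger.info("merge: %d merges, %d contigs out", n_merges, len(result))
    return result
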