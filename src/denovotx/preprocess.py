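"""Read dereplication and rare k-mer filtering.

Highly redundant read sets (PCR duplicates, very abundant transcripts) are
collapsed to unique sequences carrying a multiplicity count, and reads
containing rare k-mers — k-mers seen fewer than ``min_count`` times, the
signature of a sequencing error — are removed before assembly. The order of
the two steps matters: a k-mer is more likely to look rare after duplicates
are removed, so both orderings are supported as explicit strategies.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

from .io_formats import Read, revcomp

__all__ = [
    "KmerCountTable",
    "STRATEGIES",
    "dereplicate",
    "count_kmers",
    "filter_rare_kmer_reads",
    "preprocess",
]

logger = logging.getLogger(__name__)

#: recognised filtering strategies: no filter, filter after dereplication,
#: filter before dereplication.
STRATEGIES = ("none", "derep_then_filter", "filter_then_derep")


@dataclass
class KmerCountTable:
    """Hash-table k-mer counts over a read set.

    Keys are plain k-mer strings (no reverse-complement canonicalisation
    unless built with ``canonical=True``); k-mers spanning an N are never
    counted.
    """

    k: int
    counts: dict = field(default_factory=dict)
    canonical: bool = False

    def get(self, kmer: str) -> int:
        if self.canonical:
            rc = revcomp(kmer)
            if rc < kmer:
                kmer = rc
        return self.counts.get(kmer, 0)


def dereplicate(reads: Iterable[Read]) -> list[Read]:
    """Collapse exactly identical read sequences into one representative.

    No reverse-complement collapsing: on stranded data a read and its
    reverse complement are biologically distinct. The representative keeps
    the first-seen read's id and accumulates multiplicity; output order is
    order of first appearance, so total multiplicity mass is conserved.
    """
    table: dict[str, Read] = {}
    out: list[Read] = []
    for r in reads:
        existing = table.get(r.sequence)
        if existing is None:
            rep = Read(r.id, r.sequence, r.quality, r.stranded, r.multiplicity)
            table[r.sequence] = rep
            out.append(rep)
        else:
            existing.multiplicity += r.multiplicity
    return out


def count_kmers(
    reads: Iterable[Read], k: int, weighted: bool = False, canonical: bool = False
) -> KmerCountTable:
    """Count every (N-free) k-mer position across a read set.

    With ``weighted=True`` each read's contribution is multiplied by its
    multiplicity (used when counting over a raw, un-dereplicated pool).
    Reads shorter than k contribute nothing.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts: Counter = Counter()
    for r in reads:
        seq = r.sequence
        n_pos = len(seq) - k + 1
        if n_pos <= 0:
            continue
        w = r.multiplicity if weighted else 1
        has_n = "N" in seq
        for i in range(n_pos):
            kmer = seq[i : i + k]
            if has_n and "N" in kmer:
                continue
            if canonical:
                rc = revcomp(kmer)
                if rc < kmer:
                    kmer = rc
            counts[kmer] += w
    return KmerCountTable(k=k, counts=dict(counts), canonical=canonical)


def filter_rare_kmer_reads(
    reads: Iterable[Read],
    table: KmerCountTable,
    min_count: int = 3,
    drop_short: bool = False,
) -> tuple[list[Read], int]:
    """Drop reads containing any k-mer observed fewer than ``min_count`` times.

    A read is kept iff every one of its N-free k-mers has count >=
    ``min_count`` in ``table``. Reads shorter than k carry no k-mer
    evidence and pass by default (``drop_short=True`` discards them).
    Returns (kept, dropped_count); kept and dropped partition the input.
    """
    k = table.k
    kept: list[Read] = []
    dropped = 0
    for r in reads:
        seq = r.sequence
        n_pos = len(seq) - k + 1
        if n_pos <= 0:
            if drop_short:
                dropped += 1
            else:
                kept.append(r)
            continue
        has_n = "N" in seq
        ok = True
        for i in range(n_pos):
            kmer = seq[i : i + k]
            if has_n and "N" in kmer:
                continue
            if table.get(kmer) < min_count:
                ok = False
                break
        if ok:
            kept.append(r)
        else:
            dropped += 1
    return kept, dropped


def preprocess(
    reads: Iterable[Read],
    strategy: str = "derep_then_filter",
    k: int = 21,
    min_count: int = 3,
    canonical: bool = False,
    drop_short: bool = False,
) -> tuple[list[Read], dict]:
    """Run dereplication and rare-k-mer filtering in the requested order.

    ``derep_then_filter`` counts k-mers unweighted over the unique reads
    (rare = "occurred less than ``min_count`` times in the set of unique
    reads"); ``filter_then_derep`` counts over the raw pool weighted by
    multiplicity, filters, then dereplicates. Returns the surviving unique
    reads plus a stats dict (reads in/out, dropped by filter).
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    reads = list(reads)
    n_in = sum(r.multiplicity for r in reads)
    stats: dict = {"strategy": strategy, "reads_in": n_in}
    if strategy == "none":
        unique = dereplicate(reads)
        stats["dropped_by_filter"] = 0
    elif strategy == "derep_then_filter":
        unique = dereplicate(reads)
        stats["unique_before_filter"] = len(unique)
        table = count_kmers(unique, k, weighted=False, canonical=canonical)
        unique, dropped = filter_rare_kmer_reads(
            unique, table, min_count=min_count, drop_short=drop_short
        )
        stats["dropped_by_filter"] = dropped
    else:  # filter_then_derep
        table = count_kmers(reads, k, weighted=True, canonical=canonical)
        kept, dropped = filter_rare_kmer_reads(
            reads, table, min_count=min_count, drop_short=drop_short
        )
        stats["dropped_by_filter"] = dropped
        unique = dereplicate(kept)
    stats["unique_out"] = len(unique)
    logger.info(
        "preprocess[%s]: %d reads in, %d unique out, %d dropped by filter",
        strategy,
        n_in,
        len(unique),
        stats["dropped_by_filter"],
    )
    return unique, stats
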