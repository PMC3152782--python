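"""Internal multi-k de Bruijn graph assembler.

Nodes are (k-1)-mers, edges are observed k-mers with occurrence counts.
Assembly is deliberately conservative: error tips are clipped, then maximal
non-branching paths (unitigs) are reported. No expected-coverage repeat
resolution is attempted — the multi-k union plus downstream merging
recovers contiguity instead, which is the whole point of running a ladder
of hash lengths and merging the results.

By default the graph is double-stranded (each read and its reverse
complement are inserted) because strand assignment happens downstream from
stranded-read evidence; unitigs are then reported in their lexicographically
smaller orientation and deduplicated, which keeps output deterministic.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io_formats import Contig, Read, revcomp

__all__ = [
    "AssemblyParams",
    "DeBruijnGraph",
    "build_graph",
    "tip_clip",
    "extract_unitigs",
    "assemble",
    "multi_k_assemble",
    "DEFAULT_K_LADDER",
]

logger = logging.getLogger(__name__)

#: eight hash lengths, 19 through 33 in steps of 2
DEFAULT_K_LADDER: tuple[int, ...] = (19, 21, 23, 25, 27, 29, 31, 33)


@dataclass(slots=True)
class AssemblyParams:
    """Hash length and minimum mean unitig coverage for one assembly run."""

    k: int
    cov_cutoff: float = 1.0

    def __post_init__(self) -> None:
        if self.k < 3 or self.k % 2 == 0:
            raise ValueError(f"k must be an odd integer >= 3, got {self.k}")
        if self.cov_cutoff < 0:
            raise ValueError("cov_cutoff must be >= 0")


@dataclass
class DeBruijnGraph:
    """Edge-centric de Bruijn graph: k-mer -> occurrence count."""

    k: int
    edges: dict = field(default_factory=dict)
    double_strand: bool = True

    @property
    def nodes(self) -> set:
        out = set()
        for kmer in self.edges:
            out.add(kmer[:-1])
            out.add(kmer[1:])
        return out

    def total_edge_mass(self) -> int:
        return sum(self.edges.values())


def build_graph(reads: Iterable[Read], k: int, double_strand: bool = True) -> DeBruijnGraph:
    """Count weighted k-mers from reads (and their reverse complements).

    Edge counts equal the multiplicity-weighted number of N-free k-mer
    positions; reads shorter than k contribute nothing.
    """
    if k < 3:
        raise ValueError("k must be >= 3")
    edges: dict[str, int] = defaultdict(int)
    for r in reads:
        w = r.multiplicity
        seqs = (r.sequence, revcomp(r.sequence)) if double_strand else (r.sequence,)
        for seq in seqs:
            n_pos = len(seq) - k + 1
            if n_pos <= 0:
                continue
            if "N" in seq:
                for i in range(n_pos):
                    kmer = seq[i : i + k]
                    if "N" not in kmer:
                        edges[kmer] += w
            else:
                for i in range(n_pos):
                    edges[seq[i : i + k]] += w
    return DeBruijnGraph(k=k, edges=dict(edges), double_strand=double_strand)


def _adjacency(edges: dict):
    """Build out- and in-adjacency: node -> list of (edge_kmer, neighbor, count)."""
    out: dict[str, list] = defaultdict(list)
    inn: dict[str, list] = defaultdict(list)
    for kmer, count in edges.items():
        u, v = kmer[:-1], kmer[1:]
        out[u].append((kmer, v, count))
        inn[v].append((kmer, u, count))
    return out, inn


def tip_clip(graph: DeBruijnGraph, max_tip_len: int | None = None) -> DeBruijnGraph:
    """Remove short, weakly supported dead-end branches.

    A tip is a dead-end path of at most ``max_tip_len`` edges hanging off a
    fork; it is clipped when its mean coverage is strictly below the
    strongest competing branch at that fork. Clipping iterates to a fixed
    point, so the operation is idempotent. Default ``max_tip_len`` is 2k.
    """
    if max_tip_len is None:
        max_tip_len = 2 * graph.k
    if max_tip_len < 0:
        raise ValueError("max_tip_len must be >= 0")
    edges = dict(graph.edges)
    while True:
        out, inn = _adjacency(edges)
        to_remove: set[str] = set()

        def consider(path_edges: list, fork_branches: list, fork_edge: str) -> None:
            if len(path_edges) > max_tip_len:
                return
            competing = max(
                (c for km, _, c in fork_branches if km != fork_edge), default=None
            )
            if competing is None:
                return
            tip_cov = sum(edges[km] for km in path_edges) / len(path_edges)
            if tip_cov < competing:
                to_remove.update(path_edges)

        # out-tips: dead end with no outgoing edges, walk back to a fork
        for node in list(out.keys() | inn.keys()):
            if out.get(node) or len(inn.get(node, ())) != 1:
                continue
            path: list[str] = []
            cur = node
            for _ in range(max_tip_len + 1):
                ins = inn.get(cur, [])
                if len(ins) != 1:
                    break
                kmer, prev, _ = ins[0]
                path.append(kmer)
                prev_out = out.get(prev, [])
                if len(prev_out) > 1:
                    consider(path, prev_out, kmer)
                    break
                cur = prev
        # in-tips: no incoming edges, walk forward to a join
        for node in list(out.keys() | inn.keys()):
            if inn.get(node) or len(out.get(node, ())) != 1:
                continue
            path = []
            cur = node
            for _ in range(max_tip_len + 1):
                outs = out.get(cur, [])
                if len(outs) != 1:
                    break
                kmer, nxt, _ = outs[0]
                path.append(kmer)
                nxt_in = inn.get(nxt, [])
                if len(nxt_in) > 1:
                    consider(path, nxt_in, kmer)
                    break
                cur = nxt

        if not to_remove:
            break
        for kmer in to_remove:
            edges.pop(kmer, None)
    return DeBruijnGraph(k=graph.k, edges=edges, double_strand=graph.double_strand)


def extract_unitigs(graph: DeBruijnGraph, cov_cutoff: float = 1.0) -> list[Contig]:
    """Spell maximal non-branching paths, dropping low-coverage ones.

    A path extends while the current node has exactly one outgoing and the
    next node exactly one incoming edge. Unitigs with mean edge coverage
    below ``cov_cutoff`` are discarded. Nodes are processed in lexicographic
    order and, for a double-stranded graph, each unitig is reported once in
    its lexicographically smaller orientation — output is deterministic.
    """
    out, inn = _adjacency(graph.edges)

    def branching(node: str) -> bool:
        return len(out.get(node, ())) != 1 or len(inn.get(node, ())) != 1

    visited: set[str] = set()
    raw: list[tuple[str, float]] = []

    def walk(first_kmer: str, start_node: str) -> None:
        path = [first_kmer]
        visited.add(first_kmer)
        cur = first_kmer[1:]
        while not branching(cur):
            kmer, nxt, _ = out[cur][0]
            if kmer in visited:
                break
            visited.add(kmer)
            path.append(kmer)
            cur = nxt
        seq = start_node + "".join(km[-1] for km in path)
        cov = sum(graph.edges[km] for km in path) / len(path)
        raw.append((seq, cov))

    for node in sorted(out.keys() | inn.keys()):
        if not branching(node):
            continue
        for kmer, _, _ in sorted(out.get(node, ())):
            if kmer not in visited:
                walk(kmer, node)
    # leftover edges belong to simple cycles
    for kmer in sorted(graph.edges):
        if kmer not in visited:
            walk(kmer, kmer[:-1])

    contigs: list[Contig] = []
    seen: set[str] = set()
    for seq, cov in raw:
        if cov < cov_cutoff:
            continue
        if graph.double_strand:
            seq = min(seq, revcomp(seq))
        if seq in seen:
            continue
        seen.add(seq)
        contigs.append(Contig(id="", sequence=seq))
    contigs.sort(key=lambda c: c.sequence)
    for i, c in enumerate(contigs):
        c.id = f"u{i}"
    return contigs


def assemble(
    reads: Sequence[Read],
    params: AssemblyParams,
    max_tip_len: int | None = None,
    double_strand: bool = True,
) -> list[Contig]:
    """One assembly run: build graph, clip tips, extract unitigs.

    Contigs are tagged with the hash length in their provenance; output is
    deterministic for a given input.
    """
    reads = list(reads)
    if reads:
        min_len = min(len(r.sequence) for r in reads)
        if params.k > min_len:
            logger.warning(
                "k=%d exceeds minimum read length %d; short reads contribute nothing",
                params.k,
                min_len,
            )
    graph = build_graph(reads, params.k, double_strand=double_strand)
    graph = tip_clip(graph, max_tip_len=max_tip_len)
    contigs = extract_unitigs(graph, cov_cutoff=params.cov_cutoff)
    for c in contigs:
        c.id = f"k{params.k}.{c.id}"
        c.provenance = [("assembly_k", params.k)]
    return contigs


def multi_k_assemble(
    reads: Sequence[Read],
    k_values: Sequence[int] = DEFAULT_K_LADDER,
    cov_cutoff: float = 1.0,
    max_tip_len: int | None = None,
    double_strand: bool = True,
) -> list[Contig]:
    """Union of independent single-k assemblies over a ladder of hash lengths.

    Runs are independent, so results do not depend on execution order; the
    union is sorted by contig id for determinism.
    """
    if not k_values:
        raise ValueError("k_values must be non-empty")
    all_contigs: list[Contig] = []
    for k in k_values:
        contigs = assemble(
            reads,
            AssemblyParams(k=k, cov_cutoff=cov_cutoff),
            max_tip_len=max_tip_len,
            double_strand=double_strand,
        )
        logger.info("assembly k=%d: %d unitigs", k, len(contigs))
        all_contigs.extend(contigs)
    all_contigs.sort(key=lambda c: c.id)
    return all_contigs
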