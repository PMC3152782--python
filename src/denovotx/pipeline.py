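"""End-to-end pipeline: preprocess -> multi-k assembly -> merge -> finish.

Stages run in a fixed order with per-stage counts collected into a stats
dict and, when an output directory is given, per-stage FASTA artifacts
written so failures are debuggable. Rerunning with identical inputs and
config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from .assembler import DEFAULT_K_LADDER, multi_k_assemble
from .evaluate import EvaluationReport, evaluate_assembly
from .io_formats import Contig, GeneModel, Read, write_fasta
from .merge import OverlapParams, merge_contigs, remove_duplicate_contigs
from .preprocess import preprocess
from .strand_ops import (
    map_reads,
    orient_contig,
    polish_consensus,
    revcomp_base_counts,
    split_low_coverage,
    split_strand_transitions,
    StrandCoverage,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters; serializable to/from YAML with strict keys."""

    # preprocessing
    filter_strategy: str = "derep_then_filter"
    filter_k: int = 21
    min_kmer_count: int = 3
    canonical_kmers: bool = False
    # assembly
    k_values: tuple = DEFAULT_K_LADDER
    cov_cutoff: float = 1.0
    max_tip_len: Optional[int] = None
    single_strand_graph: bool = False
    # merging
    min_overlap: int = 40
    min_identity: float = 0.94
    # strand ops
    seed_k: int = 11
    max_mismatches: int = 2
    min_span_reads: int = 3
    window: int = 50
    purity: float = 0.9
    polish_min_depth: int = 3
    strand_split: bool = True
    # output / evaluation
    min_contig_length: int = 100
    aligned_frac: float = 0.95
    gene_frac: float = 0.8
    fusion_frac: float = 0.5
    max_intron: int = 5000

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "k_values" in data:
            data = {**data, "k_values": tuple(data["k_values"])}
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["k_values"] = list(d["k_values"])
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "wt") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class PipelineResult:
    contigs: list
    stats: dict
    report: Optional[EvaluationReport] = None
    mapping: object = None
    merged_contigs: list = field(default_factory=list)
    multi_k_contigs: list = field(default_factory=list)

    def contigs_for_k(self, k: int) -> list:
        """The single-k slice of the multi-k assembly union."""
        return [c for c in self.multi_k_contigs if ("assembly_k", k) in c.provenance]


def _finish_contigs(merged, mapping, config, read_length):
    """Low-coverage split -> strand split -> orient -> polish."""
    finished: list[Contig] = []
    n_low_splits = 0
    n_strand_splits = 0
    n_corrections = 0
    for contig in sorted(merged, key=lambda c: c.id):
        depth = mapping.total_depth[contig.id]
        counts = mapping.base_counts[contig.id]
        cov = mapping.coverage[contig.id]
        fragments = split_low_coverage(
            contig,
            depth,
            min_reads=config.min_span_reads,
            read_length=read_length,
        )
        if len(fragments) > 1:
            n_low_splits += len(fragments) - 1
        for frag, (fs, fe) in fragments:
            frag_cov = StrandCoverage(frag.id, cov.fwd[fs:fe], cov.rev[fs:fe])
            if config.strand_split:
                segments = split_strand_transitions(
                    frag, frag_cov, window=config.window, purity=config.purity
                )
            else:
                segments = [((0, len(frag.sequence)), None)]
            if len(segments) > 1:
                n_strand_splits += len(segments) - 1
            for seg_idx, ((ss, se), strand) in enumerate(segments):
                piece = Contig(
                    id=f"{frag.id}.t{seg_idx}" if len(segments) > 1 else frag.id,
                    sequence=frag.sequence[ss:se],
                    provenance=frag.provenance
                    + ([("strand_segment", (ss, se, strand))] if len(segments) > 1 else []),
                )
                piece_counts = counts[:, fs + ss : fs + se]
                oriented = orient_contig(piece, strand)
                if strand == "-":
                    piece_counts = revcomp_base_counts(piece_counts)
                polished, ncorr = polish_consensus(
                    oriented, piece_counts, min_depth=config.polish_min_depth
                )
                n_corrections += ncorr
                finished.append(polished)
    return finished, {
        "low_coverage_splits": n_low_splits,
        "strand_splits": n_strand_splits,
        "polish_corrections": n_corrections,
    }


def run_pipeline(
    stranded_reads: Sequence[Read],
    unstranded_reads: Sequence[Read],
    config: PipelineConfig | None = None,
    genome: Optional[dict] = None,
    genes: Optional[Sequence[GeneModel]] = None,
    outdir=None,
) -> PipelineResult:
    """Run the full assembly pipeline on stranded/non-stranded read pools.

    Read pools are preprocessed independently (dereplication must not merge
    reads across pools, since strandedness is a read attribute), pooled,
    assembled over the k ladder, deduplicated, merged, and finished by
    mapping the preprocessed reads back for splitting, orientation and
    polishing. If ``genome`` and ``genes`` are given, the final contigs
    are evaluated against them.
    """
    if config is None:
        config = PipelineConfig()
    stranded_reads = list(stranded_reads)
    unstranded_reads = list(unstranded_reads)
    if not stranded_reads and not unstranded_reads:
        raise ValueError("at least one read pool must be non-empty")
    if not stranded_reads:
        logger.warning("stranded pool empty: contigs will be emitted unoriented")
    stats: dict = {}

    pooled: list[Read] = []
    for name, pool in (("stranded", stranded_reads), ("unstranded", unstranded_reads)):
        if not pool:
            stats[f"preprocess_{name}"] = {"reads_in": 0, "unique_out": 0}
            continue
        for r in pool:
            r.stranded = name == "stranded"
        unique, pstats = preprocess(
            pool,
            strategy=config.filter_strategy,
            k=config.filter_k,
            min_count=config.min_kmer_count,
            canonical=config.canonical_kmers,
        )
        stats[f"preprocess_{name}"] = pstats
        pooled.extend(unique)
    if not pooled:
        raise ValueError("no reads survived preprocessing")
    # conservation check: dereplication preserves multiplicity mass
    mass_in = len(stranded_reads) + len(unstranded_reads)
    if config.filter_strategy == "none":
        mass_out = sum(r.multiplicity for r in pooled)
        if mass_out != mass_in:
            raise AssertionError("dereplication lost multiplicity mass")

    read_length = max(len(r.sequence) for r in pooled)

    contigs = multi_k_assemble(
        pooled,
        k_values=config.k_values,
        cov_cutoff=config.cov_cutoff,
        max_tip_len=config.max_tip_len,
        double_strand=not config.single_strand_graph,
    )
    stats["assembly"] = {"n_contigs": len(contigs), "k_values": list(config.k_values)}

    deduped = remove_duplicate_contigs(contigs)
    stats["dedup"] = {"n_contigs": len(deduped)}
    merged = merge_contigs(deduped, OverlapParams(config.min_overlap, config.min_identity))
    stats["merge"] = {"n_contigs": len(merged)}

    mapping = map_reads(
        pooled, merged, seed_k=config.seed_k, max_mismatches=config.max_mismatches
    )
    stats["mapping"] = {
        "n_hits": len(mapping.hits),
        "n_ambiguous": mapping.n_ambiguous,
        "n_unmapped": mapping.n_unmapped,
    }

    finished, finish_stats = _finish_contigs(merged, mapping, config, read_length)
    stats["finish"] = finish_stats

    final = [c for c in finished if len(c.sequence) >= config.min_contig_length]
    final.sort(key=lambda c: c.id)
    stats["final"] = {
        "n_contigs": len(final),
        "total_bp": sum(len(c.sequence) for c in final),
        "n_oriented": sum(1 for c in final if c.oriented),
    }

    report = None
    if genome is not None and genes is not None:
        report = evaluate_assembly(
            final,
            genome,
            genes,
            aligned_frac=config.aligned_frac,
            gene_frac=config.gene_frac,
            fusion_frac=config.fusion_frac,
            max_intron=config.max_intron,
            min_contig_length=config.min_contig_length,
        )
        stats["evaluation"] = report.to_dict()

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(deduped, outdir / "assembly_multi_k.fa", min_length=0)
        write_fasta(merged, outdir / "assembly_merged.fa", min_length=0)
        write_fasta(final, outdir / "transcripts.fa", min_length=0)
        with open(outdir / "stats.json", "wt") as fh:
            json.dump(stats, fh, indent=2, default=str)
        config.to_yaml(outdir / "config.yaml")

    return PipelineResult(
        contigs=final,
        stats=stats,
        report=report,
        mapping=mapping,
        merged_contigs=merged,
        multi_k_contigs=contigs,
    )
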