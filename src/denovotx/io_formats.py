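"""Record model and readers/writers for FASTQ, FASTA and GFF3.

All coordinates are 0-based half-open internally; GFF3's 1-based closed
convention is converted at the parsing boundary. ``N`` bases are preserved
through I/O (downstream modules simply never count k-mers spanning an N).
Gzip input is detected by magic bytes, so ``.gz`` and plain files both work
with every reader.
"""

from __future__ import annotations

import gzip
import io
import os
import tempfile
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

from Bio import SeqIO

__all__ = [
    "Read",
    "Contig",
    "GeneModel",
    "AlignmentHit",
    "ParseError",
    "revcomp",
    "read_fastq",
    "read_fasta",
    "write_fasta",
    "write_fastq",
    "read_gff",
    "write_gff",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class ParseError(ValueError):
    """Raised for malformed FASTQ/FASTA/GFF input."""


@dataclass(slots=True)
class Read:
    """A single sequencing read.

    ``stranded`` is True when the library protocol guarantees the read
    sequence is the mRNA sense strand. ``multiplicity`` counts how many
    identical input reads this record represents (1 before dereplication).
    """

    id: str
    sequence: str
    quality: Optional[list[int]] = None
    stranded: bool = False
    multiplicity: int = 1

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"read {self.id!r} has empty sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"read {self.id!r}: quality length {len(self.quality)} != "
                f"sequence length {len(self.sequence)}"
            )
        if self.multiplicity < 1:
            raise ValueError(f"read {self.id!r}: multiplicity must be >= 1")


@dataclass(slots=True)
class Contig:
    """An assembled sequence with provenance.

    ``provenance`` is a list of (tag, details) pairs recording the k values
    a contig came from, merge history and split events. ``oriented`` becomes
    True once the contig has been set to the mRNA sense strand.
    """

    id: str
    sequence: str
    provenance: list = field(default_factory=list)
    oriented: bool = False

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"contig {self.id!r} has empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(slots=True)
class GeneModel:
    """An annotated gene interval, 0-based half-open."""

    id: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"gene {self.id!r}: start {self.start} >= end {self.end}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(slots=True)
class AlignmentHit:
    """A query-vs-target alignment scored as s = matches - mismatches.

    ``blocks`` are (query_start, query_end, target_start, target_end)
    tuples, 0-based half-open, strictly increasing and non-overlapping on
    both sides.
    """

    query_id: str
    target_id: str
    strand: str
    matches: int
    mismatches: int
    blocks: list
    score: int = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.score is None:
            self.score = self.matches - self.mismatches
        elif self.score != self.matches - self.mismatches:
            raise ValueError("score must equal matches - mismatches")

    @property
    def aligned_query_bases(self) -> int:
        return sum(qe - qs for qs, qe, _, _ in self.blocks)

    def target_intervals(self) -> list[tuple[int, int]]:
        return [(ts, te) for _, _, ts, te in self.blocks]


# ---------------------------------------------------------------------------
# file handling


def _open_text(path):
    """Open a possibly-gzipped file as text, sniffing the magic bytes."""
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def read_fastq(path) -> Iterator[Read]:
    """Stream reads from a 4-line-record FASTQ file (plain or gzip).

    Raises :class:`ParseError` naming the failing record index if a record
    is malformed (missing header, quality/sequence length mismatch).
    """
    with _open_text(path) as handle:
        index = 0
        parser = SeqIO.parse(handle, "fastq")
        while True:
            try:
                rec = next(parser)
            except StopIteration:
                return
            except ValueError as exc:
                raise ParseError(f"malformed FASTQ record at index {index}: {exc}") from exc
            yield Read(
                id=rec.id,
                sequence=str(rec.seq).upper(),
                quality=list(rec.letter_annotations["phred_quality"]),
            )
            index += 1


def read_fasta(path) -> Iterator[tuple[str, str]]:
    """Stream (id, sequence) pairs from FASTA; sequences are uppercased."""
    with _open_text(path) as handle:
        saw_header = False
        for line in handle:
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">") and not saw_header:
                raise ParseError("FASTA: sequence data before first '>' header")
            saw_header = True
            break
        handle.seek(0)
        for rec in SeqIO.parse(handle, "fasta"):
            yield rec.id, str(rec.seq).upper()


def write_fasta(records: Iterable[Contig], path, min_length: int = 100) -> int:
    """Write contigs of length >= ``min_length`` as wrapped FASTA; return count."""
    n = 0
    with open(path, "wt") as out:
        for contig in records:
            if len(contig.sequence) < min_length:
                continue
            out.write(f">{contig.id}\n")
            seq = contig.sequence
            for i in range(0, len(seq), 60):
                out.write(seq[i : i + 60] + "\n")
            n += 1
    return n


def write_fastq(reads: Iterable[Read], path, default_quality: int = 40) -> int:
    """Write reads as FASTQ; reads without quality get a constant score."""
    n = 0
    qchar = chr(default_quality + 33)
    with open(path, "wt") as out:
        for r in reads:
            if r.quality is None:
                qual = qchar * len(r.sequence)
            else:
                qual = "".join(chr(q + 33) for q in r.quality)
            out.write(f"@{r.id}\n{r.sequence}\n+\n{qual}\n")
            n += 1
    return n


def read_gff(path, feature_type: str = "gene") -> list[GeneModel]:
    """Parse gene models of ``feature_type`` from a GFF3 file.

    Coordinates are converted from GFF's 1-based closed to 0-based
    half-open. Records with end < start raise :class:`ParseError`.
    """
    import gffutils

    tmp_path = None
    src = os.fspath(path)
    with open(src, "rb") as fh:
        if fh.read(2) == b"\x1f\x8b":
            with gzip.open(src, "rt") as gz, tempfile.NamedTemporaryFile(
                "wt", suffix=".gff3", delete=False
            ) as tmp:
                tmp.write(gz.read())
                tmp_path = tmp.name
            src = tmp_path
    try:
        try:
            db = gffutils.create_db(
                src,
                dbfn=":memory:",
                force=True,
                keep_order=True,
                merge_strategy="create_unique",
            )
        except Exception as exc:  # gffutils raises assorted error types
            raise ParseError(f"malformed GFF3: {exc}") from exc
        models = []
        for feat in db.features_of_type(feature_type):
            if feat.end < feat.start:
                raise ParseError(
                    f"GFF3 feature {feat.id!r}: end {feat.end} < start {feat.start}"
                )
            strand = feat.strand if feat.strand in "+-" else "+"
            models.append(
                GeneModel(
                    id=feat.id,
                    chrom=feat.seqid,
                    strand=strand,
                    start=feat.start - 1,
                    end=feat.end,
                )
            )
        return models
    finally:
        if tmp_path is not None:
            os.unlink(tmp_path)


def write_gff(genes: Iterable[GeneModel], path, source: str = "denovotx") -> int:
    """Write gene models as GFF3 (converting back to 1-based closed)."""
    n = 0
    with open(path, "wt") as out:
        out.write("##gff-version 3\n")
        for g in genes:
            out.write(
                f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.id}\n"
            )
            n += 1
    return n
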