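"""Readers and writers for the on-disk formats the pipeline touches.

All sequence data enters the toolkit through :func:`read_sequences` and all
pairwise-alignment data through :func:`read_tabular_alignments`; downstream
modules only ever see :class:`SeqRecord` and :class:`Hsp` objects and never
re-parse files themselves.

Coordinate conventions
----------------------
Internally every span is 0-based half-open.  Everything written to disk
(tabular alignments, GFF3, TSV reports) is 1-based inclusive, matching the
BLAST outfmt-6 and MISA conventions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

__all__ = [
    "ParseError",
    "SeqRecord",
    "Hsp",
    "read_sequences",
    "write_sequences",
    "read_tabular_alignments",
    "write_tabular_alignments",
    "write_gff3",
    "reverse_complement",
]

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


def _sanitize(raw: str, record_id: str) -> str:
    """Uppercase a sequence and map non-{A,C,G,T,N} symbols to N.

    The scanners downstream define their behaviour only over the 5-letter
    DNA alphabet, so lowercase (soft-masked) bases and IUPAC ambiguity codes
    other than N are normalised to N with a logged warning.
    """
    seq = raw.upper()
    if set(seq) <= _VALID_BASES:
        return seq
    n_bad = sum(1 for c in seq if c not in _VALID_BASES)
    logger.warning(
        "record %s: %d non-ACGTN symbol(s) mapped to N", record_id, n_bad
    )
    return "".join(c if c in _VALID_BASES else "N" for c in seq)


@dataclass
class SeqRecord:
    """One read or transcript.

    ``sequence`` is an uppercase DNA string over {A,C,G,T,N}; ``quality``,
    when present, holds Sanger (offset-33) integer scores, one per base.
    """

    id: str
    sequence: str
    description: str = ""
    quality: list[int] | None = None

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"invalid record id: {self.id!r}")
        self.sequence = _sanitize(self.sequence, self.id)
        if len(self.sequence) < 1:
            raise ValueError(f"record {self.id}: empty sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"record {self.id}: quality length {len(self.quality)} != "
                f"sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def reverse_complement(self, new_id: str | None = None) -> "SeqRecord":
        return SeqRecord(
            id=new_id or self.id,
            sequence=reverse_complement(self.sequence),
            description=self.description,
            quality=None if self.quality is None else self.quality[::-1],
        )


@dataclass
class Hsp:
    """One high-scoring segment pair between two sequences.

    Coordinates are 1-based inclusive with ``q_start <= q_end`` and
    ``s_start <= s_end``; a minus-strand hit (reported by aligners with
    ``sstart > send``) is normalised on ingest and carries ``strand == '-'``.
    """

    query_id: str
    subject_id: str
    identity_pct: float
    aln_len: int
    mismatch: int
    gap_open: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    score: float
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.q_start > self.q_end or self.s_start > self.s_end:
            raise ValueError("HSP coordinates not normalised (start > end)")
        if not (0.0 <= self.identity_pct <= 100.0):
            raise ValueError(f"identity_pct out of range: {self.identity_pct}")
        if self.aln_len <= 0:
            raise ValueError("aln_len must be positive")
        if self.score < 0:
            raise ValueError("score must be non-negative")


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        return format
    suffix = path.suffix.lower()
    if suffix in {".fq", ".fastq"}:
        return "fastq"
    return "fasta"


def read_sequences(path: str | Path, format: str | None = None) -> list[SeqRecord]:
    """Read FASTA or FASTQ into a list of :class:`SeqRecord`, order preserved.

    Multi-line FASTA bodies are concatenated.  Duplicate ids and malformed
    records raise :class:`ParseError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    with open(path) as fh:
        first = ""
        for line in fh:
            if line.strip():
                first = line
                break
        if first:
            expect = ">" if fmt == "fasta" else "@"
            if not first.startswith(expect):
                raise ParseError(
                    f"{path}: line 1: expected {fmt} record starting with "
                    f"{expect!r}, got {first.strip()[:20]!r}"
                )
    records: list[SeqRecord] = []
    seen: set[str] = set()
    try:
        for bio in SeqIO.parse(str(path), fmt):
            if bio.id in seen:
                raise ParseError(f"{path}: duplicate record id {bio.id!r}")
            seen.add(bio.id)
            qual = None
            if "phred_quality" in bio.letter_annotations:
                qual = list(bio.letter_annotations["phred_quality"])
            desc = bio.description
            if desc.startswith(bio.id):
                desc = desc[len(bio.id):].strip()
            records.append(
                SeqRecord(id=bio.id, sequence=str(bio.seq), description=desc,
                          quality=qual)
            )
    except ValueError as exc:
        if isinstance(exc, ParseError):
            raise
        raise ParseError(f"{path}: malformed {fmt} record: {exc}") from exc
    return records


def write_sequences(
    records: Iterable[SeqRecord], path: str | Path, format: str | None = None
) -> None:
    """Write records as FASTA (wrapped at 60 columns) or FASTQ (offset 33)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    bios = []
    for rec in records:
        bio = _BioRecord(Seq(rec.sequence), id=rec.id, description=rec.description)
        if fmt == "fastq":
            qual = rec.quality if rec.quality is not None else [30] * len(rec)
            bio.letter_annotations["phred_quality"] = qual
        bios.append(bio)
    SeqIO.write(bios, str(path), fmt)


_TABULAR_COLS = 12


def read_tabular_alignments(path: str | Path) -> list[Hsp]:
    """Parse 12-column tabular alignments (BLAST outfmt-6 dialect).

    Columns: qid sid pident length mismatch gapopen qstart qend sstart send
    evalue bitscore.  Rows with ``sstart > send`` are normalised to
    ``strand='-'`` with ascending subject coordinates.
    """
    path = Path(path)
    hsps: list[Hsp] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != _TABULAR_COLS:
                raise ParseError(
                    f"{path}: line {lineno}: expected {_TABULAR_COLS} columns, "
                    f"got {len(fields)}"
                )
            try:
                pident = float(fields[2])
                aln_len = int(fields[3])
                mismatch = int(fields[4])
                gap_open = int(fields[5])
                qs, qe, ss, se = (int(x) for x in fields[6:10])
                evalue = float(fields[10])
                score = float(fields[11])
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: non-numeric field: {exc}"
                ) from exc
            strand = "+"
            if ss > se:
                strand = "-"
                ss, se = se, ss
            hsps.append(
                Hsp(
                    query_id=fields[0], subject_id=fields[1],
                    identity_pct=pident, aln_len=aln_len, mismatch=mismatch,
                    gap_open=gap_open, q_start=qs, q_end=qe,
                    s_start=ss, s_end=se, evalue=evalue, score=score,
                    strand=strand,
                )
            )
    return hsps


def write_tabular_alignments(hsps: Iterable[Hsp], path: str | Path) -> None:
    """Write HSPs back to the 12-column dialect (minus strand re-encoded by
    swapping subject coordinates)."""
    with open(path, "w") as fh:
        for h in hsps:
            ss, se = (h.s_end, h.s_start) if h.strand == "-" else (h.s_start, h.s_end)
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.identity_pct:g}\t{h.aln_len}\t"
                f"{h.mismatch}\t{h.gap_open}\t{h.q_start}\t{h.q_end}\t"
                f"{ss}\t{se}\t{h.evalue:g}\t{h.score:g}\n"
            )


def write_gff3(
    rows: Iterable[tuple],
    path: str | Path,
    source: str = "isoscan",
) -> None:
    """Write GFF3 features.

    Each row is ``(seqid, feature_type, start_1based, end_1based, score,
    strand, attributes_dict)``.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for seqid, ftype, start, end, score, strand, attrs in rows:
            attr_str = ";".join(f"{k}={v}" for k, v in attrs.items())
            score_str = "." if score is None else f"{score:g}"
            fh.write(
                f"{seqid}\t{source}\t{ftype}\t{start}\t{end}\t{score_str}\t"
                f"{strand}\t.\t{attr_str}\n"
            )
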