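"""Longest-ORF prediction per transcript with completeness classes.

For every frame of the requested strands, open reading frames are
enumerated using ATG starts and TAA/TAG/TGA stops under the standard
genetic code.  The ends of the transcript open the partial classes: a
reading stretch that reaches a stop without an in-frame start upstream is
5'-partial, one with a start but no stop before the transcript end is
3'-partial, and one with neither is internal.  The single best ORF (the
longest peptide, ties broken complete-first, then forward strand, then
smaller span start) is reported when it reaches ``min_aa`` residues.

This is a deliberate simplification of TransDecoder-style prediction:
there is no hexamer/Markov coding-likelihood rescoring, only the longest
open frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Seq import Seq

from ._utils import percentage
from .io_formats import SeqRecord, reverse_complement

__all__ = [
    "OrfRecord",
    "find_best_orf",
    "find_all_orfs",
    "orf_length_bins",
    "OrfBinReport",
    "orf_gff3_rows",
]

_STOPS = frozenset({"TAA", "TAG", "TGA"})
_COMPLETENESS_RANK = {
    "complete": 3, "5prime_partial": 2, "3prime_partial": 2, "internal": 1,
}


@dataclass
class OrfRecord:
    """One predicted coding region.

    ``start``/``end`` are 1-based inclusive on the forward strand of the
    transcript and include the stop codon when present; ``aa_length``
    excludes the stop.
    """

    transcript_id: str
    strand: str
    frame: int
    start: int
    end: int
    completeness: str
    peptide: str
    aa_length: int

    @property
    def nt_span(self) -> int:
        return self.end - self.start + 1


def _orf_candidates_in_frame(
    seq: str, frame: int, n_codons_min: int
) -> Iterable[tuple[int, int, bool, bool]]:
    """Yield (codon_start_idx, codon_end_idx_exclusive, has_start, has_stop)
    candidate ORFs in one frame of one strand, in codon coordinates.

    ``codon_end`` excludes the stop codon.  Candidates: from the first ATG
    of each stop-free segment, and — for the segment flush with the
    transcript 5' edge — from the frame start itself (the 5'-partial /
    internal candidate).
    """
    n = (len(seq) - frame) // 3
    codons = [seq[frame + 3 * i: frame + 3 * i + 3] for i in range(n)]
    seg_start = 0
    first_segment = True
    i = 0
    while i <= n:
        at_stop = i < n and codons[i] in _STOPS
        at_end = i == n
        if at_stop or at_end:
            has_stop = at_stop
            # candidate anchored at the segment start (transcript edge)
            if first_segment and seg_start < i:
                yield seg_start, i, codons[seg_start] == "ATG", has_stop
            # candidate anchored at the first ATG inside the segment
            for j in range(seg_start, i):
                if codons[j] == "ATG":
                    if not (first_segment and j == seg_start):
                        yield j, i, True, has_stop
                    break
            if at_stop:
                seg_start = i + 1
                first_segment = False
        i += 1


def _classify(has_start: bool, has_stop: bool) -> str:
    if has_start and has_stop:
        return "complete"
    if has_stop:
        return "5prime_partial"
    if has_start:
        return "3prime_partial"
    return "internal"


def find_all_orfs(
    record: SeqRecord, min_aa: int = 100, strands: str = "both"
) -> list[OrfRecord]:
    """All qualifying ORFs (>= min_aa residues) on the requested strands."""
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    if strands not in {"both", "forward"}:
        raise ValueError("strands must be 'both' or 'forward'")
    length = len(record)
    out: list[OrfRecord] = []
    strand_seqs = [("+", record.sequence)]
    if strands == "both":
        strand_seqs.append(("-", reverse_complement(record.sequence)))
    for strand, seq in strand_seqs:
        for frame in range(3):
            for c_start, c_end, has_start, has_stop in _orf_candidates_in_frame(
                seq, frame, min_aa
            ):
                aa_len = c_end - c_start
                if aa_len < min_aa:
                    continue
                nt_start = frame + 3 * c_start
                nt_end = frame + 3 * c_end + (3 if has_stop else 0)
                if strand == "-":
                    o_start, o_end = length - nt_end, length - nt_start
                else:
                    o_start, o_end = nt_start, nt_end
                peptide = str(
                    Seq(seq[frame + 3 * c_start: frame + 3 * c_end]).translate()
                )
                out.append(
                    OrfRecord(
                        transcript_id=record.id, strand=strand, frame=frame,
                        start=o_start + 1, end=o_end,
                        completeness=_classify(has_start, has_stop),
                        peptide=peptide, aa_length=aa_len,
                    )
                )
    return out


def _selection_key(orf: OrfRecord) -> tuple:
    # an open stretch with neither start nor stop (internal) is only a
    # last resort, however long; complete and partial ORFs compete by
    # peptide length, ties complete-first, then forward strand, then
    # smaller span start
    return (
        1 if orf.completeness == "internal" else 0,
        -orf.aa_length,
        -_COMPLETENESS_RANK[orf.completeness],
        0 if orf.strand == "+" else 1,
        orf.start,
    )


def find_best_orf(
    record: SeqRecord, min_aa: int = 100, strands: str = "both"
) -> OrfRecord | None:
    """The single best ORF of a transcript, or None if none reaches min_aa."""
    candidates = find_all_orfs(record, min_aa=min_aa, strands=strands)
    if not candidates:
        return None
    return min(candidates, key=_selection_key)


@dataclass
class OrfBinReport:
    """Counts and percentages of complete-ORF peptide lengths in the bins
    <=1000 aa, (1000, 2000] aa and >2000 aa."""

    counts: tuple[int, int, int]
    percentages: tuple[float, float, float]
    n_complete: int


def orf_length_bins(complete_orfs: Sequence[OrfRecord]) -> OrfBinReport:
    """Bin complete-ORF peptide lengths; percentages use the complete-ORF
    count as denominator (half-up, 2 decimals)."""
    lengths = [o.aa_length for o in complete_orfs]
    bins = [
        sum(1 for x in lengths if x <= 1000),
        sum(1 for x in lengths if 1000 < x <= 2000),
        sum(1 for x in lengths if x > 2000),
    ]
    n = len(lengths)
    pcts = tuple(percentage(b, n, 2) for b in bins) if n else (0.0, 0.0, 0.0)
    return OrfBinReport(counts=tuple(bins), percentages=pcts, n_complete=n)


def orf_gff3_rows(orfs: Sequence[OrfRecord]) -> list[tuple]:
    rows = []
    for o in orfs:
        attrs = {
            "ID": f"{o.transcript_id}.orf",
            "completeness": o.completeness,
            "aa_length": o.aa_length,
        }
        rows.append((o.transcript_id, "CDS", o.start, o.end, None, o.strand, attrs))
    return rows


def write_bin_report_tsv(report: OrfBinReport, path: str | Path) -> None:
    labels = ("<=1000 aa", "1000-2000 aa", ">2000 aa")
    with open(path, "w") as fh:
        fh.write("bin\tcount\tpercent\n")
        for label, count, pct in zip(labels, report.counts, report.percentages):
            fh.write(f"{label}\t{count}\t{pct:.2f}\n")
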