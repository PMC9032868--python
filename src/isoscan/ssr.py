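"""MISA-style microsatellite (SSR) detection and reporting.

A simple sequence repeat is a maximal perfect tandem repeat of a 1-6 bp
motif.  Following the MISA convention, each unit size has its own minimum
repeat count (defaults 10/6/5/5/5/5 for mono- through hexanucleotides),
only complete units count towards the reported span, runs are reported at
their smallest primitive unit (an (AT)n run is never additionally
reported as (ATAT)n/2), N bases terminate any run, and hits separated by
at most ``max_compound_interruption`` bases (default 100) are grouped as
a compound SSR.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ._utils import percentage, round_half_up
from .io_formats import SeqRecord, reverse_complement

__all__ = [
    "SsrThresholds",
    "SsrHit",
    "SsrReport",
    "find_ssrs",
    "assign_compounds",
    "canonical_motif",
    "ssr_report",
    "ssr_gff3_rows",
    "UNIT_NAMES",
]

UNIT_NAMES = {
    1: "Mononucleotide", 2: "Dinucleotide", 3: "Trinucleotide",
    4: "Tetranucleotide", 5: "Pentanucleotide", 6: "Hexanucleotide",
}


@dataclass
class SsrThresholds:
    """Minimum repeat counts per unit size 1..6 and compound spacing."""

    min_repeats: dict[int, int] = field(
        default_factory=lambda: {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}
    )
    max_compound_interruption: int = 100

    def __post_init__(self) -> None:
        if set(self.min_repeats) != {1, 2, 3, 4, 5, 6}:
            raise ValueError("min_repeats must cover unit sizes 1..6")
        if any(v < 1 for v in self.min_repeats.values()):
            raise ValueError("minimum repeat counts must be >= 1")
        if self.max_compound_interruption < 0:
            raise ValueError("max_compound_interruption must be >= 0")

    @classmethod
    def from_definition(cls, definition: str) -> "SsrThresholds":
        """Parse a MISA-style definition string like ``"1-10 2-6 3-5 4-5 5-5 6-5"``."""
        pairs = {}
        for token in definition.split():
            unit, thr = token.split("-")
            pairs[int(unit)] = int(thr)
        return cls(min_repeats=pairs)


@dataclass
class SsrHit:
    """One microsatellite; span is 1-based inclusive on the sequence."""

    seq_id: str
    motif: str
    unit_size: int
    repeats: int
    start: int
    end: int
    compound_id: int | None = None

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _is_primitive(motif: str) -> bool:
    """True when the motif is not itself a repetition of a shorter unit."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


def canonical_motif(motif: str) -> str:
    """Lexicographically minimal string over all rotations of the motif and
    of its reverse complement (so (AG)n and (CT)n share one class)."""
    rc = reverse_complement(motif)
    candidates = [
        s[i:] + s[:i] for s in (motif, rc) for i in range(len(s))
    ]
    return min(candidates)


def find_ssrs(
    record: SeqRecord, thresholds: SsrThresholds | None = None
) -> list[SsrHit]:
    """All maximal perfect tandem repeats meeting the thresholds.

    For each unit size u, maximal intervals with period u are located
    (vectorised ``s[i] == s[i+u]`` run detection); an interval of length L
    yields ``L // u`` complete repeats anchored at the interval start.
    Non-primitive motifs are skipped — such runs are reported at their
    smallest primitive unit instead.  Hits are returned sorted by start
    position then unit size, with compound groups assigned.
    """
    thresholds = thresholds or SsrThresholds()
    seq = record.sequence
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    valid = arr != ord("N")
    hits: list[SsrHit] = []
    for u in range(1, 7):
        min_r = thresholds.min_repeats[u]
        if len(seq) < u * min_r:
            continue
        match = (arr[u:] == arr[:-u]) & valid[u:] & valid[:-u]
        if not match.any():
            continue
        # boundaries of True runs in the match array
        padded = np.concatenate(([False], match, [False]))
        diff = np.diff(padded.astype(np.int8))
        starts = np.nonzero(diff == 1)[0]
        ends = np.nonzero(diff == -1)[0]  # exclusive in match coords
        for k, m_end in zip(starts, ends):
            run_len = int(m_end - k) + u  # bases in the periodic interval
            repeats = run_len // u
            if repeats < min_r:
                continue
            motif = seq[k: k + u]
            if "N" in motif or not _is_primitive(motif):
                continue
            hits.append(
                SsrHit(
                    seq_id=record.id, motif=motif, unit_size=u,
                    repeats=repeats, start=int(k) + 1, end=int(k) + u * repeats,
                )
            )
    hits.sort(key=lambda h: (h.start, h.unit_size))
    assign_compounds(hits, thresholds.max_compound_interruption)
    return hits


def assign_compounds(hits: list[SsrHit], max_interruption: int) -> None:
    """Group hits whose gap to the previous hit is at most the interruption.

    Groups of two or more hits share a ``compound_id`` (numbered from 0
    per sequence); isolated hits keep ``compound_id = None``.
    """
    if not hits:
        return
    group: list[SsrHit] = [hits[0]]
    next_id = 0
    prev_end = hits[0].end

    def _flush(members: list[SsrHit], gid: int) -> int:
        if len(members) > 1:
            for m in members:
                m.compound_id = gid
            return gid + 1
        return gid

    for hit in hits[1:]:
        gap = hit.start - prev_end - 1
        if gap <= max_interruption:
            group.append(hit)
        else:
            next_id = _flush(group, next_id)
            group = [hit]
        prev_end = max(prev_end, hit.end)
    _flush(group, next_id)


@dataclass
class SsrReport:
    """Dataset-level SSR statistics in the shape of a MISA summary table."""

    n_sequences: int
    total_bp: int
    n_ssrs: int
    n_sequences_with_ssr: int
    n_sequences_with_multiple: int
    n_compound_ssrs: int
    counts_by_unit: dict[int, int]
    fractions_by_unit: dict[int, float]
    density_per_mbp: dict[str, float]  # canonical motif -> SSRs per Mbp

    def table_rows(self) -> list[tuple[str, int | float]]:
        rows: list[tuple[str, int | float]] = [
            ("Total number of sequences examined", self.n_sequences),
            ("Total size of examined sequences (bp)", self.total_bp),
            ("Total number of identified SSRs", self.n_ssrs),
            ("Number of SSR-containing sequences", self.n_sequences_with_ssr),
            ("Number of sequences containing more than 1 SSR",
             self.n_sequences_with_multiple),
            ("Number of SSRs present in compound formation", self.n_compound_ssrs),
        ]
        for u in range(1, 7):
            rows.append((UNIT_NAMES[u], self.counts_by_unit.get(u, 0)))
        return rows


def ssr_report(
    hits_by_seq: dict[str, list[SsrHit]],
    records: Sequence[SeqRecord],
) -> SsrReport:
    """Aggregate per-sequence hits into the summary report.

    Per-unit fractions are percentages of the total SSR count (half-up,
    2 decimals, omitted when there are no hits); density is SSRs per Mbp
    of examined sequence per canonical motif class.
    """
    all_hits = [h for hits in hits_by_seq.values() for h in hits]
    total_bp = sum(len(r) for r in records)
    counts_by_unit = Counter(h.unit_size for h in all_hits)
    n_total = len(all_hits)
    fractions = (
        {u: percentage(counts_by_unit.get(u, 0), n_total, 2) for u in range(1, 7)}
        if n_total
        else {}
    )
    motif_counts = Counter(canonical_motif(h.motif) for h in all_hits)
    density = (
        {
            m: round_half_up(c / (total_bp / 1e6), 2)
            for m, c in sorted(motif_counts.items())
        }
        if total_bp
        else {}
    )
    return SsrReport(
        n_sequences=len(records),
        total_bp=total_bp,
        n_ssrs=n_total,
        n_sequences_with_ssr=sum(1 for h in hits_by_seq.values() if h),
        n_sequences_with_multiple=sum(1 for h in hits_by_seq.values() if len(h) > 1),
        n_compound_ssrs=sum(1 for h in all_hits if h.compound_id is not None),
        counts_by_unit={u: counts_by_unit.get(u, 0) for u in range(1, 7)},
        fractions_by_unit=fractions,
        density_per_mbp=density,
    )


def ssr_gff3_rows(hits_by_seq: dict[str, list[SsrHit]]) -> list[tuple]:
    rows = []
    for seq_id in sorted(hits_by_seq):
        for i, h in enumerate(hits_by_seq[seq_id]):
            attrs = {
                "ID": f"{seq_id}.ssr{i}",
                "motif": h.motif,
                "repeats": h.repeats,
            }
            if h.compound_id is not None:
                attrs["compound"] = f"{seq_id}.c{h.compound_id}"
            rows.append((seq_id, "microsatellite", h.start, h.end, None, "+", attrs))
    return rows


def write_ssr_table_tsv(report: SsrReport, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("item\tvalue\n")
        for name, value in report.table_rows():
            fh.write(f"{name}\t{value}\n")
        for u in range(1, 7):
            if u in report.fractions_by_unit:
                fh.write(
                    f"{UNIT_NAMES[u]} fraction (%)\t"
                    f"{report.fractions_by_unit[u]:.2f}\n"
                )


def write_density_tsv(report: SsrReport, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("canonical_motif\tssrs_per_mbp\n")
        for motif, dens in report.density_per_mbp.items():
            fh.write(f"{motif}\t{dens:.2f}\n")
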