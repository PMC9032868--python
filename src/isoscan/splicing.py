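"""Alternative-splicing candidate detection from paired HSPs.

Two isoforms of one gene that differ by an internal block (a retained
intron or a skipped exon) align as two collinear high-scoring segment
pairs: contiguous on one sequence, separated by an unaligned gap on the
other.  An event is called when, for a pair of same-orientation HSPs,

* the two spans on one sequence (the *contiguous* side) overlap or are
  separated by strictly less than ``max_contiguous_overlap`` bases;
* on the other sequence (the *gapped* side) the spans are separated by a
  gap strictly greater than ``min_gap`` bases whose boundaries lie at
  least ``min_end_distance`` bases from both sequence ends;
* optionally, the two HSPs jointly cover at least
  ``min_contiguous_coverage`` of the contiguous sequence.

HSPs can come from a pre-computed 12-column tabular alignment file or be
generated internally with the NCBI ``blastn`` command-line tool (all-vs-all,
the strategy the screening criteria were designed around).
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Sequence

from .io_formats import Hsp, SeqRecord, read_tabular_alignments, write_sequences

__all__ = [
    "AsCriteria",
    "AsEvent",
    "find_hsps",
    "call_as_events",
    "scan_all_pairs",
    "write_events_tsv",
]


@dataclass
class AsCriteria:
    """Thresholds of the AS-gap rule.

    ``max_contiguous_overlap`` bounds (exclusively) both the overlap and
    the separation tolerated on the contiguous side; ``min_gap`` is an
    exclusive lower bound on the gap length; ``min_end_distance`` is an
    inclusive lower bound on the distance of the gap from both sequence
    ends.
    """

    max_contiguous_overlap: int = 5
    min_gap: int = 100
    min_end_distance: int = 100
    require_same_orientation: bool = True
    min_contiguous_coverage: float | None = 0.8

    def __post_init__(self) -> None:
        if min(self.max_contiguous_overlap, self.min_gap, self.min_end_distance) < 0:
            raise ValueError("criteria must be non-negative")
        if self.min_contiguous_coverage is not None and not (
            0.0 < self.min_contiguous_coverage <= 1.0
        ):
            raise ValueError("min_contiguous_coverage must lie in (0, 1]")


@dataclass
class AsEvent:
    """One called AS gap; gap span is 1-based inclusive on the gapped
    sequence."""

    gapped_id: str
    contiguous_id: str
    gap_start: int
    gap_end: int
    gap_len: int
    dist_5prime: int
    dist_3prime: int
    hsps: tuple[Hsp, Hsp]


def _require_blast() -> tuple[str, str]:
    blastn = shutil.which("blastn")
    makedb = shutil.which("makeblastdb")
    if blastn is None or makedb is None:
        raise RuntimeError(
            "blastn/makeblastdb not found on PATH; install NCBI BLAST+ or "
            "supply pre-computed tabular alignments"
        )
    return blastn, makedb


def _blast_pairs(
    queries: Sequence[SeqRecord],
    subjects: Sequence[SeqRecord],
    min_score: float,
    min_identity: float,
) -> list[Hsp]:
    """All-vs-all blastn (task blastn, no dusting) filtered by thresholds."""
    blastn, makedb = _require_blast()
    with tempfile.TemporaryDirectory(prefix="isoscan_blast_") as tmp:
        tmp_path = Path(tmp)
        qfile = tmp_path / "query.fasta"
        sfile = tmp_path / "subject.fasta"
        write_sequences(queries, qfile)
        write_sequences(subjects, sfile)
        subprocess.run(
            [makedb, "-in", str(sfile), "-dbtype", "nucl"],
            check=True, capture_output=True,
        )
        out = tmp_path / "hits.tsv"
        subprocess.run(
            [
                blastn, "-task", "blastn", "-query", str(qfile),
                "-db", str(sfile), "-out", str(out), "-outfmt", "6",
                "-evalue", "1e-5", "-dust", "no", "-soft_masking", "false",
                "-num_threads", "1",
            ],
            check=True, capture_output=True,
        )
        hsps = read_tabular_alignments(out)
    return [
        h for h in hsps
        if h.score >= min_score and h.identity_pct >= min_identity
    ]


def find_hsps(
    a: SeqRecord,
    b: SeqRecord,
    min_score: float = 50.0,
    min_identity: float = 90.0,
) -> list[Hsp]:
    """Local-alignment HSPs between two sequences (both orientations).

    Runs blastn with ``a`` as query and ``b`` as subject and keeps hits
    with bit score >= ``min_score`` and percent identity >=
    ``min_identity``, sorted by query start.
    """
    hsps = _blast_pairs([a], [b], min_score, min_identity)
    hsps.sort(key=lambda h: (h.q_start, h.s_start, -h.score))
    return hsps


def _gap_between(lo_end: int, hi_start: int) -> int:
    """Bases strictly between two 1-based inclusive spans (negative =
    overlap)."""
    return hi_start - lo_end - 1


def _check_pair(
    h1: Hsp,
    h2: Hsp,
    len_q: int,
    len_s: int,
    criteria: AsCriteria,
) -> AsEvent | None:
    """Evaluate one ordered HSP pair; returns an event or None.

    The pair is examined in both roles: query contiguous / subject gapped
    and vice versa; at most one role can satisfy the rule (the gap must
    exceed ``min_gap`` while the other side stays within the overlap
    tolerance).
    """
    if criteria.require_same_orientation and h1.strand != h2.strand:
        return None
    # order the two HSPs along the query
    lo, hi = (h1, h2) if h1.q_start <= h2.q_start else (h2, h1)
    q_sep = _gap_between(lo.q_end, hi.q_start)
    if lo.strand == "+":
        s_lo, s_hi = lo, hi
    else:
        # minus-strand pairs run antiparallel on the subject
        s_lo, s_hi = (lo, hi) if lo.s_start <= hi.s_start else (hi, lo)
    if s_lo is lo:
        s_sep = _gap_between(lo.s_end, hi.s_start)
    else:
        s_sep = _gap_between(hi.s_end, lo.s_start)

    tol = criteria.max_contiguous_overlap
    for gap_side, sep, contiguous_sep in (
        ("subject", s_sep, q_sep),
        ("query", q_sep, s_sep),
    ):
        # contiguous side: |overlap or separation| strictly below tolerance
        if abs(contiguous_sep) >= tol:
            continue
        if sep <= criteria.min_gap:  # gap must be strictly greater
            continue
        if gap_side == "subject":
            gapped_id, contiguous_id = lo.subject_id, lo.query_id
            gap_start = s_lo.s_end + 1
            gap_end = s_hi.s_start - 1
            gapped_len = len_s
            contiguous_len = len_q
            covered = (lo.q_end - lo.q_start + 1) + (hi.q_end - hi.q_start + 1)
        else:
            gapped_id, contiguous_id = lo.query_id, lo.subject_id
            gap_start = lo.q_end + 1
            gap_end = hi.q_start - 1
            gapped_len = len_q
            contiguous_len = len_s
            covered = (
                (lo.s_end - lo.s_start + 1) + (hi.s_end - hi.s_start + 1)
            )
        gap_len = gap_end - gap_start + 1
        dist5 = gap_start - 1
        dist3 = gapped_len - gap_end
        if dist5 < criteria.min_end_distance or dist3 < criteria.min_end_distance:
            continue
        if criteria.min_contiguous_coverage is not None:
            if covered / contiguous_len < criteria.min_contiguous_coverage:
                continue
        return AsEvent(
            gapped_id=gapped_id, contiguous_id=contiguous_id,
            gap_start=gap_start, gap_end=gap_end, gap_len=gap_len,
            dist_5prime=dist5, dist_3prime=dist3, hsps=(lo, hi),
        )
    return None


def call_as_events(
    hsps: Sequence[Hsp],
    len_query: int,
    len_subject: int,
    criteria: AsCriteria | None = None,
) -> list[AsEvent]:
    """Apply the AS-gap rule to every same-orientation HSP pair of one
    transcript pair; events are deduplicated by (gapped id, gap span)."""
    criteria = criteria or AsCriteria()
    if not hsps:
        return []
    pair_ids = {(h.query_id, h.subject_id) for h in hsps}
    if len(pair_ids) > 1:
        raise ValueError(f"HSPs from more than one transcript pair: {pair_ids}")
    events: dict[tuple, AsEvent] = {}
    for h1, h2 in combinations(hsps, 2):
        event = _check_pair(h1, h2, len_query, len_subject, criteria)
        if event is None:
            continue
        key = (event.gapped_id, event.gap_start, event.gap_end)
        if key not in events:
            events[key] = event
    return sorted(
        events.values(), key=lambda e: (e.gapped_id, e.gap_start, e.gap_end)
    )


def scan_all_pairs(
    records: Sequence[SeqRecord],
    criteria: AsCriteria | None = None,
    min_score: float = 50.0,
    min_identity: float = 90.0,
) -> list[AsEvent]:
    """AS events over all unordered pairs of a transcript collection.

    One all-vs-all blastn run generates the HSPs; each unordered pair is
    evaluated once with the lexicographically smaller id as query, so the
    result is independent of input order.
    """
    criteria = criteria or AsCriteria()
    if len(records) < 2:
        return []
    lengths = {r.id: len(r) for r in records}
    if len(lengths) != len(records):
        raise ValueError("duplicate record ids")
    hsps = _blast_pairs(records, records, min_score, min_identity)
    by_pair: dict[tuple[str, str], list[Hsp]] = {}
    for h in hsps:
        if h.query_id == h.subject_id:
            continue
        if h.query_id < h.subject_id:  # canonical orientation only
            by_pair.setdefault((h.query_id, h.subject_id), []).append(h)
    events: list[AsEvent] = []
    for (qid, sid) in sorted(by_pair):
        pair_hsps = sorted(
            by_pair[(qid, sid)], key=lambda h: (h.q_start, h.s_start, -h.score)
        )
        events.extend(
            call_as_events(pair_hsps, lengths[qid], lengths[sid], criteria)
        )
    events.sort(key=lambda e: (e.gapped_id, e.contiguous_id, e.gap_start))
    return events


def write_events_tsv(events: Sequence[AsEvent], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "gapped_id\tcontiguous_id\tgap_start\tgap_end\tgap_len\t"
            "dist_5prime\tdist_3prime\thsp1\thsp2\n"
        )
        for e in events:
            h1, h2 = e.hsps
            fh.write(
                f"{e.gapped_id}\t{e.contiguous_id}\t{e.gap_start}\t{e.gap_end}\t"
                f"{e.gap_len}\t{e.dist_5prime}\t{e.dist_3prime}\t"
                f"{h1.q_start}-{h1.q_end}:{h1.s_start}-{h1.s_end}\t"
                f"{h2.q_start}-{h2.q_end}:{h2.s_start}-{h2.s_end}\n"
            )
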