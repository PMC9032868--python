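"""Full-length non-chimeric (FLNC) read classification.

A full-length cDNA read carries the 5' primer at its head, a poly(A) tail,
and the reverse complement of the 3' primer at its tail; a chimeric read
additionally contains an interior primer copy (two cDNAs fused during
library preparation).  Classification searches primers by edit distance
(long reads indel as well as substitute), detects a tolerant poly(A) run
immediately upstream of the 3' primer, and emits the trimmed insert for
FLNC reads.  Reads whose primers are found in the flipped arrangement are
reverse-complemented before reporting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import edlib

from ._utils import percentage
from .io_formats import SeqRecord, reverse_complement

__all__ = [
    "FlncParams",
    "PrimerPair",
    "FlncRecord",
    "classify_read",
    "classify_reads",
    "flnc_rate",
    "write_classification_tsv",
    "write_summary_json",
]


@dataclass
class FlncParams:
    """Tunables of the classifier.

    ``max_primer_mismatch`` is an edit distance (substitutions + indels);
    ``search_window`` bounds how far from each read end a terminal primer
    may start; the poly(A) run must be at least ``min_polya_len`` bases
    with a non-A fraction of at most ``max_polya_nonA_frac``; inserts
    shorter than ``min_insert_len`` are rejected.
    """

    max_primer_mismatch: int = 3
    search_window: int = 100
    min_polya_len: int = 20
    max_polya_nonA_frac: float = 0.1
    min_insert_len: int = 50

    def __post_init__(self) -> None:
        if min(self.max_primer_mismatch, self.search_window,
               self.min_polya_len, self.min_insert_len) < 0:
            raise ValueError("FlncParams fields must be non-negative")
        if not 0.0 <= self.max_polya_nonA_frac <= 1.0:
            raise ValueError("max_polya_nonA_frac must lie in [0, 1]")


@dataclass
class PrimerPair:
    """5' and 3' cDNA primers, both given 5'->3'.

    In a forward-oriented read the layout is
    ``five + insert + poly(A) + reverse_complement(three)``.
    """

    five: str
    three: str

    def __post_init__(self) -> None:
        if not self.five or not self.three:
            raise ValueError("both primers must be non-empty")
        self.five = self.five.upper()
        self.three = self.three.upper()


@dataclass
class FlncRecord:
    """Classification result for one read.

    Spans are 0-based half-open on the *reported* orientation of the read
    (reads detected in reverse arrangement are flipped first, recorded by
    ``orientation == '-'``).  ``insert`` is present iff the label is FLNC.
    """

    read_id: str
    label: str  # FLNC | NON_FL | CHIMERIC
    orientation: str = "+"
    primer5_span: tuple[int, int] | None = None
    polya_span: tuple[int, int] | None = None
    primer3_span: tuple[int, int] | None = None
    insert: str | None = None


def _find_terminal_primer(
    seq: str, primer: str, end: str, params: FlncParams
) -> tuple[int, int, int] | None:
    """Best edit-distance hit of a primer near one read end.

    Returns ``(start, end, distance)`` (0-based half-open on ``seq``) or
    None.  The hit must start (5' end) or finish (3' end) within
    ``search_window`` of the respective read end.  Among equal-distance
    hits the outermost one is taken.
    """
    k = params.max_primer_mismatch
    w = params.search_window + len(primer) + k
    if end == "5":
        region = seq[: min(w, len(seq))]
        offset = 0
    else:
        offset = max(0, len(seq) - w)
        region = seq[offset:]
    if len(region) < len(primer) - k:
        return None
    res = edlib.align(primer, region, mode="HW", task="locations", k=k)
    if res["editDistance"] < 0:
        return None
    locs = [(s, e + 1) for s, e in res["locations"]]
    if end == "5":
        locs = [(s, e) for s, e in locs if s <= params.search_window]
        if not locs:
            return None
        s, e = min(locs)  # outermost = closest to the 5' end
    else:
        locs = [
            (s, e) for s, e in locs
            if (len(region) - e) <= params.search_window
        ]
        if not locs:
            return None
        s, e = max(locs, key=lambda x: x[1])  # outermost = closest to 3' end
    return s + offset, e + offset, res["editDistance"]


def _polya_run(seq: str, end: int, params: FlncParams) -> tuple[int, int] | None:
    """Tolerant poly(A) run ending at ``end`` (0-based, exclusive).

    The run is the maximal-scoring suffix window under +1 per A / -2 per
    non-A (ties resolved to the shortest window), the same style of rule
    used for quality trimming; it tolerates isolated interruptions while
    anchoring the boundary at the last A-poor position.  The window is
    accepted when it is at least ``min_polya_len`` long with a non-A
    fraction of at most ``max_polya_nonA_frac``; otherwise None.
    """
    best_score = 0
    best_start = end
    score = 0
    start = end
    while start > 0:
        start -= 1
        score += 1 if seq[start] == "A" else -2
        if score > best_score:
            best_score = score
            best_start = start
        elif score < best_score - 60:
            break  # a real tail cannot recover from this deficit
    length = end - best_start
    if length < params.min_polya_len:
        return None
    non_a = sum(1 for c in seq[best_start:end] if c != "A")
    if non_a > params.max_polya_nonA_frac * length:
        return None
    return best_start, end


def _interior_has_primer(
    interior: str, primers: Sequence[str], k: int
) -> bool:
    for p in primers:
        if len(interior) < len(p) - k:
            continue
        res = edlib.align(p, interior, mode="HW", task="distance", k=k)
        if res["editDistance"] >= 0:
            return True
    return False


def _try_orientation(
    seq: str, primers: PrimerPair, params: FlncParams
) -> FlncRecord | None:
    """Attempt full-length detection on one orientation of the sequence."""
    p3rc = reverse_complement(primers.three)
    hit5 = _find_terminal_primer(seq, primers.five, "5", params)
    hit3 = _find_terminal_primer(seq, p3rc, "3", params)
    if hit5 is None or hit3 is None:
        return None
    s5, e5, _ = hit5
    s3, e3, _ = hit3
    if e5 >= s3:
        return None
    polya = _polya_run(seq, s3, params)
    if polya is None:
        return None
    pa_start, pa_end = polya
    if pa_start <= e5:
        return None
    insert = seq[e5:pa_start]
    search = [
        primers.five, primers.three,
        p3rc, reverse_complement(primers.five),
    ]
    if _interior_has_primer(insert, search, params.max_primer_mismatch):
        return FlncRecord(
            read_id="", label="CHIMERIC", primer5_span=(s5, e5),
            polya_span=(pa_start, pa_end), primer3_span=(s3, e3),
        )
    if len(insert) < params.min_insert_len:
        return None
    return FlncRecord(
        read_id="", label="FLNC", primer5_span=(s5, e5),
        polya_span=(pa_start, pa_end), primer3_span=(s3, e3), insert=insert,
    )


def classify_read(
    read: SeqRecord, primers: PrimerPair, params: FlncParams | None = None
) -> FlncRecord:
    """Classify one read as FLNC, NON_FL or CHIMERIC.

    FLNC requires the 5' primer near the head, the reverse-complemented 3'
    primer near the tail, an adjacent qualifying poly(A) run, no interior
    primer occurrence, and a trimmed insert of at least ``min_insert_len``
    bases.  Both orientations are tried; classification is total.
    """
    params = params or FlncParams()
    result = _try_orientation(read.sequence, primers, params)
    orientation = "+"
    if result is None:
        result = _try_orientation(
            reverse_complement(read.sequence), primers, params
        )
        orientation = "-"
    if result is None:
        return FlncRecord(read_id=read.id, label="NON_FL")
    result.read_id = read.id
    result.orientation = orientation
    return result


def classify_reads(
    reads: Iterable[SeqRecord],
    primers: PrimerPair,
    params: FlncParams | None = None,
) -> list[FlncRecord]:
    params = params or FlncParams()
    return [classify_read(r, primers, params) for r in reads]


def flnc_rate(n_flnc: int, n_total: int) -> float:
    """FLNC percentage of total reads, half-up to 2 decimals."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_flnc <= n_total:
        raise ValueError("need 0 <= n_flnc <= n_total")
    return percentage(n_flnc, n_total, 2)


def _span_str(span: tuple[int, int] | None) -> str:
    if span is None:
        return "."
    return f"{span[0] + 1}-{span[1]}"  # report 1-based inclusive


def write_classification_tsv(records: Sequence[FlncRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "read_id\tlabel\torientation\tprimer5\tpolya\tprimer3\tinsert_len\n"
        )
        for r in records:
            ins_len = len(r.insert) if r.insert is not None else 0
            fh.write(
                f"{r.read_id}\t{r.label}\t{r.orientation}\t"
                f"{_span_str(r.primer5_span)}\t{_span_str(r.polya_span)}\t"
                f"{_span_str(r.primer3_span)}\t{ins_len}\n"
            )


def write_summary_json(records: Sequence[FlncRecord], path: str | Path) -> dict:
    n_total = len(records)
    n_flnc = sum(1 for r in records if r.label == "FLNC")
    n_chim = sum(1 for r in records if r.label == "CHIMERIC")
    summary = {
        "n_reads": n_total,
        "n_flnc": n_flnc,
        "n_chimeric": n_chim,
        "n_non_fl": n_total - n_flnc - n_chim,
        "flnc_rate_pct": flnc_rate(n_flnc, n_total) if n_total else 0.0,
    }
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
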