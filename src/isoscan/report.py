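"""Dataset-level summary statistics and percentage arithmetic.

Every percentage in a report is recomputed from integer counts with exact
half-up decimal rounding; no percentage is ever carried through from an
input file.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from ._utils import percentage, round_half_up
from .io_formats import SeqRecord

__all__ = ["LengthSummary", "summarize_lengths", "category_percentages"]


@dataclass
class LengthSummary:
    """Length distribution of a sequence collection.

    The histogram uses fixed-width right-open bins ``[i*w, (i+1)*w)``
    starting at 0 and covering the maximum length; counts sum to ``n``.
    """

    n: int
    total_bp: int
    mean: float  # half-up, 1 decimal
    min: int
    max: int
    n50: int
    bin_width: int
    histogram: list[int]


def summarize_lengths(
    records: Sequence[SeqRecord], bin_width: int = 1000
) -> LengthSummary:
    """Length summary of a collection; empty input gives a zero summary."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lengths = sorted((len(r) for r in records), reverse=True)
    if not lengths:
        return LengthSummary(0, 0, 0.0, 0, 0, 0, bin_width, [])
    total = sum(lengths)
    n50 = 0
    acc = 0
    for x in lengths:
        acc += x
        if acc * 2 >= total:
            n50 = x
            break
    n_bins = max(lengths) // bin_width + 1
    hist = [0] * n_bins
    for x in lengths:
        hist[x // bin_width] += 1
    return LengthSummary(
        n=len(lengths),
        total_bp=total,
        mean=round_half_up(total / len(lengths), 1),
        min=min(lengths),
        max=max(lengths),
        n50=n50,
        bin_width=bin_width,
        histogram=hist,
    )


def category_percentages(
    counts: Mapping[str, int], denominator: int, decimals: int = 2
) -> dict[str, float]:
    """100*count/denominator per label, half-up to ``decimals``.

    Categories need not be exhaustive (their sum may be below the
    denominator, as in benchmark-completeness summaries where
    single-copy/duplicated/fragmented/missing are scored against a fixed
    reference set).
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    for label, count in counts.items():
        if count < 0:
            raise ValueError(f"negative count for {label!r}")
    return {
        label: percentage(count, denominator, decimals)
        for label, count in counts.items()
    }


def write_length_summary_tsv(summary: LengthSummary, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("item\tvalue\n")
        fh.write(f"n_sequences\t{summary.n}\n")
        fh.write(f"total_bp\t{summary.total_bp}\n")
        fh.write(f"mean_length\t{summary.mean:.1f}\n")
        fh.write(f"min_length\t{summary.min}\n")
        fh.write(f"max_length\t{summary.max}\n")
        fh.write(f"n50\t{summary.n50}\n")
        for i, count in enumerate(summary.histogram):
            lo = i * summary.bin_width
            hi = (i + 1) * summary.bin_width
            fh.write(f"bin_{lo}_{hi}\t{count}\n")
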