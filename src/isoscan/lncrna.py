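"""lncRNA screening: length filter, coding-potential votes, consensus set.

Long non-coding RNAs are called as transcripts longer than ``min_len``
(strictly, by default 200 nt) that every supplied coding-potential method
votes non-coding.  External predictor outputs (CPC, CNCI, CPAT, Pfam, ...)
are ingested as two-column TSVs of ``transcript_id <TAB> coding|noncoding``;
a built-in ORF-based heuristic is available as an additional method, so
the consensus can be computed without running any external tool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Sequence

from .io_formats import SeqRecord
from .orf import OrfRecord

__all__ = [
    "MethodCalls",
    "LncrnaCall",
    "builtin_noncoding_call",
    "read_method_calls",
    "consensus_lncrna",
]


@dataclass
class MethodCalls:
    """The set of transcripts one method calls non-coding."""

    method: str
    noncoding_ids: set[str] = field(default_factory=set)


def builtin_noncoding_call(
    record: SeqRecord,
    orf: OrfRecord | None,
    max_orf_aa: int = 100,
    max_orf_coverage: float = 0.5,
) -> bool:
    """ORF-based coding-potential heuristic.

    A transcript is called non-coding when it has no predicted ORF, or its
    best ORF is both short (< ``max_orf_aa`` residues) and covers less
    than ``max_orf_coverage`` of the transcript.
    """
    if orf is None:
        return True
    return (
        orf.aa_length < max_orf_aa
        and orf.nt_span / len(record) < max_orf_coverage
    )


def read_method_calls(method: str, path: str | Path) -> MethodCalls:
    """Read a two-column predictor table (id, coding|noncoding)."""
    noncoding: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2 or fields[1] not in {"coding", "noncoding"}:
                raise ValueError(
                    f"{path}: line {lineno}: expected 'id<TAB>coding|noncoding'"
                )
            if fields[1] == "noncoding":
                noncoding.add(fields[0])
    return MethodCalls(method=method, noncoding_ids=noncoding)


@dataclass
class LncrnaCall:
    transcript_id: str
    length: int
    votes: dict[str, bool]
    consensus: bool


def consensus_lncrna(
    records: Sequence[SeqRecord],
    method_calls: Sequence[MethodCalls],
    min_len: int = 200,
) -> tuple[list[LncrnaCall], dict]:
    """Consensus lncRNA set and Venn-region counts.

    A transcript is a consensus lncRNA when its length is strictly greater
    than ``min_len`` and *every* supplied method votes it non-coding.
    ``venn_counts`` maps each non-empty method combination (a sorted tuple
    of method names) to the number of transcripts voted non-coding by
    exactly that combination, plus per-method totals under ``totals``.
    """
    if not method_calls:
        raise ValueError("at least one method is required")
    known_ids = {r.id for r in records}
    for mc in method_calls:
        unknown = mc.noncoding_ids - known_ids
        if unknown:
            raise ValueError(
                f"method {mc.method}: unknown transcript id "
                f"{sorted(unknown)[0]!r}"
            )
    methods = [mc.method for mc in method_calls]
    by_method = {mc.method: mc.noncoding_ids for mc in method_calls}
    calls: list[LncrnaCall] = []
    for rec in records:
        votes = {m: rec.id in by_method[m] for m in methods}
        consensus = len(rec) > min_len and all(votes.values())
        calls.append(
            LncrnaCall(
                transcript_id=rec.id, length=len(rec), votes=votes,
                consensus=consensus,
            )
        )
    union = set().union(*by_method.values())
    regions: dict[tuple[str, ...], int] = {}
    for r in range(1, len(methods) + 1):
        for combo in combinations(sorted(methods), r):
            combo_set = set(combo)
            count = sum(
                1
                for tid in union
                if {m for m in methods if tid in by_method[m]} == combo_set
            )
            regions[combo] = count
    venn = {
        "regions": regions,
        "totals": {m: len(by_method[m]) for m in methods},
    }
    return calls, venn


def write_votes_tsv(calls: Sequence[LncrnaCall], path: str | Path) -> None:
    if not calls:
        Path(path).write_text("transcript_id\tlength\tconsensus\n")
        return
    methods = sorted(calls[0].votes)
    with open(path, "w") as fh:
        fh.write("transcript_id\tlength\t" + "\t".join(methods) + "\tconsensus\n")
        for c in calls:
            vote_cols = "\t".join(str(int(c.votes[m])) for m in methods)
            fh.write(
                f"{c.transcript_id}\t{c.length}\t{vote_cols}\t{int(c.consensus)}\n"
            )


def write_venn_tsv(venn: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("methods\tcount\n")
        for combo in sorted(venn["regions"]):
            fh.write(f"{'+'.join(combo)}\t{venn['regions'][combo]}\n")
        for method in sorted(venn["totals"]):
            fh.write(f"total:{method}\t{venn['totals'][method]}\n")
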