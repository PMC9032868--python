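"""Greedy identity clustering and redundancy collapse.

Stands in for the usual isoform-level consensus clustering plus CD-HIT
style redundancy removal: records are visited longest first and each one
joins the first existing cluster whose representative it matches at or
above the identity threshold with sufficient coverage of the shorter
sequence, otherwise it founds a new cluster.  The procedure is fully
deterministic (the length-then-id sort makes it independent of input file
order).

Identity is defined over a global alignment with free end gaps (affine
gap costs: match +2, mismatch -3, open -5, extend -2) as
``matches / alignment columns`` between the first and last aligned pair;
coverage is the fraction of the shorter sequence inside that core.  An
optional shared-k-mer prefilter skips alignments that cannot possibly
reach the threshold; it never changes the result, only the running time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import Align

from .io_formats import SeqRecord

__all__ = [
    "Cluster",
    "cluster_sequences",
    "collapse_representatives",
    "alignment_identity",
    "write_membership_tsv",
]


@dataclass
class Cluster:
    representative: str
    members: list[str] = field(default_factory=list)
    identities: dict[str, float] = field(default_factory=dict)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    # free end gaps: the shorter sequence may slide inside the longer one
    aligner.end_deletion_score = 0
    aligner.end_insertion_score = 0
    return aligner


def alignment_identity(seq_a: str, seq_b: str) -> tuple[float, float]:
    """(identity, coverage_of_shorter) of the best free-end-gap alignment.

    Identity is matches / columns over the aligned core (internal gaps
    count as columns, terminal overhangs do not); coverage is the span of
    the shorter sequence inside the core divided by its length.
    """
    aligner = _make_aligner()
    aln = aligner.align(seq_a, seq_b)[0]
    t_blocks, q_blocks = aln.aligned
    if len(t_blocks) == 0:
        return 0.0, 0.0
    matches = 0
    aligned_pairs = 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        aligned_pairs += te - ts
        matches += sum(
            1 for x, y in zip(seq_a[ts:te], seq_b[qs:qe]) if x == y
        )
    t_core = t_blocks[-1][1] - t_blocks[0][0]
    q_core = q_blocks[-1][1] - q_blocks[0][0]
    columns = t_core + q_core - aligned_pairs
    identity = matches / columns if columns else 0.0
    shorter_core = t_core if len(seq_a) <= len(seq_b) else q_core
    coverage = shorter_core / min(len(seq_a), len(seq_b))
    return identity, coverage


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i: i + k] for i in range(len(seq) - k + 1)}


def cluster_sequences(
    records: Sequence[SeqRecord],
    identity_threshold: float = 0.99,
    min_coverage: float = 0.9,
    use_prefilter: bool = True,
    prefilter_k: int = 15,
) -> list[Cluster]:
    """Greedy incremental clustering of sequences by global identity.

    Records are sorted by length descending (ties broken by id); each
    record joins the first representative it matches at
    ``identity >= identity_threshold`` with
    ``coverage of the shorter sequence >= min_coverage``, else founds a
    new cluster.  Returns clusters in foundation order.
    """
    if not 0 < identity_threshold <= 1 or not 0 < min_coverage <= 1:
        raise ValueError("thresholds must lie in (0, 1]")
    ordered = sorted(records, key=lambda r: (-len(r), r.id))
    clusters: list[Cluster] = []
    rep_seqs: list[str] = []
    rep_kmers: list[set[str]] = []
    for rec in ordered:
        rec_kmers = _kmer_set(rec.sequence, prefilter_k) if use_prefilter else set()
        assigned = False
        for idx, cluster in enumerate(clusters):
            rep_seq = rep_seqs[idx]
            if use_prefilter and len(rec) >= prefilter_k and len(rep_seq) >= prefilter_k:
                # at >=99% identity over >=90% of the shorter sequence a
                # shared 15-mer is unavoidable; no shared k-mer => skip
                if not (rec_kmers & rep_kmers[idx]):
                    continue
            identity, coverage = alignment_identity(rep_seq, rec.sequence)
            if identity >= identity_threshold and coverage >= min_coverage:
                cluster.members.append(rec.id)
                cluster.identities[rec.id] = identity
                assigned = True
                break
        if not assigned:
            clusters.append(
                Cluster(representative=rec.id, members=[rec.id],
                        identities={rec.id: 1.0})
            )
            rep_seqs.append(rec.sequence)
            rep_kmers.append(rec_kmers)
    return clusters


def collapse_representatives(
    clusters: Sequence[Cluster], records: Iterable[SeqRecord]
) -> list[SeqRecord]:
    """One representative per cluster: the longest member (ties by id)."""
    by_id = {r.id: r for r in records}
    out: list[SeqRecord] = []
    for cluster in clusters:
        best = min(cluster.members, key=lambda m: (-len(by_id[m]), m))
        rec = by_id[best]
        out.append(SeqRecord(id=rec.id, sequence=rec.sequence,
                             description=rec.description))
    return out


def write_membership_tsv(clusters: Sequence[Cluster], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster\trepresentative\tmember\tidentity_to_representative\n")
        for i, cluster in enumerate(clusters):
            for member in cluster.members:
                fh.write(
                    f"{i}\t{cluster.representative}\t{member}\t"
                    f"{cluster.identities[member]:.4f}\n"
                )
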