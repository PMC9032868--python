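"""Deterministic synthetic full-length-read generator with a truth table.

Emulates the shape of a PacBio Iso-Seq style CCS dataset — ~2 kb-centred
log-normal read lengths, reads carrying 5'/3' cDNA primers and a poly(A)
tail, a mixture of full-length non-chimeric (FLNC), non-full-length and
chimeric reads — together with planted features (microsatellites, ORFs,
isoform families, alternative-splicing pairs) and a machine-readable truth
table so every downstream detector can be scored against known ground
truth.

All randomness flows from a single :class:`numpy.random.Generator`, so a
fixed seed yields byte-identical FASTA and truth-table output.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_formats import SeqRecord, reverse_complement, write_sequences

__all__ = [
    "DEFAULT_PRIMER_5",
    "DEFAULT_PRIMER_3",
    "FixtureConfig",
    "SsrPlantSpec",
    "OrfPlantSpec",
    "FamilySpec",
    "ReadTruth",
    "SsrTruth",
    "OrfTruth",
    "AsPairTruth",
    "TruthTable",
    "make_reads",
    "make_as_pair",
    "make_as_pair_set",
    "make_cluster_families",
    "random_dna",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = ("TAA", "TAG", "TGA")


def _default_primers() -> tuple[str, str]:
    ref = importlib.resources.files("isoscan").joinpath("data/primers.fa")
    seqs = []
    for line in ref.read_text().splitlines():
        if line and not line.startswith(">"):
            seqs.append(line.strip())
    return seqs[0], seqs[1]


DEFAULT_PRIMER_5, DEFAULT_PRIMER_3 = _default_primers()


def random_dna(rng: np.random.Generator, length: int) -> str:
    """Uniform random DNA string of the given length."""
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


@dataclass
class SsrPlantSpec:
    """Plant ``count`` copies of a perfect tandem repeat motif^repeats."""

    motif: str
    repeats: int
    count: int = 1


@dataclass
class OrfPlantSpec:
    """Plant ``count`` complete ORFs of ``aa_length`` residues (incl. Met)."""

    aa_length: int
    count: int = 1


@dataclass
class FamilySpec:
    """Isoform-family structure for the clustering stage."""

    n_families: int = 5
    members_per_family: int = 4
    length_mean: float = 2000.0
    within_identity: float = 0.995
    between_identity: float = 0.85


@dataclass
class FixtureConfig:
    """Study conditions for one synthetic dataset.

    Read lengths are log-normal with the given arithmetic mean/sd (the
    real data this emulates is centred near 2 kb).  Label fractions refer
    to FLNC (both primers + poly(A), no interior primer), reads missing
    the 5' primer, and chimeric reads (two concatenated cDNAs); the
    remainder are full-length reads whose poly(A) tail is too short.
    """

    seed: int = 1
    n_reads: int = 1000
    length_mean: float = 2000.0
    length_sd: float = 1000.0
    primer_5: str = DEFAULT_PRIMER_5
    primer_3: str = DEFAULT_PRIMER_3
    polya_len_mean: float = 30.0
    fraction_flnc: float = 0.80
    fraction_missing_primer: float = 0.15
    fraction_chimeric: float = 0.05
    ssr_plants: list[SsrPlantSpec] = field(default_factory=list)
    orf_plants: list[OrfPlantSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        fracs = (
            self.fraction_flnc,
            self.fraction_missing_primer,
            self.fraction_chimeric,
        )
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ValueError("label fractions must lie in [0, 1]")
        if sum(fracs) > 1.0 + 1e-9:
            raise ValueError("label fractions must sum to at most 1")
        if self.n_reads < 1:
            raise ValueError("n_reads must be positive")
        if self.length_mean <= 0 or self.length_sd <= 0:
            raise ValueError("length parameters must be positive")
        if self.polya_len_mean <= 0:
            raise ValueError("polya_len_mean must be positive")
        for spec in self.ssr_plants:
            if not spec.motif or not set(spec.motif) <= set("ACGT"):
                raise ValueError(f"invalid SSR motif {spec.motif!r}")
            if spec.repeats < 1 or spec.count < 0:
                raise ValueError("SSR plant repeats/count must be positive")
        for spec in self.orf_plants:
            if spec.aa_length < 2 or spec.count < 0:
                raise ValueError("ORF plant aa_length must be >= 2")


@dataclass
class ReadTruth:
    read_id: str
    label: str  # FLNC | NON_FL | CHIMERIC
    insert_start: int  # 1-based inclusive, on the read; 0 when no insert
    insert_end: int
    insert: str


@dataclass
class SsrTruth:
    read_id: str
    motif: str
    repeats: int
    start: int  # 1-based inclusive, on the trimmed insert
    end: int


@dataclass
class OrfTruth:
    read_id: str
    start: int  # 1-based inclusive on the insert, includes the stop codon
    end: int
    aa_length: int
    peptide: str


@dataclass
class AsPairTruth:
    gapped_id: str
    contiguous_id: str
    gap_start: int  # 1-based inclusive on the gapped sequence
    gap_end: int
    gap_len: int
    callable: bool


@dataclass
class TruthTable:
    """Planted features of one synthetic dataset."""

    reads: list[ReadTruth] = field(default_factory=list)
    ssrs: list[SsrTruth] = field(default_factory=list)
    orfs: list[OrfTruth] = field(default_factory=list)
    as_pairs: list[AsPairTruth] = field(default_factory=list)
    families: dict[str, int] = field(default_factory=dict)

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        with open(directory / "truth_reads.tsv", "w") as fh:
            fh.write("read_id\tlabel\tinsert_start\tinsert_end\n")
            for r in self.reads:
                fh.write(f"{r.read_id}\t{r.label}\t{r.insert_start}\t{r.insert_end}\n")
        with open(directory / "truth_ssrs.tsv", "w") as fh:
            fh.write("read_id\tmotif\trepeats\tstart\tend\n")
            for s in self.ssrs:
                fh.write(f"{s.read_id}\t{s.motif}\t{s.repeats}\t{s.start}\t{s.end}\n")
        with open(directory / "truth_orfs.tsv", "w") as fh:
            fh.write("read_id\tstart\tend\taa_length\n")
            for o in self.orfs:
                fh.write(f"{o.read_id}\t{o.start}\t{o.end}\t{o.aa_length}\n")
        with open(directory / "truth_as_pairs.tsv", "w") as fh:
            fh.write("gapped_id\tcontiguous_id\tgap_start\tgap_end\tgap_len\tcallable\n")
            for p in self.as_pairs:
                fh.write(
                    f"{p.gapped_id}\t{p.contiguous_id}\t{p.gap_start}\t"
                    f"{p.gap_end}\t{p.gap_len}\t{int(p.callable)}\n"
                )
        with open(directory / "truth_families.tsv", "w") as fh:
            fh.write("seq_id\tfamily\n")
            for sid in sorted(self.families):
                fh.write(f"{sid}\t{self.families[sid]}\n")


def _lognormal_lengths(
    rng: np.random.Generator, n: int, mean: float, sd: float, minimum: int = 200
) -> np.ndarray:
    """Log-normal lengths with the requested arithmetic mean and sd."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    lengths = rng.lognormal(mu, np.sqrt(sigma2), size=n)
    return np.maximum(lengths.astype(int), minimum)


def _polya(rng: np.random.Generator, mean_len: float) -> str:
    """Poly(A) tail: geometric length around the mean, 0-2 non-A interruptions."""
    length = max(int(rng.geometric(1.0 / mean_len)), 25)
    tail = ["A"] * length
    for pos in rng.choice(length, size=int(rng.integers(0, 3)), replace=False):
        # keep the first and last 5 bases pure A so the tail stays anchored
        if 5 <= pos < length - 5:
            tail[pos] = "CGT"[rng.integers(0, 3)]
    return "".join(tail)


def _plant_ssr(
    insert: str, spec: SsrPlantSpec, rng: np.random.Generator
) -> tuple[str, int, int] | None:
    """Splice motif^repeats into the insert (replacing bases, keeping length).

    The single base on each side of the planted block is rewritten so the
    tandem run can neither extend nor shift its anchor, making the planted
    span exactly the maximal repeat.
    """
    u = len(spec.motif)
    block = spec.motif * spec.repeats
    if len(insert) < len(block) + 20:
        return None
    # keep clear of the last 6 insert bases, which are rewritten later to
    # anchor the poly(A) boundary
    pos = int(rng.integers(5, len(insert) - len(block) - 8))
    left_forbidden = spec.motif[-1]
    right_forbidden = spec.motif[(len(block)) % u]
    left = _other_base(rng, left_forbidden)
    right = _other_base(rng, right_forbidden)
    new = insert[: pos - 1] + left + block + right + insert[pos + len(block) + 1:]
    return new, pos, pos + len(block)  # 0-based half-open span of the block


def _other_base(rng: np.random.Generator, forbidden: str) -> str:
    choices = [b for b in "ACGT" if b != forbidden]
    return choices[int(rng.integers(0, 3))]


def _random_orf(rng: np.random.Generator, aa_length: int) -> str:
    """ATG + (aa_length-1) random non-stop codons + one stop codon."""
    codons = ["ATG"]
    while len(codons) < aa_length:
        c = random_dna(rng, 3)
        if c not in _STOPS:
            codons.append(c)
    codons.append(_STOPS[int(rng.integers(0, 3))])
    return "".join(codons)


def _plant_orf(
    insert: str, spec: OrfPlantSpec, rng: np.random.Generator
) -> tuple[str, int, int] | None:
    """Splice a complete ORF into the insert, preceded by an in-frame stop.

    The in-frame stop immediately upstream prevents a background ATG from
    extending the open reading frame past the planted start.
    """
    orf = _random_orf(rng, spec.aa_length)
    block = "TAA" + orf
    if len(insert) < len(block) + 20:
        return None
    pos = int(rng.integers(3, len(insert) - len(block) - 8))
    new = insert[:pos] + block + insert[pos + len(block):]
    start = pos + 3  # 0-based start of the ATG
    return new, start, start + len(orf)  # half-open, includes stop codon


def make_reads(config: FixtureConfig) -> tuple[list[SeqRecord], TruthTable]:
    """Generate reads with planted features and their truth table.

    FLNC reads are ``primer_5 + insert + poly(A) + revcomp(primer_3)``;
    NON_FL reads lack either the 5' primer or a sufficient poly(A) tail;
    CHIMERIC reads are two full cDNA units concatenated, so they carry an
    interior primer copy.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_reads
    labels = rng.choice(
        ["FLNC", "NON_FL_PRIMER", "CHIMERIC", "NON_FL_POLYA"],
        size=n,
        p=[
            config.fraction_flnc,
            config.fraction_missing_primer,
            config.fraction_chimeric,
            max(
                0.0,
                1.0
                - config.fraction_flnc
                - config.fraction_missing_primer
                - config.fraction_chimeric,
            ),
        ],
    )
    insert_lens = _lognormal_lengths(rng, n, config.length_mean, config.length_sd)
    p5, p3rc = config.primer_5, reverse_complement(config.primer_3)

    records: list[SeqRecord] = []
    truth = TruthTable()
    flnc_indices = [i for i in range(n) if labels[i] == "FLNC"]

    # assign planted features to distinct FLNC reads, SSRs first then ORFs
    plant_assignment: dict[int, tuple[str, object]] = {}
    cursor = 0
    for spec in config.ssr_plants:
        for _ in range(spec.count):
            if cursor < len(flnc_indices):
                plant_assignment[flnc_indices[cursor]] = ("ssr", spec)
                cursor += 1
    for spec in config.orf_plants:
        for _ in range(spec.count):
            if cursor < len(flnc_indices):
                plant_assignment[flnc_indices[cursor]] = ("orf", spec)
                cursor += 1

    for i in range(n):
        rid = f"read_{i:05d}"
        label = labels[i]
        insert = random_dna(rng, int(insert_lens[i]))

        kind_spec = plant_assignment.get(i)
        if kind_spec is not None:
            kind, spec = kind_spec
            if kind == "ssr":
                planted = _plant_ssr(insert, spec, rng)
                if planted is not None:
                    insert, s0, s1 = planted
                    truth.ssrs.append(
                        SsrTruth(
                            read_id=rid, motif=spec.motif, repeats=spec.repeats,
                            start=s0 + 1, end=s1,
                        )
                    )
            else:
                planted = _plant_orf(insert, spec, rng)
                if planted is not None:
                    insert, o0, o1 = planted
                    truth.orfs.append(
                        OrfTruth(
                            read_id=rid, start=o0 + 1, end=o1,
                            aa_length=spec.aa_length, peptide="",
                        )
                    )

        # make the insert/poly(A) boundary unambiguous: a tail detector has
        # no way to distinguish genomic 3'-terminal A's from the tail, so
        # the last six insert bases are forced non-A
        if len(insert) > 6:
            insert = insert[:-6] + "".join(
                _other_base(rng, "A") for _ in range(6)
            )
        tail = _polya(rng, config.polya_len_mean)
        if label == "FLNC":
            seq = p5 + insert + tail + p3rc
            ins_start = len(p5) + 1
            truth.reads.append(
                ReadTruth(rid, "FLNC", ins_start, ins_start + len(insert) - 1, insert)
            )
        elif label == "NON_FL_PRIMER":
            seq = insert + tail + p3rc
            truth.reads.append(ReadTruth(rid, "NON_FL", 0, 0, ""))
        elif label == "NON_FL_POLYA":
            seq = p5 + insert + "A" * 8 + p3rc
            truth.reads.append(ReadTruth(rid, "NON_FL", 0, 0, ""))
        else:  # CHIMERIC: two cDNA units fused end to end
            insert2 = random_dna(rng, max(200, int(insert_lens[i] // 2)))
            tail2 = _polya(rng, config.polya_len_mean)
            seq = p5 + insert + tail + p3rc + p5 + insert2 + tail2 + p3rc
            truth.reads.append(ReadTruth(rid, "CHIMERIC", 0, 0, ""))
        records.append(SeqRecord(id=rid, sequence=seq))
    return records, truth


def make_as_pair(
    total_len: int,
    gap_start: int,
    gap_len: int,
    seed: int = 0,
    id_prefix: str = "as",
    min_gap: int = 100,
    min_end_distance: int = 100,
) -> tuple[SeqRecord, SeqRecord, AsPairTruth]:
    """Construct an isoform pair differing by one internal deletion.

    Sequence B equals sequence A with the 0-based block
    ``[gap_start, gap_start + gap_len)`` removed, so an all-vs-all aligner
    sees two collinear segment pairs separated on A by the retained block
    (the "AS gap").  ``callable`` records whether that geometry satisfies
    the event criteria: gap strictly longer than ``min_gap`` and both gap
    boundaries at least ``min_end_distance`` bases from the ends of A.
    """
    if gap_start < 1 or gap_len < 1 or gap_start + gap_len >= total_len:
        raise ValueError("gap must lie strictly inside the sequence with flanks >= 1")
    rng = np.random.default_rng(seed)
    a_seq = random_dna(rng, total_len)
    b_seq = a_seq[:gap_start] + a_seq[gap_start + gap_len:]
    a = SeqRecord(id=f"{id_prefix}_A", sequence=a_seq)
    b = SeqRecord(id=f"{id_prefix}_B", sequence=b_seq)
    dist5 = gap_start
    dist3 = total_len - (gap_start + gap_len)
    is_callable = (
        gap_len > min_gap and dist5 >= min_end_distance and dist3 >= min_end_distance
    )
    truth = AsPairTruth(
        gapped_id=a.id, contiguous_id=b.id,
        gap_start=gap_start + 1, gap_end=gap_start + gap_len,
        gap_len=gap_len, callable=is_callable,
    )
    return a, b, truth


def make_as_pair_set(
    n_pairs: int = 10,
    n_decoys: int = 50,
    total_len: int = 1000,
    gap_len: int = 200,
    seed: int = 0,
) -> tuple[list[SeqRecord], TruthTable]:
    """A scan-ready mixture of callable AS pairs and unrelated decoys."""
    rng = np.random.default_rng(seed)
    records: list[SeqRecord] = []
    truth = TruthTable()
    for i in range(n_pairs):
        margin = 150
        gap_start = int(rng.integers(margin, total_len - gap_len - margin))
        a, b, pair_truth = make_as_pair(
            total_len, gap_start, gap_len,
            seed=int(rng.integers(0, 2**31 - 1)), id_prefix=f"pair{i:02d}",
        )
        records.extend([a, b])
        truth.as_pairs.append(pair_truth)
    for i in range(n_decoys):
        length = int(rng.integers(total_len // 2, total_len * 2))
        records.append(SeqRecord(id=f"decoy{i:02d}", sequence=random_dna(rng, length)))
    return records, truth


def make_cluster_families(
    spec: FamilySpec, seed: int = 0
) -> tuple[list[SeqRecord], TruthTable]:
    """Generate isoform families of near-identical members.

    Each member carries independent point substitutions at rate
    ``(1 - within_identity) / 2`` relative to its family ancestor, so any
    two members of one family agree at ~``within_identity`` of positions;
    ancestors of different families are independent random sequences, far
    below ``between_identity``.
    """
    if not 0 < spec.between_identity < spec.within_identity <= 1:
        raise ValueError("need 0 < between_identity < within_identity <= 1")
    if spec.n_families < 1 or spec.members_per_family < 1:
        raise ValueError("need at least one family with one member")
    rng = np.random.default_rng(seed)
    mut_rate = (1.0 - spec.within_identity) / 2.0
    records: list[SeqRecord] = []
    truth = TruthTable()
    lengths = _lognormal_lengths(
        rng, spec.n_families, spec.length_mean, spec.length_mean / 4.0, minimum=500
    )
    for f in range(spec.n_families):
        ancestor = np.frombuffer(random_dna(rng, int(lengths[f])).encode(), dtype=np.uint8)
        for m in range(spec.members_per_family):
            member = ancestor.copy()
            hits = np.nonzero(rng.random(len(member)) < mut_rate)[0]
            for pos in hits:
                current = chr(member[pos])
                member[pos] = ord(_other_base(rng, current))
            sid = f"fam{f:02d}_m{m:02d}"
            records.append(SeqRecord(id=sid, sequence=member.tobytes().decode()))
            truth.families[sid] = f
    return records, truth


def write_fixture(
    records: Sequence[SeqRecord], truth: TruthTable, directory: str | Path
) -> None:
    """Write reads.fasta plus the truth-table TSVs into a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_sequences(records, directory / "reads.fasta")
    truth.write(directory)
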