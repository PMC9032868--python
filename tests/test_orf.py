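import pytest
from Bio.Seq import Seq

from isoscan import synthetic
from isoscan.io_formats import SeqRecord, reverse_complement
from isoscan.orf import find_best_orf, orf_length_bins

_STOPS = {"TAA", "TAG", "TGA"}
_RANK = {"complete": 3, "5prime_partial": 2, "3prime_partial": 2, "internal": 1}


def brute_force_best_orf(seq, min_aa, strands="both"):
    """Exhaustive enumeration over every frame, strand and start anchor."""
    n = len(seq)
    candidates = []
    strand_seqs = [("+", seq)]
    if strands == "both":
        strand_seqs.append(("-", reverse_complement(seq)))
    for strand, s in strand_seqs:
        for frame in range(3):
            codons = [s[i: i + 3] for i in range(frame, len(s) - 2, 3)]
            stops = [i for i, c in enumerate(codons) if c in _STOPS]
            for j, codon in enumerate(codons):
                # anchors: any ATG, or the very start of the frame (the
                # transcript edge opens a partial/internal candidate)
                if codon in _STOPS:
                    continue
                if codon != "ATG" and j != 0:
                    continue
                nxt = [i for i in stops if i >= j]
                end = nxt[0] if nxt else len(codons)
                has_stop = bool(nxt)
                aa = end - j
                if aa < min_aa:
                    continue
                has_start = codon == "ATG"
                if has_start and has_stop:
                    cls = "complete"
                elif has_stop:
                    cls = "5prime_partial"
                elif has_start:
                    cls = "3prime_partial"
                else:
                    cls = "internal"
                nt_start = frame + 3 * j
                nt_end = frame + 3 * end + (3 if has_stop else 0)
                if strand == "-":
                    o_start, o_end = n - nt_end, n - nt_start
                else:
                    o_start, o_end = nt_start, nt_end
                candidates.append(
                    (cls, aa, strand, o_start + 1, o_end,
                     s[frame + 3 * j: frame + 3 * end])
                )
    if not candidates:
        return None
    return min(
        candidates,
        key=lambda c: (
            1 if c[0] == "internal" else 0, -c[1], -_RANK[c[0]],
            0 if c[2] == "+" else 1, c[3],
        ),
    )


class TestFindBestOrf:
    def test_minimal_complete_orf(self):
        o = find_best_orf(SeqRecord(id="x", sequence="ATGAAATAA"), min_aa=1)
        assert (o.peptide, o.completeness, o.start, o.end) == ("MK", "complete", 1, 9)

    def test_missing_stop_is_three_prime_partial(self):
        o = find_best_orf(SeqRecord(id="x", sequence="ATGAAAAAA"), min_aa=1)
        assert (o.peptide, o.completeness) == ("MKK", "3prime_partial")

    def test_reverse_complement_found_on_minus_strand(self):
        seq = reverse_complement("ATGAAATAA")
        o = find_best_orf(SeqRecord(id="x", sequence=seq), min_aa=1)
        assert (o.peptide, o.completeness, o.strand) == ("MK", "complete", "-")

    def test_no_orf_returns_none(self):
        assert find_best_orf(SeqRecord(id="x", sequence="CCCCCCCC"), min_aa=5) is None

    def test_five_prime_partial_at_transcript_edge(self):
        # no ATG before the stop, frame starts at the transcript edge
        o = find_best_orf(SeqRecord(id="x", sequence="AAAAAATAGCCC"), min_aa=2)
        assert o.completeness == "5prime_partial"
        assert o.start == 1

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(100):
            length = int(rng.integers(200, 1001))
            seq = synthetic.random_dna(rng, length)
            ours = find_best_orf(SeqRecord(id="r", sequence=seq), min_aa=25)
            oracle = brute_force_best_orf(seq, min_aa=25)
            if oracle is None:
                assert ours is None
                continue
            cls, aa, strand, start, end, nt = oracle
            assert (ours.completeness, ours.aa_length, ours.strand,
                    ours.start, ours.end) == (cls, aa, strand, start, end)

    def test_peptide_is_translation_of_span(self, rng):
        for _ in range(20):
            seq = synthetic.random_dna(rng, 600)
            o = find_best_orf(SeqRecord(id="r", sequence=seq), min_aa=20)
            if o is None:
                continue
            nt = seq[o.start - 1: o.end]
            if o.strand == "-":
                nt = reverse_complement(nt)
            if o.completeness in {"complete", "5prime_partial"}:
                nt = nt[:-3]  # drop the stop codon
            assert str(Seq(nt).translate()) == o.peptide

    def test_planted_orf_recovered(self):
        cfg = synthetic.FixtureConfig(
            seed=31, n_reads=30,
            orf_plants=[synthetic.OrfPlantSpec(aa_length=250, count=10)],
        )
        _, truth = synthetic.make_reads(cfg)
        inserts = {t.read_id: t.insert for t in truth.reads if t.label == "FLNC"}
        assert truth.orfs
        for planted in truth.orfs:
            rec = SeqRecord(id=planted.read_id, sequence=inserts[planted.read_id])
            o = find_best_orf(rec, min_aa=100)
            assert o is not None
            assert (o.start, o.end, o.strand, o.completeness) == (
                planted.start, planted.end, "+", "complete",
            )


class TestOrfLengthBins:
    def test_boundary_placement(self):
        orfs = [_complete(aa) for aa in (999, 1000, 1001, 2001)]
        report = orf_length_bins(orfs)
        assert report.counts == (2, 1, 1)

    def test_single_orf_is_100_percent(self):
        report = orf_length_bins([_complete(10)])
        assert report.percentages == (100.0, 0.0, 0.0)

    def test_percentages_sum_to_100_within_slack(self, rng):
        orfs = [_complete(int(a)) for a in rng.integers(50, 2500, size=200)]
        report = orf_length_bins(orfs)
        assert abs(sum(report.percentages) - 100.0) <= 0.02

    def test_empty_input_gives_zero_report(self):
        report = orf_length_bins([])
        assert report.counts == (0, 0, 0) and report.n_complete == 0


def _complete(aa):
    from isoscan.orf import OrfRecord

    return OrfRecord(
        transcript_id="t", strand="+", frame=0, start=1, end=3 * (aa + 1),
        completeness="complete", peptide="M" * aa, aa_length=aa,
    )
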