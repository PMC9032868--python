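import pytest

from isoscan import synthetic
from isoscan.io_formats import SeqRecord, reverse_complement
from isoscan.ssr import (
    SsrThresholds,
    canonical_motif,
    find_ssrs,
    ssr_report,
)


def _primitive(motif):
    n = len(motif)
    return not any(
        n % d == 0 and motif == motif[:d] * (n // d) for d in range(1, n)
    )


def brute_force_ssrs(seq, thresholds=None):
    """Independent scanner: checks every start position and unit size."""
    thresholds = thresholds or SsrThresholds()
    found = []
    n = len(seq)
    for u in range(1, 7):
        min_r = thresholds.min_repeats[u]
        for i in range(n - u + 1):
            motif = seq[i: i + u]
            if "N" in motif or not _primitive(motif):
                continue
            # anchored at i only when the period breaks at i-1
            if i >= 1 and i - 1 + u < n and seq[i - 1] == seq[i - 1 + u]:
                continue
            r = 1
            while seq[i + u * r: i + u * (r + 1)] == motif:
                r += 1
            if r >= min_r:
                found.append((u, motif, r, i + 1, i + u * r))
    found.sort(key=lambda t: (t[3], t[0]))
    return found


class TestFindSsrs:
    def test_mononucleotide_at_default_boundary(self):
        (hit,) = find_ssrs(SeqRecord(id="x", sequence="AAAAAAAAAA"))
        assert (hit.motif, hit.repeats, hit.start, hit.end) == ("A", 10, 1, 10)

    def test_dinucleotide_at_default_boundary(self):
        (hit,) = find_ssrs(SeqRecord(id="x", sequence="ATATATATATAT"))
        assert (hit.motif, hit.repeats) == ("AT", 6)

    def test_dinucleotide_below_threshold_not_reported(self):
        assert find_ssrs(SeqRecord(id="x", sequence="ATATATATAT")) == []

    def test_n_terminates_runs(self):
        hits = find_ssrs(SeqRecord(id="x", sequence="AAAAANAAAAA"))
        assert hits == []

    def test_incomplete_trailing_unit_not_counted(self):
        # (AT) x 6 plus a dangling A: span covers complete units only
        (hit,) = find_ssrs(SeqRecord(id="x", sequence="ATATATATATATA"))
        assert (hit.repeats, hit.start, hit.end) == (6, 1, 12)

    def test_matches_brute_force_on_random_sequences(self, rng):
        for _ in range(20):
            seq = synthetic.random_dna(rng, 2000)
            rec = SeqRecord(id="r", sequence=seq)
            ours = [
                (h.unit_size, h.motif, h.repeats, h.start, h.end)
                for h in find_ssrs(rec)
            ]
            assert ours == brute_force_ssrs(seq)

    def test_same_unit_hits_do_not_overlap(self, rng):
        # AT-rich sequences make tandem repeats common
        for _ in range(20):
            seq = "".join(
                "AT"[int(b)] if c < 0.8 else "CG"[int(b)]
                for b, c in zip(rng.integers(0, 2, 500), rng.random(500))
            )
            hits = find_ssrs(SeqRecord(id="r", sequence=seq))
            by_unit = {}
            for h in hits:
                by_unit.setdefault(h.unit_size, []).append(h)
            for same in by_unit.values():
                same.sort(key=lambda h: h.start)
                for a, b in zip(same, same[1:]):
                    assert a.end < b.start

    def test_reverse_complement_mirrors_spans(self, rng):
        seq = (
            synthetic.random_dna(rng, 100) + "AAG" * 8 + synthetic.random_dna(rng, 100)
        )
        fwd = find_ssrs(SeqRecord(id="f", sequence=seq))
        rev = find_ssrs(SeqRecord(id="r", sequence=reverse_complement(seq)))
        n = len(seq)
        mirrored = sorted(
            (n - h.end + 1, n - h.start + 1, reverse_complement(h.motif))
            for h in fwd
        )
        got = sorted((h.start, h.end, h.motif) for h in rev)
        # motifs may be rotated between the two scans; compare canonically
        assert [(s, e, canonical_motif(m)) for s, e, m in mirrored] == [
            (s, e, canonical_motif(m)) for s, e, m in got
        ]

    def test_compound_grouping_within_interruption_distance(self, rng):
        spacer_short = synthetic.random_dna(rng, 50)
        spacer_long = synthetic.random_dna(rng, 150)
        seq = "AAAAAAAAAAG" + spacer_short + "GATATATATATATG" + spacer_long + "GAAAAAAAAAA"
        hits = find_ssrs(SeqRecord(id="x", sequence=seq))
        assert len(hits) == 3
        assert hits[0].compound_id is not None
        assert hits[0].compound_id == hits[1].compound_id
        assert hits[2].compound_id is None


class TestSsrReport:
    def test_fraction_of_printed_unit_counts(self):
        # per-class fractions recomputed from a published-scale count table
        counts = {1: 21885, 2: 9024, 3: 5553, 4: 466, 5: 124, 6: 209}
        hits = {}
        k = 0
        for u, c in counts.items():
            for j in range(c):
                hits.setdefault(f"s{k % 97}", []).append(
                    _make_hit(u, f"s{k % 97}")
                )
                k += 1
        records = [SeqRecord(id=f"s{i}", sequence="ACGT" * 10) for i in range(97)]
        report = ssr_report(hits, records)
        assert report.n_ssrs == 37261
        assert report.fractions_by_unit[1] == 58.73
        assert report.fractions_by_unit[3] == 14.90
        assert report.fractions_by_unit[4] == 1.25
        assert report.fractions_by_unit[5] == 0.33
        assert report.fractions_by_unit[6] == 0.56

    def test_fractions_sum_to_100_within_rounding_slack(self, rng):
        for _ in range(5):
            counts = {u: int(rng.integers(1, 5000)) for u in range(1, 7)}
            hits = {"s": []}
            for u, c in counts.items():
                hits["s"].extend(_make_hit(u, "s") for _ in range(c))
            report = ssr_report(hits, [SeqRecord(id="s", sequence="ACGT")])
            assert abs(sum(report.fractions_by_unit.values()) - 100.0) <= 0.03

    def test_empty_hit_set(self):
        report = ssr_report({}, [])
        assert report.n_ssrs == 0 and report.fractions_by_unit == {}

    def test_sequence_level_counts(self, rng):
        spacer = synthetic.random_dna(rng, 200)
        rec_a = SeqRecord(
            id="a", sequence="AAAAAAAAAAG" + spacer + "GATATATATATAT"
        )
        rec_b = SeqRecord(id="b", sequence="GGGGGGGGGG")
        rec_c = SeqRecord(id="c", sequence="ACGTACGTAC")
        hits = {r.id: find_ssrs(r) for r in (rec_a, rec_b, rec_c)}
        report = ssr_report(hits, [rec_a, rec_b, rec_c])
        assert report.n_sequences == 3
        assert report.n_sequences_with_ssr == 2
        assert report.n_sequences_with_multiple == 1
        assert report.n_ssrs == 3


def _make_hit(unit, seq_id):
    from isoscan.ssr import SsrHit

    motifs = {1: "A", 2: "AT", 3: "AAG", 4: "AAAT", 5: "AAAAT", 6: "AAAAAT"}
    reps = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}[unit]
    return SsrHit(
        seq_id=seq_id, motif=motifs[unit], unit_size=unit, repeats=reps,
        start=1, end=unit * reps,
    )
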