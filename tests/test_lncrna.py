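import pytest

from isoscan import synthetic
from isoscan.io_formats import SeqRecord
from isoscan.lncrna import (
    MethodCalls,
    builtin_noncoding_call,
    consensus_lncrna,
    read_method_calls,
)
from isoscan.orf import find_best_orf


_STOPS = {"TAA", "TAG", "TGA"}


def _max_frame_run(seq):
    """Longest stop-free codon run over all six frames (partial ORFs at
    the transcript edges count as coding evidence too)."""
    from isoscan.io_formats import reverse_complement

    best = 0
    for s in (seq, reverse_complement(seq)):
        for f in range(3):
            cur = 0
            for i in range(f, len(s) - 2, 3):
                if s[i: i + 3] in _STOPS:
                    cur = 0
                else:
                    cur += 1
                    best = max(best, cur)
    return best


def _records(n=8, length=300):
    return [SeqRecord(id=f"t{i}", sequence="ACGT" * (length // 4)) for i in range(n)]


class TestBuiltinCall:
    def test_transcript_without_orf_is_noncoding(self):
        rec = SeqRecord(id="t", sequence="CCCCCCGGGGGG" * 30)
        assert builtin_noncoding_call(rec, None) is True

    def test_long_covering_orf_is_coding(self, rng):
        orf_nt = synthetic._random_orf(rng, 150)
        rec = SeqRecord(id="t", sequence="CCC" + orf_nt + "GGG")
        best = find_best_orf(rec, min_aa=50)
        assert builtin_noncoding_call(rec, best) is False

    def test_planted_labels_recovered(self, rng):
        # coding: transcript dominated by a long complete ORF;
        # non-coding: ORF-poor sequence (no stop-free frame >= 60 codons,
        # enforced by rejection sampling with an independent frame scan)
        correct = 0
        n_each = 200
        for i in range(n_each):
            orf_nt = synthetic._random_orf(rng, 150)
            pad = synthetic.random_dna(rng, 100)
            rec = SeqRecord(id=f"c{i}", sequence=pad + orf_nt + pad[:50])
            best = find_best_orf(rec, min_aa=30)
            if builtin_noncoding_call(rec, best) is False:
                correct += 1
        for i in range(n_each):
            seq = synthetic.random_dna(rng, 400)
            while _max_frame_run(seq) >= 60:
                seq = synthetic.random_dna(rng, 400)
            rec = SeqRecord(id=f"n{i}", sequence=seq)
            best = find_best_orf(rec, min_aa=30)
            if builtin_noncoding_call(rec, best) is True:
                correct += 1
        assert correct / (2 * n_each) >= 0.95


class TestConsensus:
    def test_length_exactly_200_excluded(self):
        rec = SeqRecord(id="t0", sequence="A" * 200)
        calls, _ = consensus_lncrna(
            [rec], [MethodCalls("CPC", {"t0"})], min_len=200
        )
        assert calls[0].consensus is False

    def test_one_dissenting_method_blocks_consensus(self):
        recs = _records(1, 400)
        methods = [
            MethodCalls("CNCI", {"t0"}),
            MethodCalls("CPC", {"t0"}),
            MethodCalls("CPAT", {"t0"}),
            MethodCalls("PFAM", set()),
        ]
        calls, _ = consensus_lncrna(recs, methods)
        assert calls[0].consensus is False

    def test_consensus_equals_naive_intersection(self, rng):
        recs = [
            SeqRecord(id=f"t{i}", sequence=synthetic.random_dna(rng, int(l)))
            for i, l in enumerate(rng.integers(100, 600, size=50))
        ]
        ids = [r.id for r in recs]
        methods = [
            MethodCalls(name, {i for i in ids if rng.random() < 0.5})
            for name in ("CNCI", "CPC", "CPAT", "PFAM")
        ]
        calls, venn = consensus_lncrna(recs, methods, min_len=200)
        got = {c.transcript_id for c in calls if c.consensus}
        naive = set(ids)
        for m in methods:
            naive &= m.noncoding_ids
        naive &= {r.id for r in recs if len(r) > 200}
        assert got == naive

    def test_venn_regions_partition_the_union(self, rng):
        recs = _records(30, 400)
        ids = [r.id for r in recs]
        methods = [
            MethodCalls(name, {i for i in ids if rng.random() < 0.4})
            for name in ("CNCI", "CPC", "CPAT")
        ]
        _, venn = consensus_lncrna(recs, methods)
        union = set()
        for m in methods:
            union |= m.noncoding_ids
        assert sum(venn["regions"].values()) == len(union)

    def test_adding_a_method_never_grows_consensus(self, rng):
        recs = _records(30, 400)
        ids = [r.id for r in recs]
        base = [
            MethodCalls(name, {i for i in ids if rng.random() < 0.6})
            for name in ("CNCI", "CPC")
        ]
        extra = MethodCalls("CPAT", {i for i in ids if rng.random() < 0.6})
        calls2, _ = consensus_lncrna(recs, base)
        calls3, _ = consensus_lncrna(recs, base + [extra])
        set2 = {c.transcript_id for c in calls2 if c.consensus}
        set3 = {c.transcript_id for c in calls3 if c.consensus}
        assert set3 <= set2

    def test_unknown_transcript_id_rejected(self):
        with pytest.raises(ValueError, match="ghost"):
            consensus_lncrna(_records(2), [MethodCalls("CPC", {"ghost"})])

    def test_method_table_parsing(self, tmp_path):
        p = tmp_path / "calls.tsv"
        p.write_text("t0\tnoncoding\nt1\tcoding\n")
        mc = read_method_calls("CPC", p)
        assert mc.noncoding_ids == {"t0"}
        bad = tmp_path / "bad.tsv"
        bad.write_text("t0\tmaybe\n")
        with pytest.raises(ValueError):
            read_method_calls("CPC", bad)
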