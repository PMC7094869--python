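import numpy as np
import pandas as pd
import pytest

from smallrna_pingpong.align import Alignment, FivePrimeIndex
from smallrna_pingpong.pingpong import (
    compare_ratios,
    overlap_histogram,
    pingpong_ratio,
    qualifying_pairs,
)


def sense(read_id, fp, weight=1.0, length=25):
    return Alignment(read_id, "te1", fp, "sense", 0, weight, length)


def antisense(read_id, fp, weight=1.0, length=25):
    # 5' end of an antisense read is start + length - 1
    return Alignment(read_id, "te1", fp - length + 1, "antisense", 0, weight, length)


def brute_force_histogram(alignments, o_max=30):
    """All-pairs double loop over sense x antisense alignments."""
    hist = {o: 0.0 for o in range(1, o_max + 1)}
    s = [a for a in alignments if a.orientation == "sense"]
    t = [a for a in alignments if a.orientation == "antisense"]
    for x in s:
        for y in t:
            o = y.five_prime - x.five_prime + 1
            if 1 <= o <= o_max:
                hist[o] += x.weight * y.weight
    return hist


def brute_force_qualifying(alignments, seqs):
    """All-pairs qualifying-read weights under the overlap-10 10A/1U OR rule."""
    qualifying = {}
    s = [a for a in alignments if a.orientation == "sense" and a.length >= 10]
    t = [a for a in alignments if a.orientation == "antisense"]
    for x in s:
        for y in t:
            if y.five_prime - x.five_prime + 1 != 10:
                continue
            if seqs[x.read_id][9] == "A" or seqs[y.read_id][0] == "T":
                qualifying[x.read_id] = x.weight
                qualifying[y.read_id] = y.weight
    return sum(qualifying.values())


class TestOverlapHistogram:
    def test_signature_bin(self):
        idx = FivePrimeIndex.from_alignments([sense("s", 0), antisense("a", 9)])
        assert overlap_histogram(idx, "te1")[10] == 1.0

    def test_overlap_nine(self):
        idx = FivePrimeIndex.from_alignments([sense("s", 0), antisense("a", 8)])
        hist = overlap_histogram(idx, "te1")
        assert hist[9] == 1.0 and hist[10] == 0.0

    def test_o_max_below_signature_errors(self):
        with pytest.raises(ValueError):
            overlap_histogram(FivePrimeIndex(), "te1", o_max=9)

    def test_matches_brute_force(self, rng):
        alns = []
        for i in range(150):
            fp = int(rng.integers(0, 120))
            w = float(rng.choice([0.25, 0.5, 1.0]))
            alns.append(sense(f"s{i}", fp, w) if rng.random() < 0.5 else antisense(f"a{i}", fp, w))
        idx = FivePrimeIndex.from_alignments(alns)
        got = overlap_histogram(idx, "te1")
        expected = brute_force_histogram(alns)
        for o in range(1, 31):
            assert got[o] == pytest.approx(expected[o])

    def test_bilinearity(self, rng):
        alns = [sense(f"s{i}", int(rng.integers(0, 50))) for i in range(30)] + [
            antisense(f"a{i}", int(rng.integers(0, 50))) for i in range(30)
        ]
        base = overlap_histogram(FivePrimeIndex.from_alignments(alns), "te1")
        doubled_alns = [
            Alignment(a.read_id, a.feature, a.start, a.orientation, 0,
                      a.weight * (2 if a.orientation == "sense" else 1), a.length)
            for a in alns
        ]
        doubled = overlap_histogram(FivePrimeIndex.from_alignments(doubled_alns), "te1")
        for o in range(1, 31):
            assert doubled[o] == pytest.approx(2 * base[o])


class TestQualifyingPairs:
    @pytest.mark.parametrize(
        "tenth,first,overlap,expected",
        [
            ("A", "G", 10, 2.0),  # sense 10A alone satisfies the OR rule
            ("C", "T", 10, 2.0),  # antisense 1U alone satisfies it
            ("C", "C", 10, 0.0),  # both conditions fail
            ("A", "T", 9, 0.0),  # overlap must be exactly 10
        ],
    )
    def test_or_rule(self, tenth, first, overlap, expected):
        s_seq = "G" * 9 + tenth + "G" * 15
        a_seq = first + "G" * 24
        alns = [sense("s", 0), antisense("a", overlap - 1)]
        res = qualifying_pairs(alns, {"s": s_seq, "a": a_seq}, "te1")
        assert res.read_weight == expected

    def test_short_sense_reads_excluded_with_counter(self):
        alns = [Alignment("s", "te1", 0, "sense", 0, 1.0, 8), antisense("a", 9)]
        res = qualifying_pairs(alns, {"s": "AAAAAAAA", "a": "T" + "G" * 24}, "te1")
        assert res.read_weight == 0.0
        assert res.n_short_excluded == 1

    def test_each_read_counted_once(self):
        # one antisense read qualifying against two sense reads
        alns = [sense("s1", 0), sense("s2", 0), antisense("a", 9)]
        seqs = {"s1": "G" * 9 + "A" + "G" * 15, "s2": "G" * 9 + "A" + "G" * 15, "a": "T" + "G" * 24}
        res = qualifying_pairs(alns, seqs, "te1")
        assert res.read_weight == 3.0  # s1 + s2 + a, the shared read a once

    def test_matches_brute_force(self, rng):
        alns, seqs = [], {}
        for i in range(200):
            fp = int(rng.integers(0, 60))
            seq = "".join(rng.choice(list("ACGT"), size=25))
            if rng.random() < 0.5:
                alns.append(sense(f"s{i}", fp))
                seqs[f"s{i}"] = seq
            else:
                alns.append(antisense(f"a{i}", fp))
                seqs[f"a{i}"] = seq
        res = qualifying_pairs(alns, seqs, "te1")
        assert res.read_weight == pytest.approx(brute_force_qualifying(alns, seqs))


class TestRatio:
    @pytest.mark.parametrize("q,total,expected", [(4, 20, 0.2), (0, 50, 0.0), (0, 0, 0.0)])
    def test_arithmetic(self, q, total, expected):
        assert pingpong_ratio(q, total) == expected

    def test_scale_invariance(self):
        """Doubling the library leaves the ratio unchanged (library-size-free)."""
        assert pingpong_ratio(8, 40) == pingpong_ratio(4, 20)


class TestCompareRatios:
    def test_identical_inputs_p_one(self):
        ratios = pd.DataFrame(np.linspace(0.1, 0.5, 6)[:, None] * [1, 1, 1],
                              index=[f"te{i}" for i in range(6)])
        cmp = compare_ratios(ratios, ratios.copy())
        assert cmp.p_value == 1.0

    def test_uniform_shift_exact_p(self):
        """10 TEs all shifted +0.1: one-sided sign-enumeration p is 1/1024."""
        rng = np.random.default_rng(0)
        a = pd.DataFrame(rng.uniform(0.1, 0.5, size=(10, 3)), index=[f"te{i}" for i in range(10)])
        b = a + 0.1
        from smallrna_pingpong.differential import wilcoxon_signed_rank

        diffs = (b.mean(axis=1) - a.mean(axis=1)).values
        assert wilcoxon_signed_rank(diffs, alternative="greater") == pytest.approx(1 / 1024)
        cmp = compare_ratios(a, b)
        assert cmp.p_value == pytest.approx(2 / 1024)

    def test_too_few_features_undefined(self):
        a = pd.DataFrame(np.ones((4, 2)), index=[f"te{i}" for i in range(4)])
        cmp = compare_ratios(a, a + 0.1)
        assert np.isnan(cmp.p_value)
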