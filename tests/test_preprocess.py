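import numpy as np
import pytest

from smallrna_pingpong.align import revcomp
from smallrna_pingpong.io_formats import FeatureClass, ReferenceFeature, SmallRNARead
from smallrna_pingpong.preprocess import (
    classify_by_length,
    clip_adapter,
    deplete_matching,
    five_prime_profile,
    preprocess_library,
)

from conftest import random_dna

ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


class TestClipAdapter:
    def test_full_adapter_suffix_clipped(self, rng):
        insert = random_dna(rng, 21)
        read = SmallRNARead("r", insert + ADAPTER)
        clipped = clip_adapter(read, ADAPTER)
        assert clipped.seq == insert and clipped.length == 21

    def test_no_adapter_discarded_by_default(self, rng):
        read = SmallRNARead("r", random_dna(rng, 30))
        assert clip_adapter(read, ADAPTER) is None
        assert clip_adapter(read, ADAPTER, keep_unclipped=True) is read

    def test_short_insert_discarded(self, rng):
        read = SmallRNARead("r", random_dna(rng, 10) + ADAPTER)
        assert clip_adapter(read, ADAPTER, min_insert=18) is None

    def test_adapter_shorter_than_min_match_errors(self):
        with pytest.raises(ValueError):
            clip_adapter(SmallRNARead("r", "ACGTACGTACGT"), "ACGTAC", min_match=8)

    def test_clipped_lengths_match_generator_inserts(self, rng, small_refs):
        te = small_refs[0]
        inserts = []
        reads = []
        for i in range(500):
            n = int(rng.integers(18, 30))
            start = int(rng.integers(0, te.length - n))
            inserts.append(n)
            reads.append(SmallRNARead(f"r{i}", te.seq[start : start + n] + ADAPTER))
        clipped = [clip_adapter(r, ADAPTER) for r in reads]
        # adapter-prefix collisions inside the insert can only shorten, never miss
        assert all(c is not None for c in clipped)
        assert [c.length for c in clipped] == inserts


class TestDepletion:
    def test_hairpin_substring_depleted(self, small_refs):
        hp = next(f for f in small_refs if f.feature_class is FeatureClass.miRNA_hairpin)
        read = SmallRNARead("r", hp.seq[5:27])
        res = deplete_matching([read], [hp])
        assert res.retained == []
        assert res.hairpin_total == 1

    def test_two_mismatches_retained(self, small_refs):
        hp = next(f for f in small_refs if f.feature_class is FeatureClass.miRNA_hairpin)
        seq = hp.seq[5:27]
        flip = lambda c: "A" if c != "A" else "C"
        seq = flip(seq[0]) + seq[1] + flip(seq[2]) + seq[3:]
        res = deplete_matching([SmallRNARead("r", seq)], [hp], max_mismatch=1)
        assert len(res.retained) == 1

    def test_empty_depletion_set_warns_and_retains(self):
        res = deplete_matching([SmallRNARead("r", "ACGTACGTACGTACGTACGT")], [])
        assert len(res.retained) == 1
        assert res.hairpin_total == 0
        assert res.warning is not None

    def test_matches_brute_force_scan(self, rng, small_refs):
        """Depletion equals the all-offsets, all-strands Hamming scan."""
        depl = [f for f in small_refs if f.feature_class in (FeatureClass.rRNA, FeatureClass.miRNA_hairpin)]
        reads = []
        for i in range(300):
            if rng.random() < 0.5:
                ref = depl[int(rng.integers(len(depl)))]
                n = int(rng.integers(20, 28))
                start = int(rng.integers(0, ref.length - n))
                seq = ref.seq[start : start + n]
                if rng.random() < 0.3:
                    pos = int(rng.integers(0, n))
                    seq = seq[:pos] + str(rng.choice([c for c in "ACGT" if c != seq[pos]])) + seq[pos + 1 :]
                if rng.random() < 0.5:
                    seq = revcomp(seq)
                reads.append(SmallRNARead(f"r{i}", seq))
            else:
                reads.append(SmallRNARead(f"r{i}", random_dna(rng, int(rng.integers(20, 28)))))
        res = deplete_matching(reads, depl, max_mismatch=1)
        retained_ids = {r.read_id for r in res.retained}
        for read in reads:
            hit = False
            for ref in depl:
                for query in (read.seq, revcomp(read.seq)):
                    for start in range(ref.length - read.length + 1):
                        if sum(a != b for a, b in zip(query, ref.seq[start : start + read.length])) <= 1:
                            hit = True
            assert (read.read_id not in retained_ids) == hit

    def test_partition_invariant(self, small_library, small_refs):
        reads, _ = small_library
        depl = [f for f in small_refs if f.feature_class in (FeatureClass.rRNA, FeatureClass.miRNA_hairpin)]
        res = deplete_matching(reads, depl)
        assert len(res.retained) + sum(res.depleted_counts.values()) == len(reads)


@pytest.mark.parametrize(
    "length,label",
    [(22, "siRNA"), (23, "piRNA"), (29, "piRNA"), (30, "other"), (20, "siRNA"), (19, "other"), (18, "other")],
)
def test_classify_by_length_boundaries(length, label):
    assert classify_by_length(length) == label
    assert classify_by_length(SmallRNARead("r", "A" * length)) == label


class TestFivePrimeProfile:
    def test_all_u_reads(self):
        reads = [SmallRNARead(f"r{i}", "T" + "A" * 23) for i in range(10)]
        prof = five_prime_profile(reads)
        assert prof.fractions.loc[24, "U"] == 1.0
        assert prof.counts[24] == 10

    def test_uniform_first_base_near_quarter(self, rng):
        reads = [SmallRNARead(f"r{i}", random_dna(rng, 24)) for i in range(10_000)]
        prof = five_prime_profile(reads)
        # binomial 99.9% bound: 0.25 +- 3.3*sqrt(.25*.75/1e4)
        for base in "ACGU":
            assert abs(prof.fractions.loc[24, base] - 0.25) < 0.015

    def test_absent_lengths_zero_flagged(self):
        prof = five_prime_profile([SmallRNARead("r", "A" * 25)])
        assert prof.counts[24] == 0
        assert prof.fractions.loc[24].sum() == 0.0

    def test_rows_sum_to_one(self, small_library):
        reads, _ = small_library
        prof = five_prime_profile(reads)
        sums = prof.fractions.sum(axis=1)
        nonzero = prof.counts > 0
        assert np.allclose(sums[nonzero], 1.0)


def test_preprocess_partition_and_class_sums(small_library, small_refs):
    reads, _ = small_library
    depl = [f for f in small_refs if f.feature_class in (FeatureClass.rRNA, FeatureClass.miRNA_hairpin)]
    pre = preprocess_library(reads, depl)
    assert pre.n_input == len(reads)
    assert len(pre.retained) + sum(pre.depleted_counts.values()) + pre.n_discarded_clip == pre.n_input
    assert sum(pre.class_counts().values()) == len(pre.retained)
    assert pre.hairpin_total <= pre.library_total
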