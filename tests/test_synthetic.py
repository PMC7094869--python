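import numpy as np
import pytest

from smallrna_pingpong.io_formats import FeatureClass
from smallrna_pingpong.synthetic import (
    LibraryParams,
    generate_reference_set,
    scaled_params,
    simulate_condition_pair,
    simulate_library,
)


class TestReferenceSet:
    def test_seed_determinism(self):
        a = generate_reference_set(n_te=2, te_length=500, n_hairpins=3, seed=7)
        b = generate_reference_set(n_te=2, te_length=500, n_hairpins=3, seed=7)
        assert [(f.name, f.seq, f.feature_class) for f in a] == [
            (f.name, f.seq, f.feature_class) for f in b
        ]

    def test_zero_te_errors(self):
        with pytest.raises(ValueError):
            generate_reference_set(n_te=0, te_length=500, n_hairpins=1, seed=0)

    def test_short_te_errors(self):
        with pytest.raises(ValueError):
            generate_reference_set(n_te=1, te_length=35, n_hairpins=1, seed=0)

    def test_includes_rrna_decoy(self):
        refs = generate_reference_set(n_te=1, te_length=500, n_hairpins=1, seed=0)
        assert any(f.feature_class is FeatureClass.rRNA for f in refs)

    def test_base_composition_near_uniform(self):
        refs = generate_reference_set(n_te=5, te_length=2000, n_hairpins=1, seed=1)
        pooled = "".join(f.seq for f in refs)
        n = len(pooled)
        assert n >= 10_000
        for base in "ACGT":
            # 99.99% binomial bound around 0.25
            assert abs(pooled.count(base) / n - 0.25) < 4 * np.sqrt(0.25 * 0.75 / n)


class TestSimulateLibrary:
    def test_read_count_conservation(self, small_refs):
        params = LibraryParams(n_reads=1234, seed=5)
        reads, truth = simulate_library(params, small_refs)
        assert len(reads) == 1234
        assert truth.n_reads == 1234
        assert sum(truth.class_totals.values()) == 1234

    def test_seed_determinism(self, small_refs):
        params = LibraryParams(n_reads=500, seed=9)
        r1, t1 = simulate_library(params, small_refs)
        r2, t2 = simulate_library(params, small_refs)
        assert [(r.read_id, r.seq) for r in r1] == [(r.read_id, r.seq) for r in r2]
        assert t1.emissions.equals(t2.emissions)

    def test_zero_pingpong_no_intended_pairs(self, small_refs):
        params = LibraryParams(n_reads=1000, pingpong_fraction=0.0, seed=2)
        _, truth = simulate_library(params, small_refs)
        assert sum(truth.intended_pairs.values()) == 0
        assert (truth.emissions["pair_id"] == -1).all()

    def test_full_pingpong_all_te_reads_paired(self, small_refs):
        params = LibraryParams(n_reads=2000, pingpong_fraction=1.0, a10_bias=1.0, seed=3)
        _, truth = simulate_library(params, small_refs)
        te = truth.emissions[truth.emissions["read_class"] == "te_piRNA"]
        n_te = len(te)
        assert sum(truth.intended_pairs.values()) == n_te // 2
        assert (te["pair_id"] >= 0).sum() == 2 * (n_te // 2)

    def test_intended_pairs_bounded_by_paired_reads(self, small_library):
        _, truth = small_library
        te = truth.emissions[truth.emissions["read_class"] == "te_piRNA"]
        assert sum(truth.intended_pairs.values()) <= (te["pair_id"] >= 0).sum() // 2 + 1

    def test_reads_are_reference_substrings_except_forced(self, small_refs):
        from smallrna_pingpong.align import revcomp

        params = LibraryParams(n_reads=500, seed=4)
        reads, truth = simulate_library(params, small_refs)
        by_name = {f.name: f.seq for f in small_refs}
        by_id = {r.read_id: r for r in reads}
        for row in truth.emissions.itertuples():
            window = by_name[row.feature][row.start : row.start + row.length]
            expected = revcomp(window) if row.orientation == "antisense" else window
            mm = sum(a != b for a, b in zip(expected, by_id[row.read_id].seq))
            assert mm <= 1  # at most the one forced signature base

    def test_no_transposon_errors(self, small_refs):
        refs = [f for f in small_refs if f.feature_class is not FeatureClass.transposon]
        with pytest.raises(ValueError, match="transposon"):
            simulate_library(LibraryParams(n_reads=10), refs)

    def test_invalid_mix_errors(self):
        params = LibraryParams(class_mix={"te_piRNA": 0.9, "siRNA": 0.2, "miRNA_hairpin": 0.0, "rRNA": 0.0})
        with pytest.raises(ValueError):
            params.validate()

    def test_adapter_appended(self, small_refs):
        params = LibraryParams(n_reads=50, adapter="TGGAATTCTCGG", seed=6)
        reads, _ = simulate_library(params, small_refs)
        assert all(r.seq.endswith("TGGAATTCTCGG") for r in reads)


class TestConditionPair:
    def test_replicate_determinism(self, small_refs):
        base = LibraryParams(n_reads=400, seed=0)
        p1 = simulate_condition_pair(base, {"transposon": 2.0}, 2, small_refs, seed=13)
        p2 = simulate_condition_pair(base, {"transposon": 2.0}, 2, small_refs, seed=13)
        for (ra, _), (rb, _) in zip(p1.libraries_b, p2.libraries_b):
            assert [(r.read_id, r.seq) for r in ra] == [(r.read_id, r.seq) for r in rb]

    def test_hairpin_expectation_fixed_under_te_fold(self):
        base = LibraryParams(n_reads=10_000)
        scaled = scaled_params(base, {"transposon": 3.0})
        hairpin_a = base.n_reads * base.class_mix["miRNA_hairpin"]
        hairpin_b = scaled.n_reads * scaled.class_mix["miRNA_hairpin"]
        assert hairpin_b == pytest.approx(hairpin_a, rel=1e-3)
        te_a = base.n_reads * base.class_mix["te_piRNA"]
        te_b = scaled.n_reads * scaled.class_mix["te_piRNA"]
        assert te_b == pytest.approx(3 * te_a, rel=1e-3)

    def test_too_few_replicates_errors(self, small_refs):
        with pytest.raises(ValueError):
            simulate_condition_pair(LibraryParams(n_reads=10), {}, 1, small_refs)

    def test_nonpositive_fold_errors(self):
        with pytest.raises(ValueError):
            scaled_params(LibraryParams(), {"transposon": 0.0})


def test_u1_bias_recovered_in_antisense_reads(small_refs):
    """Forced 5'-U fraction of antisense piRNAs approximates u1_bias."""
    params = LibraryParams(
        n_reads=4000,
        class_mix={"te_piRNA": 1.0, "siRNA": 0.0, "miRNA_hairpin": 0.0, "rRNA": 0.0},
        pingpong_fraction=0.0,
        sense_fraction=0.0,
        u1_bias=0.8,
        seed=21,
    )
    # hairpin features are still required as the normalizer reference
    reads, truth = simulate_library(params, small_refs)
    u_frac = np.mean([r.seq[0] == "T" for r in reads])
    assert 0.77 < u_frac < 0.83
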