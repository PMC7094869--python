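import numpy as np
import pytest

from smallrna_pingpong import LibraryParams, generate_reference_set
from smallrna_pingpong.io_formats import FeatureClass, ReferenceFeature


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def small_refs():
    """3 transposons, 3 hairpins, 1 rRNA, 2 genes, 2 clusters (seed-fixed)."""
    return generate_reference_set(n_te=3, te_length=600, n_hairpins=3, seed=7)


@pytest.fixture(scope="session")
def small_library(small_refs):
    """One 5000-read library with deliberate ping-pong structure."""
    from smallrna_pingpong import simulate_library

    params = LibraryParams(n_reads=5000, pingpong_fraction=0.4, seed=11)
    reads, truth = simulate_library(params, small_refs)
    return reads, truth


def make_feature(seq, name="feat", feature_class=FeatureClass.transposon):
    return ReferenceFeature(name, seq, feature_class)


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))
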