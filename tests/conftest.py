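import numpy as np
import pytest

import aptapair as ap


@pytest.fixture(scope="session")
def dinuc_table():
    return ap.load_default_table(2)


@pytest.fixture(scope="session")
def trinuc_table():
    return ap.load_default_table(3)


@pytest.fixture(scope="session")
def scales():
    return ap.load_default_scales()


@pytest.fixture(scope="session")
def small_corpus():
    """A 20-pos / 60-neg corpus with moderate planted signal, shared read-only."""
    return ap.generate_corpus(ap.FixtureConfig(n_pos=20, n_neg=60, effect_size=1.0, seed=7))


@pytest.fixture(scope="session")
def small_matrix(small_corpus):
    X, fdict = ap.build_feature_matrix(
        small_corpus.dataset, small_corpus.pssms, small_corpus.tracks
    )
    return X, small_corpus.dataset.labels, fdict


def random_nucleotide(rng, length, rna=False):
    letters = "ACGU" if rna else "ACGT"
    return ap.NucleotideSequence(
        f"n{length}", "".join(rng.choice(list(letters), size=length))
    )


def random_protein(rng, length):
    from aptapair.sequence_io import AMINO_ACIDS

    return ap.ProteinSequence(f"p{length}", "".join(rng.choice(list(AMINO_ACIDS), size=length)))


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
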