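import numpy as np
import pytest

import aptapair as ap
from aptapair.errors import DimensionError
from aptapair.protein_features import DISORDER_SUMMARY_NAMES

from .conftest import random_protein
from .oracles import autocovariance_naive, bigram_naive, dct_naive


def _scale_from_signal(values):
    """Wrap an arbitrary 20-value signal as an (unstandardized) scale."""
    from aptapair.sequence_io import AMINO_ACIDS

    return ap.HydropathyScale("test", dict(zip(AMINO_ACIDS, values)))


class TestDCT:
    def test_constant_signal_concentrates_in_dc(self):
        prot = ap.ProteinSequence("p", "A" * 52)
        scale = _scale_from_signal([3.0] * 20)
        g = ap.dct_features(prot, scale, n_components=52)
        assert g[0] == pytest.approx(3.0 * np.sqrt(52))
        np.testing.assert_allclose(g[1:], 0.0, atol=1e-10)

    def test_parseval_energy_identity(self, rng):
        """The full orthonormal transform preserves signal energy."""
        prot = random_protein(rng, 60)
        scale = _scale_from_signal(rng.normal(size=20))
        g = ap.dct_features(prot, scale, n_components=60)
        np.testing.assert_allclose(
            np.sum(g**2), np.sum(scale.signal(prot) ** 2), rtol=1e-12
        )

    def test_matches_naive_direct_sum(self, rng):
        prot = random_protein(rng, 60)
        scale = _scale_from_signal(rng.normal(size=20))
        got = ap.dct_features(prot, scale, n_components=52)
        want = dct_naive(scale.signal(prot), 52)
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_linearity(self, rng):
        prot = random_protein(rng, 55)
        vals = rng.normal(size=20)
        alpha = float(rng.normal())
        g1 = ap.dct_features(prot, _scale_from_signal(vals), 52)
        g2 = ap.dct_features(prot, _scale_from_signal(alpha * vals), 52)
        np.testing.assert_allclose(g2, alpha * g1, atol=1e-9)

    def test_short_protein_errors_unless_padded(self):
        prot = ap.ProteinSequence("p", "MKV" * 10)  # L = 30
        scale = _scale_from_signal(np.arange(20.0))
        with pytest.raises(DimensionError):
            ap.dct_features(prot, scale, 52)
        g = ap.dct_features(prot, scale, 52, pad_short=True)
        assert g.shape == (52,)


class TestBigramPSSM:
    def test_zero_matrix_fallback_gives_zeros(self):
        z = ap.PSSMProfile.zero("p", 10)
        for mode in ("none", "sigmoid"):
            np.testing.assert_array_equal(ap.bigram_pssm_features(z, mode), np.zeros(400))

    def test_single_transition(self):
        m = np.zeros((2, 20))
        m[0, 3] = 1.0  # D at position 1
        m[1, 7] = 1.0  # G at position 2
        b = ap.bigram_pssm_features(ap.PSSMProfile("p", m), normalize="none")
        assert b[3 * 20 + 7] == 1.0
        assert b.sum() == 1.0

    def test_dimension_is_400(self, rng):
        m = rng.normal(size=(10, 20))
        assert ap.bigram_pssm_features(ap.PSSMProfile("p", m)).shape == (400,)

    def test_matches_triple_loop(self, rng):
        m = rng.normal(size=(10, 20))
        got = ap.bigram_pssm_features(ap.PSSMProfile("p", m), normalize="none")
        np.testing.assert_allclose(got, bigram_naive(m), atol=1e-10)

    def test_sum_identity_on_nonnegative_matrices(self, rng):
        """sum_{m,n} B[m,n] = sum_i rowsum_i * rowsum_{i+1} (normalize=none)."""
        for _ in range(10):
            m = rng.random((8, 20))
            b = ap.bigram_pssm_features(ap.PSSMProfile("p", m), normalize="none")
            rows = m.sum(axis=1)
            np.testing.assert_allclose(b.sum(), np.dot(rows[:-1], rows[1:]), rtol=1e-10)

    def test_length_one_rejected(self):
        with pytest.raises(DimensionError):
            ap.bigram_pssm_features(ap.PSSMProfile("p", np.zeros((1, 20))), "none")


class TestDisorder:
    def test_constant_track_zero_autocovariance(self):
        t = ap.DisorderTrack("p", np.full(60, 0.4))
        np.testing.assert_allclose(ap.disorder_autocovariance(t, 51), 0.0, atol=1e-15)

    def test_lag_count_at_benchmark_minimum(self):
        t = ap.DisorderTrack("p", np.linspace(0, 1, 52))
        assert ap.disorder_autocovariance(t, 51).shape == (51,)

    def test_matches_direct_summation(self, rng):
        t = ap.DisorderTrack("p", rng.random(70))
        got = ap.disorder_autocovariance(t, 51)
        np.testing.assert_allclose(got, autocovariance_naive(list(t.scores), 51), atol=1e-12)

    def test_shift_invariance(self, rng):
        base = rng.random(70) * 0.5
        a = ap.disorder_autocovariance(ap.DisorderTrack("p", base), 20)
        b = ap.disorder_autocovariance(ap.DisorderTrack("p", base + 0.3), 20)
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_track_too_short_for_lags(self):
        with pytest.raises(DimensionError):
            ap.disorder_autocovariance(ap.DisorderTrack("p", np.zeros(51)), 51)

    def test_all_disordered_segment_summary(self):
        t = ap.DisorderTrack("p", np.full(10, 0.9))
        f = ap.disorder_segment_features(t)
        got = dict(zip(DISORDER_SUMMARY_NAMES, f))
        assert got["dis_mean"] == pytest.approx(0.9)
        assert got["dis_sd"] == pytest.approx(0.0)
        assert got["n_disorder_segments"] == 1
        assert got["min_disorder_len"] == got["max_disorder_len"] == 10
        assert got["n_nondisorder_segments"] == 0
        assert got["min_nondisorder_len"] == got["max_nondisorder_len"] == 0

    def test_run_length_definition(self):
        t = ap.DisorderTrack("p", np.array([0.9, 0.9, 0.1, 0.9]))
        f = dict(zip(DISORDER_SUMMARY_NAMES, ap.disorder_segment_features(t)))
        assert f["n_disorder_segments"] == 2
        assert (f["min_disorder_len"], f["max_disorder_len"]) == (1, 2)
        assert f["n_nondisorder_segments"] == 1
        assert (f["min_nondisorder_len"], f["max_nondisorder_len"]) == (1, 1)

    def test_segments_partition_the_track(self, rng):
        for _ in range(20):
            t = ap.DisorderTrack("p", rng.random(40))
            f = dict(zip(DISORDER_SUMMARY_NAMES, ap.disorder_segment_features(t)))
            assert f["n_disorder_segments"] + f["n_nondisorder_segments"] >= 1

    def test_disorder_block_dimension_59(self, rng):
        t = ap.DisorderTrack("p", rng.random(60))
        assert ap.disorder_features(t, ap.ProteinFeatureConfig()).shape == (59,)


class TestEncodeProtein:
    def test_dimension_563_and_block_layout(self, rng, scales):
        prot = random_protein(rng, 60)
        profile = ap.PSSMProfile("p60", rng.integers(-10, 11, (60, 20)).astype(float))
        track = ap.DisorderTrack("p60", rng.random(60))
        v, names = ap.encode_protein(prot, profile, track, scales)
        assert len(v) == len(names) == 563
        assert sum(n.startswith("dct") for n in names) == 104
        assert sum(n.startswith("bg_") for n in names) == 400
        assert sum(n.startswith("ac_") for n in names) + len(DISORDER_SUMMARY_NAMES) == 59

    def test_zero_pssm_only_silences_bigram_block(self, rng, scales):
        prot = random_protein(rng, 60)
        track = ap.DisorderTrack("p60", rng.random(60))
        profile = ap.PSSMProfile("p60", rng.integers(-10, 11, (60, 20)).astype(float))
        v_full, names = ap.encode_protein(prot, profile, track, scales)
        v_zero, _ = ap.encode_protein(
            prot, ap.PSSMProfile.zero("p60", 60), track, scales
        )
        bg = np.array([n.startswith("bg_") for n in names])
        assert not v_zero[bg].any()
        np.testing.assert_array_equal(v_zero[~bg], v_full[~bg])

    def test_mismatched_track_length_rejected(self, rng, scales):
        prot = random_protein(rng, 60)
        profile = ap.PSSMProfile("p", np.zeros((60, 20)))
        with pytest.raises(DimensionError):
            ap.encode_protein(prot, profile, ap.DisorderTrack("p", np.zeros(59)), scales)
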