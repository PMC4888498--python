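import numpy as np
import pytest

import aptapair as ap
from aptapair.aptamer_features import _ktuples
from aptapair.errors import ValidationError

from .conftest import random_nucleotide
from .oracles import pseknc_theta_naive, pseknc_vector_naive


class TestStandardization:
    def test_output_is_mean0_sd1(self, dinuc_table):
        m = dinuc_table.as_matrix()
        np.testing.assert_allclose(m.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(m.std(axis=0), 1.0, atol=1e-9)

    def test_idempotent(self, dinuc_table):
        again = ap.standardize_properties(dinuc_table)
        np.testing.assert_allclose(again.as_matrix(), dinuc_table.as_matrix(), atol=1e-9)

    def test_constant_property_rejected(self):
        values = {t: np.array([1.0, float(i)]) for i, t in enumerate(_ktuples(2))}
        table = ap.KTuplePropertyTable(2, ("const", "varies"), values)
        with pytest.raises(ValidationError, match="const"):
            ap.standardize_properties(table)


class TestKtupleFrequencies:
    def test_acgt_dinucleotides(self):
        f = ap.ktuple_frequencies(ap.NucleotideSequence("a", "ACGT"), 2)
        expected = np.zeros(16)
        for t in ("AC", "CG", "GT"):
            expected[_ktuples(2).index(t)] = 1 / 3
        np.testing.assert_allclose(f, expected)

    def test_homopolymer_trinucleotide(self):
        f = ap.ktuple_frequencies(ap.NucleotideSequence("a", "AAAAAAAA"), 3)
        assert f[_ktuples(3).index("AAA")] == 1.0 and f.sum() == 1.0

    def test_u_maps_to_t(self):
        fu = ap.ktuple_frequencies(ap.NucleotideSequence("r", "ACGU"), 2)
        ft = ap.ktuple_frequencies(ap.NucleotideSequence("d", "ACGT"), 2)
        np.testing.assert_array_equal(fu, ft)

    def test_random_sequences_normalized(self, rng):
        for _ in range(20):
            seq = random_nucleotide(rng, 25)
            for K in (2, 3):
                assert ap.ktuple_frequencies(seq, K).sum() == pytest.approx(1.0)

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            ap.ktuple_frequencies(ap.NucleotideSequence("a", "AC"), 3)


class TestCorrelationFactors:
    def test_homopolymer_thetas_vanish(self, dinuc_table):
        theta = ap.correlation_factors(
            ap.NucleotideSequence("a", "AAAAAAAA"), dinuc_table, lam=6
        )
        np.testing.assert_allclose(theta, 0.0, atol=1e-12)

    def test_lambda_too_large_names_sequence(self, dinuc_table):
        with pytest.raises(ValidationError, match="short"):
            ap.correlation_factors(
                ap.NucleotideSequence("short", "ACGT"), dinuc_table, lam=3
            )

    def test_matches_naive_double_loop(self, rng, dinuc_table, trinuc_table):
        """Vectorized thetas equal the brute-force evaluation on 100 random
        sequences of lengths 8-40."""
        for _ in range(100):
            L = int(rng.integers(8, 41))
            seq = random_nucleotide(rng, L, rna=bool(rng.integers(2)))
            for table in (dinuc_table, trinuc_table):
                lam = int(rng.integers(1, L - table.K + 1))
                got = ap.correlation_factors(seq, table, lam)
                want = pseknc_theta_naive(seq.dna, table, lam)
                np.testing.assert_allclose(got, want, atol=1e-10)
                assert np.all(got >= 0)


class TestPseKNCVector:
    def test_homopolymer_is_indicator(self, dinuc_table):
        v, names = ap.pseknc_vector(
            ap.NucleotideSequence("a", "AAAAAAAA"), dinuc_table, ap.PseKNCConfig(2, 6)
        )
        assert v[0] == pytest.approx(1.0)  # AA is the first lexicographic tuple
        np.testing.assert_allclose(v[1:], 0.0, atol=1e-12)

    def test_matches_naive(self, rng, dinuc_table):
        for _ in range(25):
            seq = random_nucleotide(rng, int(rng.integers(8, 30)))
            v, _ = ap.pseknc_vector(seq, dinuc_table, ap.PseKNCConfig(2, 3, omega=0.5))
            want = pseknc_vector_naive(seq.dna, dinuc_table, 3, 0.5)
            np.testing.assert_allclose(v, want, atol=1e-10)

    def test_sums_to_one_nonnegative(self, rng, dinuc_table, trinuc_table):
        """Normalization invariant over 1000 random sequences."""
        for i in range(1000):
            L = int(rng.integers(8, 41))
            seq = random_nucleotide(rng, L)
            table = dinuc_table if i % 2 == 0 else trinuc_table
            lam = min(5, L - table.K)
            v, _ = ap.pseknc_vector(seq, table, ap.PseKNCConfig(table.K, lam))
            assert v.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(v >= 0)

    def test_omega_to_zero_limit(self, rng, dinuc_table):
        """As omega -> 0 the vector converges to [frequencies | zeros]."""
        seq = random_nucleotide(rng, 20)
        v, _ = ap.pseknc_vector(seq, dinuc_table, ap.PseKNCConfig(2, 4, omega=1e-12))
        freqs = ap.ktuple_frequencies(seq, 2)
        np.testing.assert_allclose(v[:16], freqs, atol=1e-8)
        np.testing.assert_allclose(v[16:], 0.0, atol=1e-8)

    def test_order_sensitivity_lives_in_theta_block(self, dinuc_table):
        """Two sequences with identical dinucleotide composition but different
        order share the frequency block yet differ in the theta block."""
        from itertools import permutations

        groups: dict[tuple, list[str]] = {}
        for perm in set(permutations("AACCGGTT")):
            s = "".join(perm)
            key = tuple(ap.ktuple_frequencies(ap.NucleotideSequence("x", s), 2))
            groups.setdefault(key, []).append(s)
        pair = None
        for members in groups.values():
            for a in members:
                for b in members:
                    if a >= b:
                        continue
                    ta = ap.correlation_factors(ap.NucleotideSequence("a", a), dinuc_table, 3)
                    tb = ap.correlation_factors(ap.NucleotideSequence("b", b), dinuc_table, 3)
                    if not np.allclose(ta, tb):
                        pair = (a, b)
                        break
                if pair:
                    break
            if pair:
                break
        assert pair is not None, "no equal-composition, different-theta pair found"
        s1 = ap.NucleotideSequence("s1", pair[0])
        s2 = ap.NucleotideSequence("s2", pair[1])
        np.testing.assert_array_equal(
            ap.ktuple_frequencies(s1, 2), ap.ktuple_frequencies(s2, 2)
        )
        v1 = ap.correlation_factors(s1, dinuc_table, 3)
        v2 = ap.correlation_factors(s2, dinuc_table, 3)
        assert not np.allclose(v1, v2)


class TestEncodeAptamer:
    def test_benchmark_dimension_91(self):
        v, names = ap.encode_aptamer(ap.NucleotideSequence("a", "ACGTACGTACGT"))
        assert len(v) == len(names) == 91  # (16+6) + (64+5)

    def test_pure_composition_dimension_80(self, dinuc_table, trinuc_table):
        v, _ = ap.encode_aptamer(
            ap.NucleotideSequence("a", "ACGTACGT"),
            {2: dinuc_table, 3: trinuc_table},
            {2: ap.PseKNCConfig(2, 0), 3: ap.PseKNCConfig(3, 0)},
        )
        assert len(v) == 80

    def test_each_half_sums_to_one(self, rng):
        v, names = ap.encode_aptamer(random_nucleotide(rng, 30))
        split = 22  # 16 + lambda_2
        assert v[:split].sum() == pytest.approx(1.0)
        assert v[split:].sum() == pytest.approx(1.0)

    def test_too_short_sequence_errors(self):
        with pytest.raises(ValidationError):
            ap.encode_aptamer(ap.NucleotideSequence("a", "ACGTA"))
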