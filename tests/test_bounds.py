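"""Expectation sandwich, variance upper bound and the bias bracket."""

import numpy as np
import pytest

import subrate as sr


def _single_singleton_spectrum():
    # one distinct k-mer occurring once
    return sr.build_spectrum("ACGT", 4)


def _distant_singletons(m: int, k: int = 6):
    """m mutually distant singleton k-mers separated by long unique spacers.

    Built from a random string that happens to be repeat-free at this k.
    """
    rng = np.random.default_rng(100 + m)
    while True:
        seq = sr.random_sequence(m + k - 1, rng)
        spec = sr.build_spectrum(seq, k)
        if spec.L0 == spec.L == m:
            return spec


class TestExpectationBounds:
    def test_single_singleton_collapses(self):
        spec = _single_singleton_spectrum()
        q = sr.r_to_q(0.1, 4)
        LE, UE, beta = sr.expectation_bounds(spec, 0.1, mode="exact")
        assert LE == pytest.approx(1 - q)
        assert UE == pytest.approx(1 - q)  # empty beta sum
        assert beta == 0.0

    def test_repeat_free_fast_mode(self):
        spec = _distant_singletons(30)
        r = 0.05
        q = sr.r_to_q(r, spec.k)
        LE, UE, _ = sr.expectation_bounds(spec, r, mode="fast")
        assert LE == pytest.approx(spec.L0 * (1 - q))
        assert UE == pytest.approx(spec.L0 * (1 - q) + spec.L0 * q)

    def test_sandwich_contains_F(self):
        """LE <= F(q) <= UE for random strings across an r grid."""
        rng = np.random.default_rng(6)
        for _ in range(5):
            spec = sr.build_spectrum(sr.random_sequence(60, rng), 5)
            hist = sr.abundance_histogram(spec)
            for r in np.linspace(0.02, 0.9, 12):
                q = sr.r_to_q(r, 5)
                LE, UE, _ = sr.expectation_bounds(spec, float(r), mode="exact")
                assert LE <= sr.F_eval(hist, q) + 1e-9
                assert sr.F_eval(hist, q) <= UE + 1e-9

    def test_exact_beta_never_looser_than_fast(self):
        spec = sr.build_spectrum(sr.random_sequence(200, 8), 4)
        for r in (0.05, 0.2, 0.5):
            _, ue_exact, _ = sr.expectation_bounds(spec, r, mode="exact")
            _, ue_fast, _ = sr.expectation_bounds(spec, r, mode="fast")
            assert ue_exact <= ue_fast + 1e-9

    def test_invalid_r(self):
        spec = _single_singleton_spectrum()
        for r in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError):
                sr.expectation_bounds(spec, r)


class TestVarianceUpper:
    def test_single_singleton_hand_instantiated(self):
        # LE = UE = 1 - q, so L0 - UE = q; pair term empty
        spec = _single_singleton_spectrum()
        r = 0.05
        q = sr.r_to_q(r, 4)
        bounds = sr.expectation_bounds(spec, r)[:2]
        expected = q - q * q if q >= 0.5 else 0.25
        assert sr.variance_upper(spec, r, bounds) == pytest.approx(expected)

    def test_distant_singletons_pair_term(self):
        """m mutually distant singletons: pair term = m(m-1) q^2.

        Positions spaced >= k apart so every pair has sep({tau, v}) = 2;
        the spectrum is assembled directly rather than from one contiguous
        string (where adjacent windows necessarily overlap).
        """
        m, k = 12, 6
        rng = np.random.default_rng(112)
        kmers = set()
        while len(kmers) < m:
            kmers.add(sr.random_sequence(k, rng))
        spec = sr.SpectrumIndex(
            k=k, L=m, kmers={t: [1 + i * k] for i, t in enumerate(sorted(kmers))}
        )
        spec.validate()
        r = 0.3
        q = sr.r_to_q(r, spec.k)
        LE, UE, _ = sr.expectation_bounds(spec, r, mode="fast")
        u_var = sr.variance_upper(spec, r, (LE, UE))
        x = m - UE
        bern = x - x * x if x >= 0.5 else 0.25
        assert u_var == pytest.approx(m * (m - 1) * q**2 + bern, rel=1e-9)

    def test_dominates_empirical_variance(self, tandem_source):
        """U_Var >= Monte-Carlo Var[I] over 500 substitution replicates."""
        k, r = 10, 0.05
        spec = sr.build_spectrum(tandem_source, k)
        s_set = frozenset(spec.kmers)
        children = np.random.SeedSequence(12).spawn(500)
        I_vals = np.array(
            [
                len(s_set & sr.kmer_set(sr.mutate(tandem_source, r, np.random.default_rng(c)), k))
                for c in children
            ],
            dtype=float,
        )
        bounds = sr.expectation_bounds(spec, r, mode="exact")[:2]
        u_var = sr.variance_upper(spec, r, bounds)
        emp_var = I_vals.var(ddof=1)
        # allow 3 standard errors on the variance estimate itself
        se_var = emp_var * np.sqrt(2.0 / (len(I_vals) - 1))
        assert emp_var <= u_var + 3 * se_var
        # and the empirical mean respects the expectation sandwich
        se_mean = I_vals.std(ddof=1) / np.sqrt(len(I_vals))
        assert bounds[0] - 3 * se_mean <= I_vals.mean() <= bounds[1] + 3 * se_mean


class TestPairTermDecomposition:
    def test_matches_bruteforce_on_random_spectra(self):
        """The decomposed pair term equals the all-pairs merge oracle."""
        from subrate.bounds import _pair_term, _pair_term_bruteforce

        rng = np.random.default_rng(77)
        for k, length in ((3, 80), (4, 150), (6, 300), (2, 40)):
            spec = sr.build_spectrum(sr.random_sequence(length, rng), k)
            for q in (0.1, 0.5, 0.9):
                assert _pair_term(spec, q) == pytest.approx(
                    _pair_term_bruteforce(spec, q), rel=1e-10
                )

    def test_tandem_spectrum(self, tandem_source):
        from subrate.bounds import _pair_term, _pair_term_bruteforce

        spec = sr.build_spectrum(tandem_source[:600], 8)
        assert _pair_term(spec, 0.3) == pytest.approx(
            _pair_term_bruteforce(spec, 0.3), rel=1e-10
        )


class TestAlphaTerm:
    def test_repeat_free_is_zero(self):
        h = sr.AbundanceHistogram.from_counts(6, {1: 50})
        assert sr.alpha_term(h, (10.0, 40.0)) == 0.0

    def test_matches_fine_grid_oracle(self):
        h = sr.AbundanceHistogram.from_counts(4, {1: 3, 2: 1})
        LE, UE = 1.0, 3.0
        # F(q) = 4 - 3q - q^2: closed-form derivatives, vectorized fine grid
        xs = np.linspace(1e-7, 1 - 1e-7, 10**6)
        d1 = -(3 + 2 * xs)
        d2 = -2.0
        d3 = 0.0
        phi = (d3 * d1 - 3 * d2 * d2) / (6 * (-(d1**5)))
        oracle = max(float(phi.max()), 0.0) * max(h.L0 - LE, UE)
        got = sr.alpha_term(h, (LE, UE))
        assert got == pytest.approx(oracle, rel=1e-6, abs=1e-12)

    def test_scales_linearly_in_prefactor(self):
        h = sr.AbundanceHistogram.from_counts(4, {1: 3, 2: 2})
        a1 = sr.alpha_term(h, (h.L0 - 1.0, 2.0))  # prefactor 2
        a2 = sr.alpha_term(h, (h.L0 - 1.0, 4.0))  # prefactor 4
        assert a2 == pytest.approx(2 * a1, rel=1e-9)

    def test_requires_singleton(self):
        h = sr.AbundanceHistogram.from_counts(4, {2: 5})
        with pytest.raises(ValueError):
            sr.alpha_term(h, (1.0, 2.0))


class TestBiasBracket:
    def test_single_singleton_zero_bias(self):
        """Linear F: the bracket collapses to the true q exactly."""
        spec = _single_singleton_spectrum()
        for r in (0.01, 0.1, 0.4):
            rep = sr.bias_bounds_q(spec, r)
            q = sr.r_to_q(r, 4)
            assert rep.Eq_lower == pytest.approx(q, abs=1e-9)
            assert rep.Eq_upper == pytest.approx(q, abs=1e-9)

    def test_repeat_free_upper_is_q(self):
        spec = _distant_singletons(25)
        r = 0.08
        rep = sr.bias_bounds_q(spec, r, mode="fast")
        assert rep.Eq_upper == pytest.approx(sr.r_to_q(r, spec.k), abs=1e-9)

    def test_bracket_ordering_and_clamping(self, tandem_source):
        spec = sr.build_spectrum(tandem_source, 10)
        for r in (0.01, 0.05, 0.2):
            rep = sr.bias_bounds_q(spec, r, mode="exact")
            assert 0.0 <= rep.Eq_lower <= rep.Eq_upper <= 1.0
            assert rep.LE <= rep.UE
            assert rep.alpha >= 0.0

    def test_upper_bound_decreases_as_LE_increases(self):
        h = sr.AbundanceHistogram.from_counts(6, {1: 40, 3: 10})
        vals = [sr.solve_q_hat(h, le) for le in np.linspace(5, 45, 9)]
        assert all(a > b for a, b in zip(vals, vals[1:]))
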