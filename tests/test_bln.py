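"""Binomial-logit-normal distribution: exactness, limits, and oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom

from asevar.bln import (
    BLNParams,
    _cdf_arrays,
    _logpmf_arrays,
    bln_logpmf,
    bln_sample,
    bln_two_sided_p,
)
from oracles import mc_bln_pmf


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n": -1},
            {"n": 2, "sigma": -0.1},
            {"n": 2, "mu": np.inf},
            {"n": 2, "sigma": np.nan},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            BLNParams(**{"mu": 0.0, "sigma": 0.0, **kwargs})

    def test_support_and_order_validation(self):
        with pytest.raises(ValueError):
            bln_logpmf(3, BLNParams(2, 0, 0.5))
        with pytest.raises(ValueError):
            bln_logpmf(-1, BLNParams(2, 0, 0.5))
        with pytest.raises(ValueError):
            bln_logpmf(1, BLNParams(2, 0, 0.5), quad_order=1)
        with pytest.raises(ValueError):
            bln_two_sided_p(0, BLNParams(0, 0, 0.5))
        with pytest.raises(ValueError):
            bln_sample(BLNParams(2, 0, 0.5), size=-1, seed=0)


class TestLogPmf:
    def test_degenerate_cases(self):
        assert bln_logpmf(1, BLNParams(2, 0, 0)) == pytest.approx(np.log(0.5), abs=1e-12)
        assert bln_logpmf(0, BLNParams(0, 0, 1)) == 0.0

    @pytest.mark.parametrize("n", [1, 10, 100, 1000])
    @pytest.mark.parametrize("sigma", [0.0, 0.05, 0.5, 2.0])
    @pytest.mark.parametrize("mu", [-1.0, 0.0, 1.0])
    def test_normalization(self, n, sigma, mu):
        x = np.arange(n + 1)
        lp = _logpmf_arrays(x, n, mu, np.full(n + 1, sigma))
        assert abs(np.exp(lp).sum() - 1.0) < 1e-8

    @pytest.mark.parametrize("n", [1, 10, 100, 1000])
    @pytest.mark.parametrize("mu", [-1.0, 0.0, 0.7])
    def test_sigma_zero_is_binomial(self, n, mu):
        x = np.arange(n + 1)
        expected = binom.logpmf(x, n, 1.0 / (1.0 + np.exp(-mu)))
        got = _logpmf_arrays(x, n, mu, np.zeros(n + 1))
        assert np.allclose(got, expected, atol=1e-9, rtol=0)

    @pytest.mark.parametrize("n,sigma", [(20, 0.7), (101, 0.3), (50, 2.0)])
    def test_symmetry_at_mu_zero(self, n, sigma):
        x = np.arange(n + 1)
        lp = _logpmf_arrays(x, n, 0.0, np.full(n + 1, sigma))
        assert np.abs(lp - lp[::-1]).max() < 1e-10

    def test_large_n_stays_finite(self):
        lp = _logpmf_arrays(np.arange(0, 100001, 5000), 100000, 0.0, 0.3)
        assert np.all(np.isfinite(lp))

    @pytest.mark.parametrize("n,sigma,seed", [(20, 1.0, 3), (100, 0.1, 4)])
    def test_matches_monte_carlo_oracle(self, n, sigma, seed):
        freq, se = mc_bln_pmf(n, 0.0, sigma, draws=10**6, seed=seed)
        pmf = np.exp(_logpmf_arrays(np.arange(n + 1), n, 0.0, np.full(n + 1, sigma)))
        mask = pmf > 1e-4
        z = np.abs(pmf[mask] - freq[mask]) / se[mask]
        assert z.max() < 3.0

    def test_allelic_ratio_variance_monotone_in_sigma(self):
        n = 50
        x = np.arange(n + 1)
        ratios = x / n
        variances = []
        for sigma in [0.0, 0.1, 0.3, 0.6, 1.0, 2.0]:
            pmf = np.exp(_logpmf_arrays(x, n, 0.0, np.full(n + 1, sigma)))
            variances.append(np.sum(pmf * ratios**2) - np.sum(pmf * ratios) ** 2)
        assert np.all(np.diff(variances) >= -1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        n=st.integers(min_value=1, max_value=300),
        sigma=st.floats(min_value=0.0, max_value=3.0, allow_nan=False),
        mu=st.floats(min_value=-2.0, max_value=2.0, allow_nan=False),
    )
    def test_normalization_property(self, n, sigma, mu):
        x = np.arange(n + 1)
        lp = _logpmf_arrays(x, n, mu, np.full(n + 1, sigma))
        assert abs(np.exp(lp).sum() - 1.0) < 1e-8


class TestTwoSidedP:
    def test_center_of_symmetric_law_is_one(self):
        assert bln_two_sided_p(5, BLNParams(10, 0, 0.5)) == 1.0

    def test_binomial_closed_form(self):
        assert bln_two_sided_p(0, BLNParams(10, 0, 0)) == pytest.approx(2 * 0.5**10, rel=1e-12)

    def test_extreme_observation_equals_doubled_point_mass(self):
        p = bln_two_sided_p(100, BLNParams(100, 0, 0.1))
        expected = 2.0 * np.exp(bln_logpmf(100, BLNParams(100, 0, 0.1)))
        assert p == pytest.approx(expected, rel=1e-8)
        # Monte-Carlo cross-check: no draw out of 10^6 should land at x = n,
        # consistent with the quadrature tail being far below 1/draws
        freq, _ = mc_bln_pmf(100, 0.0, 0.1, draws=10**6, seed=11)
        assert p < 1e-6
        assert freq[100] * 10**6 <= 3

    @pytest.mark.parametrize("n,sigma", [(31, 0.4), (100, 0.15)])
    def test_symmetric_in_x_reflection(self, n, sigma):
        x = np.arange(n + 1)
        p = np.array([bln_two_sided_p(int(v), BLNParams(n, 0, sigma)) for v in x])
        assert np.allclose(p, p[::-1], rtol=0, atol=1e-12)

    def test_monotone_in_imbalance(self):
        n = 60
        params = BLNParams(n, 0, 0.3)
        p = [bln_two_sided_p(x, params) for x in range(30, 61)]
        assert np.all(np.diff(p) <= 1e-12)

    def test_monotone_in_sigma_for_imbalanced_counts(self):
        p = [bln_two_sided_p(45, BLNParams(60, 0, s)) for s in [0.05, 0.1, 0.3, 0.6, 1.0]]
        assert np.all(np.diff(p) >= -1e-12)

    @pytest.mark.parametrize("n,sigma", [(500, 0.5), (2000, 0.1)])
    def test_tail_integral_matches_pmf_sum(self, n, sigma):
        """The scaled-node tail integral must agree with summed AGHQ pmf."""
        x = np.arange(n + 1)
        pmf = np.exp(_logpmf_arrays(x, n, 0.0, np.full(n + 1, sigma)))
        cdf = _cdf_arrays(x, np.full(n + 1, n), 0.0, sigma)
        assert np.abs(np.cumsum(pmf) - cdf).max() < 1e-8


class TestSampling:
    def test_no_trials_yield_zeros(self):
        assert np.all(bln_sample(BLNParams(0, 0, 1.0), 5, seed=0) == 0)

    def test_seed_determinism(self):
        a = bln_sample(BLNParams(50, 0, 0.4), 1000, seed=123)
        b = bln_sample(BLNParams(50, 0, 0.4), 1000, seed=123)
        assert np.array_equal(a, b)

    def test_binomial_mean(self):
        draws = bln_sample(BLNParams(50, 0, 0), 10**5, seed=1)
        se = np.sqrt(50 * 0.25 / 10**5)
        assert abs(draws.mean() - 25.0) < 3 * se

    def test_empirical_pmf_matches_quadrature(self):
        n, sigma, size = 100, 0.4, 10**5
        draws = bln_sample(BLNParams(n, 0, sigma), size, seed=7)
        freq = np.bincount(draws, minlength=n + 1) / size
        pmf = np.exp(_logpmf_arrays(np.arange(n + 1), n, 0.0, np.full(n + 1, sigma)))
        se = np.sqrt(pmf * (1 - pmf) / size)
        mask = pmf > 1e-4
        z = np.abs(freq[mask] - pmf[mask]) / se[mask]
        # ~100 bins: allow the expected handful of chance 3-SE exceedances
        assert np.mean(z > 3.0) <= 0.05
        assert z.max() < 5.0
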