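"""Probability structure of the zero-inflated geometric INAR process."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zigcusum import (
    ZIGParams,
    innovation_pmf,
    marginal_pmf,
    process_moments,
    simulate_path,
    transition_pmf,
)
from zigcusum.model import innovation_mixture, transition_matrix

JGRID = np.arange(200)


def valid_params():
    """Strategy over parameter sets satisfying the stationarity constraint."""

    def build(theta, p, beta, frac):
        lo = p / (beta + p * (1 - beta))
        if lo >= 0.999:
            return None
        alpha = lo + (0.999 - lo) * frac
        return ZIGParams(theta, p, alpha, beta)

    return st.builds(
        build,
        st.floats(0.2, 8.0),
        st.floats(0.01, 0.6),
        st.floats(0.05, 0.95),
        st.floats(0.01, 0.99),
    ).filter(lambda x: x is not None)


class TestParamsValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(theta=-1.0, p=0.2, alpha=0.5, beta=0.5),
            dict(theta=0.0, p=0.2, alpha=0.5, beta=0.5),
            dict(theta=1.0, p=0.0, alpha=0.5, beta=0.5),
            dict(theta=1.0, p=1.0, alpha=0.5, beta=0.5),
            dict(theta=1.0, p=0.2, alpha=1.2, beta=0.5),
            dict(theta=1.0, p=0.2, alpha=0.5, beta=-0.1),
        ],
    )
    def test_out_of_range_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ZIGParams(**kwargs)

    def test_stationarity_constraint_rejected(self):
        # p/(beta + p(1-beta)) = 0.5/0.55 ~ 0.909 > alpha = 0.3
        with pytest.raises(ValueError, match="stationarity"):
            ZIGParams(theta=1.0, p=0.5, alpha=0.3, beta=0.1)

    def test_constraint_boundary_is_exclusive(self):
        p, beta = 0.3, 0.5
        lo = p / (beta + p * (1 - beta))
        with pytest.raises(ValueError):
            ZIGParams(1.0, p, lo, beta)
        ZIGParams(1.0, p, lo + 1e-6, beta)  # just inside is fine


class TestMarginalPmf:
    def test_closed_form_at_zero(self):
        # p + (1-p)/(1+theta) with theta=1, p=0.2
        params = ZIGParams(1.0, 0.2, 0.7, 0.5)
        assert marginal_pmf(params, 0) == pytest.approx(0.6, abs=1e-12)

    def test_normalizes(self, params_crime):
        total = marginal_pmf(params_crime, JGRID).sum()
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_small_p_limit_is_geometric(self):
        theta = 2.0
        params = ZIGParams(theta, 1e-9, 0.7, 0.5)
        j = np.arange(10)
        geometric = theta**j / (1 + theta) ** (j + 1)
        np.testing.assert_allclose(marginal_pmf(params, j), geometric, rtol=1e-6)

    def test_rejects_bad_support(self, params_small):
        with pytest.raises(ValueError):
            marginal_pmf(params_small, -1)
        with pytest.raises(ValueError):
            marginal_pmf(params_small, 1.5)


class TestInnovationPmf:
    def test_mixture_weights_valid(self, params_small):
        weights, scale2 = innovation_mixture(params_small)
        assert np.all(weights >= 0) and np.all(weights <= 1)
        assert weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert scale2 > 0

    def test_third_weight_sign_tracks_constraint(self):
        # weight is proportional to alpha(beta + p(1-beta)) - p, positive inside
        params = ZIGParams(1.0, 0.3, 0.9, 0.5)
        w, _ = innovation_mixture(params)
        assert w[2] > 0

    def test_normalizes(self, params_small):
        assert innovation_pmf(params_small, JGRID).sum() == pytest.approx(1.0, abs=1e-10)

    @settings(deadline=None, max_examples=40)
    @given(valid_params())
    def test_pmf_properties_hold_over_parameter_region(self, params):
        w, _ = innovation_mixture(params)
        assert np.all(w > -1e-12) and np.all(w < 1 + 1e-12)
        pmf = innovation_pmf(params, np.arange(400))
        assert np.all(pmf >= 0)
        assert pmf.sum() == pytest.approx(1.0, abs=1e-8)


class TestTransitionPmf:
    def test_rows_normalize(self):
        params = ZIGParams(5.0, 0.3, 0.8, 0.8)
        for i in range(21):
            row = np.array([transition_pmf(params, j, i) for j in range(400)])
            assert row.sum() == pytest.approx(1.0, abs=1e-10)

    def test_empty_thinning_reduces_to_innovation(self, params_small):
        j = np.arange(30)
        trans = np.array([transition_pmf(params_small, jj, 0) for jj in j])
        np.testing.assert_allclose(trans, innovation_pmf(params_small, j), atol=1e-14)

    def test_stationary_marginal_is_invariant(self):
        # convolution identity: sum_i P(X=i) P(j|i) = P(X=j)
        params = ZIGParams(1.0, 0.1, 0.5, 0.5)
        nmax = 120
        T = transition_matrix(params, nmax)
        pi = marginal_pmf(params, np.arange(nmax + 1))
        lhs = pi @ T
        err = np.max(np.abs(lhs[:31] - pi[:31]))
        assert err < 1e-8

    @pytest.mark.parametrize(
        "params",
        [
            ZIGParams(1.0, 0.1, 0.5, 0.5),
            ZIGParams(1.0, 0.3, 0.5, 0.8),
            ZIGParams(5.0, 0.3, 0.8, 0.8),
            ZIGParams(3.0, 0.2, 0.6, 0.7),
        ],
        ids=str,
    )
    def test_invariance_across_parameter_grid(self, params):
        nmax = 250
        T = transition_matrix(params, nmax)
        pi = marginal_pmf(params, np.arange(nmax + 1))
        assert np.max(np.abs((pi @ T)[:40] - pi[:40])) < 1e-8


class TestProcessMoments:
    def test_tabulated_values(self, params_small):
        m = process_moments(params_small)
        assert m.mean == pytest.approx(0.9)
        assert m.variance == pytest.approx(0.9 * 2.1)
        assert process_moments(ZIGParams(1.0, 0.1, 0.5, 0.7)).acf1 == pytest.approx(0.15)

    def test_overdispersion(self, params_crime):
        m = process_moments(params_crime)
        assert m.variance > m.mean
        # dispersion index has closed form (1+p) theta + 1
        assert m.variance / m.mean == pytest.approx(
            (1 + params_crime.p) * params_crime.theta + 1
        )


class TestSimulatePath:
    def test_reproducible(self, params_small):
        a = simulate_path(params_small, 500, seed=7)
        b = simulate_path(params_small, 500, seed=7)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, simulate_path(params_small, 500, seed=8))

    def test_moments_match_closed_form(self):
        params = ZIGParams(2.0, 0.2, 0.5, 0.5)
        n = 200_000
        x = simulate_path(params, n, seed=11)
        m = process_moments(params)
        se_mean = np.sqrt(m.variance / n) * np.sqrt((1 + m.acf1) / (1 - m.acf1))
        assert abs(x.mean() - m.mean) < 3 * se_mean
        acf1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert abs(acf1 - m.acf1) < 3 / np.sqrt(n)

    def test_zero_fraction_matches_marginal(self):
        params = ZIGParams(1.0, 0.5, 0.9, 0.5)
        x = simulate_path(params, 100_000, seed=3)
        p0 = marginal_pmf(params, 0)  # = 0.75
        assert p0 == pytest.approx(0.75)
        assert abs(np.mean(x == 0) - p0) < 3 * np.sqrt(p0 * (1 - p0) / x.size) * 2

    def test_fixed_start_and_errors(self, params_small):
        x = simulate_path(params_small, 10, x0=4, seed=0)
        assert x.size == 10 and np.all(x >= 0)
        with pytest.raises(ValueError):
            simulate_path(params_small, 0, seed=0)
        with pytest.raises(ValueError):
            simulate_path(params_small, 10, x0=-2, seed=0)
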