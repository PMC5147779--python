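"""Statistical operations: definitional oracles, EM recovery, size control."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from yeastcycle.stats import (
    cv,
    fit_poisson,
    fit_two_component_poisson,
    ndt_estimate,
    pearson_r,
    prefers_mixture,
    sic1_halflife,
    size_control_slope,
)

finite_vectors = st.lists(
    st.floats(min_value=-1e6, max_value=1e6, allow_nan=False,
              allow_infinity=False),
    min_size=4, max_size=40)


class TestDescriptors:
    def test_constant_vector_cv_zero(self):
        assert cv([5.0] * 10) == 0.0

    def test_hand_computed_cv(self):
        # {1, 3}: sd = sqrt(2), mean = 2
        assert cv([1.0, 3.0]) == pytest.approx(np.sqrt(2) / 2)

    def test_zero_mean_undefined(self):
        assert np.isnan(cv([-1.0, 1.0]))

    @settings(max_examples=200, deadline=None)
    @given(finite_vectors)
    def test_cv_matches_definition(self, xs):
        x = np.array(xs)
        if abs(x.mean()) < 1e-9:
            return
        expected = x.std(ddof=1) / x.mean()
        assert cv(x) == pytest.approx(expected, rel=1e-9, abs=1e-12)

    def test_perfect_linear_correlations(self):
        x = np.arange(10.0)
        assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    @settings(max_examples=200, deadline=None)
    @given(finite_vectors, st.randoms(use_true_random=False))
    def test_pearson_matches_definition(self, xs, rnd):
        x = np.array(xs)
        y = np.array([rnd.uniform(-10, 10) for _ in xs])
        if x.std() < 1e-9 or y.std() < 1e-9:
            return
        xc, yc = x - x.mean(), y - y.mean()
        expected = (xc * yc).sum() / np.sqrt((xc ** 2).sum()
                                             * (yc ** 2).sum())
        assert pearson_r(x, y) == pytest.approx(expected, abs=1e-9)

    def test_zero_variance_correlation_undefined(self):
        assert np.isnan(pearson_r([1, 1, 1], [1, 2, 3]))


class TestNdt:
    def test_exact_doubling(self):
        t = np.arange(0, 500, 10.0)
        counts = 2 ** (t / 100.0) * 4
        assert ndt_estimate(t, counts) == pytest.approx(100.0)

    def test_robust_to_unit_perturbations(self):
        rng = np.random.default_rng(0)
        t = np.arange(0, 600, 10.0)
        counts = np.round(2 ** (t / 120.0) * 8
                          + rng.integers(-1, 2, t.size))
        assert ndt_estimate(t, counts) == pytest.approx(120.0, rel=0.05)

    def test_non_increasing_rejected(self):
        with pytest.raises(ValueError):
            ndt_estimate([0, 10, 20], [5, 5, 5])


class TestSizeControl:
    MU = 0.007

    def test_perfect_sizer_has_slope_minus_one(self):
        # T_unbud = ln(V*/V_bir)/mu for cells below the critical size
        rng = np.random.default_rng(3)
        v_star = 45.0
        v_bir = rng.uniform(20.0, 42.0, 400)
        t_unbud = np.log(v_star / v_bir) / self.MU
        slope = size_control_slope(v_bir, t_unbud, self.MU)
        assert slope == pytest.approx(-1.0, abs=0.02)

    def test_timer_has_slope_zero(self):
        rng = np.random.default_rng(4)
        v_bir = rng.uniform(20.0, 42.0, 400)
        t_unbud = np.full(400, 30.0)
        slope = size_control_slope(v_bir, t_unbud, self.MU)
        assert abs(slope) < 0.02

    def test_invariant_to_volume_rescaling(self):
        rng = np.random.default_rng(5)
        v_bir = rng.uniform(20.0, 42.0, 300)
        t_unbud = np.log(50.0 / v_bir) / self.MU + rng.normal(0, 3, 300)
        s1 = size_control_slope(v_bir, t_unbud, self.MU)
        s2 = size_control_slope(v_bir * 7.3, t_unbud, self.MU)
        assert s1 == pytest.approx(s2, rel=1e-9)

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            size_control_slope([30.0, 31.0], [10.0, 11.0], self.MU)


class TestMixtureFits:
    def test_poisson_mle_is_sample_mean(self):
        rng = np.random.default_rng(0)
        k = rng.poisson(6.0, 2000)
        fit = fit_poisson(k)
        assert fit.params["lam"] == pytest.approx(k.mean())

    def test_single_poisson_preferred_on_poisson_data(self):
        rng = np.random.default_rng(1)
        k = rng.poisson(6.0, 3000)
        assert not prefers_mixture(k)
        # and the mixture degenerates: equal rates or vanishing weight
        fit = fit_two_component_poisson(k)
        w, l1, l2 = fit.params["w"], fit.params["lam1"], fit.params["lam2"]
        # the two rates collapse toward each other (vs the true 10-unit
        # separation used in the recovery test) or one weight vanishes
        assert (abs(l1 - l2) < 1.5 or min(w, 1 - w) < 0.05)

    def test_mixture_recovery_within_ten_percent(self):
        rng = np.random.default_rng(2)
        z = rng.random(5000) < 0.5
        k = np.where(z, rng.poisson(2.0, 5000), rng.poisson(12.0, 5000))
        fit = fit_two_component_poisson(k)
        lam_lo = min(fit.params["lam1"], fit.params["lam2"])
        lam_hi = max(fit.params["lam1"], fit.params["lam2"])
        w_lo = (fit.params["w"] if fit.params["lam1"] < fit.params["lam2"]
                else 1 - fit.params["w"])
        assert lam_lo == pytest.approx(2.0, rel=0.10)
        assert lam_hi == pytest.approx(12.0, rel=0.10)
        assert w_lo == pytest.approx(0.5, abs=0.05)
        assert prefers_mixture(k)

    def test_em_likelihood_not_below_single_poisson(self):
        rng = np.random.default_rng(3)
        k = rng.poisson(4.0, 800)
        assert (fit_two_component_poisson(k).log_likelihood
                >= fit_poisson(k).log_likelihood - 1e-6)


class TestSic1Decay:
    def test_exact_exponential(self):
        t = np.arange(0, 80.0, 0.5)
        n = 4000 * np.exp(-0.1 * t)
        assert sic1_halflife(t, n) == pytest.approx(np.log(2) / 0.1,
                                                    rel=0.02)

    def test_noisy_exponential_recovered(self):
        rng = np.random.default_rng(6)
        t = np.arange(0, 80.0, 1.0)
        n = rng.poisson(1000 * np.exp(-0.08 * t))
        assert sic1_halflife(t, n) == pytest.approx(np.log(2) / 0.08,
                                                    rel=0.10)

    def test_no_decay_flagged_none(self):
        t = np.arange(0, 50.0)
        n = np.full(50, 800.0)
        assert sic1_halflife(t, n) is None
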