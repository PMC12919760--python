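"""Mixture-cure survival model: likelihood, fitting, ranking, waning."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from her2ce.survival import (FAMILY_PARAM_NAMES, LifeTable, MixtureCureModel,
                             ParametricFamily, WaningSchedule,
                             blend_background_mortality,
                             effective_hazard_ratio, fit_mixture_cure,
                             mixture_cure_survival, negative_log_likelihood,
                             rank_by_information_criteria,
                             survival_to_cycle_prob)


class TestMixtureSurvival:
    def test_closed_form_exponential_mixture(self):
        latent = ParametricFamily("exponential", (0.1,))
        expected = 0.3 + 0.7 * math.exp(-1.2)
        assert mixture_cure_survival(12.0, 0.3, latent) == pytest.approx(
            expected, abs=1e-12
        )

    def test_boundary_values(self):
        latent = ParametricFamily("lognormal", (2.5, 0.8))
        assert mixture_cure_survival(0.0, 0.3, latent) == pytest.approx(1.0)
        assert mixture_cure_survival(1e6, 1.0, latent) == pytest.approx(1.0)

    def test_negative_time_rejected(self):
        latent = ParametricFamily("exponential", (0.1,))
        with pytest.raises(ValueError):
            mixture_cure_survival(-1.0, 0.3, latent)

    @given(
        pi=st.floats(0.0, 1.0),
        meanlog=st.floats(0.5, 4.0),
        sdlog=st.floats(0.2, 2.0),
    )
    def test_curve_non_increasing_and_bounded(self, pi, meanlog, sdlog):
        """S(t) is non-increasing and confined to [pi, 1] for random
        parameter draws."""
        latent = ParametricFamily("lognormal", (meanlog, sdlog))
        t = np.linspace(0, 600, 301)
        s = mixture_cure_survival(t, pi, latent)
        assert np.all(np.diff(s) <= 1e-12)
        assert np.all(s <= 1.0 + 1e-12)
        assert np.all(s >= pi - 1e-12)


class TestLikelihood:
    def test_empty_data_zero(self):
        latent = ParametricFamily("exponential", (0.1,))
        assert negative_log_likelihood([], [], 0.5, latent) == 0.0

    def test_censored_fully_cured_is_zero(self):
        latent = ParametricFamily("exponential", (0.1,))
        assert negative_log_likelihood([10.0], [0], 1.0, latent) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_single_event_hand_value(self):
        # event at t=5 with pi=0.2, exponential rate 0.1:
        # -log(0.8 * 0.1 * exp(-0.5))
        latent = ParametricFamily("exponential", (0.1,))
        expected = -math.log(0.8 * 0.1 * math.exp(-0.5))
        assert negative_log_likelihood([5.0], [1], 0.2, latent) == pytest.approx(
            expected, abs=1e-12
        )

    def test_nonpositive_time_rejected(self):
        latent = ParametricFamily("exponential", (0.1,))
        with pytest.raises(ValueError):
            negative_log_likelihood([0.0], [1], 0.2, latent)


class TestFitting:
    def test_parameter_recovery_single_dataset(self, rng):
        """MLE recovers the cure fraction within +-0.05 at n=2000."""
        n, pi, meanlog, sdlog = 2000, 0.60, 2.5, 0.8
        cured = rng.random(n) < pi
        t = rng.lognormal(meanlog, sdlog, n)
        t[cured] = np.inf
        cens = 96.0
        event = (t <= cens).astype(int)
        time = np.minimum(t, cens)
        res = fit_mixture_cure(time, event, "lognormal")
        assert res.converged
        assert abs(res.cure_fraction - pi) < 0.05
        assert abs(res.latent.params[0] - meanlog) < 0.15

    def test_refit_is_deterministic(self, ipd):
        m = MixtureCureModel.from_dataframe(ipd, arm="TRAS")
        a, b = m.fit("lognormal"), m.fit("lognormal")
        assert a.cure_fraction == b.cure_fraction
        assert a.latent.params == b.latent.params
        assert a.loglik == b.loglik

    def test_all_censored_hits_cure_boundary(self):
        time = np.full(50, 120.0)
        event = np.zeros(50, dtype=int)
        res = fit_mixture_cure(time, event, "lognormal")
        assert res.cure_fraction == pytest.approx(1.0)
        assert res.boundary

    def test_information_criteria_consistency(self, ipd):
        """AIC/BIC recomputed from loglik and k match the stored fields."""
        m = MixtureCureModel.from_dataframe(ipd, arm="TRAS")
        for fit in m.fit_all():
            assert fit.aic == pytest.approx(2 * fit.k - 2 * fit.loglik, abs=1e-9)
            assert fit.bic == pytest.approx(
                fit.k * math.log(fit.n) - 2 * fit.loglik, abs=1e-9
            )

    def test_too_few_event_times_rejected(self):
        with pytest.raises(ValueError, match="distinct event times"):
            fit_mixture_cure([5.0, 5.0, 30.0], [1, 1, 0], "weibull")


class TestRanking:
    def _fake(self, family, loglik, n=100):
        params = {"exponential": (0.1,), "weibull": (1.0, 10.0),
                  "lognormal": (2.0, 1.0), "loglogistic": (1.0, 10.0)}
        from her2ce.survival import MixtureCureResults
        return MixtureCureResults(family, 0.5, ParametricFamily(family, params[family]),
                                  loglik, n, True, False)

    def test_single_fit_selected(self):
        f = self._fake("lognormal", -50.0)
        _, selected, _ = rank_by_information_criteria([f])
        assert selected is f

    def test_equal_loglik_fewer_params_wins(self):
        f2 = self._fake("exponential", -50.0)  # k=2
        f3 = self._fake("weibull", -50.0)  # k=3
        ranked, selected, _ = rank_by_information_criteria([f3, f2])
        assert selected.family == "exponential"

    def test_mixed_n_rejected(self):
        with pytest.raises(ValueError, match="sample sizes"):
            rank_by_information_criteria(
                [self._fake("exponential", -50.0, n=100),
                 self._fake("weibull", -50.0, n=200)]
            )


class TestCycleProbability:
    def test_exponential_is_memoryless(self):
        rate = 0.07
        latent = ParametricFamily("exponential", (rate,))
        sf = lambda t: mixture_cure_survival(t, 0.0, latent)
        expected = 1.0 - math.exp(-rate)
        for k in (0, 5, 50, 200):
            assert survival_to_cycle_prob(sf, k) == pytest.approx(
                expected, abs=1e-10
            )

    def test_constant_survival_gives_zero(self):
        assert survival_to_cycle_prob(lambda t: 0.8, 3) == 0.0

    def test_cured_plateau_probability_vanishes(self):
        latent = ParametricFamily("lognormal", (2.0, 0.5))
        sf = lambda t: mixture_cure_survival(t, 0.5, latent)
        assert survival_to_cycle_prob(sf, 500) < 1e-9

    def test_exhausted_cohort_is_error(self):
        with pytest.raises(ValueError, match="exhausted"):
            survival_to_cycle_prob(lambda t: 0.0, 1)


class TestWaning:
    def test_full_effect_before_window(self):
        sched = WaningSchedule()
        assert effective_hazard_ratio(0.54, 60.0, sched) == 0.54

    def test_no_effect_from_window_end(self):
        sched = WaningSchedule()
        assert effective_hazard_ratio(0.54, 120.0, sched) == 1.0
        assert effective_hazard_ratio(0.54, 500.0, sched) == 1.0

    def test_log_linear_midpoint(self):
        sched = WaningSchedule(t_full=84, t_none=120)
        assert effective_hazard_ratio(0.54, 102.0, sched) == pytest.approx(
            math.sqrt(0.54), abs=1e-12
        )

    def test_linear_shape_midpoint(self):
        sched = WaningSchedule(shape="linear")
        assert effective_hazard_ratio(0.54, 102.0, sched) == pytest.approx(
            (1 + 0.54) / 2, abs=1e-12
        )

    @pytest.mark.parametrize("shape", ["log-linear", "linear"])
    def test_continuity_at_window_edges(self, shape):
        sched = WaningSchedule(shape=shape)
        for t_edge in (84.0, 120.0):
            left = effective_hazard_ratio(0.54, t_edge - 1e-9, sched)
            right = effective_hazard_ratio(0.54, t_edge + 1e-9, sched)
            assert abs(left - right) < 1e-9
        # exact continuity at the knots to 1e-12 via limits
        assert abs(effective_hazard_ratio(0.54, 84.0, sched) - 0.54) < 1e-12
        assert abs(effective_hazard_ratio(0.54, 120.0, sched) - 1.0) < 1e-12

    def test_monotone_toward_null(self):
        sched = WaningSchedule()
        ts = np.linspace(84, 120, 100)
        hrs = [effective_hazard_ratio(0.54, t, sched) for t in ts]
        assert np.all(np.diff(hrs) >= -1e-12)

    def test_invalid_hr_rejected(self):
        with pytest.raises(ValueError):
            effective_hazard_ratio(0.0, 50.0, WaningSchedule())


class TestLifeTableBlending:
    def test_zero_background_leaves_disease_unchanged(self):
        lt = LifeTable(np.arange(101), np.zeros(101))
        p = np.array([0.01, 0.02, 0.03])
        out = blend_background_mortality(p, lt, baseline_age=52)
        np.testing.assert_allclose(out, p, atol=1e-15)

    def test_monthly_conversion_closed_form(self):
        q = np.full(101, 0.12)
        lt = LifeTable(np.arange(101), q)
        out = blend_background_mortality(np.zeros(3), lt, baseline_age=52)
        expected = 1.0 - 0.88 ** (1.0 / 12.0)
        np.testing.assert_allclose(out, expected, atol=1e-14)

    def test_both_zero_gives_zero(self):
        lt = LifeTable(np.arange(101), np.zeros(101))
        assert blend_background_mortality(np.zeros(2), lt, 52.0).sum() == 0.0

    def test_age_beyond_table_is_error(self):
        lt = LifeTable(np.arange(60), np.full(60, 0.01))
        with pytest.raises(ValueError, match="outside"):
            blend_background_mortality(np.zeros(24), lt, baseline_age=59.5)

    def test_csv_round_trip(self, tmp_path):
        from her2ce.datasets import synthetic_life_table
        lt = synthetic_life_table()
        path = tmp_path / "lt.csv"
        lt.to_csv(path)
        back = LifeTable.from_csv(path)
        np.testing.assert_allclose(back.annual_q, lt.annual_q)


class TestParametricFamilyValidation:
    @pytest.mark.parametrize("family", list(FAMILY_PARAM_NAMES))
    def test_wrong_arity_rejected(self, family):
        with pytest.raises(ValueError):
            ParametricFamily(family, (1.0, 2.0, 3.0))

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError):
            ParametricFamily("weibull", (1.0, -2.0))
        # meanlog may be negative, sdlog may not
        ParametricFamily("lognormal", (-1.0, 0.5))
        with pytest.raises(ValueError):
            ParametricFamily("lognormal", (1.0, 0.0))
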