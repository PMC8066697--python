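"""Kaplan-Meier, censored Weibull fitting, annual probabilities,
background-mortality convergence, and Cholesky factors."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from renalcea.survival import (AnnualProbabilityVector, FitError,
                               MortalityTable, SurvivalDataset,
                               SurvivalInputError, annual_transition_probs,
                               apply_background_convergence, cholesky_factor,
                               fit_weibull, kaplan_meier,
                               weibull_annual_probs, weibull_log_likelihood)


def ds(times, events, **kw):
    kw.setdefault("endpoint", "dwfg")
    kw.setdefault("diet", "dash")
    kw.setdefault("group", 1)
    return SurvivalDataset(times=np.asarray(times, float),
                           events=np.asarray(events, bool), **kw)


class TestKaplanMeier:
    def test_uniform_events_product_limit(self):
        est = kaplan_meier(ds([1, 2, 3, 4], [1, 1, 1, 1]))
        for t, s in [(1, 0.75), (2, 0.50), (3, 0.25), (4, 0.0)]:
            assert est.survival_at(t) == pytest.approx(s)

    def test_censoring_shrinks_risk_sets(self):
        # events at 1 and 3; censored at 2, 2, 4: S(1) = 4/5,
        # S(3) = 0.8 * (1 - 1/2) over the remaining risk set {3, 4}
        est = kaplan_meier(ds([1, 2, 2, 3, 4], [1, 0, 0, 1, 0]))
        assert est.survival_at(1) == pytest.approx(0.8)
        assert est.survival_at(3) == pytest.approx(0.4)
        assert est.survival_at(0.5) == 1.0

    def test_all_censored_flags_and_fit_refuses(self):
        data = ds([1.0, 2.0], [0, 0])
        est = kaplan_meier(data)
        assert est.all_censored
        assert np.all(est.survival == 1.0)
        with pytest.raises(FitError, match="at least one"):
            fit_weibull(data)

    def test_empty_dataset_rejected(self):
        with pytest.raises(SurvivalInputError):
            kaplan_meier(ds([], []))

    def test_nonpositive_times_rejected(self):
        with pytest.raises(SurvivalInputError):
            ds([1.0, 0.0], [1, 1])

    @given(st.lists(st.floats(0.1, 50.0), min_size=2, max_size=12,
                    unique=True))
    def test_uncensored_product_limit_identity(self, times):
        # with no censoring, KM after k events equals (n - k) / n
        n = len(times)
        est = kaplan_meier(ds(times, [1] * n))
        for k, t in enumerate(sorted(times), start=1):
            assert est.survival_at(t) == pytest.approx((n - k) / n)


class TestWeibullFit:
    def test_exponential_closed_form(self):
        rng = np.random.default_rng(0)
        times = rng.exponential(10.0, size=200)
        fit = fit_weibull(ds(times, [1] * 200), fixed_shape=1.0)
        assert fit.shape == 1.0
        assert fit.scale == pytest.approx(times.sum() / 200)

    def test_optimum_beats_surrounding_grid(self):
        rng = np.random.default_rng(1)
        times = 12.0 * rng.weibull(1.5, size=400)
        events = np.ones(400, bool)
        fit = fit_weibull(ds(times, events))
        ll_hat = weibull_log_likelihood(np.log(fit.shape), np.log(fit.scale),
                                        times, events)
        grid = np.linspace(-0.25, 0.25, 50)
        lls = [weibull_log_likelihood(np.log(fit.shape) + da,
                                      np.log(fit.scale) + db, times, events)
               for da in grid for db in grid]
        assert ll_hat >= max(lls) - 1e-6

    def test_loglik_matches_lifelines(self):
        from lifelines import WeibullFitter
        rng = np.random.default_rng(2)
        times = 20.0 * rng.weibull(1.3, size=500)
        events = times < 15.0
        times = np.minimum(times, 15.0)
        wf = WeibullFitter().fit(times, event_observed=events)
        ours = weibull_log_likelihood(np.log(wf.rho_), np.log(wf.lambda_),
                                      times, events)
        assert ours == pytest.approx(wf.log_likelihood_, rel=1e-9)

    def test_information_criteria_from_loglik(self):
        rng = np.random.default_rng(3)
        times = 8.0 * rng.weibull(1.2, size=300)
        fit = fit_weibull(ds(times, [1] * 300))
        assert fit.aic == pytest.approx(4.0 - 2.0 * fit.log_likelihood)
        assert fit.bic == pytest.approx(2.0 * np.log(300)
                                        - 2.0 * fit.log_likelihood)

    def test_covariance_is_symmetric_psd(self):
        rng = np.random.default_rng(4)
        times = 25.0 * rng.weibull(1.4, size=800)
        events = times < 20.0
        fit = fit_weibull(ds(np.minimum(times, 20.0), events))
        cov = fit.covariance
        assert np.allclose(cov, cov.T)
        assert np.all(np.linalg.eigvalsh(cov) > 0)
        # variances shrink roughly as 1/n: must be small at n=800
        assert cov[0, 0] < 0.01 and cov[1, 1] < 0.01


class TestAnnualProbabilities:
    def test_memoryless_case_constant(self):
        p = weibull_annual_probs(1.0, 7.0, 20)
        assert np.allclose(p, 1.0 - np.exp(-1.0 / 7.0))

    def test_increasing_hazard_first_cycle(self):
        p = weibull_annual_probs(2.0, 10.0, 5)
        assert p[0] == pytest.approx(1.0 - np.exp(-0.01))
        assert np.all(np.diff(p) > 0)

    @given(st.floats(0.6, 3.0), st.floats(3.0, 60.0))
    def test_telescoping_product_rebuilds_survival(self, shape, scale):
        horizon = 40
        p = weibull_annual_probs(shape, scale, horizon)
        rebuilt = np.cumprod(1.0 - p)
        t = np.arange(1, horizon + 1, dtype=float)
        expected = np.exp(-((t / scale) ** shape))
        assert np.max(np.abs(rebuilt - expected)) < 1e-12


def vec(values, endpoint="dwfg", group=1):
    return AnnualProbabilityVector(endpoint=endpoint, group=group,
                                   values=np.asarray(values, float))


class TestBackgroundConvergence:
    def table(self, start_age, qs):
        ages = np.arange(start_age, start_age + len(qs))
        return MortalityTable(ages, np.asarray(qs))

    def test_no_crossing_leaves_vector_unchanged(self):
        probs = vec([0.05] * 10)
        table = self.table(53, [0.01] * 10)
        out = apply_background_convergence(probs, table, 53.0)
        assert out.converged_from is None
        assert np.array_equal(out.values, probs.values)

    def test_crossing_index_and_replacement(self):
        background = np.linspace(0.005, 0.020, 20)
        probs = vec([0.010] * 20)
        table = self.table(60, background)
        out = apply_background_convergence(probs, table, 60.0)
        expected_idx = int(np.argmax(background > 0.010))
        assert out.converged_from == expected_idx
        assert np.array_equal(out.values[:expected_idx],
                              probs.values[:expected_idx])
        assert np.all(out.values[expected_idx:]
                      >= background[expected_idx:] - 1e-15)

    def test_graft_failure_vector_rejected(self):
        with pytest.raises(ValueError, match="DWFG"):
            apply_background_convergence(
                vec([0.01], endpoint="graft_failure"),
                self.table(50, [0.02]), 50.0)


class TestCholesky:
    def test_identity(self):
        assert np.array_equal(cholesky_factor(np.eye(2)), np.eye(2))

    def test_hand_factorisation(self):
        L = cholesky_factor(np.array([[4.0, 2.0], [2.0, 5.0]]))
        assert np.allclose(L, [[2.0, 0.0], [1.0, 2.0]])

    @given(st.floats(0.1, 5.0), st.floats(0.1, 5.0), st.floats(-0.95, 0.95))
    def test_reconstruction_residual(self, s1, s2, rho):
        cov = np.array([[s1 * s1, rho * s1 * s2],
                        [rho * s1 * s2, s2 * s2]])
        L = cholesky_factor(cov)
        assert np.max(np.abs(L @ L.T - cov)) < 1e-10
        assert L[0, 1] == 0.0

    def test_non_psd_rejected(self):
        with pytest.raises(ValueError, match="positive semi-definite"):
            cholesky_factor(np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestMortalityTable:
    def test_lookup_clamps_to_range(self):
        t = MortalityTable(np.arange(50, 60), np.linspace(0.01, 0.1, 10))
        assert t.lookup(40) == pytest.approx(0.01)
        assert t.lookup(99) == pytest.approx(0.1)
        assert t.lookup(55.7) == t.lookup(55)

    def test_csv_round_trip(self, tmp_path):
        t = MortalityTable.gompertz_makeham()
        path = tmp_path / "life.csv"
        t.to_csv(path)
        back = MortalityTable.from_csv(path)
        assert np.array_equal(back.ages, t.ages)
        assert np.allclose(back.q, t.q)

    def test_synthetic_table_plausible_adult_mortality(self):
        t = MortalityTable.gompertz_makeham()
        assert 0.001 < t.lookup(53) < 0.01
        assert 0.02 < t.lookup(80) < 0.10
        assert np.all(np.diff(t.q) >= 0)
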