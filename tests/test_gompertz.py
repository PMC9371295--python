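"""Gompertz hazard arithmetic and transition-specific maximum likelihood."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from statelife.gompertz import (GompertzPHModel, _numeric_hessian, _nll_grad,
                                _nll_grad_hess, design_matrix, episode_loglik,
                                fit_model_set, fit_transition,
                                fit_transition_arrays, compare_models,
                                gompertz_cumhaz, gompertz_hazard,
                                gompertz_invert_cumhaz)


def _episodes_df(t0, t1, d, sex=None):
    df = pd.DataFrame({"transition_id": 1, "t_entry": t0, "t_exit": t1,
                       "status": d})
    if sex is not None:
        df["sex"] = sex
        df["simd_quintile"] = 5
    return df


def _simulate_episodes(shape, rate, beta_female, n, rng):
    """Left-truncated, right-censored draws from a known Gompertz PH model."""
    female = rng.random(n) < 0.5
    lp = beta_female * female
    t0 = rng.uniform(0.0, 20.0, n)
    e = rng.exponential(1.0, n)
    t_event = t0 + gompertz_invert_cumhaz(e, t0, shape, rate, lp)
    t_cens = t0 + rng.uniform(1.0, 6.0, n)
    t1 = np.minimum(t_event, t_cens)
    d = (t_event <= t_cens).astype(float)
    return _episodes_df(t0, t1, d, np.where(female, "female", "male"))


class TestHazardArithmetic:
    def test_hazard_at_origin_is_rate(self):
        assert gompertz_hazard(0.0, 0.1, 0.05) == pytest.approx(0.05)

    def test_cumhaz_closed_form(self):
        # (0.05/0.1) * (e^0.2 - 1)
        assert gompertz_cumhaz(0.0, 2.0, 0.1, 0.05) == pytest.approx(0.1107014, abs=1e-6)

    def test_proportional_hazards_scaling(self):
        t = np.linspace(0, 30, 7)
        assert np.allclose(gompertz_hazard(t, 0.1, 0.05, np.log(2)),
                           2 * gompertz_hazard(t, 0.1, 0.05))
        assert np.allclose(gompertz_cumhaz(0.0, t, 0.1, 0.05, np.log(2)),
                           2 * gompertz_cumhaz(0.0, t, 0.1, 0.05))

    def test_shape_zero_continuous_limit(self):
        for s in (1e-9, -1e-9, 0.0):
            assert gompertz_cumhaz(1.0, 4.0, s, 0.02) == pytest.approx(0.06, rel=1e-6)

    @pytest.mark.parametrize("shape", [-0.08, 0.0, 0.12])
    def test_cumhaz_matches_quadrature(self, shape):
        rng = np.random.default_rng(5)
        for _ in range(25):
            t0 = rng.uniform(0, 30)
            t1 = t0 + rng.uniform(0.01, 20)
            rate, lp = rng.uniform(0.001, 0.2), rng.normal()
            num, _ = integrate.quad(lambda u: gompertz_hazard(u, shape, rate, lp),
                                    t0, t1, epsabs=1e-12, epsrel=1e-12)
            assert gompertz_cumhaz(t0, t1, shape, rate, lp) == pytest.approx(num, abs=1e-8)

    def test_invert_cumhaz_roundtrip(self):
        rng = np.random.default_rng(6)
        e = rng.exponential(1.0, 100)
        t0 = rng.uniform(0, 20, 100)
        s = gompertz_invert_cumhaz(e, t0, 0.09, 0.02, 0.3)
        back = gompertz_cumhaz(t0, t0 + s, 0.09, 0.02, 0.3)
        assert np.allclose(back, e, rtol=1e-10)

    def test_invert_cumhaz_negative_shape_defective(self):
        # total remaining hazard is finite; large draws never happen
        s = gompertz_invert_cumhaz(np.array([50.0]), 0.0, -0.2, 0.01)
        assert np.isinf(s[0])


class TestEpisodeLoglik:
    def test_empty_is_zero(self):
        assert episode_loglik(_episodes_df([], [], []), 0.1, 0.05) == 0.0

    def test_censored_exponential_window(self):
        df = _episodes_df([0.0], [7.0], [0])
        assert episode_loglik(df, 0.0, 0.3) == pytest.approx(-0.3 * 7.0)

    def test_matches_quadrature_oracle(self):
        rng = np.random.default_rng(11)
        t0 = rng.uniform(0, 10, 100)
        t1 = t0 + rng.uniform(0.1, 10, 100)
        d = (rng.random(100) < 0.3).astype(int)
        shape, rate = 0.07, 0.04
        expected = 0.0
        for a, b, ev in zip(t0, t1, d):
            H, _ = integrate.quad(lambda u: gompertz_hazard(u, shape, rate),
                                  a, b, epsabs=1e-13)
            expected += ev * np.log(gompertz_hazard(b, shape, rate)) - H
        got = episode_loglik(_episodes_df(t0, t1, d), shape, rate)
        assert got == pytest.approx(expected, abs=1e-8)

    def test_analytic_derivatives_match_numerics(self):
        rng = np.random.default_rng(12)
        t0 = rng.uniform(0, 5, 60)
        t1 = t0 + rng.uniform(0.1, 5, 60)
        d = (rng.random(60) < 0.4).astype(float)
        X = rng.normal(size=(60, 2))
        theta = np.array([0.06, np.log(0.03), 0.2, -0.4])
        args = (t0, t1, d, X, "gompertz")
        nll, grad, H = _nll_grad_hess(theta, *args)
        eps = 1e-7
        for j in range(4):
            tp = theta.copy(); tp[j] += eps
            tm = theta.copy(); tm[j] -= eps
            num = (_nll_grad(tp, *args)[0] - _nll_grad(tm, *args)[0]) / (2 * eps)
            assert grad[j] == pytest.approx(num, rel=1e-5, abs=1e-7)
        Hnum = _numeric_hessian(lambda th: _nll_grad(th, *args), theta)
        assert np.allclose(H, Hnum, rtol=1e-4, atol=1e-6)


class TestFitting:
    def test_exponential_mle_closed_form(self):
        # 10 events over 200 person-years -> rate 0.05
        t0 = np.zeros(20)
        t1 = np.full(20, 10.0)
        d = np.zeros(20)
        d[:10] = 1.0
        fit = fit_transition_arrays(t0, t1, d, np.empty((20, 0)), [],
                                    distribution="exponential")
        assert fit.rate == pytest.approx(10.0 / 200.0, rel=1e-8)
        assert fit.shape == 0.0

    def test_parameter_recovery_within_3se(self):
        rng = np.random.default_rng(2024)
        df = _simulate_episodes(0.08, 0.02, -0.3, 5000, rng)
        fit = fit_transition(df, ["female"])
        se = fit.se()
        assert abs(fit.shape - 0.08) < 3 * se["shape"]
        assert abs(np.log(fit.rate) - np.log(0.02)) < 3 * se["log_rate"]
        assert abs(fit.coefficients["female"] + 0.3) < 3 * se["female"]

    def test_duplicating_episodes_halves_variance(self):
        rng = np.random.default_rng(3)
        df = _simulate_episodes(0.05, 0.03, 0.2, 800, rng)
        fit1 = fit_transition(df, ["female"])
        fit2 = fit_transition(pd.concat([df, df], ignore_index=True), ["female"])
        assert fit2.shape == pytest.approx(fit1.shape, abs=1e-6)
        assert fit2.rate == pytest.approx(fit1.rate, rel=1e-6)
        se1, se2 = fit1.se(), fit2.se()
        for k in se1:
            assert se2[k] == pytest.approx(se1[k] / np.sqrt(2), rel=1e-3)

    def test_zero_events_fails(self):
        with pytest.raises(ValueError, match="zero events"):
            fit_transition_arrays(np.zeros(5), np.ones(5), np.zeros(5),
                                  np.empty((5, 0)), [])

    def test_gompertz_nests_exponential(self):
        rng = np.random.default_rng(4)
        df = _simulate_episodes(0.1, 0.03, 0.0, 1500, rng)
        gom = fit_transition(df, [])
        expo = fit_transition(df, [], distribution="exponential")
        assert gom.loglik >= expo.loglik - 1e-9

    def test_hr_invariant_to_covariate_origin(self):
        rng = np.random.default_rng(9)
        df = _simulate_episodes(0.06, 0.02, 0.0, 1200, rng)
        df["x"] = rng.normal(2.0, 1.0, len(df))
        shifted = df.copy()
        shifted["x"] = shifted["x"] - 7.5
        b1 = fit_transition(df, ["x"]).coefficients["x"]
        b2 = fit_transition(shifted, ["x"]).coefficients["x"]
        assert b1 == pytest.approx(b2, abs=1e-6)


class TestModelSet:
    def test_null_covariates_recovered(self, default_sim):
        import statelife as sl
        from statelife.gompertz import TransitionModel
        base = sl.default_config(100).true_models
        models = {tid: TransitionModel(m.shape, m.rate, {})
                  for tid, m in base.items()}
        cfg = sl.default_config(6000, seed=31, true_models=models)
        sim = sl.simulate_cohort(cfg)
        build = sl.build_analysis_episodes(sim.cohort)
        ms = fit_model_set(build.episodes, "set1")
        for tid, m in ms.models.items():
            assert abs(m.coefficients["female"]) < 3 * m.se()["female"], tid

    def test_deprivation_sign_on_death_transitions(self, default_sim):
        build = __import__("statelife").build_analysis_episodes(default_sim.cohort)
        ms = fit_model_set(build.episodes, "set2", compute_vcov=False)
        for tid in (2, 4, 6, 7):
            assert np.exp(ms.models[tid].coefficients["q1"]) > 1.0

    def test_set1_equals_quintile_free_set2(self, default_sim):
        # on episodes whose quintile column is constant, dropping the dummy
        # columns reproduces the sex-only fit exactly
        build = __import__("statelife").build_analysis_episodes(default_sim.cohort)
        epi = build.episodes[build.episodes["simd_quintile"] == 5]
        epi = epi[epi["transition_id"] == 7].copy()
        X1, n1 = design_matrix(epi, ["female"])
        X2, n2 = design_matrix(epi, ["female", "q1", "q2", "q3", "q4"])
        args = (epi["t_entry"].to_numpy(), epi["t_exit"].to_numpy(),
                epi["status"].to_numpy(dtype=float))
        f1 = fit_transition_arrays(*args, X1, n1, compute_vcov=False)
        f2 = fit_transition_arrays(*args, X2, n2, compute_vcov=False)
        assert f2.coefficients["female"] == pytest.approx(f1.coefficients["female"], abs=1e-5)
        assert f2.rate == pytest.approx(f1.rate, rel=1e-5)


class TestModelComparison:
    def test_identical_fit_zero_delta(self, default_sim):
        import statelife as sl
        build = sl.build_analysis_episodes(default_sim.cohort)
        ms = fit_model_set(build.episodes, "set1", compute_vcov=False)
        rep = compare_models({"a": ms, "b": ms})
        assert np.allclose(rep["delta_a"], 0) and np.allclose(rep["delta_b"], 0)

    def test_aic_prefers_true_gompertz(self, default_sim):
        import statelife as sl
        build = sl.build_analysis_episodes(default_sim.cohort)
        gom = fit_model_set(build.episodes, "set1", compute_vcov=False)
        expo = fit_model_set(build.episodes, "set1", distribution="exponential",
                             compute_vcov=False)
        rep = compare_models({"gompertz": gom, "exponential": expo})
        # death transitions have strongly age-graded hazards; the true model wins
        for tid in (2, 4, 6, 7):
            row = rep[rep["transition"] == tid].iloc[0]
            assert row["best"] == "gompertz", tid

    def test_mismatched_episodes_rejected(self, default_sim):
        import statelife as sl
        build = sl.build_analysis_episodes(default_sim.cohort)
        ms = fit_model_set(build.episodes, "set1", compute_vcov=False)
        half = fit_model_set(build.episodes.iloc[: len(build.episodes) // 2]
                             if True else build.episodes, "set1",
                             compute_vcov=False)
        with pytest.raises(ValueError, match="episode counts differ"):
            compare_models({"a": ms, "b": half})


class TestAlgebraicProperties:
    """Hypothesis-driven invariants of the hazard algebra."""

    from hypothesis import given, settings, strategies as st

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(shape=st.floats(-0.3, 0.3), rate=st.floats(1e-4, 0.5),
           t0=st.floats(0, 30), d1=st.floats(0.01, 15), d2=st.floats(0.01, 15))
    def test_cumhaz_additive_over_windows(self, shape, rate, t0, d1, d2):
        whole = gompertz_cumhaz(t0, t0 + d1 + d2, shape, rate)
        split = (gompertz_cumhaz(t0, t0 + d1, shape, rate)
                 + gompertz_cumhaz(t0 + d1, t0 + d1 + d2, shape, rate))
        assert whole == pytest.approx(split, rel=1e-9, abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(shape=st.floats(-0.3, 0.3), rate=st.floats(1e-4, 0.5),
           e=st.floats(1e-6, 5), t0=st.floats(0, 30))
    def test_inversion_is_inverse(self, shape, rate, e, t0):
        s = gompertz_invert_cumhaz(np.array([e]), t0, shape, rate)[0]
        if np.isfinite(s):
            assert gompertz_cumhaz(t0, t0 + s, shape, rate) == \
                pytest.approx(e, rel=1e-8)
        else:
            # defective distribution: total remaining hazard below the draw
            total = gompertz_cumhaz(t0, 1e4, shape, rate)
            assert total < e
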