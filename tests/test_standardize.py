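"""Standardization: closed forms, symmetry, delta-method CIs."""

import numpy as np
import pandas as pd
import pytest

from policyits.model import ModelSpec, MultilevelPoissonITS
from policyits.recovery import recovery_config
from policyits.scenarios import ExposureScenario, apply_scenario
from policyits.config import PopulationConfig
from policyits.simulate import generate_population, true_marginal_effect
from policyits.standardize import predict_rate, standardize


@pytest.fixture(scope="module")
def glm_fit():
    """Fixed-effects fit on a homogeneous covariate-free cohort."""
    cfg = recovery_config(n_clusters=30, seed=50, households_per_cluster=6.0,
                          psi11=0.0)
    records, _ = generate_population(cfg)
    sc = ExposureScenario.primary()
    inc, _ = apply_scenario(records, sc)
    spec = ModelSpec(outcome="delivery",
                     fixed_terms=("time", "subsidy", "post_time"),
                     random_terms=())
    res = MultilevelPoissonITS.from_records(inc, spec, sc).fit()
    return res


class TestPredictRate:
    def test_closed_form_rates(self, glm_fit):
        """With beta0=log(0.5), beta2=log(1.2), beta1=beta3=0 the two
        counterfactual rates are 0.5 and 0.6 (RR 1.2) at every horizon."""
        res = glm_fit
        beta = res.params.copy()
        beta[:] = 0.0
        beta["intercept"] = np.log(0.5)
        beta["subsidy"] = np.log(1.2)
        eb = res.eb_predict()
        for h in (0, 18, 42):
            r1, _ = predict_rate(res, eb, 1, h, beta=beta.to_numpy())
            r0, _ = predict_rate(res, eb, 0, h, beta=beta.to_numpy())
            assert np.allclose(r1, 0.6) and np.allclose(r0, 0.5)

    def test_null_subsidy_effect_equal_rates(self, glm_fit):
        res = glm_fit
        beta = res.params.copy()
        beta["subsidy"] = 0.0
        beta["post_time"] = 0.0
        eb = res.eb_predict()
        for h in (0, 24):
            r1, _ = predict_rate(res, eb, 1, h, beta=beta.to_numpy())
            r0, _ = predict_rate(res, eb, 0, h, beta=beta.to_numpy())
            assert np.allclose(r1, r0)

    def test_matches_hand_computed_linear_predictor(self, simple_fit):
        _, _, res = simple_fit
        eb = res.eb_predict()
        h = 12
        rates, _ = predict_rate(res, eb, 1, h)
        b = res.bundle
        beta = res.params
        cutoff = b.scenario.cutoff_month
        T = cutoff - b.spec.time_origin + h
        cl = np.searchsorted(b.cluster_gi.starts, np.arange(b.n),
                             side="right") - 1
        u0 = eb.cluster_effects["intercept"].to_numpy()[cl]
        eta = (beta["intercept"] + beta["time"] * T + beta["subsidy"]
               + beta["post_time"] * h + u0)
        assert np.allclose(rates, np.minimum(np.exp(eta), 1.0), atol=1e-12)

    def test_negative_horizon_rejected(self, glm_fit):
        with pytest.raises(ValueError):
            predict_rate(glm_fit, glm_fit.eb_predict(), 1, -1)


class TestStandardize:
    def test_deterministic(self, simple_fit):
        _, _, res = simple_fit
        g1 = standardize(res, horizons=(0, 6), ci=False)
        g2 = standardize(res, horizons=(0, 6), ci=False)
        pd.testing.assert_frame_equal(g1.table, g2.table)

    def test_rr_rd_consistency(self, simple_fit):
        _, _, res = simple_fit
        g = standardize(res, ci=False)
        t = g.table
        assert (t.rr > 0).all()
        assert np.allclose(t.rd, t.rate_with - t.rate_without)
        assert ((t.rr_lo if "rr_lo" in t else t.rr) <= t.rr).all()

    def test_swapping_subsidy_coding_inverts_rr(self, simple_fit):
        _, _, res = simple_fit
        eb = res.eb_predict()
        h = 6
        r1, _ = predict_rate(res, eb, 1, h)
        r0, _ = predict_rate(res, eb, 0, h)
        rr = r1.mean() / r0.mean()
        rr_swapped = r0.mean() / r1.mean()
        assert rr_swapped == pytest.approx(1 / rr, rel=1e-12)

    def test_increasing_slope_change_gives_monotone_rr(self, glm_fit):
        res = glm_fit
        beta = res.params.copy()
        beta["subsidy"] = 0.05
        beta["post_time"] = 0.004
        beta["intercept"] = np.log(0.2)
        beta["time"] = 0.0
        theta = res.theta.copy()
        theta[:len(beta)] = beta.to_numpy()
        res2 = type(res)(res.model, theta=theta, loglik=res.loglik,
                         converged=True)
        g = standardize(res2, ci=False)
        assert (np.diff(g.table.rr.to_numpy()) > 0).all()

    @pytest.mark.parametrize("outcome,horizon", [("delivery", 0),
                                                 ("mortality", 12)])
    def test_truth_parameter_grid_matches_independent_oracle(self, outcome,
                                                             horizon):
        """The standardization machinery, run at the generator-truth
        coefficients and drawn random effects, reproduces the marginal RR
        from an independent Monte-Carlo population draw."""
        from policyits.recovery import run_standardization_oracle
        out = run_standardization_oracle(seed=5, horizon=horizon,
                                         n_clusters=150, outcome=outcome)
        se = np.hypot(out["se_standardize"], out["se_oracle"])
        assert abs(out["rr_standardize"] - out["rr_oracle"]) < 2 * se
        se_rd = np.hypot(out["rd_se_standardize"], out["rd_se_oracle"])
        assert abs(out["rd_standardize"] - out["rd_oracle"]) < 2 * se_rd

    def test_empty_records_rejected(self, glm_fit):
        res = glm_fit
        y_old = res.bundle.y
        res.bundle.y = y_old[:0]
        try:
            with pytest.raises(ValueError):
                standardize(res)
        finally:
            res.bundle.y = y_old


class TestDeltaCI:
    def test_zero_covariance_degenerate_ci(self, glm_fit):
        res = glm_fit
        res._cov_robust = None
        old = res.robust_cov
        res.robust_cov = lambda **kw: np.zeros((res.model.layout.p,
                                                res.model.layout.p))
        try:
            g = standardize(res, horizons=(0,))
        finally:
            res.robust_cov = old
        row = g.table.iloc[0]
        assert row.rr_lo == pytest.approx(row.rr, rel=1e-9)
        assert row.rd_lo == pytest.approx(row.rd, abs=1e-12)

    def test_ci_brackets_point(self, simple_fit):
        _, _, res = simple_fit
        g = standardize(res)
        t = g.table
        assert ((t.rr_lo <= t.rr) & (t.rr <= t.rr_hi)).all()
        assert ((t.rd_lo <= t.rd) & (t.rd <= t.rd_hi)).all()

    def test_matches_parametric_bootstrap(self, glm_fit):
        """Delta CI half-width within 10% of a 2000-draw parametric
        bootstrap over the robust coefficient distribution."""
        res = glm_fit
        cov = res.robust_cov()
        g = standardize(res, horizons=(0,), robust=True)
        eb = res.eb_predict()
        rng = np.random.default_rng(0)
        draws = rng.multivariate_normal(res.params.to_numpy(), cov, 2000)
        log_rrs = []
        for beta in draws:
            r1, _ = predict_rate(res, eb, 1, 0, beta=beta)
            r0, _ = predict_rate(res, eb, 0, 0, beta=beta)
            log_rrs.append(np.log(r1.mean() / r0.mean()))
        boot_se = np.std(log_rrs, ddof=1)
        row = g.table.iloc[0]
        delta_se = np.log(row.rr_hi / row.rr) / 1.959963984540054
        assert delta_se == pytest.approx(boot_se, rel=0.10)


def test_two_vs_three_level_rr_agreement():
    """Woman-level intercept in or out: standardized RRs agree closely
    (the rationale for reporting two-level results)."""
    import warnings
    cfg = PopulationConfig(n_clusters=250, n_regions=13,
                           households_per_cluster_mean=10.0, seed=88)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        df, _ = generate_population(cfg)
    sc = ExposureScenario.primary()
    win = df[(df.birth_month >= 12) & (df.birth_month < 132)]
    inc, _ = apply_scenario(win, sc)
    kw = dict(outcome="mortality",
              fixed_terms=("time", "subsidy", "post_time", "rural"),
              random_terms=("intercept",), quadrature_nodes=5)
    res2 = MultilevelPoissonITS.from_records(
        inc, ModelSpec(n_levels=2, **kw), sc).fit(restarts=0)
    res3 = MultilevelPoissonITS.from_records(
        inc, ModelSpec(n_levels=3, **kw), sc).fit(restarts=0)
    g2 = standardize(res2, horizons=(0, 42), ci=False)
    g3 = standardize(res3, horizons=(0, 42), ci=False)
    assert np.abs(g2.table.rr.to_numpy() - g3.table.rr.to_numpy()).max() \
        < 0.02
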