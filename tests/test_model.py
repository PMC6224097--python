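"""Model fitting: GLM oracle, robust variance, LRT, EB, VIF, screens."""

import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from policyits.config import PopulationConfig
from policyits.model import (ConfounderDecision, ModelSpec,
                             MultilevelPoissonITS, build_design,
                             confounder_screen, lrt, overdispersion_check,
                             vif)
from policyits.recovery import recovery_config
from policyits.scenarios import ExposureScenario, apply_scenario
from policyits.simulate import generate_population
from conftest import small_config


@pytest.fixture(scope="module")
def glm_setting():
    """No-random-effects cohort and the fitted model."""
    cfg = small_config(seed=3)
    for oc in ("delivery", "mortality"):
        cfg.true_psi[oc].update(psi11=0.0, psi22=0.0, psi33=0.0,
                                corr_int_subsidy=0.0, corr_int_time=0.0,
                                level2_var=0.0)
    records, _ = generate_population(cfg)
    sc = ExposureScenario.primary()
    inc, _ = apply_scenario(records, sc)
    spec = ModelSpec(outcome="delivery", random_terms=())
    model = MultilevelPoissonITS.from_records(inc, spec, sc)
    return model, model.fit()


class TestGLMOracle:
    def test_matches_statsmodels_poisson(self, glm_setting):
        model, res = glm_setting
        glm = sm.GLM(model.bundle.y, model.bundle.X,
                     family=sm.families.Poisson()).fit()
        assert np.abs(res.params.to_numpy() - glm.params).max() < 1e-6
        assert res.loglik == pytest.approx(glm.llf, abs=1e-6)

    def test_record_clustered_sandwich_matches_hc0(self, glm_setting):
        model, res = glm_setting
        V = res.robust_cov(cluster="record", df_correction=False)
        glm = sm.GLM(model.bundle.y, model.bundle.X,
                     family=sm.families.Poisson()).fit(cov_type="HC0")
        assert np.abs(np.sqrt(np.diag(V)) - glm.bse).max() < 1e-8

    def test_region_clustered_se_finite_nonnegative(self, glm_setting):
        _, res = glm_setting
        se = res.bse(robust=True)
        assert np.isfinite(se).all() and (se >= 0).all()

    def test_robust_se_invariant_to_region_relabelling(self, glm_setting):
        model, res = glm_setting
        V1 = res.robust_cov(cluster="region")
        # relabel regions by permutation: same partition, same sandwich
        b = model.bundle
        perm = np.random.default_rng(0).permutation(100)
        old = b.region_of_cluster.copy()
        b.region_of_cluster = perm[old]
        try:
            V2 = res.robust_cov(cluster="region")
        finally:
            b.region_of_cluster = old
        assert np.allclose(V1, V2, atol=1e-12)

    def test_single_group_rejected(self, glm_setting):
        model, res = glm_setting
        b = model.bundle
        old = b.region_of_cluster.copy()
        b.region_of_cluster = np.zeros_like(old)
        try:
            with pytest.raises(ValueError, match=">= 2"):
                res.robust_cov(cluster="region")
        finally:
            b.region_of_cluster = old


def test_mixed_fit_robust_se_positive(simple_fit):
    _, _, res = simple_fit
    se = res.bse(robust=True)
    assert np.isfinite(se).all() and (se > 0).all()
    # robust and model-based are on comparable scales
    ratio = se / res.bse(robust=False)
    assert ((ratio > 0.2) & (ratio < 5)).all()


def test_all_zero_outcome_does_not_crash():
    cfg = small_config(seed=8, n_clusters=20)
    records, _ = generate_population(cfg)
    records = records.copy()
    records["facility_delivery"] = 0
    sc = ExposureScenario.primary()
    inc, _ = apply_scenario(records, sc)
    spec = ModelSpec(outcome="delivery", random_terms=())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = MultilevelPoissonITS.from_records(inc, spec, sc).fit()
    assert np.isfinite(res.params.drop("intercept")).all()
    assert res.params["intercept"] < -10  # boundary: log rate -> -inf


def test_boundary_variance_collapses_to_simple_poisson():
    """Data with no cluster heterogeneity: the random intercept collapses
    and the fit reduces to the fixed-effects model."""
    cfg = recovery_config(n_clusters=50, seed=21, households_per_cluster=6.0,
                          psi11=0.0)
    records, _ = generate_population(cfg)
    sc = ExposureScenario.primary()
    inc, _ = apply_scenario(records, sc)
    spec = ModelSpec(outcome="delivery",
                     fixed_terms=("time", "subsidy", "post_time"),
                     random_terms=("intercept",))
    res = MultilevelPoissonITS.from_records(inc, spec, sc).fit(restarts=0)
    assert "intercept" in res.collapsed_random_terms
    assert res.psi is None or len(res.psi) == 0


class TestLRT:
    def test_identical_models_statistic_zero(self, simple_fit):
        _, _, res = simple_fit
        out = lrt(res, res)
        assert out.statistic == 0.0 and out.p_value == 1.0

    def test_nested_loglik_monotone_and_df(self, glm_setting):
        model, res_full = glm_setting
        b = model.bundle
        spec0 = ModelSpec(outcome="delivery", random_terms=(),
                          fixed_terms=("time", "subsidy", "post_time"))
        # rebuild nested model on identical records
        cfg = small_config(seed=3)
        for oc in ("delivery", "mortality"):
            cfg.true_psi[oc].update(psi11=0.0, psi22=0.0, psi33=0.0,
                                    corr_int_subsidy=0.0, level2_var=0.0)
        records, _ = generate_population(cfg)
        sc = ExposureScenario.primary()
        inc, _ = apply_scenario(records, sc)
        res0 = MultilevelPoissonITS.from_records(inc, spec0, sc).fit()
        out = lrt(res0, res_full)
        assert out.statistic >= 0
        assert out.df == res_full.k_params - res0.k_params
        with pytest.raises(ValueError, match="not nested"):
            lrt(res_full, res0)

    def test_boundary_variance_power(self):
        """Simulated psi22 > 0: the boundary LRT for the random subsidy
        slope rejects at 0.05 in the majority of seeds."""
        rejections = 0
        n_seeds = 8
        for i in range(n_seeds):
            # large clusters and a low event rate: variance components of a
            # binary outcome under the Poisson working likelihood are
            # attenuated, so power needs informative cluster sizes
            cfg = recovery_config(n_clusters=60, seed=430 + i,
                                  households_per_cluster=25.0,
                                  psi11=0.25, psi22=0.5, corr=0.0)
            cfg.true_beta["delivery"] = {"intercept": float(np.log(0.15)),
                                         "time": 0.001, "subsidy": 0.14,
                                         "post_time": 0.0}
            records, _ = generate_population(cfg)
            sc = ExposureScenario.primary()
            inc, _ = apply_scenario(records, sc)
            spec1 = ModelSpec(outcome="delivery",
                              fixed_terms=("time", "subsidy", "post_time"),
                              random_terms=("intercept", "subsidy"),
                              covariance_structure="diagonal",
                              quadrature_nodes=5)
            spec0 = spec1.drop_random("subsidy")
            r0 = MultilevelPoissonITS.from_records(inc, spec0, sc).fit(
                restarts=0)
            r1 = MultilevelPoissonITS.from_records(inc, spec1, sc).fit(
                restarts=0, collapse_boundary=False)
            out = lrt(r0, r1, boundary=True)
            assert out.statistic >= -1e-8
            rejections += out.p_value < 0.05
        assert rejections > n_seeds / 2


class TestEB:
    def test_modes_match_grid_argmax(self, simple_fit):
        _, _, res = simple_fit
        eb = res.eb_predict()
        b = res.bundle
        beta = res.params.to_numpy()
        psi11 = float(res.psi.iloc[0, 0])
        eta = b.X @ beta
        grid = np.linspace(-4, 4, 80001)
        for k in (0, 7, 23):
            idx = slice(b.cluster_gi.starts[k],
                        b.cluster_gi.starts[k + 1]
                        if k + 1 < b.n_clusters else b.n)
            f = (b.y[idx, None] * (eta[idx, None] + grid)
                 - np.exp(eta[idx, None] + grid)).sum(axis=0) \
                - grid ** 2 / (2 * psi11)
            assert eb.cluster_effects.iloc[k, 0] == pytest.approx(
                grid[np.argmax(f)], abs=1e-4)

    def test_high_rate_cluster_positive_intercept(self, simple_fit):
        _, inc, res = simple_fit
        eb = res.eb_predict()
        rates = inc.groupby("cluster_id")["facility_delivery"].mean()
        hi = rates.idxmax()
        lo = rates.idxmin()
        assert eb.cluster_effects.loc[hi, "intercept"] > 0
        assert eb.cluster_effects.loc[lo, "intercept"] < 0

    def test_zero_psi_gives_zero_predictions(self, glm_setting):
        _, res = glm_setting
        eb = res.eb_predict()
        assert eb.cluster_effects.shape[1] == 0 or \
            np.allclose(eb.cluster_effects.to_numpy(), 0.0)


class TestVIF:
    def test_orthogonal_columns_give_one(self):
        rng = np.random.default_rng(0)
        n = 4000
        df = _toy_records(n, rng)
        sc = ExposureScenario.primary()
        spec = ModelSpec(outcome="delivery", random_terms=(),
                         fixed_terms=("worked", "newborn_female"))
        b = build_design(df, spec, sc)
        v = vif(b)
        assert (np.abs(v - 1.0) < 0.05).all()

    def test_known_correlation_closed_form(self):
        rng = np.random.default_rng(1)
        n = 200000
        rho = 0.6
        x1 = rng.binomial(1, 0.5, n)
        # construct binary x2 with correlation ~rho to x1
        flip = rng.random(n) < (1 + rho) / 2
        x2 = np.where(flip, x1, 1 - x1)
        df = _toy_records(n, rng)
        df["mother_worked"] = x1
        df["newborn_female"] = x2
        sc = ExposureScenario.primary()
        spec = ModelSpec(outcome="delivery", random_terms=(),
                         fixed_terms=("worked", "newborn_female"))
        b = build_design(df, spec, sc)
        v = vif(b)
        emp_rho = np.corrcoef(x1, x2)[0, 1]
        assert v["worked"] == pytest.approx(1 / (1 - emp_rho ** 2), rel=1e-6)

    def test_duplicated_column_flagged(self):
        rng = np.random.default_rng(2)
        df = _toy_records(1000, rng)
        df["newborn_female"] = df["mother_worked"]
        sc = ExposureScenario.primary()
        spec = ModelSpec(outcome="delivery", random_terms=(),
                         fixed_terms=("worked", "newborn_female"))
        b = build_design(df, spec, sc)
        v = vif(b)
        assert np.isinf(v["worked"]) and np.isinf(v["newborn_female"])


def _toy_records(n, rng):
    return pd.DataFrame({
        "region_id": 0, "cluster_id": rng.integers(0, 10, n),
        "household_id": np.arange(n), "woman_id": np.arange(n),
        "birth_id": np.arange(n), "birth_month": rng.integers(0, 132, n),
        "calendar_month_of_year": 1, "facility_delivery":
            rng.binomial(1, 0.4, n), "neonatal_death": 0,
        "rural": rng.binomial(1, 0.5, n), "wealth_quintile": 1,
        "education": "none", "literate": 0, "mother_age_group": "20-24",
        "multiple_birth": 0, "birth_order_cat": "2-4",
        "preceding_interval_cat": "<36",
        "mother_worked": rng.binomial(1, 0.5, n),
        "newborn_female": rng.binomial(1, 0.5, n),
    })


class TestOverdispersion:
    def test_statistic_nonnegative_and_bernoulli_not_rejected(self):
        cfg = recovery_config(n_clusters=40, seed=31,
                              households_per_cluster=6.0)
        records, _ = generate_population(cfg)
        sc = ExposureScenario.primary()
        inc, _ = apply_scenario(records, sc)
        spec = ModelSpec(outcome="delivery",
                         fixed_terms=("time", "subsidy", "post_time"),
                         random_terms=())
        out = overdispersion_check(inc, spec, sc)
        assert out.statistic >= -1e-8
        assert out.boundary
        assert out.p_value > 0.05


class TestConfounderScreen:
    def test_identical_coefficient_dropped(self, simple_fit):
        _, _, res = simple_fit
        assert confounder_screen(res, res).keep is False

    def test_twenty_percent_change_kept(self, simple_fit):
        _, _, res = simple_fit
        other = _FakeFit({"subsidy": 0.12})
        base = _FakeFit({"subsidy": 0.10})
        out = confounder_screen(other, base)
        assert out.keep and out.relative_change == pytest.approx(0.2)

    def test_zero_reference_indeterminate(self):
        out = confounder_screen(_FakeFit({"subsidy": 0.1}),
                                _FakeFit({"subsidy": 0.0}))
        assert out.indeterminate and out.keep


class _FakeFit:
    def __init__(self, params):
        self.params = pd.Series(params)
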