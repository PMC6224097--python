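"""Synthetic DHS-like hierarchical birth histories.

The generator draws a region > cluster > household > woman > birth hierarchy
and produces the two binary outcomes (facility delivery, neonatal death)
from the segmented log-rate model

    log p = (b0 + g0_jk + g00_k) + (b1 + g1_k) T + (b2 + g2_k) I
            + (b3 + g3_k) post_time + covariate terms,

with cluster-level random intercept/subsidy/time effects drawn from a
configurable (possibly rank-deficient) trivariate normal, an optional
woman-level intercept, and per-birth rates truncated into (0, 1) before the
Bernoulli draw.  Exposure I is the *actual* cluster-level exposure under a
staggered 0-3 month roll-out; downstream scenarios re-assign exposure from
the birth month alone, which is what creates the misclassification the
sensitivity analyses probe.

All randomness flows from the single config seed through fixed-order
`SeedSequence` spawns, so identical configs give identical record tables.
"""

from __future__ import annotations

import warnings
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .config import (AGE_LEVELS, EDUCATION_LEVELS, INTERVAL_LEVELS,
                     ORDER_LEVELS, PopulationConfig)

__all__ = ["generate_population", "true_marginal_effect", "TruncationWarning"]


class TruncationWarning(UserWarning):
    """Raised when the log-link implies rate > 1 for many births."""


# ---------------------------------------------------------------------------
# hierarchy and covariates
# ---------------------------------------------------------------------------

def _births_per_woman(cfg: PopulationConfig, rng: np.random.Generator,
                      n_women: int) -> np.ndarray:
    """1 + NegBin(r, mu) truncated to support {1..8}."""
    r, mu = cfg.births_nb_r, cfg.births_nb_mu
    p = r / (r + mu)
    pmf = stats.nbinom.pmf(np.arange(8), r, p)
    pmf = pmf / pmf.sum()
    return rng.choice(8, size=n_women, p=pmf) + 1


def _seasonal_month_draw(cfg, rng, lo, max_first):
    """First-birth month per woman in [lo, max_first], seasonally weighted."""
    n = max_first.size
    if cfg.seasonal_multiplier is None:
        u = rng.random(n)
        return lo + np.floor(u * (max_first - lo + 1)).astype(int)
    w = np.asarray(cfg.seasonal_multiplier, dtype=float)
    wmax = w.max()
    out = np.empty(n, dtype=int)
    pending = np.ones(n, dtype=bool)
    for _ in range(64):
        idx = np.flatnonzero(pending)
        if idx.size == 0:
            break
        u = rng.random(idx.size)
        prop = lo + np.floor(u * (max_first[idx] - lo + 1)).astype(int)
        accept = rng.random(idx.size) < w[prop % 12] / wmax
        out[idx[accept]] = prop[accept]
        pending[idx[accept]] = False
    if pending.any():  # pathological weights: fall back to uniform
        idx = np.flatnonzero(pending)
        u = rng.random(idx.size)
        out[idx] = lo + np.floor(u * (max_first[idx] - lo + 1)).astype(int)
    return out


def _simulate_structure(cfg: PopulationConfig,
                        rng: np.random.Generator) -> Dict[str, np.ndarray]:
    """Draw the hierarchy, birth timing and covariates (no outcomes)."""
    lo, hi = cfg.observation_window
    margins = cfg.covariate_margins

    # clusters in regions (regions as contiguous, near-even blocks)
    region_of_cluster = np.sort(np.arange(cfg.n_clusters) % cfg.n_regions)
    rural_cluster = (rng.random(cfg.n_clusters) >= cfg.urban_fraction)
    rollout = cfg.subsidy_month + rng.integers(
        0, cfg.rollout_spread_months + 1, size=cfg.n_clusters)

    # households and women
    n_hh = 1 + rng.poisson(max(cfg.households_per_cluster_mean - 1.0, 0.0),
                           size=cfg.n_clusters)
    hh_cluster = np.repeat(np.arange(cfg.n_clusters), n_hh)
    n_households = hh_cluster.size
    wealth_hh = rng.choice(5, size=n_households,
                           p=np.asarray(margins["wealth_quintile"], float))
    n_w = 1 + rng.poisson(cfg.extra_women_per_household_mean,
                          size=n_households)
    woman_hh = np.repeat(np.arange(n_households), n_w)
    n_women = woman_hh.size

    # per-woman reproductive history
    n_del = _births_per_woman(cfg, rng, n_women)
    max_del = int(n_del.max())
    prior_parity = rng.choice(len(cfg.prior_parity_probs), size=n_women,
                              p=np.asarray(cfg.prior_parity_probs, float))

    m_ge36, m_lt36, _ = np.asarray(margins["preceding_interval_cat"], float)
    q_ge36 = m_ge36 / (m_ge36 + m_lt36)
    # window compression shortens long gaps for high-parity women; draw long
    # gaps at inflated odds so the realized >=36-month share hits the margin
    q_draw = min(1.0, q_ge36 * 1.30)
    long_gap = rng.random((n_women, max_del - 1)) < q_draw if max_del > 1 \
        else np.zeros((n_women, 0), bool)
    gaps = np.where(
        long_gap,
        36.0 + rng.exponential(12.0, size=long_gap.shape),
        9.0 + rng.uniform(0.0, 27.0, size=long_gap.shape))
    gaps = np.clip(np.rint(gaps), 9, 120).astype(int)
    active = np.arange(1, max_del)[None, :] < n_del[:, None]
    gaps = np.where(active, gaps, 0)
    span = gaps.sum(axis=1)
    # compress histories that do not fit in the observation window
    too_long = span > (hi - lo)
    if too_long.any():
        scale = (hi - lo) / np.maximum(span, 1)
        gaps[too_long] = np.maximum(
            np.rint(gaps[too_long] * scale[too_long, None]).astype(int), 9)
        gaps = np.where(active, gaps, 0)
        span = np.minimum(gaps.sum(axis=1), hi - lo)
        gaps = np.where(gaps.cumsum(axis=1) <= (hi - lo), gaps, 0)
        span = gaps.sum(axis=1)
    first_month = _seasonal_month_draw(cfg, rng, lo, hi - span)
    offsets = np.concatenate(
        [np.zeros((n_women, 1), int), gaps.cumsum(axis=1)], axis=1)
    months = first_month[:, None] + offsets  # (n_women, max_del)

    # mother's birth month -> age at each delivery
    age_first = np.clip(rng.normal(cfg.age_first_birth_mean,
                                   cfg.age_first_birth_sd, n_women), 15.0, 35.0)
    prior_months = rng.gamma(np.maximum(prior_parity, 1e-12),
                             cfg.mean_prior_interval_months)
    prior_months = np.where(prior_parity > 0, prior_months, 0.0)
    mother_birth = first_month - np.rint(age_first * 12 + prior_months).astype(int)

    # woman-level covariates
    edu = rng.choice(3, size=n_women, p=np.asarray(margins["education"], float))
    p_lit = np.array([0.0, 0.45, 0.95])
    e = np.asarray(margins["education"], float)
    p_lit[0] = np.clip(
        (margins["literate"] - p_lit[1] * e[1] - p_lit[2] * e[2]) / e[0], 0, 1)
    literate = rng.random(n_women) < p_lit[edu]
    worked = rng.random(n_women) < margins["mother_worked"]

    # expand to deliveries
    del_woman = np.repeat(np.arange(n_women), n_del)
    del_index = np.concatenate([np.arange(k) for k in n_del])
    del_month = months[del_woman, del_index]
    n_deliveries = del_woman.size

    twin = rng.random(n_deliveries) < cfg.twin_prob
    # keep births per woman within 1..8
    births_w = np.bincount(del_woman, weights=1 + twin, minlength=n_women)
    over = births_w > 8
    if over.any():
        twin &= ~over[del_woman]

    # expand to births
    reps = 1 + twin.astype(int)
    b_del = np.repeat(np.arange(n_deliveries), reps)
    woman = del_woman[b_del]
    bm = del_month[b_del]
    n_births = b_del.size

    hh = woman_hh[woman]
    cluster = hh_cluster[hh]
    order = prior_parity[woman] + del_index[b_del] + 1
    order_cat = np.where(order == 1, 0, np.where(order <= 4, 1, 2))

    prev_gap = np.zeros(n_births, dtype=float)
    di = del_index[b_del]
    has_prev = di > 0
    prev_gap[has_prev] = gaps[woman[has_prev], di[has_prev] - 1]
    # first observed delivery of a woman with prior births: gap unobserved,
    # draw its category from the conditional margins
    unobs = (~has_prev) & (order > 1)
    drawn_long = rng.random(n_births) < q_ge36
    interval_cat = np.where(
        order == 1, 2,
        np.where(has_prev, np.where(prev_gap >= 36, 0, 1),
                 np.where(drawn_long, 0, 1)))
    interval_cat = np.where(unobs & (interval_cat == 2), 1, interval_cat)

    age_years = np.clip((bm - mother_birth[woman]) / 12.0, 15.0, 49.0)
    age_grp = np.clip(((age_years - 15.0) // 5).astype(int), 0, 5)
    age_grp = np.where(age_years >= 40, 5, age_grp)

    female = rng.random(n_births) < margins["newborn_female"]

    return {
        "region_id": region_of_cluster[cluster], "cluster_id": cluster,
        "household_id": hh, "woman_id": woman,
        "birth_id": np.arange(n_births), "birth_month": bm,
        "calendar_month_of_year": bm % 12 + 1,
        "rural": rural_cluster[cluster].astype(int),
        "wealth_quintile": wealth_hh[hh] + 1,
        "education": edu[woman], "literate": literate[woman].astype(int),
        "mother_age_group": age_grp,
        "multiple_birth": twin[b_del].astype(int),
        "birth_order_cat": order_cat, "preceding_interval_cat": interval_cat,
        "mother_worked": worked[woman].astype(int),
        "newborn_female": female.astype(int),
        "true_exposed": (bm >= rollout[cluster]).astype(int),
        "_rollout": rollout, "_n_women": n_women,
        "_n_households": n_households,
    }


# ---------------------------------------------------------------------------
# outcome model
# ---------------------------------------------------------------------------

def _psd_factor(cov: np.ndarray) -> np.ndarray:
    """Factor A with A A' = cov, valid for rank-deficient matrices."""
    w, v = np.linalg.eigh(np.asarray(cov, float))
    w = np.clip(w, 0.0, None)
    return v * np.sqrt(w)


def _fixed_eta(beta: Dict[str, float], frame: Dict[str, np.ndarray],
               T: np.ndarray, I: np.ndarray, pt: np.ndarray) -> np.ndarray:
    """Fixed-effect linear predictor for one outcome."""
    b = lambda k: beta.get(k, 0.0)
    eta = np.full(T.shape, b("intercept"), dtype=float)
    eta += b("time") * T + b("subsidy") * I + b("post_time") * pt
    eta += b("rural") * frame["rural"]
    eta += b("subsidy_x_rural") * I * frame["rural"]
    wq = frame["wealth_quintile"]
    for lev, name in ((2, "poorer"), (3, "middle"), (4, "richer"), (5, "richest")):
        eta += b(f"wealth:{name}") * (wq == lev)
    eta += b("illiterate") * (1 - frame["literate"])
    edu = frame["education"]
    eta += b("education:primary") * (edu == 1)
    eta += b("education:secondary+") * (edu == 2)
    eta += b("multiple") * frame["multiple_birth"]
    ag = frame["mother_age_group"]
    for gi, lab in enumerate(AGE_LEVELS[1:], start=1):
        eta += b(f"age:{lab}") * (ag == gi)
    oc = frame["birth_order_cat"]
    eta += b("order:2-4") * (oc == 1) + b("order:5+") * (oc == 2)
    eta += b("interval:<36") * (frame["preceding_interval_cat"] == 1)
    eta += b("worked") * frame["mother_worked"]
    eta += b("newborn_female") * frame["newborn_female"]
    return eta


def _random_eta(frame, u: np.ndarray, v: Optional[np.ndarray],
                T, I, pt=None) -> np.ndarray:
    cl = frame["cluster_id"]
    eta = u[cl, 0] + u[cl, 1] * I + u[cl, 2] * T
    if v is not None:
        eta = eta + v[frame["woman_id"]]
    return eta


def _draw_effects(cfg, outcome, rng, n_women):
    u = rng.standard_normal((cfg.n_clusters, 3)) @ _psd_factor(
        cfg.psi_matrix(outcome)).T
    l2 = cfg.true_psi[outcome].get("level2_var", 0.0)
    v = rng.standard_normal(n_women) * np.sqrt(l2) if l2 > 0 else None
    return u, v


def generate_population(config: PopulationConfig
                        ) -> Tuple[pd.DataFrame, dict]:
    """Generate birth records and a generator-truth sidecar.

    Returns a record table (one row per live birth, column contract of
    `records_io`) and a dict holding the true coefficients, random-effect
    covariances, margins and diagnostics needed for recovery tests.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    s_struct, s_deliv, s_mort = ss.spawn(3)
    frame = _simulate_structure(config, np.random.default_rng(s_struct))
    rollout = frame.pop("_rollout")
    n_women = frame.pop("_n_women")
    frame.pop("_n_households")

    bm = frame["birth_month"]
    cl = frame["cluster_id"]
    I_true = frame["true_exposed"]
    pt_true = np.maximum(0, bm - rollout[cl])

    truth = {"seed": config.seed, "config_hash": config.config_hash(),
             "beta": config.true_beta, "margins": config.covariate_margins,
             "psi": {o: config.psi_matrix(o).tolist() for o in config.true_psi},
             "level2_var": {o: config.true_psi[o].get("level2_var", 0.0)
                            for o in config.true_psi},
             "rollout_month": rollout.tolist(), "truncated": {},
             "cluster_effects": {}, "woman_effects": {}}

    outcomes = {}
    for outcome, stream in (("delivery", s_deliv), ("mortality", s_mort)):
        rng = np.random.default_rng(stream)
        u, v = _draw_effects(config, outcome, rng, n_women)
        truth["cluster_effects"][outcome] = u.tolist()
        truth["woman_effects"][outcome] = None if v is None else v.tolist()
        T = (bm - config.time_origin[outcome]).astype(float)
        eta = _fixed_eta(config.true_beta[outcome], frame, T, I_true, pt_true)
        eta += _random_eta(frame, u, v, T, I_true)
        fvar = config.level1_frailty_var.get(outcome, 0.0)
        if fvar > 0:
            eta = eta + rng.standard_normal(bm.size) * np.sqrt(fvar)
        p = np.exp(eta)
        n_trunc = int((p > 1.0 - 1e-9).sum())
        truth["truncated"][outcome] = n_trunc
        if n_trunc > config.truncation_warn_fraction * bm.size:
            warnings.warn(
                f"{outcome}: log-link implied rate > 1 for {n_trunc} of "
                f"{bm.size} births (truncated)", TruncationWarning,
                stacklevel=2)
        p = np.clip(p, 0.0, 1.0 - 1e-9)
        outcomes[outcome] = (rng.random(bm.size) < p).astype(int)

    df = pd.DataFrame({
        "region_id": frame["region_id"], "cluster_id": frame["cluster_id"],
        "household_id": frame["household_id"], "woman_id": frame["woman_id"],
        "birth_id": frame["birth_id"], "birth_month": frame["birth_month"],
        "calendar_month_of_year": frame["calendar_month_of_year"],
        "facility_delivery": outcomes["delivery"],
        "neonatal_death": outcomes["mortality"],
        "rural": frame["rural"], "wealth_quintile": frame["wealth_quintile"],
        "education": np.asarray(EDUCATION_LEVELS)[frame["education"]],
        "literate": frame["literate"],
        "mother_age_group": np.asarray(AGE_LEVELS)[frame["mother_age_group"]],
        "multiple_birth": frame["multiple_birth"],
        "birth_order_cat": np.asarray(ORDER_LEVELS)[frame["birth_order_cat"]],
        "preceding_interval_cat":
            np.asarray(INTERVAL_LEVELS)[frame["preceding_interval_cat"]],
        "mother_worked": frame["mother_worked"],
        "newborn_female": frame["newborn_female"],
        "true_exposed": frame["true_exposed"],
    })
    return df, truth


# ---------------------------------------------------------------------------
# generator-truth marginal effects (oracle for the standardization)
# ---------------------------------------------------------------------------

def true_marginal_effect(config: PopulationConfig, horizon_months: int,
                         outcome: str, seed: Optional[int] = None,
                         ) -> Dict[str, float]:
    """Monte-Carlo generator-truth marginal RR and RD at a policy horizon.

    Draws a fresh population (structure, covariates and random effects) from
    the config, computes each birth's truncated rate with the subsidy on and
    off at `horizon_months` after the official start -- with calendar time set
    to the policy timeline, matching the standardization estimand -- and
    averages.  Returns the RR, RD and their Monte-Carlo standard errors
    (cluster-level delta method).
    """
    if not (0 <= horizon_months <= 42):
        raise ValueError("horizon_months must be within 0..42")
    config.validate()
    seed = config.seed + 90001 if seed is None else seed
    ss = np.random.SeedSequence(seed)
    s_struct, s_eff = ss.spawn(2)
    frame = _simulate_structure(config, np.random.default_rng(s_struct))
    frame.pop("_rollout")
    n_women = frame.pop("_n_women")
    frame.pop("_n_households")

    u, v = _draw_effects(config, outcome, np.random.default_rng(s_eff), n_women)
    origin = config.time_origin[outcome]
    T = np.full(frame["birth_month"].size,
                float(config.subsidy_month - origin + horizon_months))
    beta = config.true_beta[outcome]
    rates = {}
    for flag in (1, 0):
        I = np.full(T.size, float(flag))
        pt = np.full(T.size, float(horizon_months * flag))
        eta = _fixed_eta(beta, frame, T, I, pt) + _random_eta(frame, u, v, T, I)
        rates[flag] = np.clip(np.exp(eta), 0.0, 1.0)

    return marginal_contrast(rates[1], rates[0], frame["cluster_id"],
                             config.n_clusters)


def marginal_contrast(rates_with: np.ndarray, rates_without: np.ndarray,
                      cluster: np.ndarray, n_clusters: int) -> Dict[str, float]:
    """Mean rates, RR, RD and their cluster-level Monte-Carlo SEs."""
    K = n_clusters
    n = rates_with.size
    s1 = np.bincount(cluster, weights=rates_with, minlength=K)
    s0 = np.bincount(cluster, weights=rates_without, minlength=K)
    m1, m0 = s1.sum() / n, s0.sum() / n
    nk = np.bincount(cluster, minlength=K)
    # cluster-level covariance of the two means
    d1 = s1 - nk * m1
    d0 = s0 - nk * m0
    fac = K / (K - 1.0) / n ** 2
    v11 = fac * (d1 ** 2).sum()
    v00 = fac * (d0 ** 2).sum()
    v10 = fac * (d1 * d0).sum()
    rr = m1 / m0
    rd = m1 - m0
    rr_se = rr * np.sqrt(max(v11 / m1 ** 2 + v00 / m0 ** 2
                             - 2 * v10 / (m1 * m0), 0.0))
    rd_se = np.sqrt(max(v11 + v00 - 2 * v10, 0.0))
    return {"rr": float(rr), "rd": float(rd), "rr_se": float(rr_se),
            "rd_se": float(rd_se), "rate_with": float(m1),
            "rate_without": float(m0), "n": int(n)}
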