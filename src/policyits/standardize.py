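"""Model-based standardization: marginal rate ratios and differences.

Each birth's outcome rate is predicted under two counterfactual scenarios --
subsidy present and absent -- at horizons 0..42 months after the policy
cutoff, with the time and post-time variables replaced by the horizon's
values and the empirical-Bayes random-effect predictions held fixed.  The
per-scenario predictions are averaged over the analysis population, and the
ratio (RR) and difference (RD) of the averages are reported with
delta-method confidence intervals propagated from the (robust) covariance
of the fixed effects.

By default calendar time is standardized to the policy timeline: at horizon
h every birth is evaluated at T = (cutoff - origin) + h.  The alternative
reading -- each birth keeps its own calendar time -- is available via
``time_basis="cohort"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .model import EBPrediction, ITSResults

DEFAULT_HORIZONS = (0, 6, 12, 18, 24, 30, 36, 42)


def _counterfactual_X(res: ITSResults, subsidy_flag: int, horizon: int,
                      time_basis: str = "policy") -> np.ndarray:
    b = res.bundle
    X = b.X.copy()
    names = b.xnames
    idx = {n: i for i, n in enumerate(names)}
    cutoff = b.scenario.cutoff_month
    origin = b.spec.time_origin
    if time_basis == "policy":
        T = np.full(b.n, float(cutoff - origin + horizon))
    elif time_basis == "cohort":
        T = X[:, idx["time"]] if "time" in idx else None
    else:
        raise ValueError("time_basis must be 'policy' or 'cohort'")
    if "time" in idx:
        X[:, idx["time"]] = T
    if "subsidy" in idx:
        X[:, idx["subsidy"]] = subsidy_flag
    if "post_time" in idx:
        X[:, idx["post_time"]] = subsidy_flag * horizon
    for i, n in enumerate(names):
        if n.startswith("subsidy_x_"):
            base = n[len("subsidy_x_"):]
            base = {"illiterate": "illiterate"}.get(base, base)
            if base not in idx:
                raise ValueError(
                    f"interaction {n} lacks a main-effect column to rebuild "
                    "counterfactual predictions")
            X[:, i] = subsidy_flag * b.X[:, idx[base]]
        if n.startswith("month:"):
            month = (cutoff + horizon) % 12 + 1
            X[:, i] = 1.0 if n == f"month:{month}" else 0.0
    return X


def _random_part(res: ITSResults, eb: EBPrediction, subsidy_flag: int,
                 horizon: int, time_basis: str) -> np.ndarray:
    """EB random-effect contribution to the counterfactual linear predictor."""
    b = res.bundle
    out = np.zeros(b.n)
    q = len(b.znames)
    if q:
        ce = eb.cluster_effects
        missing = set(b.cluster_labels) - set(ce.index)
        if missing:
            raise ValueError(f"missing EB prediction for cluster(s) "
                             f"{sorted(missing)[:5]}")
        U = ce.loc[b.cluster_labels].to_numpy()  # (K, q)
        cl = np.searchsorted(b.cluster_gi.starts, np.arange(b.n),
                             side="right") - 1
        cutoff = b.scenario.cutoff_month
        origin = b.spec.time_origin
        for d, term in enumerate(b.znames):
            if term == "intercept":
                z = 1.0
            elif term == "subsidy":
                z = float(subsidy_flag)
            elif term == "time":
                z = (float(cutoff - origin + horizon) if time_basis == "policy"
                     else b.X[:, b.xnames.index("time")])
            elif term == "post_time":
                z = float(subsidy_flag * horizon)
            out += U[cl, d] * z
    if eb.woman_effects is not None and b.woman_gi is not None:
        wl = eb.woman_effects.loc[b.woman_labels].to_numpy()
        wn = np.searchsorted(b.woman_gi.starts, np.arange(b.n),
                             side="right") - 1
        out += wl[wn]
    return out


def predict_rate(res: ITSResults, eb: EBPrediction, subsidy_flag: int,
                 horizon: int, beta: Optional[np.ndarray] = None,
                 time_basis: str = "policy"):
    """Counterfactual per-birth rates; returns (rates, n_capped)."""
    if horizon < 0:
        raise ValueError("horizon must be >= 0")
    if not res.converged:
        raise ValueError("cannot standardize from a non-converged fit")
    X = _counterfactual_X(res, subsidy_flag, horizon, time_basis)
    beta = res.params.to_numpy() if beta is None else beta
    eta = X @ beta + _random_part(res, eb, subsidy_flag, horizon, time_basis)
    rate = np.exp(np.minimum(eta, 30.0))
    capped = int((rate > 1.0).sum())
    return np.minimum(rate, 1.0), capped


@dataclass
class StdGrid:
    """Standardized rates, RR and RD per horizon, with 95% CIs."""

    table: pd.DataFrame
    capped_fraction: float
    outcome: str
    scenario: str
    warning: Optional[str] = None

    def to_json(self) -> str:
        payload = {"outcome": self.outcome, "scenario": self.scenario,
                   "capped_fraction": self.capped_fraction,
                   "warning": self.warning,
                   "grid": self.table.reset_index().to_dict(orient="records")}
        import json
        return json.dumps(payload, indent=2, default=float)

    def to_text(self) -> str:
        hdr = (f"Standardized effects ({self.outcome}, {self.scenario})\n"
               f"{'h':>4}{'RR (95% CI)':>26}{'RD (95% CI)':>30}")
        lines = [hdr]
        for h, r in self.table.iterrows():
            rr = f"{r.rr:.2f} ({r.rr_lo:.2f}-{r.rr_hi:.2f})"
            rd = (f"{100 * r.rd:+.1f}% ({100 * r.rd_lo:+.1f} to "
                  f"{100 * r.rd_hi:+.1f}%)")
            lines.append(f"{h:>4}{rr:>26}{rd:>30}")
        if self.warning:
            lines.append(f"warning: {self.warning}")
        return "\n".join(lines)


def standardize(res: ITSResults, eb: Optional[EBPrediction] = None,
                horizons: Iterable[int] = DEFAULT_HORIZONS,
                level: float = 0.95, ci: bool = True, robust: bool = True,
                time_basis: str = "policy") -> StdGrid:
    """Population-standardized RR and RD over post-policy horizons.

    Averages counterfactual predictions (EB effects included) over the
    analysis population per horizon; when ``ci`` is true, adds delta-method
    intervals (log scale for RR, natural scale for RD) using the robust or
    model-based covariance of the fixed effects.
    """
    if res.bundle.n == 0:
        raise ValueError("empty analysis set")
    eb = res.eb_predict() if eb is None else eb
    cov = res.robust_cov() if robust else res.cov_model
    rows = []
    total_capped = 0
    zcrit = stats.norm.ppf(0.5 + level / 2)
    beta_hat = res.params.to_numpy()

    def effects(beta, h):
        r1, c1 = predict_rate(res, eb, 1, h, beta=beta, time_basis=time_basis)
        r0, c0 = predict_rate(res, eb, 0, h, beta=beta, time_basis=time_basis)
        return r1.mean(), r0.mean(), c1 + c0

    for h in horizons:
        m1, m0, capped = effects(beta_hat, h)
        total_capped += capped
        rr, rd = m1 / m0, m1 - m0
        row = {"rate_with": m1, "rate_without": m0, "rr": rr, "rd": rd,
               "n": res.bundle.n}
        if ci:
            g_log_rr = np.empty(beta_hat.size)
            g_rd = np.empty(beta_hat.size)
            for j in range(beta_hat.size):
                step = 1e-5 * max(1.0, abs(beta_hat[j]))
                bp, bm_ = beta_hat.copy(), beta_hat.copy()
                bp[j] += step
                bm_[j] -= step
                m1p, m0p, _ = effects(bp, h)
                m1m, m0m, _ = effects(bm_, h)
                g_log_rr[j] = (np.log(m1p / m0p) - np.log(m1m / m0m)) / (2 * step)
                g_rd[j] = ((m1p - m0p) - (m1m - m0m)) / (2 * step)
            var_log_rr = float(g_log_rr @ cov @ g_log_rr)
            var_rd = float(g_rd @ cov @ g_rd)
            if min(var_log_rr, var_rd) < -1e-12:
                raise ValueError("covariance is not positive semi-definite")
            se_log_rr = np.sqrt(max(var_log_rr, 0.0))
            se_rd = np.sqrt(max(var_rd, 0.0))
            row.update(rr_lo=rr * np.exp(-zcrit * se_log_rr),
                       rr_hi=rr * np.exp(zcrit * se_log_rr),
                       rd_lo=rd - zcrit * se_rd, rd_hi=rd + zcrit * se_rd)
        rows.append(row)
    table = pd.DataFrame(rows, index=pd.Index(list(horizons), name="horizon"))
    frac = total_capped / (2 * len(table) * res.bundle.n)
    warning = None
    if frac > 0.01:
        warning = (f"{100 * frac:.1f}% of counterfactual predictions were "
                   "capped at rate 1")
    return StdGrid(table=table, capped_fraction=frac,
                   outcome=res.bundle.spec.outcome,
                   scenario=res.bundle.scenario.name, warning=warning)
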