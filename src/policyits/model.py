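"""Segmented multilevel modified-Poisson model for policy interruption analysis.

`MultilevelPoissonITS` fits a log-link Poisson model to a binary outcome
(the "modified Poisson" device that yields rate ratios directly), with the
interrupted-time-series fixed effects

    eta = b0 + b1*T + b2*I + b3*post_time + covariates (+ interactions),

cluster-level random intercept/coefficients integrated out by adaptive
Gauss-Hermite quadrature, an optional woman-level random intercept (3-level
models), and region-clustered sandwich standard errors to repair the
mis-specified Poisson variance.  `fit()` returns an `ITSResults` object
carrying estimates, both covariance flavours, the random-effect covariance,
empirical-Bayes prediction and a summary table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._agq import (GroupIndex, birth_ll, cluster_modes, gh_rule,
                   loglik_clusters, loglik_level2_only, poisson_ll)
from .config import AGE_LEVELS, EDUCATION_LEVELS
from .scenarios import ExposureScenario

OUTCOME_COLUMNS = {"delivery": "facility_delivery",
                   "mortality": "neonatal_death"}
DEFAULT_TIME_ORIGIN = {"delivery": 65, "mortality": 0}

DEFAULT_FIXED = ("time", "subsidy", "post_time", "rural", "wealth",
                 "literacy", "multiple", "age", "order", "worked")
RANDOM_VOCAB = ("intercept", "subsidy", "time", "post_time")


@dataclass
class ModelSpec:
    """Layout of fixed effects, random terms and estimation settings."""

    outcome: str = "delivery"
    n_levels: int = 2
    time_origin: Optional[int] = None
    fixed_terms: Sequence[str] = DEFAULT_FIXED
    random_terms: Sequence[str] = ("intercept",)
    covariance_structure: str = "unstructured"
    seasonal_terms: bool = False
    quadrature_nodes: int = 7

    def __post_init__(self):
        if self.outcome not in OUTCOME_COLUMNS:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.n_levels not in (2, 3):
            raise ValueError("n_levels must be 2 or 3")
        ft = set(self.fixed_terms)
        if "education" in ft and "literacy" in ft:
            raise ValueError("education and literacy are mutually exclusive "
                             "(strongly correlated; fit them separately)")
        if "post_time" in ft and not {"subsidy", "time"} <= ft:
            raise ValueError("post_time requires subsidy and time terms")
        bad = [t for t in self.random_terms if t not in RANDOM_VOCAB]
        if bad:
            raise ValueError(f"unknown random terms {bad}")
        bad = [t for t in self.random_terms
               if t != "intercept" and t not in ft]
        if bad:
            raise ValueError(f"random coefficients {bad} need matching "
                             "fixed terms")
        if self.covariance_structure not in ("unstructured", "diagonal"):
            raise ValueError("covariance_structure must be unstructured "
                             "or diagonal")
        if self.time_origin is None:
            self.time_origin = DEFAULT_TIME_ORIGIN[self.outcome]

    def drop_random(self, term: str) -> "ModelSpec":
        return replace(self, random_terms=tuple(
            t for t in self.random_terms if t != term))


@dataclass
class DesignBundle:
    """Cluster-sorted design matrices and grouping indices."""

    y: np.ndarray
    X: np.ndarray
    xnames: List[str]
    Z: Optional[np.ndarray]
    znames: List[str]
    cluster_gi: GroupIndex
    woman_gi: Optional[GroupIndex]
    cluster_labels: np.ndarray     # original cluster ids per group
    woman_labels: Optional[np.ndarray]
    region_of_cluster: np.ndarray  # region id per cluster group
    spec: ModelSpec
    scenario: ExposureScenario
    sort_order: np.ndarray         # records row order used internally

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def n_clusters(self) -> int:
        return self.cluster_gi.n_groups


def _dummies(values, levels, prefix, ref):
    cols, names = [], []
    for lev in levels:
        if lev == ref:
            continue
        cols.append((np.asarray(values) == lev).astype(float))
        names.append(f"{prefix}:{lev}")
    return cols, names


def build_design(records: pd.DataFrame, spec: ModelSpec,
                 scenario: ExposureScenario,
                 exposure_override: Optional[np.ndarray] = None,
                 post_time_override: Optional[np.ndarray] = None
                 ) -> DesignBundle:
    """Build the fixed/random design for one outcome under a scenario.

    Reference categories follow the reported models: literate, poorest,
    single birth, age 15-19, first birth, not worked, January.  Records in
    the scenario's exclusion window must be removed upstream.  The override
    arrays (aligned with ``records`` rows) replace the scenario's exposure
    and post-time coding -- used for oracle analyses on generated data where
    the true staggered exposure is known.
    """
    bm = records["birth_month"].to_numpy()
    if scenario.excluded(bm).any():
        raise ValueError("records contain scenario-excluded births; apply "
                         "apply_scenario() first")
    order = np.lexsort((records["woman_id"].to_numpy(),
                        records["cluster_id"].to_numpy()))
    rec = records.iloc[order]
    bm = rec["birth_month"].to_numpy()

    T = (bm - spec.time_origin).astype(float)
    if exposure_override is not None:
        I = np.asarray(exposure_override, float)[order]
        pt = (np.asarray(post_time_override, float)[order]
              if post_time_override is not None
              else scenario.post_time(bm).astype(float))
    else:
        I = scenario.exposed(bm).astype(float)
        pt = scenario.post_time(bm).astype(float)

    cols: List[np.ndarray] = [np.ones(len(rec))]
    names: List[str] = ["intercept"]
    ft = list(spec.fixed_terms)

    def add(name, col):
        cols.append(np.asarray(col, float))
        names.append(name)

    if "time" in ft:
        add("time", T)
    if "subsidy" in ft:
        add("subsidy", I)
    if "post_time" in ft:
        add("post_time", pt)
    if "rural" in ft:
        add("rural", rec["rural"])
    if "wealth" in ft:
        for c, nm in zip(*_dummies(rec["wealth_quintile"], range(1, 6),
                                   "wealth", 1)):
            add(nm, c)
        # keep the published labels on the wealth dummies
        names = [{"wealth:2": "wealth:poorer", "wealth:3": "wealth:middle",
                  "wealth:4": "wealth:richer",
                  "wealth:5": "wealth:richest"}.get(n, n) for n in names]
    if "literacy" in ft:
        add("illiterate", 1 - rec["literate"])
    if "education" in ft:
        for c, nm in zip(*_dummies(rec["education"], EDUCATION_LEVELS,
                                   "education", "none")):
            add(nm, c)
    if "subsidy_x_rural" in ft:
        add("subsidy_x_rural", I * rec["rural"].to_numpy())
    if "subsidy_x_wealth" in ft:
        for c, nm in zip(*_dummies(rec["wealth_quintile"], range(1, 6),
                                   "subsidy_x_wealth", 1)):
            add(nm, I * c)
    if "subsidy_x_education" in ft:
        if "literacy" in ft:
            add("subsidy_x_illiterate",
                I * (1 - rec["literate"].to_numpy()))
        else:
            for c, nm in zip(*_dummies(rec["education"], EDUCATION_LEVELS,
                                       "subsidy_x_education", "none")):
                add(nm, I * c)
    if "multiple" in ft:
        add("multiple", rec["multiple_birth"])
    if "age" in ft:
        for c, nm in zip(*_dummies(rec["mother_age_group"], AGE_LEVELS,
                                   "age", "15-19")):
            add(nm, c)
    if "order" in ft:
        add("order:2-4", rec["birth_order_cat"] == "2-4")
        add("order:5+", rec["birth_order_cat"] == "5+")
    if "interval" in ft:
        # only the short-interval contrast: the "first birth" level is
        # collinear with the birth-order reference
        add("interval:<36", rec["preceding_interval_cat"] == "<36")
    if "worked" in ft:
        add("worked", rec["mother_worked"])
    if "newborn_female" in ft:
        add("newborn_female", rec["newborn_female"])
    if spec.seasonal_terms:
        for c, nm in zip(*_dummies(rec["calendar_month_of_year"],
                                   range(1, 13), "month", 1)):
            add(nm, c)

    X = np.column_stack(cols)
    y = rec[OUTCOME_COLUMNS[spec.outcome]].to_numpy().astype(float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in the design matrix")

    zmap = {"intercept": np.ones(len(rec)), "subsidy": I, "time": T,
            "post_time": pt}
    znames = list(spec.random_terms)
    Z = np.column_stack([zmap[t] for t in znames]) if znames else None

    cluster = rec["cluster_id"].to_numpy()
    gi = GroupIndex(cluster)
    woman_gi = None
    woman_labels = None
    if spec.n_levels == 3:
        woman_gi = GroupIndex(rec["woman_id"].to_numpy())
        woman_labels = woman_gi.labels
    region_of_cluster = rec["region_id"].to_numpy()[gi.starts]
    return DesignBundle(y=y, X=X, xnames=names, Z=Z, znames=znames,
                        cluster_gi=gi, woman_gi=woman_gi,
                        cluster_labels=gi.labels, woman_labels=woman_labels,
                        region_of_cluster=region_of_cluster, spec=spec,
                        scenario=scenario, sort_order=order)


# ---------------------------------------------------------------------------
# parameter packing
# ---------------------------------------------------------------------------

class _ParamLayout:
    """theta = [beta | cluster chol | log level2 sd | log frailty sd]."""

    def __init__(self, p: int, q: int, structure: str,
                 has_level2: bool, has_frailty: bool):
        self.p, self.q = p, q
        self.structure = structure
        self.has_level2 = has_level2
        self.has_frailty = has_frailty
        self.n_chol = 0 if q == 0 else (
            q if structure == "diagonal" else q * (q + 1) // 2)
        self.size = p + self.n_chol + int(has_level2) + int(has_frailty)

    def unpack(self, theta):
        p, q = self.p, self.q
        beta = theta[:p]
        pos = p
        L = None
        if q:
            L = np.zeros((q, q))
            if self.structure == "diagonal":
                L[np.arange(q), np.arange(q)] = np.exp(theta[pos:pos + q])
                pos += q
            else:
                for i in range(q):
                    for j in range(i):
                        L[i, j] = theta[pos]
                        pos += 1
                    L[i, i] = np.exp(theta[pos])
                    pos += 1
        l2 = np.exp(theta[pos]) if self.has_level2 else 0.0
        pos += int(self.has_level2)
        fr = np.exp(theta[pos]) if self.has_frailty else 0.0
        return beta, L, l2, fr

    def pack_start(self, beta0):
        theta = np.zeros(self.size)
        theta[:self.p] = beta0
        pos = self.p
        if self.q:
            if self.structure == "diagonal":
                theta[pos:pos + self.q] = np.log(0.3)
                pos += self.q
            else:
                for i in range(self.q):
                    pos += i  # off-diagonals start at 0
                    theta[pos] = np.log(0.3)
                    pos += 1
        if self.has_level2:
            theta[pos] = np.log(0.3)
            pos += 1
        if self.has_frailty:
            theta[pos] = np.log(0.3)
        return theta


def _irls_poisson(X, y, max_iter=100, tol=1e-10):
    """Newton-Raphson fit of the fixed-effects log-link Poisson model."""
    beta = np.zeros(X.shape[1])
    beta[0] = np.log(max(y.mean(), 1e-10))
    ll_old = -np.inf
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -40, 30)
        mu = np.exp(eta)
        g = X.T @ (y - mu)
        H = (X * mu[:, None]).T @ X
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll = poisson_ll(y, np.clip(X @ cand, -40, 30)).sum()
            if ll >= ll_old - 1e-12:
                break
            scale *= 0.5
        beta, ll_old = cand, ll
        if np.max(np.abs(g)) < tol * max(1.0, abs(ll_old)):
            break
    return beta, ll_old


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class MultilevelPoissonITS:
    """Segmented multilevel log-link Poisson model on a design bundle."""

    def __init__(self, bundle: DesignBundle, frailty: bool = False):
        self.bundle = bundle
        self.frailty = frailty
        q = 0 if bundle.Z is None else bundle.Z.shape[1]
        self.layout = _ParamLayout(
            bundle.X.shape[1], q, bundle.spec.covariance_structure,
            has_level2=bundle.spec.n_levels == 3, has_frailty=frailty)
        self._state: Dict = {}

    @classmethod
    def from_records(cls, records: pd.DataFrame, spec: ModelSpec,
                     scenario: ExposureScenario,
                     exposure_override: Optional[np.ndarray] = None,
                     post_time_override: Optional[np.ndarray] = None,
                     **kw) -> "MultilevelPoissonITS":
        return cls(build_design(records, spec, scenario, exposure_override,
                                post_time_override), **kw)

    # -- likelihood ----------------------------------------------------
    def loglik_parts(self, theta, nodes: Optional[int] = None,
                     adaptive: bool = True) -> np.ndarray:
        """Per-cluster (or per-woman / per-birth) marginal log-likelihood."""
        b = self.bundle
        nodes = nodes or b.spec.quadrature_nodes
        beta, L, l2, fr = self.layout.unpack(theta)
        eta = b.X @ beta
        if not np.isfinite(eta).all():
            bad = int(np.flatnonzero(~np.isfinite(eta))[0])
            raise FloatingPointError(
                f"non-finite linear predictor at record {bad}")
        if self.layout.q:
            psi = L @ L.T
            return loglik_clusters(
                b.y, eta, b.Z, b.cluster_gi, psi, n_nodes=nodes,
                frailty_sd=fr, woman_gi=b.woman_gi,
                level2_sd=l2 if self.layout.has_level2 else 0.0,
                adaptive=adaptive, state=self._state)
        if self.layout.has_level2:
            return loglik_level2_only(b.y, eta, b.woman_gi, l2)
        return birth_ll(b.y, eta, frailty_sd=fr)

    def loglik(self, theta, nodes=None, adaptive=True) -> float:
        return float(self.loglik_parts(theta, nodes, adaptive).sum())

    # -- fitting -------------------------------------------------------
    def fit(self, nodes: Optional[int] = None, restarts: int = 3,
            maxiter: int = 300, start: Optional[np.ndarray] = None,
            collapse_boundary: bool = True, boundary_sd: float = 1e-2,
            seed: int = 0, ftol: float = 1e-9) -> "ITSResults":
        """Maximise the marginal likelihood (quasi-Newton, random restarts).

        When a cluster-level variance collapses to the boundary the term is
        removed and the model refitted, mirroring the automatic fallback to
        a simple Poisson regression when clusters show no variance.
        """
        b = self.bundle
        if self.layout.q and b.n_clusters < 2:
            raise ValueError("need >= 2 clusters to estimate cluster "
                             "random effects")
        beta0, ll_fix = _irls_poisson(b.X, b.y)
        if self.layout.size == self.layout.p:
            eta = np.clip(b.X @ beta0, -40, 30)
            H = (b.X * np.exp(eta)[:, None]).T @ b.X
            cov = np.linalg.pinv(H)
            return ITSResults(self, np.asarray(beta0, float), cov_model=cov,
                              loglik=ll_fix, converged=True)

        x0 = self.layout.pack_start(beta0) if start is None else start

        # precondition the fixed-effect block: whiten with the Cholesky of
        # the IRLS information so the months-scaled time columns do not
        # ill-condition the quasi-Newton search
        p = self.layout.p
        eta0 = np.clip(b.X @ x0[:p], -40, 30)
        H0 = (b.X * np.exp(eta0)[:, None]).T @ b.X
        H0 += 1e-8 * np.eye(p) * max(1.0, np.trace(H0) / p)
        L0T = np.linalg.cholesky(H0).T

        def to_theta(z):
            theta = z.copy()
            theta[:p] = x0[:p] + np.linalg.solve(L0T, z[:p])
            return theta

        def to_z(theta):
            z = theta.copy()
            z[:p] = L0T @ (theta[:p] - x0[:p])
            return z

        def nll(z):
            try:
                return -self.loglik(to_theta(z), nodes=nodes)
            except (np.linalg.LinAlgError, FloatingPointError):
                return 1e12

        best = None
        rng = np.random.default_rng(seed)
        starts = [x0]
        for _ in range(max(0, restarts)):
            jit = x0.copy()
            jit[self.layout.p:] += rng.normal(0, 0.5, self.layout.size
                                              - self.layout.p)
            starts.append(jit)
        # log-sd parameters are bounded below so a vanishing variance hits a
        # clean boundary (then collapsed) instead of a flat ridge at -inf
        bounds = [(None, None)] * self.layout.p
        if self.layout.q:
            if self.layout.structure == "diagonal":
                bounds += [(-7.0, 3.0)] * self.layout.q
            else:
                for i in range(self.layout.q):
                    bounds += [(-5.0, 5.0)] * i + [(-7.0, 3.0)]
        bounds += [(-7.0, 3.0)] * (int(self.layout.has_level2)
                                   + int(self.layout.has_frailty))
        for k, s in enumerate(starts):
            res = optimize.minimize(
                nll, to_z(s), method="L-BFGS-B", bounds=bounds,
                options={"maxiter": maxiter, "ftol": ftol, "gtol": 1e-6})
            if best is None or res.fun < best.fun - 1e-9:
                best = res
            if k == 0 and res.success:
                break  # converged from the principled start; keep it
        theta = to_theta(best.x)
        converged = bool(best.success)
        if not converged:
            warnings.warn("optimizer did not report convergence; returning "
                          "best point found", RuntimeWarning, stacklevel=2)

        beta, L, l2, fr = self.layout.unpack(theta)
        collapsed: List[str] = []
        if collapse_boundary:
            drop: List[str] = []
            if self.layout.q:
                sds = np.sqrt(np.diag(L @ L.T))
                drop = [t for t, s in zip(b.znames, sds) if s < boundary_sd]
            drop_l2 = self.layout.has_level2 and l2 < boundary_sd
            if drop or drop_l2:
                spec2 = b.spec
                for t in drop:
                    spec2 = spec2.drop_random(t)
                if drop_l2:
                    spec2 = replace(spec2, n_levels=2)
                    drop = drop + ["level2_intercept"]
                sub = MultilevelPoissonITS(
                    _rebuild_bundle(b, spec2), frailty=self.frailty)
                out = sub.fit(nodes=nodes, restarts=restarts, maxiter=maxiter,
                              collapse_boundary=collapse_boundary,
                              boundary_sd=boundary_sd, seed=seed, ftol=ftol)
                out.collapsed_random_terms = drop + out.collapsed_random_terms
                return out

        ll = self.loglik(theta, nodes=nodes)
        res = ITSResults(self, theta=theta, loglik=ll, converged=converged)
        res.collapsed_random_terms = collapsed
        return res


def _rebuild_bundle(b: DesignBundle, spec2: ModelSpec) -> DesignBundle:
    znames = list(spec2.random_terms)
    if znames:
        keep = [b.znames.index(t) for t in znames]
        Z = b.Z[:, keep]
    else:
        Z = None
    kw = {}
    if spec2.n_levels == 2:
        kw = {"woman_gi": None, "woman_labels": None}
    return replace(b, Z=Z, znames=znames, spec=spec2, **kw)


class ITSResults:
    """Fit results: estimates, covariances, diagnostics, EB prediction."""

    def __init__(self, model: MultilevelPoissonITS,
                 beta: Optional[np.ndarray] = None,
                 theta: Optional[np.ndarray] = None,
                 cov_model: Optional[np.ndarray] = None,
                 loglik: float = np.nan, converged: bool = False):
        self.model = model
        self.bundle = model.bundle
        if theta is None:
            theta = np.asarray(beta, float)
        self.theta = np.asarray(theta, float)
        beta_, L, l2, fr = model.layout.unpack(self.theta)
        self.params = pd.Series(beta_, index=self.bundle.xnames, name="coef")
        self.psi = (pd.DataFrame(L @ L.T, index=self.bundle.znames,
                                 columns=self.bundle.znames)
                    if L is not None else None)
        self.level2_var = l2 ** 2 if model.layout.has_level2 else None
        self.frailty_var = fr ** 2 if model.layout.has_frailty else None
        self.loglik = loglik
        self.converged = converged
        self.collapsed_random_terms: List[str] = []
        self._cov_model = cov_model
        self._cov_robust = None
        self._eb = None
        self.n_used = {
            "births": self.bundle.n,
            "clusters": self.bundle.n_clusters,
            "women": (self.bundle.woman_gi.n_groups
                      if self.bundle.woman_gi is not None else None),
            "regions": int(np.unique(self.bundle.region_of_cluster).size),
        }

    # -- parameter counts / df ----------------------------------------
    @property
    def k_params(self) -> int:
        return self.model.layout.size

    # -- covariances ---------------------------------------------------
    def _theta_hessian(self, step: float = 1e-5) -> np.ndarray:
        f = lambda th: -self.model.loglik(th)
        return _num_hess(f, self.theta, step)

    @property
    def cov_model(self) -> np.ndarray:
        """Model-based covariance of the fixed effects (inverse information)."""
        if self._cov_model is None:
            H = self._theta_hessian()
            self._cov_model = np.linalg.pinv(H)[:self.model.layout.p,
                                                :self.model.layout.p]
        return self._cov_model

    def robust_cov(self, cluster: str = "region",
                   df_correction: bool = True) -> np.ndarray:
        """Region-clustered sandwich covariance of the fixed effects.

        ``cluster`` may be "region" (default), "cluster", or "record"
        (heteroskedasticity-robust).  A small-sample G/(G-1) factor is
        applied unless ``df_correction=False``.
        """
        p = self.model.layout.p
        if self.model.layout.size == p:
            return self._robust_cov_glm(cluster, df_correction)
        parts_fn = lambda th: self.model.loglik_parts(th)
        S = _num_jac(parts_fn, self.theta)          # (K, n_theta)
        groups = self._score_groups(cluster)
        G = int(groups.max()) + 1
        if G < 2:
            raise ValueError("need >= 2 score groups for a sandwich estimate")
        B = np.zeros((self.theta.size, self.theta.size))
        for g in range(G):
            s = S[groups == g].sum(axis=0)
            B += np.outer(s, s)
        A = self._theta_hessian()
        Ainv = np.linalg.pinv(A)
        V = Ainv @ B @ Ainv
        if df_correction:
            V *= G / (G - 1.0)
        return V[:p, :p]

    def _score_groups(self, cluster: str) -> np.ndarray:
        b = self.bundle
        if self.model.layout.q:
            per = b.region_of_cluster if cluster == "region" else \
                (b.cluster_labels if cluster == "cluster" else None)
            if per is None:
                raise ValueError("record-level clustering is not available "
                                 "once effects are integrated per cluster")
            return pd.factorize(per)[0]
        # fixed-effects model: parts are per birth
        if cluster == "record":
            return np.arange(b.n)
        key = b.cluster_gi.codes if cluster == "cluster" else \
            b.region_of_cluster[np.searchsorted(
                b.cluster_gi.starts, np.arange(b.n), side="right") - 1]
        return pd.factorize(key)[0]

    def _robust_cov_glm(self, cluster, df_correction):
        b = self.bundle
        eta = np.clip(b.X @ self.params.to_numpy(), -40, 30)
        mu = np.exp(eta)
        scores = b.X * (b.y - mu)[:, None]
        groups = self._score_groups(cluster)
        G = int(groups.max()) + 1
        if G < 2:
            raise ValueError("need >= 2 score groups for a sandwich estimate")
        Ssum = np.zeros((G, b.X.shape[1]))
        np.add.at(Ssum, groups, scores)
        B = Ssum.T @ Ssum
        A = (b.X * mu[:, None]).T @ b.X
        Ainv = np.linalg.pinv(A)
        V = Ainv @ B @ Ainv
        if df_correction:
            V *= G / (G - 1.0)
        return V

    def bse(self, robust: bool = True, **kw) -> pd.Series:
        cov = self.robust_cov(**kw) if robust else self.cov_model
        return pd.Series(np.sqrt(np.diag(cov)), index=self.params.index,
                         name="se")

    # -- empirical Bayes -----------------------------------------------
    def eb_predict(self) -> "EBPrediction":
        """Posterior modes of the random effects at the estimates."""
        if self._eb is not None:
            return self._eb
        b = self.bundle
        q = self.model.layout.q
        K = b.n_clusters
        cluster_eff = np.zeros((K, max(q, 1)))
        beta, L, l2, fr = self.model.layout.unpack(self.theta)
        eta = b.X @ beta
        if q:
            psi = L @ L.T
            psi_inv = np.linalg.pinv(psi)
            u, _, _ = cluster_modes(b.y, eta, b.Z, b.cluster_gi, psi_inv,
                                    frailty_sd=fr)
            cluster_eff = u
        woman_eff = None
        if self.model.layout.has_level2 and l2 > 0:
            cl = np.searchsorted(b.cluster_gi.starts, np.arange(b.n),
                                 side="right") - 1
            eta_u = eta + (np.einsum("nq,nq->n", b.Z, cluster_eff[cl])
                           if q else 0.0)
            woman_eff = _woman_modes(b.y, eta_u, b.woman_gi, l2 ** 2)
        self._eb = EBPrediction(
            cluster_effects=pd.DataFrame(
                cluster_eff[:, :q] if q else np.zeros((K, 0)),
                index=pd.Index(b.cluster_labels, name="cluster_id"),
                columns=b.znames),
            woman_effects=(pd.Series(
                woman_eff, index=pd.Index(b.woman_labels, name="woman_id"))
                if woman_eff is not None else None))
        return self._eb

    # -- summary --------------------------------------------------------
    def summary(self, robust: bool = True) -> str:
        se = self.bse(robust=robust)
        z = self.params / se
        pv = 2 * stats.norm.sf(np.abs(z))
        lines = [f"Multilevel Poisson ITS ({self.bundle.spec.outcome}, "
                 f"scenario={self.bundle.scenario.name})",
                 f"births={self.n_used['births']}  "
                 f"clusters={self.n_used['clusters']}  "
                 f"regions={self.n_used['regions']}  "
                 f"loglik={self.loglik:.3f}  converged={self.converged}",
                 f"{'term':<24}{'coef':>10}{'se':>10}{'p':>8}"]
        for name, c, s, p in zip(self.params.index, self.params, se, pv):
            lines.append(f"{name:<24}{c:>10.4f}{s:>10.4f}{p:>8.3f}")
        if self.psi is not None and len(self.psi):
            lines.append("Random parts (cluster level):")
            for i, t in enumerate(self.psi.index):
                lines.append(f"  psi_{t:<12}{self.psi.iloc[i, i]:>10.4f}")
        if self.level2_var is not None:
            lines.append(f"  level-2 intercept var {self.level2_var:.4f}")
        if self.collapsed_random_terms:
            lines.append("Boundary collapse removed random terms: "
                         f"{self.collapsed_random_terms}")
        return "\n".join(lines)

    def standardize(self, **kw):
        """Model-based standardization; see `policyits.standardize`."""
        from .standardize import standardize as _standardize
        return _standardize(self, **kw)

    def to_dict(self) -> dict:
        return {
            "outcome": self.bundle.spec.outcome,
            "scenario": self.bundle.scenario.name,
            "params": self.params.to_dict(),
            "se_robust": self.bse(robust=True).to_dict(),
            "psi": self.psi.to_dict() if self.psi is not None else None,
            "level2_var": self.level2_var,
            "loglik": self.loglik, "converged": self.converged,
            "collapsed_random_terms": self.collapsed_random_terms,
            "n_used": self.n_used,
        }


@dataclass
class EBPrediction:
    """Per-cluster (and per-woman) empirical-Bayes random-effect values."""

    cluster_effects: pd.DataFrame
    woman_effects: Optional[pd.Series] = None


def _woman_modes(y, eta, woman_gi: GroupIndex, var: float,
                 max_iter=50, tol=1e-10):
    """1-d Newton for the woman-intercept posterior modes, batched."""
    J = woman_gi.n_groups
    v = np.zeros(J)
    wn = np.searchsorted(woman_gi.starts, np.arange(y.size),
                         side="right") - 1
    for _ in range(max_iter):
        mu = np.exp(np.minimum(eta + v[wn], _ETA_CAP_LOCAL))
        g = woman_gi.sum(y - mu) - v / var
        h = woman_gi.sum(mu) + 1.0 / var
        step = g / h
        v = v + np.clip(step, -4, 4)
        if np.max(np.abs(g)) < tol:
            break
    return v


_ETA_CAP_LOCAL = 30.0


# ---------------------------------------------------------------------------
# numerical derivatives
# ---------------------------------------------------------------------------

def _steps(x, step):
    return step * np.maximum(1.0, np.abs(x))


def _num_jac(fn, x, step=1e-6):
    """Central-difference Jacobian of a vector-valued function."""
    h = _steps(x, step)
    cols = []
    for j in range(x.size):
        xp, xm = x.copy(), x.copy()
        xp[j] += h[j]
        xm[j] -= h[j]
        cols.append((fn(xp) - fn(xm)) / (2 * h[j]))
    return np.stack(cols, axis=-1)


def _num_hess(fn, x, step=1e-5):
    """Central-difference Hessian of a scalar function."""
    n = x.size
    h = _steps(x, step)
    H = np.empty((n, n))
    f0 = fn(x)
    fp = np.empty(n)
    fm = np.empty(n)
    for i in range(n):
        xp, xm = x.copy(), x.copy()
        xp[i] += h[i]
        xm[i] -= h[i]
        fp[i] = fn(xp)
        fm[i] = fn(xm)
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h[i] ** 2
    for i in range(n):
        for j in range(i + 1, n):
            xpp = x.copy()
            xpp[[i, j]] += [h[i], h[j]]
            xmm = x.copy()
            xmm[[i, j]] -= [h[i], h[j]]
            H[i, j] = H[j, i] = (
                (fn(xpp) - fp[i] - fp[j] + 2 * f0 - fm[i] - fm[j] + fn(xmm))
                / (2 * h[i] * h[j]))
    return H


# ---------------------------------------------------------------------------
# tests and screens
# ---------------------------------------------------------------------------

@dataclass
class LRTResult:
    statistic: float
    df: int
    p_value: float
    boundary: bool = False


def lrt(nested: ITSResults, full: ITSResults,
        boundary: bool = False) -> LRTResult:
    """Likelihood-ratio test of nested against nesting model.

    With ``boundary=True`` (a single variance component tested on its
    boundary) the reference distribution is the 50:50 chi2(0):chi2(1)
    mixture.
    """
    if nested.bundle.n != full.bundle.n:
        raise ValueError("models were fitted to different data")
    df = full.k_params - nested.k_params
    if df <= 0:
        if df == 0 and nested.k_params == full.k_params and \
                abs(nested.loglik - full.loglik) < 1e-8:
            return LRTResult(0.0, 0, 1.0, boundary)
        raise ValueError("models are not nested (df <= 0)")
    stat = max(0.0, 2.0 * (full.loglik - nested.loglik))
    if boundary:
        p = 0.5 * stats.chi2.sf(stat, 1) if stat > 0 else 1.0
        return LRTResult(stat, df, float(p), True)
    return LRTResult(stat, df, float(stats.chi2.sf(stat, df)), False)


def vif(bundle: DesignBundle) -> pd.Series:
    """Variance inflation factors of the fixed design.

    The intercept, interaction columns and seasonal dummies are excluded.
    A numerically collinear column is flagged with ``inf``.
    """
    keep = [i for i, n in enumerate(bundle.xnames)
            if n != "intercept" and not n.startswith("subsidy_x")
            and not n.startswith("month:")]
    X = bundle.X[:, keep]
    names = [bundle.xnames[i] for i in keep]
    out = {}
    ones = np.ones((X.shape[0], 1))
    for j, name in enumerate(names):
        others = np.hstack([ones, np.delete(X, j, axis=1)])
        yj = X[:, j]
        coef, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ coef
        tss = ((yj - yj.mean()) ** 2).sum()
        rss = (resid ** 2).sum()
        if tss <= 0 or rss / tss < 1e-12:
            out[name] = np.inf
        else:
            out[name] = tss / rss
    return pd.Series(out, name="vif")


def overdispersion_check(records: pd.DataFrame, spec: ModelSpec,
                         scenario: ExposureScenario,
                         **fit_kw) -> LRTResult:
    """Boundary LRT for a birth-level (level-1) random intercept.

    Compares the specified model against the same model with a log-normal
    birth-level frailty added (3-level specs are first reduced to their
    cluster-level structure for this screen).
    """
    spec0 = replace(spec, n_levels=2)
    base = MultilevelPoissonITS.from_records(records, spec0, scenario)
    with_fr = MultilevelPoissonITS.from_records(records, spec0, scenario,
                                                frailty=True)
    r0 = base.fit(**fit_kw)
    start = with_fr.layout.pack_start(r0.params.to_numpy())
    # reuse the base fit for the shared parameters
    start[:r0.theta.size] = r0.theta
    start[-1] = np.log(0.1)
    r1 = with_fr.fit(start=start, collapse_boundary=False, **fit_kw)
    return lrt(r0, r1, boundary=True)


@dataclass
class ConfounderDecision:
    keep: bool
    relative_change: float
    indeterminate: bool = False


def confounder_screen(fit_with: ITSResults, fit_without: ITSResults,
                      threshold: float = 0.10,
                      term: str = "subsidy") -> ConfounderDecision:
    """Keep a covariate if it moves the subsidy coefficient by >= 10%."""
    b_with = fit_with.params[term]
    b_without = fit_without.params[term]
    if b_without == 0:
        return ConfounderDecision(keep=True, relative_change=np.inf,
                                  indeterminate=True)
    change = abs(b_with - b_without) / abs(b_without)
    return ConfounderDecision(keep=bool(change >= threshold),
                              relative_change=float(change))
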