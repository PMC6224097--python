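"""Marginal Poisson likelihood with integrated random effects.

Numerical core for the multilevel modified-Poisson model.  Cluster-level
random effects (up to intercept/subsidy/time/post-time coefficients) are
integrated by adaptive Gauss-Hermite quadrature: each cluster's integrand is
re-centred at its posterior mode and scaled by the local curvature, so a
small tensor node set is accurate even for large clusters.  One node
recovers the Laplace approximation.  A nested woman-level intercept
(3-level models) and an optional birth-level frailty (the over-dispersion
screen) are integrated by fixed Gauss-Hermite rules on the prior scale --
their conditional sample sizes are tiny (<= 8 births per woman, 1 per
birth), where prior-scaled rules are adequate.

Everything is vectorised over clusters: per-cluster reductions use
``np.add.reduceat`` on cluster-sorted data and mode finding is a batched,
damped Newton iteration (the integrand is concave in the random effects for
the plain Poisson term).
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.special import logsumexp

_ETA_CAP = 30.0  # exp overflow guard on the linear predictor


def gh_rule(n_nodes: int, dim: int) -> Tuple[np.ndarray, np.ndarray]:
    """Tensor-product Gauss-Hermite rule: nodes (M, dim) and log-weights."""
    t, w = hermgauss(n_nodes)
    logw = np.log(w)
    if dim == 1:
        return t[:, None], logw
    grids = np.meshgrid(*([t] * dim), indexing="ij")
    nodes = np.stack([g.ravel() for g in grids], axis=1)
    wgrids = np.meshgrid(*([logw] * dim), indexing="ij")
    logws = sum(g.ravel() for g in wgrids)
    return nodes, logws


def poisson_ll(y: np.ndarray, eta: np.ndarray) -> np.ndarray:
    """log Poisson(y; exp(eta)) dropping the y! constant (0 for binary y)."""
    return y * eta - np.exp(np.minimum(eta, _ETA_CAP))


def birth_ll(y, eta, frailty_sd=0.0, n_nodes=9, deriv=False):
    """Per-birth conditional log-likelihood, optionally frailty-marginalised.

    With ``deriv=True`` also returns first and second derivatives in eta
    (needed by the cluster-mode Newton step).
    """
    if frailty_sd <= 0.0:
        mu = np.exp(np.minimum(eta, _ETA_CAP))
        ll = y * eta - mu
        if not deriv:
            return ll
        return ll, y - mu, -mu
    s, logw = gh_rule(n_nodes, 1)
    v = np.sqrt(2.0) * frailty_sd * s[:, 0]
    logc = logw - 0.5 * np.log(np.pi)
    ee = eta[..., None] + v
    mu_w = np.exp(np.minimum(ee, _ETA_CAP))
    sw = logc + y[..., None] * ee - mu_w
    ll = logsumexp(sw, axis=-1)
    if not deriv:
        return ll
    p = np.exp(sw - ll[..., None])
    m1 = (p * mu_w).sum(-1)
    m2 = (p * mu_w ** 2).sum(-1)
    return ll, y - m1, (m2 - m1 ** 2) - m1


class GroupIndex:
    """Segment boundaries of a sorted integer code vector."""

    def __init__(self, codes: np.ndarray):
        codes = np.asarray(codes)
        if codes.size and np.any(np.diff(codes) < 0):
            raise ValueError("codes must be sorted")
        self.codes = codes
        self.starts = np.flatnonzero(
            np.r_[True, np.diff(codes) != 0]) if codes.size else np.array([], int)
        self.labels = codes[self.starts] if codes.size else np.array([], int)
        self.n_groups = self.starts.size

    def sum(self, values: np.ndarray, axis: int = 0) -> np.ndarray:
        """Per-group sums along the leading axis."""
        return np.add.reduceat(values, self.starts, axis=axis)


def _chol_psd(mats: np.ndarray) -> np.ndarray:
    """Batched Cholesky with a tiny jitter fallback."""
    try:
        return np.linalg.cholesky(mats)
    except np.linalg.LinAlgError:
        eye = np.eye(mats.shape[-1])
        return np.linalg.cholesky(mats + 1e-10 * eye)


def cluster_modes(y, eta_fix, Z, gi: GroupIndex, psi_inv,
                  frailty_sd=0.0, u0=None, tol=1e-9, max_iter=50):
    """Posterior modes of cluster random effects, batched damped Newton.

    Returns (u_hat (K, q), neg_hess (K, q, q), f_hat (K,)) where f_hat is the
    joint log-density (likelihood + prior, up to the prior normalisation) at
    the mode.
    """
    K, q = gi.n_groups, Z.shape[1]
    u = np.zeros((K, q)) if u0 is None else u0.copy()
    cl = np.searchsorted(gi.starts, np.arange(y.size), side="right") - 1

    def parts(u):
        eta = eta_fix + np.einsum("nq,nq->n", Z, u[cl])
        ll, d1, d2 = birth_ll(y, eta, frailty_sd, deriv=True)
        f = gi.sum(ll) - 0.5 * np.einsum("kq,qp,kp->k", u, psi_inv, u)
        g = gi.sum(Z * d1[:, None]) - u @ psi_inv
        H = -gi.sum(Z[:, :, None] * Z[:, None, :] * d2[:, None, None]) \
            + psi_inv[None, :, :]
        return f, g, H

    f, g, H = parts(u)
    for _ in range(max_iter):
        if np.max(np.abs(g)) < tol:
            break
        step = np.linalg.solve(H, g[..., None])[..., 0]
        # damped update: halve steps for clusters whose objective worsens
        scale = np.ones(K)
        for _ in range(20):
            u_new = u + scale[:, None] * step
            f_new, g_new, H_new = parts(u_new)
            bad = f_new < f - 1e-12
            if not bad.any():
                break
            scale[bad] *= 0.5
        u, f, g, H = u_new, f_new, g_new, H_new
    return u, H, f


def loglik_clusters(y, eta_fix, Z, gi: GroupIndex, psi: np.ndarray,
                    n_nodes: int = 7, frailty_sd: float = 0.0,
                    woman_gi: Optional[GroupIndex] = None,
                    level2_sd: float = 0.0, adaptive: bool = True,
                    state: Optional[dict] = None) -> np.ndarray:
    """Per-cluster marginal log-likelihood with cluster effects integrated.

    ``psi`` is the q x q cluster covariance.  When ``woman_gi``/``level2_sd``
    are given, a woman-level intercept is integrated by a prior-scaled rule
    nested inside the (then non-adaptive) cluster rule.
    """
    q = Z.shape[1]
    sign, logdet_psi = np.linalg.slogdet(psi)
    if sign <= 0:
        raise np.linalg.LinAlgError("psi not positive definite")
    psi_inv = np.linalg.inv(psi)
    K = gi.n_groups
    cl = np.searchsorted(gi.starts, np.arange(y.size), side="right") - 1

    if woman_gi is not None and level2_sd > 0.0:
        return _loglik_three_level(y, eta_fix, Z, gi, cl, psi, n_nodes,
                                   woman_gi, level2_sd)

    if adaptive:
        u0 = state.get("u0") if state else None
        u_hat, H, f_hat = cluster_modes(y, eta_fix, Z, gi, psi_inv,
                                        frailty_sd, u0=u0)
        if state is not None:
            state["u0"] = u_hat
        C = _chol_psd(np.linalg.inv(H))  # (K, q, q)
        t, logw = gh_rule(n_nodes, q)
        M = t.shape[0]
        # u_km = u_hat_k + sqrt(2) C_k t_m
        U = u_hat[:, None, :] + np.sqrt(2.0) * \
            np.einsum("kqp,mp->kmq", C, t)
        contrib = np.empty((K, M))
        for m in range(M):
            um = U[:, m, :]
            eta = eta_fix + np.einsum("nq,nq->n", Z, um[cl])
            ll = birth_ll(y, eta, frailty_sd)
            contrib[:, m] = gi.sum(ll) - 0.5 * np.einsum(
                "kq,qp,kp->k", um, psi_inv, um) + logw[m] + (t[m] ** 2).sum()
        _, logdet_C = np.linalg.slogdet(C)
        out = logsumexp(contrib, axis=1) + 0.5 * q * np.log(2.0) + logdet_C \
            - 0.5 * (q * np.log(2 * np.pi) + logdet_psi)
        return out

    # non-adaptive, prior-scaled rule (used as a cross-check)
    A = _chol_psd(psi[None, :, :])[0]
    t, logw = gh_rule(n_nodes, q)
    M = t.shape[0]
    contrib = np.empty((K, M))
    for m in range(M):
        um = np.sqrt(2.0) * (A @ t[m])
        eta = eta_fix + Z @ um
        ll = birth_ll(y, eta, frailty_sd)
        contrib[:, m] = gi.sum(ll) + logw[m]
    return logsumexp(contrib, axis=1) - 0.5 * q * np.log(np.pi)


def _loglik_three_level(y, eta_fix, Z, gi, cl, psi, n_nodes,
                        woman_gi: GroupIndex, level2_sd: float):
    """Cluster effects by prior-scaled GH, woman intercept nested inside."""
    q = Z.shape[1]
    A = _chol_psd(psi[None, :, :])[0]
    t, logw = gh_rule(min(n_nodes, 5) if q >= 3 else n_nodes, q)
    s, logw2 = gh_rule(9, 1)
    v = np.sqrt(2.0) * level2_sd * s[:, 0]
    logc = logw2 - 0.5 * np.log(np.pi)
    M = t.shape[0]
    K = gi.n_groups
    contrib = np.empty((K, M))
    # women are nested in clusters, so cluster sums aggregate woman sums
    wstarts = woman_gi.starts
    for m in range(M):
        um = np.sqrt(2.0) * (A @ t[m])
        eta = eta_fix + Z @ um
        B = y[:, None] * (eta[:, None] + v) - \
            np.exp(np.minimum(eta[:, None] + v, _ETA_CAP))
        per_woman = np.add.reduceat(B, wstarts, axis=0) + logc
        lw = logsumexp(per_woman, axis=1)
        w_cl = cl[wstarts]
        contrib[:, m] = np.bincount(w_cl, weights=lw, minlength=K) + logw[m]
    return logsumexp(contrib, axis=1) - 0.5 * q * np.log(np.pi)


def loglik_level2_only(y, eta_fix, woman_gi: GroupIndex, level2_sd: float,
                       n_nodes: int = 9) -> np.ndarray:
    """Per-woman marginal log-likelihood, woman intercept only (no cluster)."""
    s, logw = gh_rule(n_nodes, 1)
    v = np.sqrt(2.0) * level2_sd * s[:, 0]
    logc = logw - 0.5 * np.log(np.pi)
    B = y[:, None] * (eta_fix[:, None] + v) - \
        np.exp(np.minimum(eta_fix[:, None] + v, _ETA_CAP))
    per_woman = np.add.reduceat(B, woman_gi.starts, axis=0) + logc
    return logsumexp(per_woman, axis=1)
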