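"""Overdispersed binomial GLMM for paired cluster-frequency designs.

Model
-----
For sample s of donor v with cluster count y_s out of total n_s::

    y_s ~ Binomial(n_s, p_s),   logit(p_s) = b0 + b1 * challenge_s + u_v + e_s
    u_v ~ Normal(0, sigma_u^2)          (donor random effect)
    e_s ~ Normal(0, sigma_e^2)          (sample-level random effect)

The challenge indicator is 1 for "after" samples. The sample-level
(observation-level) effect e_s absorbs extra-binomial variation —
without it, biological replicate-to-replicate scatter at large totals
would wildly overdisperse a plain binomial fit.

Estimation maximizes the exact marginal likelihood, integrating both
random effects numerically: the sample effect by adaptive Gauss-Hermite
quadrature (nodes recentred and rescaled at each integrand's mode, found
by Newton steps in closed form), nested inside an adaptive Gauss-Hermite
integral over each donor's effect. Both integrals are one-dimensional, so
the marginal likelihood is computed to quadrature accuracy rather than by
a joint Laplace approximation, which is unstable for observation-level
effects at small totals.

Inference on b1 is a Wald z test using the observed-information standard
error with the variance parameters held at their estimates (the usual
mixed-model convention). Variance estimates on the boundary (sigma = 0)
are reported as 0 with a boundary flag rather than as an error.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import expit, gammaln, log_expit, logsumexp


@lru_cache(maxsize=8)
def _gh_nodes(k: int) -> tuple[np.ndarray, np.ndarray]:
    t, w = hermgauss(k)
    return t, np.log(w)

__all__ = ["GLMMFit", "SeparationError", "fit_overdispersed_binomial_glmm",
           "glmm_loglik"]

_SIGMA_TINY = 1e-6
_BOUNDARY = 1e-4


class SeparationError(ValueError):
    """All counts are 0 or all equal their totals; the logit is unbounded."""


@dataclass
class GLMMFit:
    """Fitted overdispersed binomial mixed model for one cluster/group."""

    cluster_id: str
    group: str
    beta0: float
    beta1: float
    sigma_u: float
    sigma_e: float
    se_beta1: float
    loglik: float
    converged: bool
    boundary_u: bool = False
    boundary_e: bool = False
    n_donors: int = 0
    n_obs: int = 0
    #: degrees of freedom for small-sample Wald inference on beta1
    #: (number of donors observed at both timepoints minus one)
    df: int = 0


def _binom_logcoef(y: np.ndarray, n: np.ndarray) -> float:
    return float(np.sum(gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)))


def _inner_h(e, eta, y, n, sigma_e):
    """Log integrand of the sample-effect integral (no binomial coef)."""
    z = eta + e
    return (y * log_expit(z) + (n - y) * log_expit(-z)
            - 0.5 * (e / sigma_e) ** 2
            - np.log(sigma_e) - 0.5 * np.log(2.0 * np.pi))


def _log_g(eta, y, n, sigma_e, t_e, logw_e, want_score=False):
    """log integral over the sample effect e, elementwise in eta.

    eta, y, n broadcast to a common shape. Returns log g, and optionally
    the first and (negated) second derivative of log g with respect to a
    shift of eta: score = E[y - n p] and info = E[n p (1-p)] - Var(y - n p),
    both under the posterior of e. The variance term matters: marginalizing
    e flattens the likelihood, so the conditional Fisher information alone
    would badly overstate the curvature at large totals.
    """
    if sigma_e < _SIGMA_TINY:
        lg = y * log_expit(eta) + (n - y) * log_expit(-eta)
        if not want_score:
            return lg
        p = expit(eta)
        return lg, y - n * p, n * p * (1.0 - p)

    # Newton for the mode of the concave log-integrand
    e = np.zeros(np.broadcast_shapes(np.shape(eta), np.shape(y)))
    inv_ve = 1.0 / sigma_e**2
    for _ in range(8):
        p = expit(eta + e)
        g1 = y - n * p - e * inv_ve
        g2 = -n * p * (1.0 - p) - inv_ve
        e = e - g1 / g2
    p = expit(eta + e)
    curv = n * p * (1.0 - p) + inv_ve
    shat = 1.0 / np.sqrt(curv)

    nodes = e[..., None] + np.sqrt(2.0) * shat[..., None] * t_e
    hvals = _inner_h(nodes, np.asarray(eta)[..., None],
                     np.asarray(y)[..., None], np.asarray(n)[..., None],
                     sigma_e)
    lw = logw_e + t_e**2 + hvals
    lg = 0.5 * np.log(2.0) + np.log(shat) + logsumexp(lw, axis=-1)
    if not want_score:
        return lg
    omega = np.exp(lw - logsumexp(lw, axis=-1, keepdims=True))
    p_nodes = expit(np.asarray(eta)[..., None] + nodes)
    resid = np.asarray(y)[..., None] - np.asarray(n)[..., None] * p_nodes
    score = np.sum(omega * resid, axis=-1)
    var_resid = np.sum(omega * resid**2, axis=-1) - score**2
    cond_info = np.sum(omega * np.asarray(n)[..., None] * p_nodes
                       * (1.0 - p_nodes), axis=-1)
    info = np.maximum(cond_info - var_resid, 1e-8)
    return lg, score, info


def glmm_loglik(
    params: np.ndarray,
    y: np.ndarray,
    n: np.ndarray,
    x: np.ndarray,
    donor_idx: np.ndarray,
    n_donors: int,
    k_inner: int = 20,
    k_outer: int = 15,
) -> float:
    """Marginal log-likelihood at params = (b0, b1, sigma_u, sigma_e)."""
    b0, b1, sigma_u, sigma_e = params
    t_e, logw_e = _gh_nodes(k_inner)
    t_u, logw_u = _gh_nodes(k_outer)
    eta_fix = b0 + b1 * x

    if sigma_u < _SIGMA_TINY:
        lg = _log_g(eta_fix, y, n, sigma_e, t_e, logw_e)
        return float(np.sum(lg)) + _binom_logcoef(y, n)

    inv_vu = 1.0 / sigma_u**2
    # Newton for each donor's mode of sum_s log g_s(u) - u^2/(2 sigma_u^2)
    u = np.zeros(n_donors)
    for _ in range(6):
        _, score, info = _log_g(eta_fix + u[donor_idx], y, n, sigma_e,
                                t_e, logw_e, want_score=True)
        g1 = np.bincount(donor_idx, weights=score, minlength=n_donors) - u * inv_vu
        g2 = -np.bincount(donor_idx, weights=info, minlength=n_donors) - inv_vu
        u = u - g1 / g2
    _, _, info = _log_g(eta_fix + u[donor_idx], y, n, sigma_e,
                        t_e, logw_e, want_score=True)
    curv = np.bincount(donor_idx, weights=info, minlength=n_donors) + inv_vu
    shat = 1.0 / np.sqrt(curv)

    # outer adaptive GH: u nodes per donor
    U = u[:, None] + np.sqrt(2.0) * shat[:, None] * t_u  # donors x k_outer
    eta = eta_fix[:, None] + U[donor_idx]                # obs x k_outer
    lg = _log_g(eta, y[:, None], n[:, None], sigma_e, t_e, logw_e)
    per_donor = np.zeros((n_donors, len(t_u)))
    np.add.at(per_donor, donor_idx, lg)
    log_prior = (-0.5 * (U / sigma_u) ** 2 - np.log(sigma_u)
                 - 0.5 * np.log(2.0 * np.pi))
    lw = logw_u + t_u**2 + per_donor + log_prior
    ll_v = 0.5 * np.log(2.0) + np.log(shat) + logsumexp(lw, axis=1)
    return float(np.sum(ll_v)) + _binom_logcoef(y, n)


def _start_values(y, n, x):
    adj = np.log((y + 0.5) / (n - y + 0.5))
    b0 = float(np.mean(adj[x == 0])) if np.any(x == 0) else float(np.mean(adj))
    b1 = (float(np.mean(adj[x == 1])) - b0) if np.any(x == 1) else 0.0
    return b0, b1


def fit_overdispersed_binomial_glmm(
    rows: pd.DataFrame,
    cluster_id: str = "",
    group: str = "",
    k_inner: int = 20,
    k_outer: int = 15,
    min_donors: int = 4,
) -> GLMMFit:
    """Fit the model to one cluster's rows for one subject group.

    Parameters
    ----------
    rows
        DataFrame with columns donor_id, timepoint ("before"/"after"),
        count, total.
    min_donors
        Minimum number of donors observed at both timepoints.

    Raises
    ------
    SeparationError
        When every count is 0 or every count equals its total.
    ValueError
        When fewer than ``min_donors`` donors have both timepoints.
    """
    for col in ("donor_id", "timepoint", "count", "total"):
        if col not in rows.columns:
            raise ValueError(f"rows lack column {col!r}")
    y = rows["count"].to_numpy(dtype=float)
    n = rows["total"].to_numpy(dtype=float)
    if np.any(y > n):
        raise ValueError("count exceeds total")
    if np.all(y == 0) or np.all(y == n):
        raise SeparationError(
            "all counts are 0 or all counts equal their totals")
    x = (rows["timepoint"] == "after").to_numpy(dtype=float)
    donors = pd.Categorical(rows["donor_id"])
    donor_idx = donors.codes.astype(np.intp)
    n_donors = len(donors.categories)
    n_paired = int((rows.groupby("donor_id")["timepoint"].nunique() == 2).sum())
    if n_paired < min_donors:
        raise ValueError(
            f"need >= {min_donors} donors with both timepoints, "
            f"got {n_paired}")

    b0_init, b1_init = _start_values(y, n, x)
    x0 = np.array([b0_init, b1_init, 0.3, 0.3])
    bounds = [(None, None), (None, None), (0.0, 10.0), (0.0, 10.0)]

    def nll(p):
        return -glmm_loglik(p, y, n, x, donor_idx, n_donors,
                            k_inner=k_inner, k_outer=k_outer)

    res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 200, "ftol": 1e-9, "gtol": 1e-6})
    if not res.success:
        res2 = minimize(nll, np.clip(res.x, [-np.inf, -np.inf, 0, 0], None),
                        method="Nelder-Mead",
                        options={"maxiter": 2000, "xatol": 1e-6,
                                 "fatol": 1e-8})
        if res2.fun <= res.fun:
            res = res2
    converged = bool(res.success) and np.isfinite(res.fun)
    b0, b1, su, se_ = res.x
    su, se_ = max(su, 0.0), max(se_, 0.0)

    # Wald SE for the fixed effects at fixed variance components
    h = 1e-4
    def nll_b(b):
        return nll(np.array([b[0], b[1], su, se_]))
    H = np.zeros((2, 2))
    b = np.array([b0, b1])
    f0 = nll_b(b)
    for i in range(2):
        for j in range(i, 2):
            ei = np.eye(2)[i] * h
            ej = np.eye(2)[j] * h
            if i == j:
                H[i, i] = (nll_b(b + ei) - 2 * f0 + nll_b(b - ei)) / h**2
            else:
                H[i, j] = H[j, i] = (
                    nll_b(b + ei + ej) - nll_b(b + ei - ej)
                    - nll_b(b - ei + ej) + nll_b(b - ei - ej)
                ) / (4 * h**2)
    try:
        cov = np.linalg.inv(H)
        se_b1 = float(np.sqrt(max(cov[1, 1], 0.0)))
    except np.linalg.LinAlgError:
        se_b1 = float("nan")

    return GLMMFit(
        cluster_id=cluster_id, group=group,
        beta0=float(b0), beta1=float(b1),
        sigma_u=0.0 if su < _BOUNDARY else float(su),
        sigma_e=0.0 if se_ < _BOUNDARY else float(se_),
        se_beta1=se_b1,
        loglik=float(-res.fun),
        converged=converged,
        boundary_u=bool(su < _BOUNDARY),
        boundary_e=bool(se_ < _BOUNDARY),
        n_donors=n_donors, n_obs=len(y),
        df=max(n_paired - 1, 1),
    )
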