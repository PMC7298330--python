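"""Rasch Poisson Counts Model (RPCM) by adaptive Gauss-Hermite marginal ML.

The model: person ``v`` scores ``Y_vi ~ Poisson(mu_vi)`` with
``log mu_vi = theta_v + x_vi' beta`` where the log-ability ``theta_v`` is a
normal random intercept, ``theta_v ~ N(0, zeta)``.  On the counts scale the
expected score factorises into person ability times item easiness
(``mu = theta * sigma``), so ``exp(beta_i)`` under cell-mean item coding is
the expected score on item ``i`` for a person of average ability.

Variants fitted here differ only in the fixed-effect design:

* ``person_only``  -- a single intercept (all items equally easy);
* ``rpcm``         -- one easiness parameter per item (cell-mean coding);
* ``rpcm_r``       -- one easiness parameter per radical level, i.e. item
  difficulty fully explained by visual information load;
* arbitrary extra columns (group main effects, group x item interactions)
  for differential-item-functioning analyses.

Estimation maximises the marginal likelihood, integrating the random
intercept out per person with *adaptive* Gauss-Hermite quadrature: nodes are
centred at each person's posterior mode and scaled by the posterior
curvature, which keeps few-node rules accurate.  Scores (gradients) are
computed analytically through the Fisher identity (posterior-expected
complete-data score), so fits are fast and the observed-information matrix
is obtained by differencing the analytic gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from functools import lru_cache

import numpy as np
from numpy.polynomial.hermite import hermgauss as _hermgauss_uncached
from scipy import optimize, special, stats

from .data import ResponseMatrix


@lru_cache(maxsize=None)
def hermgauss(n: int):
    return _hermgauss_uncached(n)

__all__ = [
    "RPCMFit",
    "PersonEstimate",
    "build_design",
    "marginal_loglik",
    "fit_person_only",
    "fit_rpcm",
    "fit_rpcm_r",
    "lrt",
    "eb_person_estimates",
    "predict_mu",
    "easiness_table",
]

_LOG_ZETA_BOUNDS = (-13.0, 3.0)
_SQRT2 = np.sqrt(2.0)


# --- designs ---------------------------------------------------------------


def build_design(data: ResponseMatrix, kind: str):
    """Fixed-effect design tensor ``X`` with shape (persons, items, p).

    ``kind`` is ``"intercept"`` (person-only model), ``"items"`` (cell-mean
    item coding) or ``"radical"`` (cell-mean radical-level coding).  Returns
    ``(X, names)``.
    """
    P, I = data.scores.shape
    if kind == "intercept":
        X = np.ones((P, I, 1))
        return X, ["intercept"]
    if kind == "items":
        X = np.zeros((P, I, I))
        for i in range(I):
            X[:, i, i] = 1.0
        return X, list(data.item_ids)
    if kind == "radical":
        levels = np.unique(data.radical_levels)
        X = np.zeros((P, I, len(levels)))
        for j, lev in enumerate(levels):
            X[:, data.radical_levels == lev, j] = 1.0
        return X, [f"eta{lev}" for lev in levels]
    raise ValueError(f"unknown design kind {kind!r}")


# --- adaptive quadrature core ---------------------------------------------


def _posterior_grid(Sy, S1, zeta, x_nodes):
    """Per-person posterior mode/scale of theta under the Poisson model and
    the adaptive node positions ``mode + sqrt(2) * scale * x_k``.

    ``Sy`` = row sums of y, ``S1`` = row sums of exp(A).  The inner
    log-posterior ``Sy*t - e^t*S1 - t^2/(2 zeta)`` is strictly concave, so
    safeguarded Newton from 0 converges in a handful of steps.
    """
    theta = np.zeros_like(S1)
    inv_zeta = 1.0 / zeta
    for _ in range(80):
        et = np.exp(theta)
        g = Sy - et * S1 - theta * inv_zeta
        h = -et * S1 - inv_zeta
        step = np.clip(-g / h, -2.0, 2.0)
        theta = theta + step
        if np.max(np.abs(step)) < 1e-12:
            break
    scale = 1.0 / np.sqrt(np.exp(theta) * S1 + inv_zeta)
    nodes = theta[:, None] + _SQRT2 * scale[:, None] * x_nodes[None, :]
    return theta, scale, nodes


def _agq_collapse(g, scale, x_nodes, w_nodes):
    """Given per-(person, node) integrand log-values ``g`` (joint log density
    of data and theta), return the per-person log marginal likelihood and the
    normalised posterior node weights."""
    log_terms = np.log(w_nodes)[None, :] + g + (x_nodes**2)[None, :]
    m = log_terms.max(axis=1, keepdims=True)
    w = np.exp(log_terms - m)
    sw = w.sum(axis=1)
    ll = m[:, 0] + np.log(sw) + np.log(_SQRT2 * scale)
    post = w / sw[:, None]
    return ll, post


def _poisson_parts(data, X, beta, zeta, quad_nodes):
    """Shared quadrature quantities for the Poisson model.

    Returns (ll_per_person, post, nodes, A, aux) where ``post`` are posterior
    node weights and ``aux`` carries row sums reused by the gradient.
    """
    y = data.scores
    A = X @ beta
    if zeta == 0.0:
        ll = stats.poisson.logpmf(y, np.exp(A)).sum(axis=1)
        return ll, None, None, A, None
    x_nodes, w_nodes = hermgauss(quad_nodes)
    Sy = y.sum(axis=1).astype(float)
    S1 = np.exp(A).sum(axis=1)
    const = (y * A - special.gammaln(y + 1.0)).sum(axis=1)
    _, scale, nodes = _posterior_grid(Sy, S1, zeta, x_nodes)
    g = (
        Sy[:, None] * nodes
        - np.exp(nodes) * S1[:, None]
        + const[:, None]
        - nodes**2 / (2.0 * zeta)
        - 0.5 * np.log(2.0 * np.pi * zeta)
    )
    ll, post = _agq_collapse(g, scale, x_nodes, w_nodes)
    return ll, post, nodes, A, (Sy, S1)


def marginal_loglik(
    fixed_params,
    person_variance: float,
    data: ResponseMatrix,
    design="items",
    quad_nodes: int = 15,
) -> float:
    """Marginal log-likelihood of the RPCM at given parameter values.

    ``design`` is a design-kind string accepted by :func:`build_design` or a
    ready (persons, items, p) tensor.  ``person_variance`` is zeta, the
    variance of the normal random intercept; ``person_variance = 0`` is the
    exact fixed-ability limit.
    """
    beta = np.atleast_1d(np.asarray(fixed_params, dtype=float))
    if not np.all(np.isfinite(beta)) or not np.isfinite(person_variance):
        raise ValueError("non-finite parameters")
    if person_variance < 0:
        raise ValueError("person_variance must be >= 0")
    if quad_nodes < 3:
        raise ValueError("quad_nodes must be >= 3")
    X = design if isinstance(design, np.ndarray) else build_design(data, design)[0]
    ll, *_ = _poisson_parts(data, X, beta, float(person_variance), quad_nodes)
    return float(ll.sum())


# --- fit objects -----------------------------------------------------------


@dataclass
class RPCMFit:
    """A fitted marginal-ML count IRT model."""

    model_kind: str
    param_names: list
    beta: np.ndarray
    zeta: float
    loglik: float
    n_params: int
    vcov: np.ndarray  # fixed effects + log zeta (+ dispersion), full inverse information
    converged: bool
    quad_nodes: int
    n_obs: int
    design: np.ndarray = field(repr=False)
    boundary: bool = False
    message: str = ""

    @property
    def person_variance(self) -> float:
        return self.zeta

    @property
    def person_sd(self) -> float:
        return float(np.sqrt(self.zeta))

    def person_sd_ci(self, level: float = 0.95):
        """Wald CI for sqrt(zeta), computed on the log-zeta scale."""
        j = len(self.beta)
        se = float(np.sqrt(max(self.vcov[j, j], 0.0)))
        z = stats.norm.ppf(0.5 + level / 2.0)
        lz = np.log(self.zeta) if self.zeta > 0 else -np.inf
        return (float(np.exp((lz - z * se) / 2.0)), float(np.exp((lz + z * se) / 2.0)))

    def beta_se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.vcov)[: len(self.beta)], 0.0, None))

    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik

    def bic(self) -> float:
        return self.n_params * np.log(self.n_obs) - 2.0 * self.loglik


@dataclass
class PersonEstimate:
    """Empirical-Bayes ability estimate for one person."""

    person_id: str
    theta_log: float  # posterior mean of the log-ability intercept
    se: float  # posterior standard deviation
    reliability: float  # zeta / (zeta + se^2)


def easiness_table(fit: RPCMFit, level: float = 0.95):
    """Counts-scale easiness ``exp(beta)`` with Wald CIs per fixed effect.

    CIs are computed on the log scale and exponentiated, which yields the
    asymmetric intervals count models report.
    """
    z = stats.norm.ppf(0.5 + level / 2.0)
    se = fit.beta_se()
    rows = []
    for name, b, s in zip(fit.param_names, fit.beta, se):
        rows.append(
            {
                "param": name,
                "log_easiness": float(b),
                "easiness": float(np.exp(b)),
                "ci_low": float(np.exp(b - z * s)),
                "ci_high": float(np.exp(b + z * s)),
            }
        )
    return rows


# --- estimation ------------------------------------------------------------


def _start_values(data: ResponseMatrix, X):
    """Poisson-GLM (IRLS) start for beta; method-of-moments start for zeta."""
    y = data.scores.reshape(-1).astype(float)
    Xf = X.reshape(-1, X.shape[2])
    beta = np.zeros(X.shape[2])
    # crude but safe init: log grand mean on every active column
    gm = np.log(max(y.mean(), 0.05))
    active = Xf.sum(axis=0) > 0
    beta[active] = gm
    for _ in range(25):
        eta = Xf @ beta
        mu = np.exp(np.clip(eta, -30, 30))
        W = mu
        z = eta + (y - mu) / np.maximum(mu, 1e-10)
        WX = Xf * W[:, None]
        H = Xf.T @ WX
        b_new = np.linalg.solve(H + 1e-10 * np.eye(len(beta)), WX.T @ z)
        if np.max(np.abs(b_new - beta)) < 1e-10:
            beta = b_new
            break
        beta = b_new
    totals = data.total_scores().astype(float)
    m, v = totals.mean(), totals.var(ddof=1)
    if m > 0 and v > m:
        zeta0 = np.log1p((v - m) / m**2)
    else:
        zeta0 = 0.01
    zeta0 = float(np.clip(zeta0, 1e-3, 2.0))
    return beta, zeta0


def _nll_and_grad(params, data, X, quad_nodes):
    """Negative marginal loglik and analytic gradient in (beta, log zeta)."""
    p = X.shape[2]
    beta = params[:p]
    zeta = float(np.exp(params[p]))
    y = data.scores
    ll, post, nodes, A, aux = _poisson_parts(data, X, beta, zeta, quad_nodes)
    # posterior mean of exp(theta) per person; Poisson complete-data score
    # factorises so only this enters the beta-gradient (Fisher identity)
    e_exp_theta = (post * np.exp(nodes)).sum(axis=1)
    resid = y - e_exp_theta[:, None] * np.exp(A)  # (P, I)
    grad_beta = np.einsum("pi,pij->j", resid, X)
    e_theta2 = (post * nodes**2).sum(axis=1)
    grad_logzeta = float((e_theta2 / (2.0 * zeta) - 0.5).sum())
    g = np.concatenate([grad_beta, [grad_logzeta]])
    return -float(ll.sum()), -g


def _hessian_fd(grad_fn, params, h: float = 1e-5):
    """Observed information by central differences of the analytic gradient."""
    k = len(params)
    H = np.zeros((k, k))
    for j in range(k):
        step = h * max(1.0, abs(params[j]))
        e = np.zeros(k)
        e[j] = step
        gp = grad_fn(params + e)
        gm = grad_fn(params - e)
        H[:, j] = (gp - gm) / (2.0 * step)
    return 0.5 * (H + H.T)


def _fit(data: ResponseMatrix, X, names, model_kind: str, quad_nodes: int = 15) -> RPCMFit:
    data.require_fittable()
    if np.all(data.scores == 0):
        raise ValueError("degenerate fit: all scores are zero")
    beta0, zeta0 = _start_values(data, X)
    x0 = np.concatenate([beta0, [np.log(zeta0)]])
    p = X.shape[2]
    bounds = [(None, None)] * p + [_LOG_ZETA_BOUNDS]

    res = optimize.minimize(
        _nll_and_grad,
        x0,
        args=(data, X, quad_nodes),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-7},
    )
    beta = res.x[:p]
    log_zeta = res.x[p]
    boundary = log_zeta <= _LOG_ZETA_BOUNDS[0] + 1e-6
    zeta = 0.0 if boundary else float(np.exp(log_zeta))
    ll = -res.fun

    grad_fn = lambda q: _nll_and_grad(q, data, X, quad_nodes)[1]
    H = _hessian_fd(grad_fn, res.x)
    try:
        vcov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        vcov = np.full((p + 1, p + 1), np.nan)

    return RPCMFit(
        model_kind=model_kind,
        param_names=list(names),
        beta=beta,
        zeta=zeta,
        loglik=float(ll),
        n_params=p + 1,
        vcov=vcov,
        converged=bool(res.success),
        quad_nodes=quad_nodes,
        n_obs=data.n_obs,
        design=X,
        boundary=bool(boundary),
        message=str(res.message),
    )


def fit_person_only(data: ResponseMatrix, quad_nodes: int = 15) -> RPCMFit:
    """Null model: one intercept plus the person random intercept (all items
    assumed equally easy)."""
    X, names = build_design(data, "intercept")
    return _fit(data, X, names, "person_only", quad_nodes)


def fit_rpcm(data: ResponseMatrix, quad_nodes: int = 15) -> RPCMFit:
    """RPCM with one cell-mean-coded easiness parameter per item."""
    X, names = build_design(data, "items")
    return _fit(data, X, names, "rpcm", quad_nodes)


def fit_rpcm_r(data: ResponseMatrix, quad_nodes: int = 15) -> RPCMFit:
    """Explanatory RPCM: easiness fully determined by the radical level."""
    levels = np.unique(data.radical_levels)
    if len(levels) < 1:
        raise ValueError("no radical levels in item metadata")
    X, names = build_design(data, "radical")
    return _fit(data, X, names, "rpcm_r", quad_nodes)


def fit_with_design(
    data: ResponseMatrix, X, names, model_kind: str = "rpcm_plus_covariates",
    quad_nodes: int = 15,
) -> RPCMFit:
    """Fit an RPCM with an arbitrary fixed-effect design tensor (used for the
    DIF models: group main effects and group x item interactions)."""
    return _fit(data, np.asarray(X, dtype=float), names, model_kind, quad_nodes)


# --- inference helpers ------------------------------------------------------


def lrt(nested: RPCMFit, full: RPCMFit):
    """Likelihood-ratio test of two nested fits on the same data.

    Returns ``(chi2, df, p)``; the statistic is clipped at zero (numerical
    noise can make the larger model's loglik infinitesimally smaller when the
    extra parameters are truly null).
    """
    if nested.n_obs != full.n_obs:
        raise ValueError("fits are not on the same data")
    if nested.n_params > full.n_params:
        raise ValueError("'nested' must have fewer (or equal) parameters than 'full'")
    chi2 = max(0.0, 2.0 * (full.loglik - nested.loglik))
    df = full.n_params - nested.n_params
    p = 1.0 if df == 0 else float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def _posterior_moments(fit: RPCMFit, data: ResponseMatrix, logpmf_rows=None):
    """Posterior mean and SD of theta per person at the fitted parameters.

    ``logpmf_rows(nodes, A) -> (P, K)`` overrides the per-node complete-data
    log-likelihood; the default is the Poisson model.  Dispersion-model fits
    pass their own likelihood so posterior variances are nu-adjusted.
    """
    if fit.zeta <= 0:
        P = data.n_persons
        return np.zeros(P), np.zeros(P)
    x_nodes, w_nodes = hermgauss(fit.quad_nodes)
    y = data.scores
    A = fit.design @ fit.beta
    Sy = y.sum(axis=1).astype(float)
    S1 = np.exp(A).sum(axis=1)
    _, scale, nodes = _posterior_grid(Sy, S1, fit.zeta, x_nodes)
    if logpmf_rows is None:
        rows = (
            Sy[:, None] * nodes
            - np.exp(nodes) * S1[:, None]
            + ((y * A - special.gammaln(y + 1.0)).sum(axis=1))[:, None]
        )
    else:
        rows = logpmf_rows(nodes, A)
    g = rows - nodes**2 / (2.0 * fit.zeta) - 0.5 * np.log(2.0 * np.pi * fit.zeta)
    _, post = _agq_collapse(g, scale, x_nodes, w_nodes)
    mean = (post * nodes).sum(axis=1)
    var = (post * nodes**2).sum(axis=1) - mean**2
    return mean, np.sqrt(np.clip(var, 0.0, None))


def eb_person_estimates(fit: RPCMFit, data: ResponseMatrix, logpmf_rows=None):
    """Empirical-Bayes person estimates with conditional reliability.

    Conditional reliability of person ``v`` is ``zeta / (zeta + se_v^2)``:
    the fitted ability variance relative to itself plus the person's squared
    posterior standard error.
    """
    if not fit.converged:
        raise ValueError("empirical-Bayes estimates require a converged fit")
    mean, sd = _posterior_moments(fit, data, logpmf_rows=logpmf_rows)
    out = []
    for pid, m, s in zip(data.person_ids, mean, sd):
        rel = fit.zeta / (fit.zeta + s**2) if (fit.zeta + s**2) > 0 else 0.0
        out.append(PersonEstimate(person_id=pid, theta_log=float(m), se=float(s),
                                  reliability=float(rel)))
    return out


def conditional_reliability(person_variance: float, posterior_se: float) -> float:
    """``zeta / (zeta + se^2)`` -- equals 0.5 exactly when ``se^2 == zeta``."""
    return person_variance / (person_variance + posterior_se**2)


def predict_mu(fit: RPCMFit, theta_log: float, item: int) -> float:
    """Expected score ``exp(theta_log + log easiness of the item)``.

    For fits whose parameters are item easinesses this is ``theta * sigma_i``
    on the counts scale; ``theta_log = 0`` returns the easiness itself.
    """
    A = fit.design[0, item, :] @ fit.beta
    return float(np.exp(theta_log + A))
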