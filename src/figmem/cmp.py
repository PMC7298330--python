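"""Conway-Maxwell-Poisson (CMP) generalisations of the RPCM.

The CMP density ``P(Y=j) = lambda^j / (j!)^nu / Z(lambda, nu)`` adds a
dispersion parameter ``nu`` to the Poisson: ``nu = 1`` recovers the Poisson,
``nu > 1`` gives underdispersion, ``nu < 1`` overdispersion.  We use the
*mean* parameterisation: for a requested mean ``mu`` the rate ``lambda`` is
solved from the mean constraint ``E[Y | lambda, nu] = mu`` (Newton on
``log lambda``; the map is monotone since ``dE/dlog lambda = Var[Y] > 0``).
Fixed effects therefore keep exactly the same "expected score" reading as in
the RPCM, and the Poisson fit is the special case ``nu = 1``.

Four model variants mirror the usual naming: items as predictors with a
global (``cmp_gd``) or item-specific (``cmp_sd``) dispersion, and the
radical-explained versions ``cmp_r_gd`` / ``cmp_r_sd``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

from .data import ResponseMatrix
from .rpcm import (
    RPCMFit,
    _agq_collapse,
    _hessian_fd,
    _posterior_grid,
    build_design,
    fit_rpcm,
    fit_rpcm_r,
    hermgauss,
)

__all__ = ["CMPFit", "cmp_logpmf", "cmp_pmf_table", "fit_cmp", "information_criteria"]

_MAX_TERMS_DEFAULT = 200


# --- mean-parameterised pmf --------------------------------------------------


def _grid_length(mu_max: float, nu_min: float, cap: int) -> int:
    # support grid long enough to hold the bulk and a ~15-sigma tail of the
    # widest requested CMP (sd ~ sqrt(mu/nu))
    J = int(np.ceil(mu_max + 15.0 * np.sqrt(mu_max / min(nu_min, 1.0) + 1.0) + 25.0))
    return min(max(J, 30), cap)


def _cmp_solve(mu, nu, max_terms: int = _MAX_TERMS_DEFAULT, t0=None):
    """Solve the rate for given means and return pmf summaries.

    Vectorised over flat arrays ``mu``/``nu`` (broadcast together).  Returns a
    dict with ``t`` (= log lambda), ``logZ``, ``var`` and the expectations of
    ``lgamma(Y+1)`` and its covariance with ``Y`` (needed for nu-gradients).
    ``t0`` warm-starts the Newton iteration (e.g. the solution at the previous
    optimiser step).
    """
    mu = np.asarray(mu, dtype=float)
    nu_arr = np.broadcast_to(np.asarray(nu, dtype=float), mu.shape).copy()
    if np.any(mu <= 0) or np.any(nu_arr <= 0):
        raise ValueError("cmp requires mu > 0 and nu > 0")
    J = _grid_length(float(mu.max()), float(nu_arr.min()), max_terms)
    j = np.arange(J + 1, dtype=float)
    lgam = special.gammaln(j + 1.0)

    flat_mu = mu.reshape(-1)
    flat_nu = nu_arr.reshape(-1)
    # Shmueli asymptotic mean ~ lambda^(1/nu) - (nu-1)/(2 nu), inverted
    base = np.maximum(mu + (nu_arr - 1.0) / (2.0 * nu_arr), np.maximum(mu / 2.0, 1e-8))
    t_cold = (nu_arr * np.log(base)).reshape(-1)

    def newton(t):
        for _ in range(100):
            logw = t[:, None] * j[None, :] - flat_nu[:, None] * lgam[None, :]
            m = logw.max(axis=1, keepdims=True)
            w = np.exp(logw - m)
            sw = w.sum(axis=1)
            E = (w @ j) / sw
            E2 = (w @ (j * j)) / sw
            V = np.maximum(E2 - E * E, 1e-12)
            err = flat_mu - E
            if np.max(np.abs(err) / np.maximum(1.0, flat_mu)) < 1e-11:
                return t, logw, m, w, sw, E, V
            t = t + np.clip(err / V, -3.0, 3.0)
        return None

    result = None
    if t0 is not None and np.shape(t0) == mu.shape:
        # warm start from a previous optimiser step; can be stale after a
        # long line-search jump, in which case we fall back to the cold init
        result = newton(np.asarray(t0, dtype=float).reshape(-1).copy())
    if result is None:
        result = newton(t_cold.copy())
    if result is None:
        raise FloatingPointError("CMP mean constraint did not converge")
    t, logw, m, w, sw, E, V = result

    # tail check: the last retained term must be negligible
    tail = logw[:, -1] - (m[:, 0] + np.log(sw))
    if np.any(tail > -25.0):
        raise FloatingPointError(
            f"CMP series truncated too early (max_terms={max_terms}); "
            "increase max_terms or reduce mu"
        )

    p = w / sw[:, None]
    Elg = p @ lgam
    Eylg = p @ (j * lgam)
    shape = mu.shape
    return {
        "t": t.reshape(shape),
        "logZ": (m[:, 0] + np.log(sw)).reshape(shape),
        "mean": E.reshape(shape),
        "var": V.reshape(shape),
        "E_lgam": Elg.reshape(shape),
        "cov_y_lgam": (Eylg - E * Elg).reshape(shape),
    }


def cmp_logpmf(y, mu, nu, max_terms: int = _MAX_TERMS_DEFAULT):
    """Log-pmf of the mean-parameterised CMP, broadcasting like numpy ufuncs.

    ``nu = 1`` reproduces the Poisson log-pmf exactly (up to the rate solve
    tolerance, ~1e-11).
    """
    y_arr, mu_arr, nu_arr = np.broadcast_arrays(
        np.asarray(y, dtype=float), np.asarray(mu, dtype=float), np.asarray(nu, dtype=float)
    )
    sol = _cmp_solve(mu_arr, nu_arr, max_terms)
    out = y_arr * sol["t"] - nu_arr * special.gammaln(y_arr + 1.0) - sol["logZ"]
    return out if out.shape else float(out)


def cmp_pmf_table(mu: float, nu: float, max_terms: int = _MAX_TERMS_DEFAULT):
    """Normalised pmf over 0..J for one (mu, nu); used for sampling/moments."""
    sol = _cmp_solve(np.asarray([mu]), np.asarray([nu]), max_terms)
    J = _grid_length(mu, min(nu, 1.0), max_terms)
    j = np.arange(J + 1, dtype=float)
    logp = j * sol["t"][0] - nu * special.gammaln(j + 1.0) - sol["logZ"][0]
    p = np.exp(logp)
    return p / p.sum()


# --- fits --------------------------------------------------------------------


@dataclass
class CMPFit(RPCMFit):
    """RPCMFit extended with one or more CMP dispersion parameters."""

    dispersion_kind: str = "global"
    nu: np.ndarray = None  # estimated dispersion parameter(s)
    nu_names: list = None
    nu_index: np.ndarray = None  # item -> dispersion-parameter index

    def nu_by_item(self) -> np.ndarray:
        return self.nu[self.nu_index]


def _nu_structure(data: ResponseMatrix, dispersion_kind: str):
    I = data.n_items
    if dispersion_kind == "global":
        return np.zeros(I, dtype=int), ["nu"]
    if dispersion_kind == "per_item":
        return np.arange(I), [f"nu_{iid}" for iid in data.item_ids]
    if dispersion_kind == "per_radical":
        levels = np.unique(data.radical_levels)
        idx = np.searchsorted(levels, data.radical_levels)
        return idx, [f"nu_level{lev}" for lev in levels]
    raise ValueError(f"unknown dispersion_kind {dispersion_kind!r}")


def _cmp_nll_and_grad(params, data, X, nu_index, d, quad_nodes, max_terms, warm=None):
    """Negative marginal loglik and gradient in (beta, log zeta, log nu)."""
    p = X.shape[2]
    beta = params[:p]
    zeta = float(np.exp(params[p]))
    log_nu = params[p + 1 : p + 1 + d]
    nu_vec = np.exp(log_nu)

    y = data.scores.astype(float)
    A = X @ beta
    x_nodes, w_nodes = hermgauss(quad_nodes)
    Sy = y.sum(axis=1)
    S1 = np.exp(A).sum(axis=1)
    # quadrature grid placed by the Poisson posterior (same mean structure);
    # the integrand evaluated on it is the exact CMP joint density
    _, scale, nodes = _posterior_grid(Sy, S1, zeta, x_nodes)

    mu = np.exp(nodes[:, :, None] + A[:, None, :])  # (P, K, I)
    nu_pki = nu_vec[nu_index][None, None, :]
    t0 = warm.get("t") if warm is not None else None
    sol = _cmp_solve(mu, np.broadcast_to(nu_pki, mu.shape), max_terms, t0=t0)
    if warm is not None:
        warm["t"] = sol["t"]
    lgam_y = special.gammaln(y + 1.0)
    logpmf = y[:, None, :] * sol["t"] - nu_pki * lgam_y[:, None, :] - sol["logZ"]

    g = (
        logpmf.sum(axis=2)
        - nodes**2 / (2.0 * zeta)
        - 0.5 * np.log(2.0 * np.pi * zeta)
    )
    ll, post = _agq_collapse(g, scale, x_nodes, w_nodes)

    resid = y[:, None, :] - sol["mean"]
    # d logpmf / dA = mu * (y - mu) / Var  (chain rule through the rate solve)
    dA = (post[:, :, None] * resid * mu / sol["var"]).sum(axis=1)  # (P, I)
    grad_beta = np.einsum("pi,pij->j", dA, X)

    e_theta2 = (post * nodes**2).sum(axis=1)
    grad_logzeta = float((e_theta2 / (2.0 * zeta) - 0.5).sum())

    # d logpmf / dnu = (y - mu) * dt/dnu - lgamma(y+1) + E[lgamma(Y+1)]
    dt_dnu = sol["cov_y_lgam"] / sol["var"]
    dnu_contrib = resid * dt_dnu - lgam_y[:, None, :] + sol["E_lgam"]
    per_item = (post[:, :, None] * dnu_contrib).sum(axis=(0, 1))  # (I,)
    grad_lognu = np.array(
        [nu_vec[c] * per_item[nu_index == c].sum() for c in range(d)]
    )

    grad = np.concatenate([grad_beta, [grad_logzeta], grad_lognu])
    return -float(ll.sum()), -grad


def fit_cmp(
    data: ResponseMatrix,
    explain: str = "items",
    dispersion_kind: str = "global",
    quad_nodes: int = 15,
    max_terms: int = _MAX_TERMS_DEFAULT,
    start_fit: RPCMFit | None = None,
) -> CMPFit:
    """Marginal-ML CMP model with the usual person random intercept.

    ``explain`` chooses the fixed-effect design (``"items"`` or
    ``"radical"``); ``dispersion_kind`` is ``"global"``, ``"per_item"`` or
    ``"per_radical"``.  The four standard variants are (items, global),
    (items, per_item), (radical, global) and (radical, per_radical).
    """
    data.require_fittable()
    if explain not in ("items", "radical"):
        raise ValueError("explain must be 'items' or 'radical'")
    if explain == "radical" and dispersion_kind == "per_item":
        raise ValueError("per-item dispersion requires items as predictors")
    X, names = build_design(data, "items" if explain == "items" else "radical")
    nu_index, nu_names = _nu_structure(data, dispersion_kind)
    d = len(nu_names)

    if start_fit is None:
        start_fit = (fit_rpcm if explain == "items" else fit_rpcm_r)(data, quad_nodes)
    x0 = np.concatenate(
        [start_fit.beta, [np.log(max(start_fit.zeta, 1e-4))], np.zeros(d)]
    )
    p = X.shape[2]
    # nu bounded to [~0.3, ~12] on the natural scale: far outside anything
    # bounded count scores produce, yet inside the series-truncation budget
    bounds = [(None, None)] * p + [(-13.0, 3.0)] + [(-1.2, 2.5)] * d

    warm: dict = {}
    res = optimize.minimize(
        _cmp_nll_and_grad,
        x0,
        args=(data, X, nu_index, d, quad_nodes, max_terms, warm),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 400, "ftol": 1e-11, "gtol": 1e-6},
    )
    beta = res.x[:p]
    zeta = float(np.exp(res.x[p]))
    nu = np.exp(res.x[p + 1 : p + 1 + d])

    grad_fn = lambda q: _cmp_nll_and_grad(
        q, data, X, nu_index, d, quad_nodes, max_terms, warm
    )[1]
    H = _hessian_fd(grad_fn, res.x, h=1e-4)
    try:
        vcov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        vcov = np.full((len(res.x), len(res.x)), np.nan)

    kind = {"items": "cmp", "radical": "cmp_r"}[explain] + {
        "global": "_gd", "per_item": "_sd", "per_radical": "_sd"
    }[dispersion_kind]
    return CMPFit(
        model_kind=kind,
        param_names=list(names),
        beta=beta,
        zeta=zeta,
        loglik=float(-res.fun),
        n_params=p + 1 + d,
        vcov=vcov,
        converged=bool(res.success),
        quad_nodes=quad_nodes,
        n_obs=data.n_obs,
        design=X,
        boundary=bool(res.x[p] <= -13.0 + 1e-6),
        message=str(res.message),
        dispersion_kind=dispersion_kind,
        nu=nu,
        nu_names=nu_names,
        nu_index=nu_index,
    )


def cmp_logpmf_rows(fit: CMPFit, data: ResponseMatrix):
    """Factory for the per-node complete-data loglik under a CMP fit, for
    nu-adjusted empirical-Bayes posterior moments."""
    nu_items = fit.nu_by_item()

    def rows(nodes, A):
        mu = np.exp(nodes[:, :, None] + A[:, None, :])
        lp = cmp_logpmf(
            data.scores[:, None, :], mu, nu_items[None, None, :]
        )
        return lp.sum(axis=2)

    return rows


def information_criteria(fit: RPCMFit):
    """(AIC, BIC) of any converged fit; n_obs = persons x items."""
    if not fit.converged:
        raise ValueError("information criteria require a converged fit")
    return fit.aic(), fit.bic()
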