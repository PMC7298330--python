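"""Model, item and test diagnostics for fitted count IRT models.

Covers the standard battery for Rasch Poisson counts analyses: Pearson
residuals against empirical-Bayes predictions, the dispersion index (1 under
equidispersion, < 1 under underdispersion), covariate-adjusted expected score
frequencies, chi-square item-fit tests over total-score quantile groups,
differential item functioning via group x item interactions, and classical
descriptives (part-whole corrected discrimination, Cronbach's alpha with an
F-distribution confidence interval).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import ResponseMatrix
from .rpcm import (
    RPCMFit,
    build_design,
    eb_person_estimates,
    fit_rpcm,
    fit_with_design,
    hermgauss,
    lrt,
)

__all__ = [
    "ItemFitResult",
    "DIFResult",
    "fitted_means",
    "pearson_residuals",
    "dispersion_index",
    "caf_expected_frequencies",
    "item_fit_chisq",
    "dif_analysis",
    "descriptives",
    "cronbach_alpha",
]


def fitted_means(fit: RPCMFit, data: ResponseMatrix, logpmf_rows=None) -> np.ndarray:
    """Predicted scores ``mu_hat_vi = exp(theta_hat_v + x_vi' beta)`` with the
    empirical-Bayes posterior-mean person estimates plugged in."""
    est = eb_person_estimates(fit, data, logpmf_rows=logpmf_rows)
    theta = np.array([e.theta_log for e in est])
    A = fit.design @ fit.beta
    return np.exp(theta[:, None] + A)


def pearson_residuals(fit: RPCMFit, data: ResponseMatrix, logpmf_rows=None):
    """Pearson residual matrix ``(y - mu_hat) / sqrt(mu_hat)`` plus a
    plot-ready long table with predicted values."""
    mu = fitted_means(fit, data, logpmf_rows=logpmf_rows)
    if np.any(mu <= 0):
        raise FloatingPointError("zero predicted mean; residuals undefined")
    resid = (data.scores - mu) / np.sqrt(mu)
    long = pd.DataFrame(
        {
            "person_id": np.repeat(data.person_ids, data.n_items),
            "item_id": np.tile(data.item_ids, data.n_persons),
            "observed": data.scores.reshape(-1),
            "predicted": mu.reshape(-1),
            "residual": resid.reshape(-1),
        }
    )
    return resid, long


def dispersion_index(
    fit: RPCMFit, data: ResponseMatrix, kind: str = "conditional", logpmf_rows=None
) -> float:
    """Pearson dispersion ``phi = sum(r^2) / (n_obs - n_params)``.

    Values below 1 flag underdispersion (variance smaller than the mean),
    above 1 overdispersion.  ``kind="conditional"`` (the default, and the
    convention of the standard mixed-model software this mirrors) conditions
    on the empirical-Bayes person estimates; because the person effects
    absorb part of the residual variation, this variant sits somewhat below
    1 even for model-exact data.  ``kind="marginal"`` standardises against
    the marginal mixture mean and variance and is calibrated to 1 under the
    model.
    """
    if kind == "conditional":
        resid, _ = pearson_residuals(fit, data, logpmf_rows=logpmf_rows)
        return float((resid**2).sum() / (data.n_obs - fit.n_params))
    if kind == "marginal":
        A = fit.design @ fit.beta
        mu = np.exp(A + fit.zeta / 2.0)
        var = mu + mu**2 * (np.exp(fit.zeta) - 1.0)
        r2 = (data.scores - mu) ** 2 / var
        return float(r2.sum() / (data.n_obs - fit.n_params))
    raise ValueError(f"kind must be 'conditional' or 'marginal', got {kind!r}")


def caf_expected_frequencies(
    fit: RPCMFit, data: ResponseMatrix, score_range=None, quad_nodes: int = 41
) -> pd.DataFrame:
    """Covariate-adjusted frequency table: for each score value the observed
    count across all persons x items and the model-expected count, the person
    effect integrated out over the fitted N(0, zeta) by Gauss-Hermite
    quadrature."""
    if score_range is None:
        score_range = np.arange(0, int(data.scores.max()) + 1)
    score_range = np.asarray(score_range)
    A = fit.design @ fit.beta
    if fit.zeta > 0:
        x, w = hermgauss(quad_nodes)
        theta = np.sqrt(2.0 * fit.zeta) * x
        wn = w / np.sqrt(np.pi)
    else:
        theta = np.zeros(1)
        wn = np.ones(1)
    mu = np.exp(A[:, :, None] + theta[None, None, :])  # (P, I, K)
    expected = np.empty(len(score_range), dtype=float)
    for s_idx, s in enumerate(score_range):
        pmf = stats.poisson.pmf(s, mu)
        expected[s_idx] = float((pmf @ wn).sum())
    observed = np.array([(data.scores == s).sum() for s in score_range], dtype=float)
    return pd.DataFrame({"score": score_range, "observed": observed, "expected": expected})


# --- item fit ----------------------------------------------------------------


@dataclass
class ItemFitResult:
    item_ids: list
    chi2: np.ndarray
    df: int
    p_values: np.ndarray
    group_assignment: np.ndarray  # person -> score group index
    n_groups: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"item_id": self.item_ids, "chi2": self.chi2, "df": self.df,
             "p_value": self.p_values}
        )


def _score_groups(totals: np.ndarray, n_groups: int) -> np.ndarray:
    """Partition persons into total-score quantile groups (0.2, 0.4, ... for
    the default five).  Ties at a boundary go to the lower group; if that
    empties a group, the partition is rebalanced by rank with a warning."""
    P = len(totals)
    qs = np.quantile(totals, np.linspace(0, 1, n_groups + 1)[1:-1], method="lower")
    assign = np.searchsorted(qs, totals, side="left")
    counts = np.bincount(assign, minlength=n_groups)
    if (counts == 0).any():
        warnings.warn("empty total-score group after tie handling; regrouping by rank")
        order = np.argsort(totals, kind="stable")
        assign = np.empty(P, dtype=int)
        assign[order] = (np.arange(P) * n_groups) // P
    return assign


def item_fit_chisq(
    fit: RPCMFit, data: ResponseMatrix, n_groups: int = 5
) -> ItemFitResult:
    """Chi-square item fit over total-score quantile groups.

    Persons are ordered by total score and split into ``n_groups`` quantile
    groups.  Because the total score is sufficient for the person parameter,
    the model-expected score of person ``v`` on item ``i`` given the total is
    ``T_v * pi_vi`` with allocation probabilities
    ``pi_vi = exp(x_vi' beta) / sum_j exp(x_vj' beta)`` (the person effect
    cancels).  Per item, the group sums of observed minus expected scores are
    standardised by the multinomial variance ``T * pi * (1 - pi)`` and the
    squared deviates summed over groups; under the model the statistic is
    approximately chi-square with ``n_groups`` degrees of freedom.
    """
    if n_groups < 2:
        raise ValueError("n_groups must be >= 2")
    if data.n_persons < 2 * n_groups:
        raise ValueError("need at least 2 persons per score group")
    assign = _score_groups(data.total_scores(), n_groups)
    A = fit.design @ fit.beta
    pi = np.exp(A)
    pi /= pi.sum(axis=1, keepdims=True)
    T = data.total_scores().astype(float)
    E = T[:, None] * pi
    V = T[:, None] * pi * (1.0 - pi)
    chi2 = np.zeros(data.n_items)
    for g in range(n_groups):
        rows = assign == g
        O = data.scores[rows].sum(axis=0)
        Eg = E[rows].sum(axis=0)
        Vg = V[rows].sum(axis=0)
        chi2 += (O - Eg) ** 2 / np.where(Vg > 0, Vg, np.nan)
    p = stats.chi2.sf(chi2, n_groups)
    return ItemFitResult(
        item_ids=list(data.item_ids), chi2=chi2, df=n_groups, p_values=p,
        group_assignment=assign, n_groups=n_groups,
    )


# --- differential item functioning -------------------------------------------


@dataclass
class DIFResult:
    interaction_fit: RPCMFit
    additive_fit: RPCMFit
    base_fit: RPCMFit
    coef_table: pd.DataFrame  # per-term Wald tests of the interaction model
    lrt_interactions: tuple  # additive vs interaction model
    lrt_groups: tuple  # base RPCM vs additive model


def _dif_designs(data: ResponseMatrix, group_labels: np.ndarray):
    P, I = data.scores.shape
    groups = np.unique(group_labels)
    if len(groups) < 2:
        raise ValueError("DIF analysis needs at least 2 groups")
    Xi, names = build_design(data, "items")
    cols_add, names_add = [], []
    for g in groups[1:]:
        col = np.zeros((P, I, 1))
        col[group_labels == g, :, 0] = 1.0
        cols_add.append(col)
        names_add.append(f"group{g}")
    X_add = np.concatenate([Xi] + cols_add, axis=2)
    cols_int, names_int = [], []
    for g in groups[1:]:
        for i in range(1, I):  # first item is the interaction reference
            col = np.zeros((P, I, 1))
            col[np.ix_(group_labels == g, [i])] = 1.0
            cols_int.append(col)
            names_int.append(f"group{g}:{data.item_ids[i]}")
    X_int = np.concatenate([X_add] + cols_int, axis=2)
    return (X_add, names + names_add), (X_int, names + names_add + names_int)


def dif_analysis(
    data: ResponseMatrix, group_labels=None, quad_nodes: int = 15,
    base_fit: RPCMFit | None = None,
) -> DIFResult:
    """Differential item functioning across person groups.

    Fits the RPCM extended by group main effects (additive model) and
    additionally by group x item interactions (dummy coding, first group and
    first item as reference).  Non-significant interactions indicate equal
    item difficulty across groups; non-significant main effects in the
    additive model indicate equal mean ability.  Per-coefficient Wald tests
    carry no multiple-testing correction -- with many items and groups some
    significant terms are expected by chance.
    """
    if group_labels is None:
        if data.groups is None:
            raise ValueError("no group labels available")
        group_labels = data.groups
    group_labels = np.asarray(group_labels)
    counts = pd.Series(group_labels).value_counts()
    if (counts < 1).any() or len(counts) < 2:
        raise ValueError("each group must be non-empty and >= 2 groups required")
    (X_add, n_add), (X_int, n_int) = _dif_designs(data, group_labels)
    if base_fit is None:
        base_fit = fit_rpcm(data, quad_nodes)
    fit_add = fit_with_design(data, X_add, n_add, "rpcm_plus_covariates", quad_nodes)
    fit_int = fit_with_design(data, X_int, n_int, "rpcm_plus_covariates", quad_nodes)

    se = fit_int.beta_se()
    z = fit_int.beta / np.where(se > 0, se, np.nan)
    coef_table = pd.DataFrame(
        {
            "term": fit_int.param_names,
            "estimate": fit_int.beta,
            "se": se,
            "z": z,
            "p_value": 2.0 * stats.norm.sf(np.abs(z)),
            "is_interaction": [":" in t for t in fit_int.param_names],
        }
    )
    return DIFResult(
        interaction_fit=fit_int,
        additive_fit=fit_add,
        base_fit=base_fit,
        coef_table=coef_table,
        lrt_interactions=lrt(fit_add, fit_int),
        lrt_groups=lrt(base_fit, fit_add),
    )


# --- classical statistics -----------------------------------------------------


def descriptives(data: ResponseMatrix) -> pd.DataFrame:
    """Per-item median, mean, SD (n-1), min, max and part-whole corrected
    discrimination (item vs total-minus-item correlation)."""
    y = data.scores
    totals = y.sum(axis=1)
    rows = []
    for i, iid in enumerate(data.item_ids):
        col = y[:, i]
        rest = totals - col
        if col.std(ddof=1) == 0 or rest.std(ddof=1) == 0:
            warnings.warn(f"zero variance for item {iid}; discrimination undefined")
            disc = np.nan
        else:
            disc = float(np.corrcoef(col, rest)[0, 1])
        rows.append(
            {
                "item_id": iid,
                "radical_level": int(data.radical_levels[i]),
                "incidental_id": int(data.incidental_ids[i]),
                "median": float(np.median(col)),
                "mean": float(col.mean()),
                "sd": float(col.std(ddof=1)),
                "min": int(col.min()),
                "max": int(col.max()),
                "discrimination": disc,
            }
        )
    return pd.DataFrame(rows)


def cronbach_alpha(data: ResponseMatrix, ci_level: float = 0.95):
    """Cronbach's alpha with the F-distribution confidence interval.

    ``alpha = k/(k-1) * (1 - sum(item variances) / variance of the total)``;
    the CI uses the exact distribution of ``(1 - alpha_hat)/(1 - alpha)`` as
    F with ``(n-1, (n-1)(k-1))`` degrees of freedom.
    """
    y = data.scores
    P, k = y.shape
    if k < 2:
        raise ValueError("Cronbach's alpha needs >= 2 items")
    tot_var = y.sum(axis=1).var(ddof=1)
    if tot_var == 0:
        raise ValueError("zero total-score variance; alpha undefined")
    alpha = k / (k - 1.0) * (1.0 - y.var(axis=0, ddof=1).sum() / tot_var)
    c = 1.0 - ci_level
    df1, df2 = P - 1, (P - 1) * (k - 1)
    lo = 1.0 - (1.0 - alpha) * stats.f.ppf(1.0 - c / 2.0, df1, df2)
    hi = 1.0 - (1.0 - alpha) * stats.f.ppf(c / 2.0, df1, df2)
    return float(alpha), (float(lo), float(hi))
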