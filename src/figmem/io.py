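"""CSV interchange, legacy-dataset conversion and the end-to-end report.

The canonical interchange is a plain CSV with header
``person_id,group,R{r}_I{i},...`` (the ``group`` column is optional); cells
are integer counts in ``0..max_score``.  The converter for the legacy R
serialisation (``.rda``) shells out to ``Rscript`` when available and falls
back to ``pyreadr``; the core package itself has no R dependency.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
import shutil
import subprocess
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cmp import fit_cmp, information_criteria
from .data import ResponseMatrix
from .diagnostics import (
    caf_expected_frequencies,
    cronbach_alpha,
    descriptives,
    dif_analysis,
    dispersion_index,
    item_fit_chisq,
    pearson_residuals,
)
from .rpcm import (
    easiness_table,
    eb_person_estimates,
    fit_person_only,
    fit_rpcm,
    fit_rpcm_r,
    lrt,
)

logger = logging.getLogger("figmem")

__all__ = [
    "read_response_csv",
    "write_response_csv",
    "convert_study_data",
    "run_full_report",
]

_ITEM_COL = re.compile(r"^R(\d+)_I(\d+)$")


class ValidationError(ValueError):
    """Malformed input data (distinct from runtime/model errors)."""


def write_response_csv(data: ResponseMatrix, path) -> Path:
    path = Path(path)
    df = pd.DataFrame(data.scores, columns=data.item_ids)
    df.insert(0, "person_id", data.person_ids)
    if data.groups is not None:
        df.insert(1, "group", data.groups)
    df.to_csv(path, index=False)
    return path


def read_response_csv(path, max_score: int = 20) -> ResponseMatrix:
    """Read and validate a response matrix in the package CSV dialect.

    Item metadata (radical level, incidental id) is parsed from the
    ``R{r}_I{i}`` column names.  Every violation is reported with the row and
    column it occurred in.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str)
    if "person_id" not in df.columns:
        raise ValidationError("malformed header: missing 'person_id' column")
    item_cols = [c for c in df.columns if _ITEM_COL.match(c)]
    if not item_cols:
        raise ValidationError("malformed header: no R{r}_I{i} item columns found")
    extra = set(df.columns) - set(item_cols) - {"person_id", "group"}
    if extra:
        raise ValidationError(f"malformed header: unexpected columns {sorted(extra)}")
    person_ids = df["person_id"].tolist()
    dup = pd.Series(person_ids).duplicated()
    if dup.any():
        raise ValidationError(f"duplicate person_id in row {int(dup.idxmax()) + 2}")

    scores = np.empty((len(df), len(item_cols)), dtype=np.int64)
    for j, col in enumerate(item_cols):
        for k, cell in enumerate(df[col]):
            try:
                val = int(cell)
            except (TypeError, ValueError):
                raise ValidationError(
                    f"non-integer cell at row {k + 2}, column {col!r}: {cell!r}"
                ) from None
            if not 0 <= val <= max_score:
                raise ValidationError(
                    f"score out of range 0..{max_score} at row {k + 2}, column {col!r}: {val}"
                )
            scores[k, j] = val

    groups = None
    if "group" in df.columns:
        try:
            groups = df["group"].astype(int).to_numpy()
        except ValueError:
            groups = df["group"].to_numpy()

    radicals = np.array([int(_ITEM_COL.match(c).group(1)) for c in item_cols])
    incidentals = np.array([int(_ITEM_COL.match(c).group(2)) for c in item_cols])
    return ResponseMatrix(
        scores=scores,
        radical_levels=radicals,
        incidental_ids=incidentals,
        item_ids=item_cols,
        person_ids=person_ids,
        groups=groups,
        max_score=max_score,
    )


# --- legacy .rda conversion -----------------------------------------------------

_R_SCRIPT = r"""
args <- commandArgs(trailingOnly = TRUE)
env <- new.env()
load(args[1], envir = env)
objs <- ls(env)
df <- NULL
for (o in objs) {
  x <- get(o, envir = env)
  if (is.data.frame(x) || is.matrix(x)) { df <- as.data.frame(x); break }
}
if (is.null(df)) stop("no data.frame found in the .rda file")
write.csv(df, args[2], row.names = TRUE)
"""


def _rda_to_frame(path_to_rda: Path) -> pd.DataFrame:
    rscript = shutil.which("Rscript")
    if rscript is not None:
        with tempfile.TemporaryDirectory() as td:
            out = Path(td) / "raw.csv"
            script = Path(td) / "convert.R"
            script.write_text(_R_SCRIPT)
            proc = subprocess.run(
                [rscript, "--vanilla", str(script), str(path_to_rda), str(out)],
                capture_output=True,
                text=True,
            )
            if proc.returncode != 0:
                raise RuntimeError(f"Rscript conversion failed: {proc.stderr.strip()}")
            return pd.read_csv(out, index_col=0)
    try:
        import pyreadr  # optional dependency
    except ImportError:
        raise ImportError(
            "converting .rda requires either Rscript on PATH or the optional "
            "'pyreadr' package (pip install figmem[rda])"
        ) from None
    result = pyreadr.read_r(str(path_to_rda))
    for obj in result.values():
        if isinstance(obj, pd.DataFrame):
            return obj
    raise ValueError("no data.frame found in the .rda file")


def convert_study_data(path_to_rda, out_csv) -> Path:
    """Convert a deposited ``.rda`` response dataset to the package dialect.

    Expects one data.frame whose count columns correspond to the 9 study
    items (3 visual-load families x 3 incidentals, column-major by family);
    extra metadata columns named ``group``/``condition`` are carried over.
    """
    df = _rda_to_frame(Path(path_to_rda))
    lower = {c.lower(): c for c in df.columns}
    group_col = next((lower[k] for k in ("group", "condition", "cond") if k in lower), None)

    named = [c for c in df.columns if _ITEM_COL.match(str(c))]
    if named:
        item_cols = named
        new_names = named
    else:
        numeric = [
            c for c in df.columns
            if c != group_col and pd.api.types.is_numeric_dtype(df[c])
            and df[c].dropna().between(0, 20).all()
            and (df[c].dropna() == df[c].dropna().round()).all()
        ]
        if len(numeric) < 9:
            raise ValueError(
                f"schema error: expected 9 integer item columns in 0..20, found {len(numeric)}"
            )
        item_cols = numeric[:9]
        new_names = [f"R{r}_I{i}" for r in (1, 2, 3) for i in (1, 2, 3)]

    out = pd.DataFrame()
    out["person_id"] = [f"p{k + 1}" for k in range(len(df))]
    if group_col is not None:
        out["group"] = df[group_col].to_numpy()
    for col, name in zip(item_cols, new_names):
        out[name] = df[col].astype(int).to_numpy()
    out_csv = Path(out_csv)
    out.to_csv(out_csv, index=False)
    logger.info("converted %s -> %s (%d persons, %d items)",
                path_to_rda, out_csv, len(out), len(item_cols))
    return out_csv


# --- end-to-end report ------------------------------------------------------------


def _fit_summary(fit) -> dict:
    aic, bic = information_criteria(fit)
    out = {
        "model_kind": fit.model_kind,
        "loglik": fit.loglik,
        "n_params": fit.n_params,
        "aic": aic,
        "bic": bic,
        "person_sd": fit.person_sd,
        "person_sd_ci": list(fit.person_sd_ci()),
        "converged": fit.converged,
        "easiness": easiness_table(fit),
    }
    if hasattr(fit, "nu") and fit.nu is not None:
        out["dispersion_nu"] = {n: float(v) for n, v in zip(fit.nu_names, fit.nu)}
    return out


def run_full_report(
    data_path,
    out_dir,
    seed: int = 0,
    quad_nodes: int = 15,
    with_sd_variants: bool = False,
    make_plots: bool = True,
) -> dict:
    """Fit the whole model battery on a dataset and write a report bundle.

    Fits person-only, RPCM, RPCM-r, CMP-gd and CMP-r-gd (optionally the
    item-/radical-specific-dispersion variants), runs all diagnostics, and
    writes ``report.json``, ``report.txt`` and plot PNGs into ``out_dir``.
    Stage failures are recorded and later stages skipped, never silent.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    data = read_response_csv(data_path)
    cfg_hash = hashlib.sha256(
        json.dumps({"seed": seed, "quad_nodes": quad_nodes}, sort_keys=True).encode()
    ).hexdigest()[:12]
    report: dict = {
        "package_version": __version__,
        "seed": seed,
        "config_hash": cfg_hash,
        "n_persons": data.n_persons,
        "n_items": data.n_items,
        "stages": {},
    }

    def stage(name, fn):
        try:
            report["stages"][name] = {"status": "ok"}
            return fn()
        except Exception as exc:  # noqa: BLE001 - report and continue
            logger.error("stage %s failed: %s", name, exc)
            report["stages"][name] = {"status": "failed", "error": str(exc)}
            return None

    report["descriptives"] = stage(
        "descriptives", lambda: descriptives(data).to_dict(orient="records")
    )
    alpha_res = stage("cronbach_alpha", lambda: cronbach_alpha(data))
    if alpha_res:
        report["cronbach_alpha"] = {"alpha": alpha_res[0], "ci": list(alpha_res[1])}

    fits = {}
    fits["person_only"] = stage("fit_person_only", lambda: fit_person_only(data, quad_nodes))
    fits["rpcm"] = stage("fit_rpcm", lambda: fit_rpcm(data, quad_nodes))
    fits["rpcm_r"] = stage("fit_rpcm_r", lambda: fit_rpcm_r(data, quad_nodes))
    fits["cmp_gd"] = stage(
        "fit_cmp_gd",
        lambda: fit_cmp(data, "items", "global", quad_nodes, start_fit=fits["rpcm"]),
    )
    fits["cmp_r_gd"] = stage(
        "fit_cmp_r_gd",
        lambda: fit_cmp(data, "radical", "global", quad_nodes, start_fit=fits["rpcm_r"]),
    )
    if with_sd_variants:
        fits["cmp_sd"] = stage(
            "fit_cmp_sd",
            lambda: fit_cmp(data, "items", "per_item", quad_nodes, start_fit=fits["rpcm"]),
        )
        fits["cmp_r_sd"] = stage(
            "fit_cmp_r_sd",
            lambda: fit_cmp(data, "radical", "per_radical", quad_nodes,
                            start_fit=fits["rpcm_r"]),
        )
    report["fits"] = {
        k: _fit_summary(f) for k, f in fits.items() if f is not None
    }

    rpcm_fit = fits.get("rpcm")
    if rpcm_fit is not None and fits.get("person_only") is not None:
        chi2, df, p = lrt(fits["person_only"], rpcm_fit)
        report["lrt_person_only_vs_rpcm"] = {"chi2": chi2, "df": df, "p": p}
    if rpcm_fit is not None and fits.get("rpcm_r") is not None:
        chi2, df, p = lrt(fits["rpcm_r"], rpcm_fit)
        report["lrt_rpcm_r_vs_rpcm"] = {"chi2": chi2, "df": df, "p": p}
    for cmp_key, base_key in (("cmp_gd", "rpcm"), ("cmp_r_gd", "rpcm_r"),
                              ("cmp_sd", "cmp_gd"), ("cmp_r_sd", "cmp_r_gd")):
        if fits.get(cmp_key) is not None and fits.get(base_key) is not None:
            chi2, df, p = lrt(fits[base_key], fits[cmp_key])
            report[f"lrt_{base_key}_vs_{cmp_key}"] = {"chi2": chi2, "df": df, "p": p}

    if rpcm_fit is not None:
        report["dispersion_index_rpcm"] = stage(
            "dispersion_rpcm", lambda: dispersion_index(rpcm_fit, data)
        )
        itemfit = stage("item_fit", lambda: item_fit_chisq(rpcm_fit, data))
        if itemfit is not None:
            report["item_fit"] = itemfit.as_frame().to_dict(orient="records")
        est = stage("person_estimates", lambda: eb_person_estimates(rpcm_fit, data))
        if est is not None:
            rels = [e.reliability for e in est]
            report["conditional_reliability"] = {
                "min": float(np.min(rels)),
                "max": float(np.max(rels)),
            }
        caf = stage("caf", lambda: caf_expected_frequencies(rpcm_fit, data))
        if caf is not None:
            report["caf"] = caf.to_dict(orient="list")
        if data.groups is not None:
            dif = stage("dif", lambda: dif_analysis(data, base_fit=rpcm_fit,
                                                    quad_nodes=quad_nodes))
            if dif is not None:
                report["dif"] = {
                    "lrt_interactions": list(dif.lrt_interactions),
                    "lrt_groups": list(dif.lrt_groups),
                    "coef_table": dif.coef_table.to_dict(orient="records"),
                }
    if fits.get("rpcm_r") is not None:
        report["dispersion_index_rpcm_r"] = stage(
            "dispersion_rpcm_r", lambda: dispersion_index(fits["rpcm_r"], data)
        )

    if make_plots and rpcm_fit is not None:
        stage("plots", lambda: _write_plots(out_dir, rpcm_fit, data))

    (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    (out_dir / "report.txt").write_text(_format_text_report(report))
    return report


def _write_plots(out_dir: Path, fit, data) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    resid, long = pearson_residuals(fit, data)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(long["predicted"], long["residual"], s=6, alpha=0.4)
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_xlabel("predicted score")
    ax.set_ylabel("Pearson residual")
    fig.savefig(out_dir / "residuals.png", dpi=100)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(7, 4))
    ax.boxplot([resid[:, i] for i in range(data.n_items)], tick_labels=data.item_ids)
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_ylabel("Pearson residual")
    plt.setp(ax.get_xticklabels(), rotation=45)
    fig.tight_layout()
    fig.savefig(out_dir / "residuals_by_item.png", dpi=100)
    plt.close(fig)

    caf = caf_expected_frequencies(fit, data)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(caf["score"], caf["observed"], "o-", label="observed")
    ax.plot(caf["score"], caf["expected"], "s--", label="expected")
    ax.set_xlabel("item score")
    ax.set_ylabel("frequency")
    ax.legend()
    fig.savefig(out_dir / "caf.png", dpi=100)
    plt.close(fig)

    est = eb_person_estimates(fit, data)
    theta = np.array([e.theta_log for e in est])
    rel = np.array([e.reliability for e in est])
    order = np.argsort(theta)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(theta[order], rel[order], "-")
    ax.set_xlabel("log-ability estimate")
    ax.set_ylabel("conditional reliability")
    fig.savefig(out_dir / "conditional_reliability.png", dpi=100)
    plt.close(fig)


def _format_text_report(report: dict) -> str:
    lines = [f"figmem report (version {report['package_version']}, seed {report['seed']})",
             f"data: {report['n_persons']} persons x {report['n_items']} items", ""]
    if "cronbach_alpha" in report:
        a = report["cronbach_alpha"]
        lines.append(
            f"Cronbach's alpha: {a['alpha']:.3f} "
            f"[{a['ci'][0]:.3f}; {a['ci'][1]:.3f}]"
        )
    for key, fit in report.get("fits", {}).items():
        lines.append("")
        lines.append(f"model {key}: loglik={fit['loglik']:.2f} "
                     f"AIC={fit['aic']:.1f} BIC={fit['bic']:.1f} "
                     f"person_sd={fit['person_sd']:.3f}")
        for row in fit["easiness"]:
            lines.append(
                f"  {row['param']:>14s}: {row['easiness']:6.2f} "
                f"[{row['ci_low']:.2f}; {row['ci_high']:.2f}]"
            )
    for key in sorted(report):
        if key.startswith("lrt_"):
            t = report[key]
            lines.append(f"{key}: chi2({t['df']}) = {t['chi2']:.2f}, p = {t['p']:.4g}")
    for key in ("dispersion_index_rpcm", "dispersion_index_rpcm_r"):
        if report.get(key) is not None:
            lines.append(f"{key}: {report[key]:.3f}")
    if "conditional_reliability" in report:
        r = report["conditional_reliability"]
        lines.append(f"conditional reliability: min {r['min']:.3f}, max {r['max']:.3f}")
    return "\n".join(lines) + "\n"
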