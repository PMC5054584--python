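"""Epigenome-wide association of methylation with gestational age.

Each probe's beta value is regressed on GA with cohort indicator
covariates, pooling all cohorts in one fixed-effects model — a
meta-analysis "by indicator" rather than per-cohort inverse-variance
pooling.  Cell-type proportions can be added as covariates to probe the
robustness of results to cellular heterogeneity; :func:`compare_adjustment`
pairs the t-statistics of the two runs.

No multiple-testing correction is applied by default; the convenience
count ``n_significant`` uses nominal p < 0.05.  Bonferroni / BH-FDR
adjusted columns are available on request.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import BetaMatrix, SampleSheet, ValidationError

__all__ = ["ewas_ga", "n_significant", "compare_adjustment"]


def ewas_ga(
    beta: BetaMatrix,
    sheet: SampleSheet,
    adjust_cells: bool = False,
    proportions: pd.DataFrame | None = None,
    multiple_testing: str | None = None,
) -> pd.DataFrame:
    """Per-probe linear model ``beta_p ~ GA + cohort (+ cells)``.

    Returns a DataFrame indexed by probe with slope (beta per week), SE,
    t, p and a ``degenerate`` flag for probes constant across samples
    (their p is undefined and they are excluded from significance counts).
    Single-cohort input drops the cohort indicators automatically.
    """
    ids = [s for s in beta.sample_ids if s in set(sheet.sample_ids)]
    if len(ids) < 4:
        raise ValidationError("need at least 4 samples with metadata")
    Y = beta.data[ids].to_numpy(float)  # probes x samples
    if not np.isfinite(Y).all():
        raise ValidationError("beta matrix has missing values; impute first")

    ga = sheet.effective_ga().loc[ids].to_numpy(float)
    cols = [np.ones(len(ids)), ga]
    names = ["const", "ga"]

    cohorts = sheet.data["cohort"].reindex(ids)
    levels = [c for c in pd.unique(cohorts.dropna())]
    if len(levels) > 1:
        for lv in levels[1:]:
            cols.append((cohorts == lv).to_numpy(float))
            names.append(f"cohort_{lv}")

    if adjust_cells:
        if proportions is None:
            raise ValidationError("adjust_cells=True requires proportions")
        props = proportions.reindex(ids)
        use = props.columns[:-1] if props.shape[1] > 1 else props.columns
        for c in use:
            cols.append(props[c].to_numpy(float))
            names.append(f"cell_{c}")

    X = np.column_stack(cols)
    n, q = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < q:
        raise ValidationError("collinear EWAS design matrix")
    df = n - q
    if df < 1:
        raise ValidationError("not enough residual degrees of freedom")

    XtX_inv = np.linalg.inv(X.T @ X)
    H = XtX_inv @ X.T                      # q x n
    B = Y @ H.T                            # probes x q
    resid = Y - B @ X.T
    sigma2 = (resid**2).sum(axis=1) / df
    ga_ix = names.index("ga")
    slope = B[:, ga_ix]
    se = np.sqrt(sigma2 * XtX_inv[ga_ix, ga_ix])

    degenerate = Y.std(axis=1) == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = slope / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    slope[degenerate] = 0.0
    t[degenerate] = np.nan
    p[degenerate] = np.nan

    out = pd.DataFrame(
        {"slope": slope, "se": se, "t": t, "p": p, "degenerate": degenerate},
        index=beta.probe_ids,
    )
    out.attrs["n_samples"] = n
    out.attrs["df_resid"] = df
    if multiple_testing == "bonferroni":
        out["p_adj"] = np.minimum(out["p"] * out["p"].notna().sum(), 1.0)
    elif multiple_testing == "fdr":
        out["p_adj"] = _bh_fdr(out["p"].to_numpy())
    elif multiple_testing is not None:
        raise ValidationError("multiple_testing must be None, 'bonferroni' or 'fdr'")
    return out


def _bh_fdr(p: np.ndarray) -> np.ndarray:
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    pv = p[ok]
    m = pv.size
    order = np.argsort(pv)
    ranked = pv[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    vals = np.empty(m)
    vals[order] = np.minimum(ranked, 1.0)
    q[ok] = vals
    return q


def n_significant(results: pd.DataFrame, threshold: float = 0.05) -> int:
    """Count probes with nominal p below ``threshold`` (degenerate probes
    excluded)."""
    return int((results["p"] < threshold).sum())


def compare_adjustment(
    results_unadj: pd.DataFrame, results_adj: pd.DataFrame
) -> tuple[pd.DataFrame, float]:
    """Pair the t-statistics of a cell-adjusted and an unadjusted run.

    Returns the paired table and their Pearson correlation; a correlation
    near 1 means cellular heterogeneity barely moved the results.
    """
    if not results_unadj.index.equals(results_adj.index):
        raise ValidationError("EWAS results cover different probe sets")
    tbl = pd.DataFrame({
        "t_unadjusted": results_unadj["t"],
        "t_adjusted": results_adj["t"],
    })
    ok = tbl.notna().all(axis=1)
    if ok.sum() < 3:
        raise ValidationError("too few probes with defined statistics")
    r = float(np.corrcoef(tbl.loc[ok, "t_unadjusted"], tbl.loc[ok, "t_adjusted"])[0, 1])
    return tbl, r
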