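"""GA acceleration and its association with perinatal outcomes.

GA acceleration is the residual from an ordinary least-squares regression
of DNAm GA on clinical GA over the combined prediction set: positive values
mean the methylation profile looks "older" than the clinical estimate.
Downstream models ask whether that residual carries information about
developmental maturity:

* birthweight (grams): linear regression of birthweight on acceleration,
  adjusting for clinical GA, race, estimated cell-type proportions and
  cohort;
* birthweight percentile: same model *without* clinical GA, because the
  percentile is already conditioned on GA and sex;
* maternal insurance status (Medicaid vs private, a socioeconomic proxy):
  logistic regression of insurance on acceleration adjusting for clinical
  GA, race and cell proportions.

Cell proportions enter as all-but-one components, since the simplex
constraint makes the full set collinear with the intercept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .datamodel import ValidationError

__all__ = [
    "ga_acceleration",
    "build_acceleration_table",
    "AssocResult",
    "assoc_birthweight",
    "assoc_insurance",
]


def ga_acceleration(dnam_ga, clinical_ga) -> np.ndarray:
    """Residuals of ``dnam_ga ~ 1 + clinical_ga`` (OLS, pooled samples)."""
    dnam = np.asarray(dnam_ga, float).ravel()
    clin = np.asarray(clinical_ga, float).ravel()
    if dnam.size != clin.size or dnam.size < 3:
        raise ValidationError("need paired vectors with n >= 3")
    if np.var(clin) == 0:
        raise ValidationError("clinical GA has zero variance")
    X = sm.add_constant(clin)
    return np.asarray(sm.OLS(dnam, X).fit().resid)


def build_acceleration_table(pred_table: pd.DataFrame, sheet,
                             cell_proportions: pd.DataFrame | None = None) -> pd.DataFrame:
    """Join predictions with clinical covariates and compute acceleration.

    ``pred_table`` needs columns ``sample_id`` and ``dnam_ga_weeks``; the
    sheet supplies clinical GA, race, cohort, birthweight, percentile and
    insurance; cell proportions (samples x types) are optional.
    """
    tbl = pred_table.set_index("sample_id").copy()
    meta = sheet.data.reindex(tbl.index)
    tbl["clinical_ga_weeks"] = meta["clinical_ga_weeks"]
    for col in ("race", "cohort", "birthweight", "birthweight_percentile", "insurance"):
        tbl[col] = meta[col]
    tbl["ga_acceleration"] = ga_acceleration(
        tbl["dnam_ga_weeks"], tbl["clinical_ga_weeks"]
    )
    if cell_proportions is not None:
        props = cell_proportions.reindex(tbl.index)
        for c in props.columns:
            tbl[f"cell_{c}"] = props[c]
    return tbl.reset_index()


@dataclass
class AssocResult:
    term: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    model: object = None
    flags: tuple = ()


def _design(table: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Complete-case numeric design with dummy-coded categoricals; drops
    zero-variance and duplicated columns with a warning."""
    sub = table[columns].dropna()
    parts = []
    for col in columns:
        s = sub[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            parts.append(pd.get_dummies(s, prefix=col, drop_first=True, dtype=float))
        else:
            parts.append(s.astype(float))
    X = pd.concat(parts, axis=1)
    drop = [c for c in X.columns if X[c].nunique() <= 1]
    X2 = X.drop(columns=drop)
    # perfectly collinear columns: greedy rank check
    keep = []
    for c in X2.columns:
        cand = X2[keep + [c]].to_numpy()
        if np.linalg.matrix_rank(cand) == len(keep) + 1:
            keep.append(c)
        else:
            drop.append(c)
    if drop:
        warnings.warn(f"dropping collinear/constant covariates: {drop}", RuntimeWarning)
    return X2[keep], sub.index


def _cell_columns(table: pd.DataFrame) -> list[str]:
    cells = [c for c in table.columns if c.startswith("cell_")]
    return cells[:-1] if len(cells) > 1 else cells  # all-but-one on the simplex


def assoc_birthweight(table: pd.DataFrame, outcome: str = "grams") -> AssocResult:
    """Linear model of birthweight (grams) or birthweight percentile on GA
    acceleration plus covariates.  Clinical GA is adjusted for in the grams
    model only; the percentile outcome is already GA-standardized."""
    if outcome == "grams":
        ycol, add_ga = "birthweight", True
    elif outcome == "percentile":
        ycol, add_ga = "birthweight_percentile", False
    else:
        raise ValidationError("outcome must be 'grams' or 'percentile'")

    covs = ["ga_acceleration"]
    if add_ga:
        covs.append("clinical_ga_weeks")
    covs += [c for c in ("race", "cohort") if c in table.columns and table[c].notna().any()]
    covs += _cell_columns(table)

    sub = table[[ycol] + covs].dropna()
    if len(sub) < len(covs) + 2:
        raise ValidationError("too few complete cases for the birthweight model")
    X, idx = _design(sub, covs)
    y = sub.loc[idx, ycol].astype(float)
    res = sm.OLS(y, sm.add_constant(X)).fit()
    ci = res.conf_int().loc["ga_acceleration"]
    return AssocResult(
        term="ga_acceleration",
        estimate=float(res.params["ga_acceleration"]),
        se=float(res.bse["ga_acceleration"]),
        ci_low=float(ci[0]), ci_high=float(ci[1]),
        p=float(res.pvalues["ga_acceleration"]),
        n=int(res.nobs), model=res,
    )


def assoc_insurance(table: pd.DataFrame) -> AssocResult:
    """Logistic regression of Medicaid (vs private) insurance on GA
    acceleration, adjusting for clinical GA, race and cell proportions.

    Complete separation is flagged and the model refitted with a small L2
    penalty so a finite estimate is still reported.
    """
    covs = ["ga_acceleration", "clinical_ga_weeks"]
    covs += [c for c in ("race",) if c in table.columns and table[c].notna().any()]
    covs += _cell_columns(table)

    sub = table[["insurance"] + covs].dropna()
    sub = sub[sub["insurance"].isin(["medicaid", "private"])]
    y = (sub["insurance"] == "medicaid").astype(float)
    if y.nunique() < 2:
        raise ValidationError("degenerate outcome: all insurance labels identical")
    X, idx = _design(sub, covs)
    y = y.loc[idx]
    Xc = sm.add_constant(X)

    flags = ()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            res = sm.Logit(y, Xc).fit(disp=0)
        if not np.isfinite(res.bse["ga_acceleration"]) or res.bse["ga_acceleration"] > 1e4:
            raise np.linalg.LinAlgError("unstable fit")
    except Exception:
        flags = ("separation_fallback",)
        warnings.warn(
            "possible complete separation; refitting with an L2 penalty",
            RuntimeWarning,
        )
        res = sm.GLM(y, Xc, family=sm.families.Binomial()).fit_regularized(
            alpha=1e-3, L1_wt=0.0
        )
        est = float(res.params["ga_acceleration"])
        return AssocResult(term="ga_acceleration", estimate=est, se=np.nan,
                           ci_low=np.nan, ci_high=np.nan, p=np.nan,
                           n=int(len(y)), model=res, flags=flags)

    ci = res.conf_int().loc["ga_acceleration"]
    return AssocResult(
        term="ga_acceleration",
        estimate=float(res.params["ga_acceleration"]),
        se=float(res.bse["ga_acceleration"]),
        ci_low=float(ci[0]), ci_high=float(ci[1]),
        p=float(res.pvalues["ga_acceleration"]),
        n=int(res.nobs), model=res, flags=flags,
    )
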