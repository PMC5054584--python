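"""Elastic-net gestational-age clock: training, prediction, accuracy.

The clock is a penalized linear regression of GA (weeks) on CpG beta
values.  With mixing parameter ``alpha`` and penalty weight ``lam`` the
objective is the glmnet-style

    (1/2n) * ||y - b0 - X b||^2  +  lam * ( alpha * ||b||_1
                                           + (1 - alpha)/2 * ||b||_2^2 )

``alpha = 0.5`` (equal lasso/ridge contribution) is the default.  ``lam``
is chosen by ten-fold cross-validation: the training samples are randomly
partitioned into ten near-equal folds; for each candidate ``lam`` a model
is fitted on nine folds and its mean squared error measured on the held-out
fold; the ``lam`` minimizing the fold-averaged MSE wins.  The fitted model
keeps only the probes with nonzero coefficients.  No covariates other than
the CpGs enter the regression.

The module is organised as a model / results pair: build a
:class:`GestationalAgeClock` from data, call :meth:`fit`, get a
:class:`ClockResults` carrying the coefficients, the CV curve and accuracy
diagnostics.  The flat functions :func:`cv_lambda`, :func:`train_clock`,
:func:`predict_ga` and :func:`accuracy_metrics` are thin wrappers over the
same machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import ElasticNet

from .bmiq import GoldStandard
from .datamodel import BetaMatrix, ClockModel, SampleSheet, ValidationError

__all__ = [
    "TrainingConfig",
    "PredictionResult",
    "GestationalAgeClock",
    "ClockResults",
    "cv_lambda",
    "train_clock",
    "predict_ga",
    "accuracy_metrics",
]


@dataclass
class TrainingConfig:
    alpha: float = 0.5
    n_folds: int = 10
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-4
    standardize: bool = True
    seed: int = 0
    tol: float = 1e-4
    max_iter: int = 10_000

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValidationError("alpha must be in [0, 1]")
        if self.n_folds < 2:
            raise ValidationError("n_folds must be >= 2")


@dataclass
class PredictionResult:
    """Per-sample DNAm GA with accuracy summaries against clinical GA."""

    table: pd.DataFrame  # sample_id, dnam_ga_weeks, clinical_ga_weeks
    r: float | None = None
    median_abs_err: float | None = None
    mean_abs_err: float | None = None
    sd_abs_err: float | None = None


def _fold_assignment(n: int, n_folds: int, seed: int) -> np.ndarray:
    """Seeded random partition into near-equal folds."""
    rng = np.random.default_rng(seed)
    folds = np.arange(n) % n_folds
    return folds[rng.permutation(n)]


def _standardize(X: np.ndarray, flag: bool):
    mean = X.mean(axis=0)
    if flag:
        sd = X.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
    else:
        sd = np.ones(X.shape[1])
    return (X - mean) / sd, mean, sd


def _enet(lam: float, alpha: float, tol: float, max_iter: int) -> ElasticNet:
    # scikit-learn's parametrisation matches glmnet's with
    # alpha_skl = lam, l1_ratio = alpha
    return ElasticNet(alpha=lam, l1_ratio=alpha, tol=tol, max_iter=max_iter,
                      fit_intercept=True)


class GestationalAgeClock:
    """Elastic-net clock model specification: data plus training settings.

    Parameters
    ----------
    X : samples x probes array of beta values, no missing cells.
    y : GA per sample, decimal weeks (for blood spots: effective GA).
    probe_ids, sample_ids : optional axis labels.
    config : :class:`TrainingConfig`.
    """

    def __init__(self, X, y, probe_ids=None, sample_ids=None,
                 config: TrainingConfig | None = None):
        X = np.asarray(X, float)
        y = np.asarray(y, float).ravel()
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValidationError("X must be samples x probes aligned with y")
        if not np.isfinite(X).all():
            raise ValidationError("X contains missing values; impute first")
        if not np.isfinite(y).all():
            raise ValidationError("y contains missing values")
        if np.var(y) == 0:
            raise ValidationError("y has zero variance")
        self.X = X
        self.y = y
        self.probe_ids = (pd.Index(probe_ids) if probe_ids is not None
                          else pd.RangeIndex(X.shape[1]).astype(str))
        self.sample_ids = (pd.Index(sample_ids) if sample_ids is not None
                           else pd.RangeIndex(X.shape[0]).astype(str))
        self.config = config or TrainingConfig()
        if X.shape[0] < self.config.n_folds:
            raise ValidationError("fewer samples than CV folds")

    @classmethod
    def from_beta(cls, beta: BetaMatrix, sheet: SampleSheet,
                  config: TrainingConfig | None = None) -> "GestationalAgeClock":
        """Build the design from a probes x samples matrix and a sample
        sheet; the response is the effective GA (spot delays folded in)."""
        ids = [s for s in beta.sample_ids if s in set(sheet.sample_ids)]
        if not ids:
            raise ValidationError("no overlap between matrix samples and sheet")
        y = sheet.effective_ga().loc[ids]
        X = beta.data[ids].to_numpy().T
        return cls(X, y.to_numpy(), probe_ids=beta.probe_ids,
                   sample_ids=pd.Index(ids), config=config)

    # -- lambda path and cross-validation --------------------------------
    def lambda_path(self) -> np.ndarray:
        cfg = self.config
        Xs, _, _ = _standardize(self.X, cfg.standardize)
        yc = self.y - self.y.mean()
        n = self.y.size
        denom = max(cfg.alpha, 1e-3)  # ridge has no finite all-zero lambda
        lam_max = np.max(np.abs(Xs.T @ yc)) / (n * denom)
        lam_max = max(lam_max, 1e-12)
        return np.geomspace(lam_max, lam_max * cfg.lambda_min_ratio, cfg.n_lambda)

    def cv_lambda(self, lambdas=None) -> tuple[float, pd.DataFrame]:
        """Ten-fold CV curve of mean held-out MSE per lambda.

        Returns the minimizing lambda and the full curve (lambda, cv_mse,
        cv_se).  The fold partition is seeded and identical across
        lambdas.  Within each fold the models are fitted along the
        descending lambda path with warm starts, the standard pathwise
        coordinate-descent strategy.
        """
        cfg = self.config
        lambdas = np.asarray(self.lambda_path() if lambdas is None else lambdas, float)
        order = np.argsort(lambdas)[::-1]  # fit largest penalty first
        folds = _fold_assignment(self.y.size, cfg.n_folds, cfg.seed)

        mse = np.empty((cfg.n_folds, lambdas.size))
        for f in range(cfg.n_folds):
            tr, te = folds != f, folds == f
            Xtr, mean, sd = _standardize(self.X[tr], cfg.standardize)
            Xte = (self.X[te] - mean) / sd
            m = _enet(lambdas[order[0]], cfg.alpha, cfg.tol, cfg.max_iter)
            m.warm_start = True
            for j in order:
                m.alpha = lambdas[j]
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    m.fit(Xtr, self.y[tr])
                resid = self.y[te] - m.predict(Xte)
                mse[f, j] = float(np.mean(resid**2))

        curve = pd.DataFrame({
            "lambda": lambdas,
            "cv_mse": mse.mean(axis=0),
            "cv_se": mse.std(axis=0, ddof=1) / np.sqrt(cfg.n_folds),
        })
        best = int(np.argmin(curve["cv_mse"].to_numpy()))
        return float(lambdas[best]), curve

    # -- fitting ----------------------------------------------------------
    def fit(self, lambda_: float | None = None) -> "ClockResults":
        """Fit the clock; runs CV for lambda unless one is supplied."""
        cfg = self.config
        curve = None
        if lambda_ is None:
            lambda_, curve = self.cv_lambda()
        Xs, mean, sd = _standardize(self.X, cfg.standardize)
        m = _enet(lambda_, cfg.alpha, cfg.tol, cfg.max_iter)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m.fit(Xs, self.y)
        coef_std = m.coef_
        coef = coef_std / sd
        intercept = float(m.intercept_ - np.dot(coef, mean))
        nz = np.nonzero(coef_std != 0.0)[0]
        if cfg.alpha > 0 and nz.size == 0:
            raise ValidationError(
                "elastic net selected zero probes; try a smaller lambda"
            )
        if nz.size == 0:  # ridge keeps everything
            nz = np.arange(coef.size)
        coefficients = pd.Series(coef[nz], index=self.probe_ids[nz], name="coefficient")
        return ClockResults(model=self, lambda_=lambda_, cv_curve=curve,
                            intercept=intercept, coefficients=coefficients)


class ClockResults:
    """Fitted clock: intercept, sparse coefficients, CV diagnostics."""

    def __init__(self, model: GestationalAgeClock, lambda_: float,
                 cv_curve: pd.DataFrame | None, intercept: float,
                 coefficients: pd.Series):
        self.model = model
        self.lambda_ = lambda_
        self.cv_curve = cv_curve
        self.intercept = intercept
        self.coefficients = coefficients

    @property
    def n_selected(self) -> int:
        return int((self.coefficients != 0).sum())

    def to_clock_model(self) -> ClockModel:
        meta = {
            "alpha": self.model.config.alpha,
            "lambda": self.lambda_,
            "n_training_samples": int(self.model.y.size),
            "n_candidate_probes": int(self.model.X.shape[1]),
        }
        return ClockModel(intercept=self.intercept,
                          coefficients=self.coefficients[self.coefficients != 0],
                          metadata=meta)

    def predict(self, beta: BetaMatrix, sheet: SampleSheet | None = None,
                gold: GoldStandard | None = None) -> PredictionResult:
        return predict_ga(beta, self.to_clock_model(), sheet=sheet, gold=gold)

    def fittedvalues(self) -> np.ndarray:
        return self.intercept + self.model.X @ self._dense_coef()

    def _dense_coef(self) -> np.ndarray:
        full = pd.Series(0.0, index=self.model.probe_ids)
        full.loc[self.coefficients.index] = self.coefficients
        return full.to_numpy()

    def training_accuracy(self) -> tuple[float, float, float, float]:
        return accuracy_metrics(self.fittedvalues(), self.model.y)

    def summary(self) -> str:
        r, med, mean, sd = self.training_accuracy()
        lines = [
            "Gestational-age elastic-net clock",
            "=" * 42,
            f"training samples      {self.model.y.size:>10d}",
            f"candidate CpG probes  {self.model.X.shape[1]:>10d}",
            f"alpha (mixing)        {self.model.config.alpha:>10.3f}",
            f"lambda (penalty)      {self.lambda_:>10.5g}",
            f"selected CpG probes   {self.n_selected:>10d}",
            f"training r            {r:>10.4f}",
            f"training median |err| {med:>10.3f} weeks",
            f"training mean |err|   {mean:>10.3f} weeks",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# flat functional surface


def cv_lambda(X, y, config: TrainingConfig | None = None, lambdas=None):
    return GestationalAgeClock(X, y, config=config).cv_lambda(lambdas=lambdas)


def train_clock(X, y, config: TrainingConfig | None = None,
                probe_ids=None) -> ClockModel:
    clock = GestationalAgeClock(X, y, probe_ids=probe_ids, config=config)
    return clock.fit().to_clock_model()


def predict_ga(beta: BetaMatrix, model: ClockModel,
               sheet: SampleSheet | None = None,
               gold: GoldStandard | None = None) -> PredictionResult:
    """Apply a clock to new samples: ``dnam_ga = intercept + sum coef*beta``.

    Model probes absent from the matrix are filled with the gold-standard
    mean for that probe (warning).  If more than 20 % of the model's probes
    are missing the prediction is deemed unreliable and raises.
    """
    probes = model.probe_ids
    present = probes[probes.isin(beta.probe_ids)]
    missing = probes[~probes.isin(beta.probe_ids)]
    if len(missing) > 0.2 * len(probes):
        raise ValidationError(
            f"{len(missing)}/{len(probes)} clock probes missing from the data; "
            "prediction would be unreliable"
        )
    sub = pd.DataFrame(index=probes, columns=beta.sample_ids, dtype=float)
    sub.loc[present] = beta.data.loc[present]
    if len(missing):
        if gold is None:
            raise ValidationError(
                f"clock probes {missing.tolist()[:5]} missing and no gold "
                "standard supplied for mean substitution"
            )
        fill = gold.values.reindex(missing)
        if fill.isna().any():
            raise ValidationError("gold standard lacks some missing clock probes")
        warnings.warn(
            f"{len(missing)} clock probe(s) absent; substituted gold-standard "
            f"means: {missing.tolist()[:5]}",
            RuntimeWarning,
        )
        for p in missing:
            sub.loc[p] = fill.loc[p]
    if sub.isna().to_numpy().any():
        raise ValidationError("missing beta values among clock probes; impute first")

    dnam = model.intercept + model.coefficients.reindex(probes) @ sub
    table = pd.DataFrame({"sample_id": beta.sample_ids,
                          "dnam_ga_weeks": dnam.to_numpy(float)})
    result = PredictionResult(table=table)
    if sheet is not None:
        clin = sheet.data["clinical_ga_weeks"].reindex(beta.sample_ids)
        eff = sheet.effective_ga().reindex(beta.sample_ids)
        table["clinical_ga_weeks"] = clin.to_numpy(float)
        # accuracy is judged against the sample's effective GA (clinical GA
        # plus any blood-spot sampling delay)
        table["effective_ga_weeks"] = eff.to_numpy(float)
        ok = table["effective_ga_weeks"].notna()
        if ok.sum() >= 3:
            r, med, mn, sd = accuracy_metrics(
                table.loc[ok, "dnam_ga_weeks"], table.loc[ok, "effective_ga_weeks"]
            )
            result.r, result.median_abs_err = r, med
            result.mean_abs_err, result.sd_abs_err = mn, sd
    return result


def accuracy_metrics(pred, clinical) -> tuple[float, float, float, float]:
    """Pearson r plus median / mean / SD of the absolute error in weeks."""
    pred = np.asarray(pred, float).ravel()
    clinical = np.asarray(clinical, float).ravel()
    if pred.size != clinical.size:
        raise ValidationError("paired vectors required")
    if pred.size < 3:
        raise ValidationError("need at least 3 pairs")
    if np.std(pred) == 0 or np.std(clinical) == 0:
        r = float("nan")  # correlation undefined for a constant vector
    else:
        r = float(stats.pearsonr(pred, clinical)[0])
    err = np.abs(pred - clinical)
    return r, float(np.median(err)), float(np.mean(err)), float(np.std(err, ddof=1))
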