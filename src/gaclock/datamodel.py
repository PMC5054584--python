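"""Core data containers for neonatal methylation analysis.

Beta values are methylation fractions ``M / (M + U)`` in ``[0, 1]`` measured
at CpG probes.  All matrices in this package are probes x samples, carried as
pandas DataFrames with an explicit NaN missing state.  Cross-matrix
operations align by probe/sample *identifier*, never by position.

Gestational age (GA) is expressed in decimal weeks everywhere internally;
blood-spot sampling delays in days are converted at ingest only
(:func:`effective_ga`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "BetaMatrix",
    "DetectionPMatrix",
    "SampleSheet",
    "ProbeAnnotation",
    "ClockModel",
    "effective_ga",
]

#: plausibility window for clinical gestational age, in weeks
GA_WINDOW = (20.0, 46.0)

TISSUES = frozenset({"cord", "spot"})
INSURANCE_LEVELS = frozenset({"medicaid", "private", "unknown"})


class ValidationError(ValueError):
    """Raised when a container's invariants are violated."""


def _check_unique(labels: pd.Index, what: str) -> None:
    if labels.has_duplicates:
        dups = labels[labels.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dups[:5]}")


class _ProbeSampleMatrix:
    """Shared validation for probes x samples matrices with values in [0, 1]."""

    _value_name = "value"

    def __init__(self, data: pd.DataFrame):
        if not isinstance(data, pd.DataFrame):
            data = pd.DataFrame(data)
        data = data.astype(float)
        _check_unique(data.index, "probe id")
        _check_unique(data.columns, "sample id")
        vals = data.to_numpy()
        bad = (vals < 0) | (vals > 1)
        bad &= np.isfinite(vals)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"{self._value_name} {vals[i, j]!r} outside [0, 1] at "
                f"probe {data.index[i]!r}, sample {data.columns[j]!r}"
            )
        self.data = data

    # -- axis accessors -------------------------------------------------
    @property
    def probe_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def missing_mask(self) -> np.ndarray:
        return ~np.isfinite(self.data.to_numpy())

    def missing_fraction(self, axis: str) -> pd.Series:
        """Fraction of missing cells per probe (axis='probe') or sample."""
        isna = self.data.isna()
        if axis == "probe":
            return isna.mean(axis=1)
        if axis == "sample":
            return isna.mean(axis=0)
        raise ValueError("axis must be 'probe' or 'sample'")

    def align_check(self, other: "_ProbeSampleMatrix") -> None:
        """Require identical probe and sample axes (same ids, same order)."""
        if not self.probe_ids.equals(other.probe_ids):
            raise ValidationError("probe axes differ between matrices")
        if not self.sample_ids.equals(other.sample_ids):
            raise ValidationError("sample axes differ between matrices")

    def copy(self):
        return type(self)(self.data.copy())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        p, s = self.shape
        return f"<{type(self).__name__} {p} probes x {s} samples>"


class BetaMatrix(_ProbeSampleMatrix):
    """Probes x samples methylation fractions with a NaN missing state."""

    _value_name = "beta value"


class DetectionPMatrix(_ProbeSampleMatrix):
    """Detection p-values on the same axes as a companion :class:`BetaMatrix`.

    A high detection p-value marks a measurement indistinguishable from
    background noise on the array.
    """

    _value_name = "detection p-value"


SAMPLE_SHEET_COLUMNS = [
    "sample_id",
    "clinical_ga_weeks",
    "tissue",
    "days_to_sampling",
    "sex",
    "cohort",
    "birthweight",
    "birthweight_percentile",
    "race",
    "insurance",
]


class SampleSheet:
    """Per-sample clinical metadata.

    Required columns: ``sample_id``, ``clinical_ga_weeks`` (decimal weeks),
    ``tissue`` ('cord' umbilical cord blood, or 'spot' dried neonatal blood
    spot).  Blood spots may be collected days after birth, so spot rows must
    carry ``days_to_sampling`` (integer days >= 0); the methylation clock
    ticks through that interval, hence :func:`effective_ga`.  Optional
    columns: sex, cohort, birthweight (g), birthweight_percentile (0-100),
    race, insurance ('medicaid'/'private'/'unknown').
    """

    def __init__(self, data: pd.DataFrame):
        data = data.copy()
        for col in ("sample_id", "clinical_ga_weeks", "tissue"):
            if col not in data.columns:
                raise ValidationError(f"sample sheet missing column {col!r}")
        for col in SAMPLE_SHEET_COLUMNS:
            if col not in data.columns:
                data[col] = np.nan
        _check_unique(pd.Index(data["sample_id"]), "sample id")

        ga = pd.to_numeric(data["clinical_ga_weeks"])
        lo, hi = GA_WINDOW
        bad = ga[(ga < lo) | (ga > hi)]
        if len(bad):
            raise ValidationError(
                f"clinical_ga_weeks outside [{lo}, {hi}] for samples "
                f"{data.loc[bad.index, 'sample_id'].tolist()[:5]}"
            )
        unknown = set(data["tissue"]) - TISSUES
        if unknown:
            raise ValidationError(f"unknown tissue labels: {sorted(unknown)}")

        spot = data["tissue"] == "spot"
        days = pd.to_numeric(data["days_to_sampling"])
        if days[spot].isna().any():
            missing = data.loc[spot & days.isna(), "sample_id"].tolist()
            raise ValidationError(
                f"spot samples lack days_to_sampling: {missing[:5]}"
            )
        if days[~spot].notna().any():
            extra = data.loc[~spot & days.notna(), "sample_id"].tolist()
            raise ValidationError(
                f"days_to_sampling given for non-spot samples: {extra[:5]}"
            )
        if (days[spot] < 0).any():
            raise ValidationError("days_to_sampling must be >= 0")

        data["clinical_ga_weeks"] = ga
        data["days_to_sampling"] = days
        self.data = data.set_index("sample_id", drop=False)

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    def __len__(self) -> int:
        return len(self.data)

    def subset(self, sample_ids: Iterable[str]) -> "SampleSheet":
        ids = list(sample_ids)
        missing = set(ids) - set(self.sample_ids)
        if missing:
            raise ValidationError(f"unknown sample ids: {sorted(missing)[:5]}")
        return SampleSheet(self.data.loc[ids].reset_index(drop=True))

    def effective_ga(self) -> pd.Series:
        """Effective GA per sample (weeks); see :func:`effective_ga`."""
        days = self.data["days_to_sampling"].fillna(0.0)
        out = self.data["clinical_ga_weeks"] + days / 7.0
        out.name = "effective_ga_weeks"
        return out


def effective_ga(row: Mapping) -> float:
    """Gestational age of the *sample* in decimal weeks.

    Cord-blood samples are drawn at birth, so the sample's GA equals the
    clinical GA at birth.  Blood spots are collected up to weeks later, so
    the GA of the methylation profile is the clinical GA plus the sampling
    delay: ``clinical_ga_weeks + days_to_sampling / 7``.
    """
    tissue = row["tissue"]
    ga = float(row["clinical_ga_weeks"])
    if tissue == "cord":
        return ga
    if tissue == "spot":
        days = row.get("days_to_sampling") if hasattr(row, "get") else row["days_to_sampling"]
        if days is None or (isinstance(days, float) and np.isnan(days)):
            raise ValidationError("spot sample lacks days_to_sampling")
        return ga + float(days) / 7.0
    raise ValidationError(f"unknown tissue {tissue!r}")


class ProbeAnnotation:
    """Genomic annotation per probe: chromosome, 1-based CpG position and a
    flag for a known genetic variant within the 50-bp probe sequence."""

    def __init__(self, data: pd.DataFrame):
        data = data.copy()
        for col in ("probe_id", "chromosome", "position"):
            if col not in data.columns:
                raise ValidationError(f"probe annotation missing column {col!r}")
        if "snp_in_probe" not in data.columns:
            data["snp_in_probe"] = False
        _check_unique(pd.Index(data["probe_id"]), "probe id")
        data["position"] = pd.to_numeric(data["position"]).astype(int)
        if (data["position"] < 1).any():
            raise ValidationError("positions must be >= 1 (1-based coordinates)")
        data["snp_in_probe"] = data["snp_in_probe"].astype(bool)
        self.data = data.set_index("probe_id", drop=False)

    @property
    def probe_ids(self) -> pd.Index:
        return self.data.index

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class ClockModel:
    """A trained GA predictor: intercept (weeks) plus a sparse map of CpG
    probe -> coefficient (weeks per unit beta).

    Prediction is the linear form ``intercept + sum_p coef_p * beta_p``.
    """

    intercept: float
    coefficients: "pd.Series"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        coef = pd.Series(self.coefficients, dtype=float)
        if coef.empty:
            raise ValidationError("clock model has no coefficients")
        _check_unique(coef.index, "clock probe id")
        if not np.isfinite(self.intercept):
            raise ValidationError("intercept must be finite")
        if not np.isfinite(coef.to_numpy()).all():
            raise ValidationError("coefficients must be finite")
        self.intercept = float(self.intercept)
        self.coefficients = coef

    @property
    def probe_ids(self) -> pd.Index:
        return self.coefficients.index

    def __len__(self) -> int:
        return len(self.coefficients)
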