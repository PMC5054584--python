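"""Readers and writers for the package's delimited-text formats.

Formats
-------
* Beta / detection-p matrices: TSV or CSV, probe ids in the first column,
  sample ids in the header.  Missing cells are empty fields (canonical) or
  one of the configured sentinels ("NA", "NaN").
* Clock model: CSV with columns ``term, coefficient`` and exactly one row
  with ``term = "(Intercept)"``.
* Sample sheet: CSV with the named clinical columns.
* Probe annotation: TSV with ``probe_id, chromosome, position, snp_in_probe``.
* Genomic features: BED (0-based, half-open).
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    BetaMatrix,
    ClockModel,
    DetectionPMatrix,
    ProbeAnnotation,
    SampleSheet,
    ValidationError,
)

__all__ = [
    "read_beta_matrix",
    "write_beta_matrix",
    "read_detection_p",
    "write_detection_p",
    "read_clock_model",
    "write_clock_model",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_probe_annotation",
    "write_probe_annotation",
    "read_bed",
    "write_bed",
]

#: sentinels accepted as missing in matrix files, besides the empty field
NA_SENTINELS = ("", "NA", "NaN", "nan")

INTERCEPT_TERM = "(Intercept)"


def _sep_for(path: str, dialect: str | None) -> str:
    if dialect == "csv":
        return ","
    if dialect == "tsv":
        return "\t"
    if dialect is not None:
        raise ValueError(f"unknown dialect {dialect!r}")
    return "," if os.fspath(path).endswith(".csv") else "\t"


def _read_matrix_frame(path, dialect, na_values) -> pd.DataFrame:
    sep = _sep_for(path, dialect)
    df = pd.read_csv(
        path,
        sep=sep,
        index_col=0,
        keep_default_na=False,
        na_values=list(na_values),
        dtype=str,
    )
    if df.index.name is None and df.index.isna().any():
        raise ValidationError(f"{path}: malformed header or probe column")
    try:
        return df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"{path}: non-numeric matrix cell ({exc})") from exc


def read_beta_matrix(path, dialect: str | None = None,
                     na_values: Sequence[str] = NA_SENTINELS) -> BetaMatrix:
    """Read a probes x samples beta matrix from delimited text.

    Out-of-range values raise a :class:`ValidationError` naming the
    offending probe and sample.
    """
    return BetaMatrix(_read_matrix_frame(path, dialect, na_values))


def read_detection_p(path, dialect: str | None = None,
                     na_values: Sequence[str] = NA_SENTINELS) -> DetectionPMatrix:
    return DetectionPMatrix(_read_matrix_frame(path, dialect, na_values))


def _write_matrix(mat, path, dialect) -> None:
    sep = _sep_for(path, dialect)
    mat.data.to_csv(path, sep=sep, na_rep="", index_label="probe_id")


def write_beta_matrix(beta: BetaMatrix, path, dialect: str | None = None) -> None:
    _write_matrix(beta, path, dialect)


def write_detection_p(detp: DetectionPMatrix, path, dialect: str | None = None) -> None:
    _write_matrix(detp, path, dialect)


def read_clock_model(path) -> ClockModel:
    """Read a clock coefficient file: CSV (term, coefficient), one
    ``(Intercept)`` row, remaining rows are probe coefficients."""
    df = pd.read_csv(path, dtype={"term": str}, float_precision="round_trip")
    if list(df.columns[:2]) != ["term", "coefficient"]:
        raise ValidationError(
            f"{path}: expected columns (term, coefficient), got {list(df.columns)}"
        )
    is_int = df["term"] == INTERCEPT_TERM
    if is_int.sum() != 1:
        raise ValidationError(
            f"{path}: expected exactly one {INTERCEPT_TERM!r} row, found {int(is_int.sum())}"
        )
    intercept = float(df.loc[is_int, "coefficient"].iloc[0])
    coef = df.loc[~is_int]
    if coef["term"].duplicated().any():
        dups = coef.loc[coef["term"].duplicated(), "term"].tolist()
        raise ValidationError(f"{path}: duplicate probe terms {dups[:5]}")
    series = pd.Series(coef["coefficient"].to_numpy(float),
                       index=pd.Index(coef["term"], name="probe_id"))
    return ClockModel(intercept=intercept, coefficients=series)


def write_clock_model(model: ClockModel, path) -> None:
    rows = [{"term": INTERCEPT_TERM, "coefficient": repr(model.intercept)}]
    rows += [
        {"term": p, "coefficient": repr(float(c))}
        for p, c in model.coefficients.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_sample_sheet(path) -> SampleSheet:
    df = pd.read_csv(path, keep_default_na=False,
                     na_values=list(NA_SENTINELS), dtype={"sample_id": str})
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.data.to_csv(path, index=False, na_rep="")


def read_probe_annotation(path) -> ProbeAnnotation:
    df = pd.read_csv(path, sep="\t", keep_default_na=False,
                     na_values=list(NA_SENTINELS),
                     dtype={"probe_id": str, "chromosome": str})
    if "snp_in_probe" in df.columns:
        df["snp_in_probe"] = (
            df["snp_in_probe"].astype(str).str.lower().isin(("1", "true", "t", "yes"))
        )
    return ProbeAnnotation(df)


def write_probe_annotation(ann: ProbeAnnotation, path) -> None:
    out = ann.data.copy()
    out["snp_in_probe"] = out["snp_in_probe"].astype(int)
    out.to_csv(path, sep="\t", index=False)


def read_bed(path) -> list[tuple[str, int, int, str]]:
    """Read a BED file as ``(chrom, start, end, name)`` tuples.

    BED is 0-based, half-open.  A missing name column yields ``""``.
    """
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(f"{path}:{ln}: BED line with <3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValidationError(f"{path}:{ln}: start >= end")
            name = parts[3] if len(parts) > 3 else ""
            out.append((chrom, start, end, name))
    return out


def write_bed(intervals: Iterable[tuple], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            chrom, start, end = iv[0], iv[1], iv[2]
            name = iv[3] if len(iv) > 3 else ""
            fields = [chrom, str(int(start)), str(int(end))]
            if name:
                fields.append(str(name))
            fh.write("\t".join(fields) + "\n")
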