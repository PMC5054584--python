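"""Reference-based cell-composition estimation (constrained projection).

Cord blood is a mixture of white-blood-cell subtypes and nucleated red
blood cells, each with a characteristic methylation profile.  Given mean
beta profiles of purified cell populations at a set of cell-discriminating
probes, a sample's cell proportions ``w`` are estimated by constrained
least squares

    minimize ||y - R w||^2   subject to  w >= 0,  sum(w) <= 1,

the classic reference-based (Houseman-style) projection.  The inequality
(rather than equality) sum constraint leaves room for cell types absent
from the reference panel.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import optimize

from .datamodel import BetaMatrix, ValidationError

__all__ = ["ReferenceProfiles", "select_discriminating_probes", "estimate_proportions"]


class ReferenceProfiles:
    """Probes x cell-types matrix of mean beta per purified population,
    restricted to discriminating probes."""

    def __init__(self, data: pd.DataFrame):
        if data.shape[1] < 2:
            raise ValidationError("need at least two cell types")
        vals = data.to_numpy(float)
        if ((vals < 0) | (vals > 1)).any():
            raise ValidationError("reference betas must lie in [0, 1]")
        self.data = data.astype(float)

    @property
    def probe_ids(self) -> pd.Index:
        return self.data.index

    @property
    def cell_types(self) -> pd.Index:
        return self.data.columns


def select_discriminating_probes(
    reference_raw: dict[str, pd.DataFrame] | pd.DataFrame,
    n_per_type: int = 50,
) -> ReferenceProfiles:
    """Pick cell-discriminating probes from per-type replicate matrices.

    For each cell type, probes are ranked by the difference between that
    type's mean beta and the mean of all other types; the top ``n_per_type``
    hyper- and top ``n_per_type`` hypo-methylated probes are taken, and the
    union over types defines the reference probe set.

    ``reference_raw`` is either a mapping cell type -> probes x replicates
    matrix, or a ready probes x cell-types matrix of means.
    """
    if isinstance(reference_raw, dict):
        means = pd.DataFrame({t: df.mean(axis=1) for t, df in reference_raw.items()})
    else:
        means = reference_raw.astype(float)
    if means.shape[1] < 2:
        raise ValidationError("need at least two cell types")

    selected: set = set()
    any_signal = False
    for t in means.columns:
        others = means.drop(columns=t).mean(axis=1)
        diff = means[t] - others
        if (diff.abs() > 1e-12).any():
            any_signal = True
        up = diff[diff > 0].sort_values(ascending=False)
        down = diff[diff < 0].sort_values()
        if len(up) < n_per_type or len(down) < n_per_type:
            warnings.warn(
                f"cell type {t!r}: fewer than {n_per_type} probes in one "
                "direction; taking all available",
                RuntimeWarning,
            )
        selected.update(up.index[:n_per_type])
        selected.update(down.index[:n_per_type])
    if not any_signal:
        warnings.warn("cell types are indistinguishable; selection is degenerate",
                      RuntimeWarning)
    order = [p for p in means.index if p in selected]
    return ReferenceProfiles(means.loc[order])


def _project(y: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Solve min ||y - R w||^2 s.t. w >= 0, sum(w) <= 1 (SLSQP, tight tol)."""
    k = R.shape[1]
    w0 = np.full(k, 1.0 / (k + 1))

    def obj(w):
        r = R @ w - y
        return 0.5 * float(r @ r)

    def grad(w):
        return R.T @ (R @ w - y)

    res = optimize.minimize(
        obj, w0, jac=grad, method="SLSQP",
        bounds=[(0.0, 1.0)] * k,
        constraints=[{"type": "ineq", "fun": lambda w: 1.0 - w.sum(),
                      "jac": lambda w: -np.ones(k)}],
        options={"maxiter": 500, "ftol": 1e-14},
    )
    w = np.clip(res.x, 0.0, None)
    if w.sum() > 1.0:
        w = w / w.sum()
    return w


def estimate_proportions(
    sample_beta: BetaMatrix | pd.DataFrame | pd.Series,
    profiles: ReferenceProfiles,
) -> pd.DataFrame:
    """Estimate cell proportions per sample.

    Samples must cover at least 50 % of the reference probes; probes missing
    from a sample are dropped from its projection.
    """
    if isinstance(sample_beta, BetaMatrix):
        data = sample_beta.data
    elif isinstance(sample_beta, pd.Series):
        data = sample_beta.to_frame()
    else:
        data = sample_beta
    probes = profiles.probe_ids
    present = probes[probes.isin(data.index)]
    if len(present) < 0.5 * len(probes):
        raise ValidationError(
            f"only {len(present)}/{len(probes)} reference probes present in data"
        )
    R_full = profiles.data.loc[present].to_numpy()
    Y = data.loc[present].to_numpy(float)

    out = np.empty((data.shape[1], len(profiles.cell_types)))
    for j in range(Y.shape[1]):
        y = Y[:, j]
        ok = np.isfinite(y)
        if ok.sum() < 0.5 * len(probes):
            raise ValidationError(
                f"sample {data.columns[j]!r} observes too few reference probes"
            )
        out[j] = _project(y[ok], R_full[ok])
    return pd.DataFrame(out, index=data.columns, columns=profiles.cell_types)
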