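"""k-nearest-neighbour imputation of missing beta values (default k = 10).

Neighbours are *probes* (rows): a missing value at (probe p, sample s) is
filled from the k probes most similar to p — Euclidean distance over the
samples where both probes are observed, rescaled by the fraction of jointly
observed samples — restricted to probes observed at s, weighted by inverse
distance.  The search is fully deterministic: distance ties break on
lexicographic probe id.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datamodel import BetaMatrix, ValidationError

__all__ = ["knn_impute"]

_DIST_EPS = 1e-6


def _pairwise_distances(values: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """Distances from each row in ``rows`` to every probe.

    d(i, j) = sqrt( sum_{joint} (v_i - v_j)^2 / (n_joint / n_samples) );
    probe pairs with no jointly observed sample get +inf.
    """
    obs = np.isfinite(values)
    filled = np.where(obs, values, 0.0)
    n = values.shape[1]

    A, Ao = filled[rows], obs[rows].astype(float)
    B, Bo = filled, obs.astype(float)
    sq = (A**2) @ Bo.T + Ao @ (B**2).T - 2.0 * (A @ B.T)
    n_joint = Ao @ Bo.T
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.sqrt(np.maximum(sq, 0.0) * n / n_joint)
    d[n_joint == 0] = np.inf
    return d


def knn_impute(beta: BetaMatrix, k: int = 10) -> BetaMatrix:
    """Fill every missing cell; observed cells are untouched.

    A probe with no usable neighbour at a sample falls back to its own
    observed mean (with a warning); a fully missing probe is a validation
    error — it should have been removed by QC.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    if beta.shape[0] < k + 1:
        raise ValidationError(f"need at least k+1 = {k + 1} probes")

    values = beta.values.copy()
    obs = np.isfinite(values)
    if obs.all():
        return beta.copy()
    if (~obs).all(axis=1).any():
        bad = beta.probe_ids[(~obs).all(axis=1)].tolist()
        raise ValidationError(f"probes with no observed values: {bad[:5]}")

    probe_order = np.argsort(beta.probe_ids.to_numpy().astype(str))
    lex_rank = np.empty(len(probe_order), dtype=int)
    lex_rank[probe_order] = np.arange(len(probe_order))

    need = np.nonzero(~obs.all(axis=1))[0]
    dists = _pairwise_distances(values, need)
    probe_means = np.nanmean(values, axis=1)
    fallback_probes = []

    out = values
    for row_i, p in enumerate(need):
        d_p = dists[row_i]
        missing_at = np.nonzero(~obs[p])[0]
        for s in missing_at:
            cand = np.nonzero(obs[:, s] & np.isfinite(d_p))[0]
            cand = cand[cand != p]
            if cand.size == 0:
                out[p, s] = probe_means[p]
                fallback_probes.append(beta.probe_ids[p])
                continue
            # sort by (distance, lexicographic probe id); stable and exact
            order = np.lexsort((lex_rank[cand], d_p[cand]))
            nn = cand[order[:k]]
            w = 1.0 / (d_p[nn] + _DIST_EPS)
            out[p, s] = float(np.dot(w, values[nn, s]) / w.sum())

    if fallback_probes:
        warnings.warn(
            f"{len(fallback_probes)} value(s) imputed by probe mean "
            f"(no complete neighbour), e.g. {fallback_probes[:3]}",
            RuntimeWarning,
        )
    # weighted means of values at the ends of [0, 1] can overshoot by a
    # few ulp; clamp the float noise
    out = np.clip(out, 0.0, 1.0)
    return BetaMatrix(pd.DataFrame(out, index=beta.probe_ids, columns=beta.sample_ids))
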