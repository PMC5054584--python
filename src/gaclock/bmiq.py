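"""Gold-standard beta-mixture quantile (BMIQ) calibration.

The original BMIQ is a within-array normalization that reshapes type II
probe distributions to match type I.  The variant implemented here serves a
different purpose, between-sample calibration: a reference ("gold
standard") beta distribution is defined as the probe-wise mean over all
training samples, a 3-state beta mixture (Unmethylated / Hemimethylated /
Methylated) is fitted to the reference and to each sample, and each
sample's values are transported onto the reference distribution state by
state — U and M by beta-CDF quantile matching, H by the piecewise-linear
dilation that keeps the state boundaries continuous.

Within-state rank order is preserved exactly and output stays in [0, 1].
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .datamodel import BetaMatrix, ValidationError

__all__ = [
    "BetaMixtureFit",
    "GoldStandard",
    "fit_beta_mixture",
    "build_gold_standard",
    "bmiq_calibrate",
    "calibrate_matrix",
]

_EPS = 1e-6
STATES = ("U", "H", "M")


@dataclass
class BetaMixtureFit:
    """A fitted 3-component beta mixture, components ordered by mean
    (U < H < M)."""

    weights: np.ndarray        # (3,), sum to 1
    a: np.ndarray              # (3,) beta shape alpha, > 0
    b: np.ndarray              # (3,) beta shape beta, > 0
    thresholds: tuple[float, float]  # U/H and H/M posterior crossing points
    log_likelihood: float
    loglik_path: np.ndarray
    n_iter: int
    converged: bool

    @property
    def means(self) -> np.ndarray:
        return self.a / (self.a + self.b)

    def log_pdf(self, x: np.ndarray) -> np.ndarray:
        """n x 3 matrix of weighted component log densities."""
        x = np.clip(np.asarray(x, float), _EPS, 1.0 - _EPS)
        out = np.empty((x.size, 3))
        for k in range(3):
            out[:, k] = np.log(self.weights[k] + 1e-300) + stats.beta.logpdf(
                x.ravel(), self.a[k], self.b[k]
            )
        return out

    def posterior(self, x: np.ndarray) -> np.ndarray:
        lp = self.log_pdf(x)
        lp -= special.logsumexp(lp, axis=1, keepdims=True)
        return np.exp(lp)

    def assign_states(self, x: np.ndarray) -> np.ndarray:
        """Maximum-posterior state per value; ties resolve to the
        lower-mean state (argmax takes the first maximum)."""
        return np.argmax(self.posterior(x), axis=1)

    def to_dict(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "a": self.a.tolist(),
            "b": self.b.tolist(),
            "thresholds": list(self.thresholds),
            "log_likelihood": float(self.log_likelihood),
            "n_iter": int(self.n_iter),
            "converged": bool(self.converged),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BetaMixtureFit":
        return cls(
            weights=np.asarray(d["weights"], float),
            a=np.asarray(d["a"], float),
            b=np.asarray(d["b"], float),
            thresholds=tuple(d["thresholds"]),
            log_likelihood=float(d["log_likelihood"]),
            loglik_path=np.array([]),
            n_iter=int(d["n_iter"]),
            converged=bool(d["converged"]),
        )


def _moment_shapes(x: np.ndarray, fallback_mean: float) -> tuple[float, float]:
    """Method-of-moments beta shapes, with a mildly concentrated fallback
    when the group is empty or degenerate."""
    if x.size < 5:
        m = fallback_mean
        conc = 10.0
        return m * conc, (1 - m) * conc
    m = float(np.mean(x))
    v = float(np.var(x))
    m = min(max(m, _EPS), 1 - _EPS)
    vmax = m * (1 - m)
    if v <= 0 or v >= vmax:
        v = 0.25 * vmax
    conc = vmax / v - 1.0
    conc = max(conc, 0.05)
    return max(m * conc, 1e-3), max((1 - m) * conc, 1e-3)


def _component_q(a, bb, s1, s2, r):
    return (a - 1.0) * s1 + (bb - 1.0) * s2 - r * special.betaln(a, bb)


def _maximize_component(a0, b0, s1, s2, r, n_newton: int = 2):
    """M-step for one component: maximize the expected complete-data
    log-likelihood in (a, b) by a damped Newton iteration on the weighted
    beta log-likelihood.  The update is only accepted on improvement, so
    the EM objective cannot decrease (generalized EM)."""
    a, bb = a0, b0
    q_best = _component_q(a, bb, s1, s2, r)
    lim_lo, lim_hi = 1e-3, 1e4
    for _ in range(n_newton):
        psi_ab = special.digamma(a + bb)
        g = np.array([
            s1 - r * (special.digamma(a) - psi_ab),
            s2 - r * (special.digamma(bb) - psi_ab),
        ])
        # trigamma(x) = zeta(2, x); calling zeta directly skips the
        # polygamma dispatch overhead
        tri_a, tri_b, tri_ab = special.zeta(2.0, np.array([a, bb, a + bb]))
        H = -r * np.array([
            [tri_a - tri_ab, -tri_ab],
            [-tri_ab, tri_b - tri_ab],
        ])
        try:
            step = np.linalg.solve(H, -g)
        except np.linalg.LinAlgError:
            break
        t = 1.0
        improved = False
        for _bt in range(20):
            a_new = min(max(a + t * step[0], lim_lo), lim_hi)
            b_new = min(max(bb + t * step[1], lim_lo), lim_hi)
            q_new = _component_q(a_new, b_new, s1, s2, r)
            if q_new > q_best:
                a, bb, q_best = a_new, b_new, q_new
                improved = True
                break
            t *= 0.5
        if not improved:
            break
        if np.abs(g).max() < 1e-8 * (abs(q_best) + 1.0):
            break
    return a, bb


def _crossing(fit_w, fit_a, fit_b, k1, k2, lo, hi) -> float:
    """Posterior crossing point between components k1 and k2 in (lo, hi)."""

    def g(x):
        x = np.clip(x, _EPS, 1 - _EPS)
        return (
            np.log(fit_w[k1] + 1e-300) + stats.beta.logpdf(x, fit_a[k1], fit_b[k1])
            - np.log(fit_w[k2] + 1e-300) - stats.beta.logpdf(x, fit_a[k2], fit_b[k2])
        )

    grid = np.linspace(lo, hi, 201)
    vals = g(grid)
    sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if sign_change.size == 0:
        return 0.5 * (lo + hi)
    i = sign_change[-1] if vals[0] > 0 else sign_change[0]
    return float(optimize.brentq(g, grid[i], grid[i + 1]))


def fit_beta_mixture(
    values,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
) -> BetaMixtureFit:
    """EM fit of a 3-component beta mixture to methylation fractions.

    Initialization is deterministic (hard thresholds at 0.25 / 0.75 with
    method-of-moments shape starts), so the fit is order-invariant and
    reproducible; ``seed`` is accepted for interface symmetry but the
    procedure draws no random numbers.  Convergence is declared when the
    relative log-likelihood change drops below ``tol``; if ``max_iter`` is
    exhausted the best fit is returned with ``converged=False`` and a
    warning.
    """
    x = np.asarray(values, float).ravel()
    x = x[np.isfinite(x)]
    if x.size < 100:
        raise ValidationError(f"need >= 100 finite values to fit mixture, got {x.size}")
    x = np.clip(x, _EPS, 1.0 - _EPS)

    # deterministic initialization by hard state thresholds
    groups = [x[x < 0.25], x[(x >= 0.25) & (x <= 0.75)], x[x > 0.75]]
    anchors = (0.1, 0.5, 0.9)
    w = np.array([max(g.size, 1e-3 * x.size) for g in groups], float)
    w /= w.sum()
    a = np.empty(3)
    b = np.empty(3)
    for k, g in enumerate(groups):
        a[k], b[k] = _moment_shapes(g, anchors[k])

    lnx = np.log(x)
    ln1x = np.log1p(-x)

    path = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step (manual beta log-densities; scipy's dispatch is too slow
        # to call hundreds of times per sample)
        lp = (
            np.log(w + 1e-300)[None, :]
            + np.outer(lnx, a - 1.0)
            + np.outer(ln1x, b - 1.0)
            - special.betaln(a, b)[None, :]
        )
        mx = lp.max(axis=1)
        norm = mx + np.log(np.exp(lp - mx[:, None]).sum(axis=1))
        ll = float(norm.sum())
        path.append(ll)
        resp = np.exp(lp - norm[:, None])

        if len(path) > 1:
            rel = abs(path[-1] - path[-2]) / (abs(path[-2]) + 1.0)
            if rel < tol:
                converged = True
                break

        # M-step
        r = resp.sum(axis=0)
        w = r / x.size
        for k in range(3):
            s1 = float(resp[:, k] @ lnx)
            s2 = float(resp[:, k] @ ln1x)
            a[k], b[k] = _maximize_component(a[k], b[k], s1, s2, r[k])

    if not converged:
        warnings.warn(
            f"beta-mixture EM did not converge in {max_iter} iterations",
            RuntimeWarning,
        )

    order = np.argsort(a / (a + b))
    w, a, b = w[order], a[order], b[order]
    means = a / (a + b)
    t_uh = _crossing(w, a, b, 0, 1, means[0], means[1])
    t_hm = _crossing(w, a, b, 1, 2, means[1], means[2])
    return BetaMixtureFit(
        weights=w, a=a, b=b, thresholds=(t_uh, t_hm),
        log_likelihood=path[-1], loglik_path=np.asarray(path),
        n_iter=it, converged=converged,
    )


@dataclass
class GoldStandard:
    """Calibration reference: the probe-wise mean beta over all training
    samples, with its fitted beta mixture."""

    probe_ids: pd.Index
    values: pd.Series
    fit: BetaMixtureFit = field(repr=False)

    def save(self, values_path, fit_path) -> None:
        self.values.rename("gold_mean").to_frame().to_csv(
            values_path, sep="\t", index_label="probe_id"
        )
        with open(fit_path, "w") as fh:
            json.dump(self.fit.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, values_path, fit_path) -> "GoldStandard":
        df = pd.read_csv(values_path, sep="\t", index_col=0)
        values = df.iloc[:, 0].astype(float)
        with open(fit_path) as fh:
            fit = BetaMixtureFit.from_dict(json.load(fh))
        return cls(probe_ids=values.index, values=values, fit=fit)


def build_gold_standard(matrices: list[BetaMatrix], **fit_kwargs) -> GoldStandard:
    """Probe-wise mean over the pooled samples of all training matrices
    (missing cells ignored), plus a mixture fitted to that mean vector."""
    if not matrices:
        raise ValidationError("no matrices given")
    ref_probes = matrices[0].probe_ids
    for m in matrices[1:]:
        if not ref_probes.equals(m.probe_ids):
            raise ValidationError(
                "matrices must share an identical probe set (run intersect_probes first)"
            )
    pooled = pd.concat([m.data for m in matrices], axis=1)
    mean = pooled.mean(axis=1, skipna=True)
    if mean.isna().any():
        bad = mean.index[mean.isna()].tolist()
        raise ValidationError(f"probes with no observed values: {bad[:5]}")
    fit = fit_beta_mixture(mean.to_numpy(), **fit_kwargs)
    return GoldStandard(probe_ids=mean.index, values=mean.rename("gold_mean"), fit=fit)


def _quantile_map(x, a_from, b_from, a_to, b_to):
    q = stats.beta.cdf(np.clip(x, _EPS, 1 - _EPS), a_from, b_from)
    q = np.clip(q, 1e-12, 1 - 1e-12)
    return stats.beta.ppf(q, a_to, b_to)


def bmiq_calibrate(
    sample_values,
    gold: GoldStandard,
    sample_fit: BetaMixtureFit | None = None,
    **fit_kwargs,
) -> np.ndarray:
    """Calibrate one sample's beta values onto the gold-standard
    distribution.

    U- and M-state values are mapped by beta-CDF quantile matching from the
    sample's component onto the gold component; H-state values are mapped
    by the linear dilation carrying the sample's posterior state boundaries
    onto the images of those boundaries, which makes the transport
    continuous across states.  Missing values pass through untouched; if
    the sample mixture cannot be fitted the values are returned unchanged
    with a warning.
    """
    x = np.asarray(sample_values, float).copy()
    finite = np.isfinite(x)
    xv = np.clip(x[finite], _EPS, 1 - _EPS)

    if sample_fit is None:
        try:
            sample_fit = fit_beta_mixture(xv, **fit_kwargs)
        except (ValidationError, FloatingPointError) as exc:
            warnings.warn(f"mixture fit failed ({exc}); returning values uncalibrated",
                          RuntimeWarning)
            return x

    gfit = gold.fit
    states = sample_fit.assign_states(xv)
    out = np.empty_like(xv)

    # U and M: quantile transport through the beta CDFs
    for k in (0, 2):
        sel = states == k
        if sel.any():
            out[sel] = _quantile_map(
                xv[sel], sample_fit.a[k], sample_fit.b[k], gfit.a[k], gfit.b[k]
            )

    # H: linear dilation between the mapped state boundaries
    t_uh, t_hm = sample_fit.thresholds
    left = float(_quantile_map(np.array([t_uh]), sample_fit.a[0], sample_fit.b[0],
                               gfit.a[0], gfit.b[0])[0])
    right = float(_quantile_map(np.array([t_hm]), sample_fit.a[2], sample_fit.b[2],
                                gfit.a[2], gfit.b[2])[0])
    if right <= left:
        left, right = min(left, right), max(left, right) + 1e-9
    sel = states == 1
    if sel.any():
        span = t_hm - t_uh
        if span <= 0:
            out[sel] = 0.5 * (left + right)
        else:
            out[sel] = left + (xv[sel] - t_uh) * (right - left) / span

    out = np.clip(out, 0.0, 1.0)
    x[finite] = out
    return x


def calibrate_matrix(beta: BetaMatrix, gold: GoldStandard, **fit_kwargs) -> BetaMatrix:
    """Calibrate every sample (column) of a matrix against the gold
    standard.  Probe axes must match the reference."""
    if not beta.probe_ids.equals(pd.Index(gold.probe_ids)):
        raise ValidationError("beta matrix probes do not match the gold standard")
    out = beta.data.copy()
    for s in beta.sample_ids:
        out[s] = bmiq_calibrate(beta.data[s].to_numpy(), gold, **fit_kwargs)
    return BetaMatrix(out)
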