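"""Synthetic cord-blood-like methylation datasets with known ground truth.

The generator emulates the statistical structure of neonatal methylation
cohorts: per-sample beta profiles arise as a mixture of cell-type reference
profiles (cell proportions drawn from a Dirichlet), a subset of CpGs drifts
linearly with gestational age, cohorts contribute a probe-level batch shift,
measurement noise is added on the logit scale (which keeps betas in (0, 1)
and reproduces their heteroskedasticity), and a small fraction of cells
fails detection.

Every quantity a downstream stage estimates — GA per sample, causal CpG
slopes, cell proportions — is returned as :class:`GroundTruth`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .datamodel import BetaMatrix, DetectionPMatrix, SampleSheet, ValidationError

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_reference_profiles",
    "simulate_dataset",
]

_EPS = 1e-6


def _logit(p):
    return np.log(p) - np.log1p(-p)


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class SimulationConfig:
    """Parameters of the default synthetic scenario.

    Defaults describe a cohort structure with a wide GA span (24-44 weeks,
    covering extremely preterm through post term), 2000 CpGs of which 50
    drift with GA at 0.005-0.03 beta/week, five blood cell types, three
    cohorts with a small batch shift, logit-scale noise sd 0.3 and a 0.5 %
    detection failure rate.
    """

    n_samples: int = 450
    n_probes: int = 2000
    n_causal: int = 50
    effect_size_range: tuple[float, float] = (0.005, 0.03)
    ga_range_weeks: tuple[float, float] = (24.0, 44.0)
    n_cohorts: int = 3
    cohort_shift_sd: float = 0.01
    n_cell_types: int = 5
    cell_concentration: float = 10.0
    discriminating_fraction: float = 0.1
    discriminating_delta: float = 0.4
    noise_sd: float = 0.3
    detection_fail_rate: float = 0.005
    spot_fraction: float = 1 / 3
    max_days_to_sampling: int = 39
    seed: int = 0

    def __post_init__(self):
        if self.n_causal > self.n_probes:
            raise ValidationError("n_causal must be <= n_probes")
        lo, hi = self.ga_range_weeks
        if not (20.0 <= lo < hi <= 46.0):
            raise ValidationError("ga_range_weeks must lie within [20, 46]")
        for name in ("detection_fail_rate", "spot_fraction", "discriminating_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.n_cell_types < 1:
            raise ValidationError("need at least one cell type")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """What the generator planted: causal probe slopes (beta/week), true
    cell-type proportions per sample, and true (effective) GA per sample."""

    causal_slopes: pd.Series
    cell_proportions: pd.DataFrame
    true_ga: pd.Series
    cohort: pd.Series = field(default=None)
    reference_profiles: pd.DataFrame = field(default=None)

    def __post_init__(self):
        props = self.cell_proportions.to_numpy()
        if (props < -1e-12).any():
            raise ValidationError("cell proportions must be non-negative")
        if not np.allclose(props.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError("cell proportions must sum to 1 per sample")


def simulate_reference_profiles(
    cell_types: int,
    n_probes: int,
    seed: int,
    discriminating_fraction: float = 0.1,
    delta: float = 0.4,
) -> pd.DataFrame:
    """Probes x cell-types matrix of mean beta per purified cell population.

    A configurable fraction of probes discriminates between types: at such a
    probe one type is shifted by at least ``delta`` (on the beta scale) from
    the shared baseline, mimicking the lineage-specific marks that make
    reference-based deconvolution possible.  Non-discriminating probes are
    identical across types.
    """
    if cell_types < 1:
        raise ValidationError("cell_types must be >= 1")
    rng = np.random.default_rng(seed)
    base = rng.uniform(0.05, 0.95, size=n_probes)
    profiles = np.tile(base[:, None], (1, cell_types))
    n_disc = int(round(discriminating_fraction * n_probes))
    if n_disc and cell_types >= 2:
        disc_idx = rng.choice(n_probes, size=n_disc, replace=False)
        owner = rng.integers(0, cell_types, size=n_disc)
        for i, p in enumerate(disc_idx):
            b = base[p]
            # shift the owning type by >= delta, towards the roomier side
            direction = 1.0 if b + delta <= 1.0 - _EPS else -1.0
            if direction > 0 and b + delta > 1.0 - _EPS:
                direction = -1.0
            shift = delta + rng.uniform(0.0, 0.1)
            target = np.clip(b + direction * shift, _EPS, 1.0 - _EPS)
            if abs(target - b) < delta:  # clipped into range; push other way
                target = np.clip(b - direction * shift, _EPS, 1.0 - _EPS)
            profiles[p, owner[i]] = target
    probe_ids = [f"cg{i:06d}" for i in range(n_probes)]
    cols = [f"cell{t}" for t in range(cell_types)]
    return pd.DataFrame(profiles, index=pd.Index(probe_ids, name="probe_id"), columns=cols)


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[BetaMatrix, DetectionPMatrix, SampleSheet, GroundTruth]:
    """Generate one synthetic multi-cohort dataset.

    Deterministic given ``config.seed``.  Betas are complete (no NaN); the
    planted detection failures live in the detection-p matrix, so the QC
    masking step is what introduces missingness, as with real arrays.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, p = cfg.n_samples, cfg.n_probes

    ref = simulate_reference_profiles(
        cfg.n_cell_types, p, seed=int(rng.integers(2**31 - 1)),
        discriminating_fraction=cfg.discriminating_fraction,
        delta=cfg.discriminating_delta,
    )
    probe_ids = ref.index
    sample_ids = pd.Index([f"s{i:04d}" for i in range(n)], name="sample_id")

    # true (effective) GA of each sample's methylation profile
    lo, hi = cfg.ga_range_weeks
    true_ga = rng.uniform(lo, hi, size=n)
    ga_mid = 0.5 * (lo + hi)

    # cohort structure: contiguous random blocks, last cohorts are blood spots
    cohort_of = rng.integers(0, cfg.n_cohorts, size=n)
    cohort_labels = np.array([f"cohort{c}" for c in cohort_of])
    n_spot_cohorts = int(round(cfg.spot_fraction * cfg.n_cohorts))
    spot_cohorts = set(range(cfg.n_cohorts - n_spot_cohorts, cfg.n_cohorts))
    is_spot = np.isin(cohort_of, list(spot_cohorts))

    # cell mixture
    conc = np.full(cfg.n_cell_types, cfg.cell_concentration)
    props = rng.dirichlet(conc, size=n)  # n x types

    mu = ref.to_numpy() @ props.T  # p x n

    # GA-associated CpGs: linear drift anchored at the GA midpoint
    causal_idx = rng.choice(p, size=cfg.n_causal, replace=False) if cfg.n_causal else np.array([], int)
    slo, shi = cfg.effect_size_range
    slopes = rng.uniform(slo, shi, size=cfg.n_causal) * rng.choice([-1.0, 1.0], size=cfg.n_causal)
    if cfg.n_causal:
        mu[causal_idx, :] += slopes[:, None] * (true_ga[None, :] - ga_mid)

    # cohort batch shift on the beta scale, per probe per cohort
    if cfg.cohort_shift_sd > 0:
        shifts = rng.normal(0.0, cfg.cohort_shift_sd, size=(p, cfg.n_cohorts))
        mu += shifts[:, cohort_of]

    mu = np.clip(mu, _EPS, 1.0 - _EPS)
    if cfg.noise_sd > 0:
        beta = _expit(_logit(mu) + rng.normal(0.0, cfg.noise_sd, size=mu.shape))
    else:
        beta = mu
    beta = np.clip(beta, _EPS, 1.0 - _EPS)

    # detection p-values: passing cells well under the 0.001 threshold,
    # failures uniformly above it
    detp = rng.uniform(0.0, 5e-4, size=beta.shape)
    fails = rng.random(size=beta.shape) < cfg.detection_fail_rate
    detp[fails] = rng.uniform(2e-3, 1.0, size=int(fails.sum()))

    # sample sheet: spots are sampled days after birth; their methylation
    # reflects the effective GA, so clinical GA = effective - delay
    days = np.where(is_spot, rng.integers(0, cfg.max_days_to_sampling + 1, size=n), 0)
    clinical_ga = true_ga - days / 7.0
    # keep clinical GA inside the plausibility window
    clip_lo = 20.0 + 1e-6
    adj = np.maximum(clip_lo - clinical_ga, 0.0)
    days = days - np.ceil(adj * 7.0).astype(int).clip(min=0)
    days = np.clip(days, 0, None)
    clinical_ga = true_ga - days / 7.0

    race = rng.choice(["groupA", "groupB"], size=n, p=[0.6, 0.4])
    sex = rng.choice(["F", "M"], size=n)
    insurance = rng.choice(["medicaid", "private"], size=n, p=[0.4, 0.6])
    birthweight = np.clip(
        -3600.0 + 180.0 * clinical_ga + rng.normal(0.0, 300.0, size=n), 400.0, None
    )
    bw_percentile = rng.uniform(0.0, 100.0, size=n)

    sheet = SampleSheet(pd.DataFrame({
        "sample_id": sample_ids,
        "clinical_ga_weeks": clinical_ga,
        "tissue": np.where(is_spot, "spot", "cord"),
        "days_to_sampling": np.where(is_spot, days, np.nan),
        "sex": sex,
        "cohort": cohort_labels,
        "birthweight": birthweight,
        "birthweight_percentile": bw_percentile,
        "race": race,
        "insurance": insurance,
    }))

    truth = GroundTruth(
        causal_slopes=pd.Series(slopes, index=probe_ids[causal_idx], name="slope"),
        cell_proportions=pd.DataFrame(props, index=sample_ids, columns=ref.columns),
        true_ga=pd.Series(true_ga, index=sample_ids, name="true_ga_weeks"),
        cohort=pd.Series(cohort_labels, index=sample_ids, name="cohort"),
        reference_profiles=ref,
    )

    beta_m = BetaMatrix(pd.DataFrame(beta, index=probe_ids, columns=sample_ids))
    detp_m = DetectionPMatrix(pd.DataFrame(detp, index=probe_ids, columns=sample_ids))
    return beta_m, detp_m, sheet, truth
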