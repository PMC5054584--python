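"""Quality control for beta matrices.

Pipeline order matters and is fixed: detection-p masking first, then probes
with too much missing data are dropped, then samples (missing fractions
recomputed on the probe-filtered matrix), then the probe sets of multiple
datasets are intersected so every dataset carries the same probes.

Both the ">5 % missing" filters and the "detection p above 0.001" mask are
strict inequalities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .datamodel import BetaMatrix, DetectionPMatrix, ValidationError

__all__ = ["QCReport", "mask_by_detection", "filter_missingness", "intersect_probes"]


@dataclass
class QCReport:
    """What QC removed and what survived."""

    n_cells_masked: int = 0
    probes_dropped: "pd.Series" = field(default_factory=lambda: pd.Series(dtype=float))
    samples_dropped: "pd.Series" = field(default_factory=lambda: pd.Series(dtype=float))
    probes_retained: int = 0
    samples_retained: int = 0

    def to_dict(self) -> dict:
        return {
            "n_cells_masked": int(self.n_cells_masked),
            "probes_dropped": {k: float(v) for k, v in self.probes_dropped.items()},
            "samples_dropped": {k: float(v) for k, v in self.samples_dropped.items()},
            "probes_retained": int(self.probes_retained),
            "samples_retained": int(self.samples_retained),
        }


def mask_by_detection(
    beta: BetaMatrix, detp: DetectionPMatrix, threshold: float = 0.001
) -> tuple[BetaMatrix, int]:
    """Set to missing every cell whose detection p-value is strictly above
    ``threshold``; all other cells are untouched."""
    beta.align_check(detp)
    fail = detp.data.to_numpy() > threshold
    was_missing = beta.data.isna().to_numpy()
    n_masked = int((fail & ~was_missing).sum())
    masked = beta.data.mask(pd.DataFrame(fail, index=beta.probe_ids, columns=beta.sample_ids))
    return BetaMatrix(masked), n_masked


def filter_missingness(
    beta: BetaMatrix, probe_max: float = 0.05, sample_max: float = 0.05
) -> tuple[BetaMatrix, QCReport]:
    """Drop probes with missing fraction strictly above ``probe_max``, then
    drop samples with missing fraction strictly above ``sample_max``.

    The sample fractions are computed *after* probe removal, so a sample can
    be rescued by the removal of a bad probe — the order is part of the
    contract.
    """
    probe_frac = beta.missing_fraction("probe")
    bad_probes = probe_frac[probe_frac > probe_max]
    kept = beta.data.drop(index=bad_probes.index)
    if kept.shape[0] == 0:
        raise ValidationError("all probes removed by missingness filter")

    sample_frac = kept.isna().mean(axis=0)
    bad_samples = sample_frac[sample_frac > sample_max]
    kept = kept.drop(columns=bad_samples.index)
    if kept.shape[1] == 0:
        raise ValidationError("all samples removed by missingness filter")

    report = QCReport(
        n_cells_masked=0,
        probes_dropped=bad_probes,
        samples_dropped=bad_samples,
        probes_retained=kept.shape[0],
        samples_retained=kept.shape[1],
    )
    return BetaMatrix(kept), report


def intersect_probes(matrices: list[BetaMatrix]) -> list[BetaMatrix]:
    """Restrict every matrix to the probes present in all of them.

    Output probe order is the first matrix's order restricted to the common
    set, applied identically to every output.
    """
    if len(matrices) < 2:
        raise ValidationError("need at least two matrices to intersect")
    common = set(matrices[0].probe_ids)
    for m in matrices[1:]:
        common &= set(m.probe_ids)
    if not common:
        raise ValidationError("empty probe intersection across datasets")
    order = [p for p in matrices[0].probe_ids if p in common]
    return [BetaMatrix(m.data.loc[order]) for m in matrices]
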