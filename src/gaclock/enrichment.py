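"""CpG-feature derivation and enrichment of predictor CpGs.

Islands come in as BED intervals (0-based, half-open).  Shores are the
1.5 kb flanks of each island minus any island overlap; shelves are the
next 1.5 kb beyond the shores, minus island and shore overlap.  Probes
(1-based positions) are intersected with these features; for the mutually
exclusive island-context label, islands take precedence over shores over
shelves, and anything else is open sea.

Enrichment of the clock's CpGs against the eligible probe universe is a
two-sided Fisher exact test per feature on the 2x2 table
(in/out predictor) x (in/out feature), with the sample odds ratio
(Haldane 0.5 correction only when a cell is zero).  The same machinery
serves user-supplied probe lists (chromatin states, SNP-in-probe flags,
race-associated CpGs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import ProbeAnnotation, ValidationError

__all__ = [
    "GenomicFeatureSet",
    "derive_shores_shelves",
    "annotate_probes",
    "EnrichmentResult",
    "fisher_enrichment",
]

SHORE_BP = 1500
SHELF_BP = 1500


@dataclass
class GenomicFeatureSet:
    """Named set of genomic intervals, 0-based half-open, normalized to be
    sorted and non-overlapping per chromosome."""

    label: str
    intervals: dict  # chrom -> (m, 2) int array, sorted, disjoint

    @classmethod
    def from_tuples(cls, label: str, tuples) -> "GenomicFeatureSet":
        by_chrom: dict[str, list] = {}
        for tup in tuples:
            chrom, start, end = tup[0], int(tup[1]), int(tup[2])
            if start >= end:
                raise ValidationError(f"interval start >= end: {tup}")
            if start < 0:
                raise ValidationError(f"negative interval start: {tup}")
            by_chrom.setdefault(chrom, []).append((start, end))
        return cls(label, {c: _merge(np.array(v, int)) for c, v in by_chrom.items()})

    def to_tuples(self) -> list[tuple[str, int, int]]:
        out = []
        for chrom in sorted(self.intervals):
            for s, e in self.intervals[chrom]:
                out.append((chrom, int(s), int(e)))
        return out

    def total_bp(self) -> int:
        return int(sum((iv[:, 1] - iv[:, 0]).sum() for iv in self.intervals.values()))

    def contains(self, chrom: str, pos0: int) -> bool:
        iv = self.intervals.get(chrom)
        if iv is None or iv.size == 0:
            return False
        i = np.searchsorted(iv[:, 0], pos0, side="right") - 1
        return i >= 0 and pos0 < iv[i, 1]

    def chromosomes(self) -> set:
        return set(self.intervals)


def _merge(iv: np.ndarray) -> np.ndarray:
    if iv.size == 0:
        return iv.reshape(0, 2)
    iv = iv[np.argsort(iv[:, 0], kind="stable")]
    out = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.array(out, int)


def _expand(iv: np.ndarray, bp: int) -> np.ndarray:
    out = iv.copy()
    out[:, 0] = np.maximum(out[:, 0] - bp, 0)
    out[:, 1] = out[:, 1] + bp
    return _merge(out)


def _subtract(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Set difference a \\ b for merged interval arrays."""
    if a.size == 0:
        return a.reshape(0, 2)
    if b.size == 0:
        return a
    out = []
    for s, e in a:
        cur = s
        for bs, be in b:
            if be <= cur or bs >= e:
                continue
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return np.array(out, int).reshape(-1, 2)


def derive_shores_shelves(
    islands: GenomicFeatureSet,
) -> tuple[GenomicFeatureSet, GenomicFeatureSet]:
    """Shores = +/-1.5 kb island flanks minus islands; shelves = the next
    1.5 kb beyond the shores, minus islands and shores.  Coordinates are
    clipped at zero."""
    shores = {}
    shelves = {}
    for chrom, iv in islands.intervals.items():
        exp1 = _expand(iv, SHORE_BP)
        exp2 = _expand(iv, SHORE_BP + SHELF_BP)
        shores[chrom] = _subtract(exp1, iv)
        shelves[chrom] = _subtract(exp2, exp1)
    return (GenomicFeatureSet("shore", shores), GenomicFeatureSet("shelf", shelves))


ISLAND_CONTEXT_PRECEDENCE = ("island", "shore", "shelf")


def annotate_probes(
    annotation: ProbeAnnotation,
    features: list[GenomicFeatureSet],
    context_labels: tuple = ISLAND_CONTEXT_PRECEDENCE,
) -> pd.DataFrame:
    """Label each probe with every feature containing its position.

    Returns a boolean column per feature plus an ``island_context`` column
    using the precedence island > shore > shelf > ``"open_sea"``.  Raises
    when probe and feature chromosome names do not overlap at all.
    """
    probe_chroms = set(annotation.data["chromosome"])
    feat_chroms = set().union(*(f.chromosomes() for f in features)) if features else set()
    if features and not (probe_chroms & feat_chroms):
        raise ValidationError(
            "chromosome naming mismatch between probes and features: "
            f"probes use {sorted(probe_chroms)[:3]}, features use "
            f"{sorted(feat_chroms)[:3]}"
        )

    out = pd.DataFrame(index=annotation.probe_ids)
    chrom = annotation.data["chromosome"].to_numpy()
    pos0 = annotation.data["position"].to_numpy() - 1  # 1-based -> 0-based
    for feat in features:
        hits = np.zeros(len(out), bool)
        for c in feat.chromosomes():
            sel = chrom == c
            if not sel.any():
                continue
            iv = feat.intervals[c]
            idx = np.searchsorted(iv[:, 0], pos0[sel], side="right") - 1
            ok = (idx >= 0) & (pos0[sel] < iv[np.clip(idx, 0, None), 1])
            hits[np.nonzero(sel)[0]] = ok
        out[feat.label] = hits

    context = np.full(len(out), "open_sea", dtype=object)
    for lab in reversed(context_labels):
        if lab in out.columns:
            context[out[lab].to_numpy()] = lab
    out["island_context"] = context
    return out


@dataclass
class EnrichmentResult:
    feature: str
    in_pred_in_feat: int
    in_pred_out_feat: int
    out_pred_in_feat: int
    out_pred_out_feat: int
    odds_ratio: float
    p: float

    @property
    def table(self) -> np.ndarray:
        return np.array([
            [self.in_pred_in_feat, self.in_pred_out_feat],
            [self.out_pred_in_feat, self.out_pred_out_feat],
        ])


def _sample_or(a: int, b: int, c: int, d: int) -> float:
    if a * d == 0 and b * c == 0:
        return 1.0  # association undefined (an empty margin); treat as null
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def fisher_enrichment(
    predictor_probes,
    universe_probes,
    labels: pd.DataFrame,
) -> list[EnrichmentResult]:
    """Fisher exact enrichment of predictor CpGs per feature.

    ``labels`` is a boolean DataFrame (probe x feature), e.g. the output of
    :func:`annotate_probes` without the context column.  The predictor set
    must be a subset of the universe.  Two-sided p-values sum all 2x2
    tables (fixed margins) whose probability does not exceed the observed
    table's.
    """
    pred = pd.Index(pd.unique(pd.Series(list(predictor_probes))))
    universe = pd.Index(pd.unique(pd.Series(list(universe_probes))))
    if len(pred) == 0 or len(universe) == 0:
        raise ValidationError("empty predictor or universe set")
    if not pred.isin(universe).all():
        raise ValidationError("predictor probes must be a subset of the universe")
    missing = universe[~universe.isin(labels.index)]
    if len(missing):
        raise ValidationError(f"universe probes without labels: {missing.tolist()[:5]}")

    lab = labels.loc[universe]
    in_pred = universe.isin(pred)
    results = []
    for feature in lab.columns:
        if lab[feature].dtype == object:
            continue
        in_feat = lab[feature].to_numpy(bool)
        a = int((in_pred & in_feat).sum())
        b = int((in_pred & ~in_feat).sum())
        c = int((~in_pred & in_feat).sum())
        d = int((~in_pred & ~in_feat).sum())
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        results.append(EnrichmentResult(
            feature=str(feature),
            in_pred_in_feat=a, in_pred_out_feat=b,
            out_pred_in_feat=c, out_pred_out_feat=d,
            odds_ratio=_sample_or(a, b, c, d), p=float(p),
        ))
    return results
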