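"""Island/shore/shelf interval algebra, probe annotation and Fisher
enrichment against enumeration oracles."""

from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gaclock import (
    GenomicFeatureSet,
    ProbeAnnotation,
    ValidationError,
    annotate_probes,
    derive_shores_shelves,
    fisher_enrichment,
)


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by full hypergeometric enumeration: sum the
    probabilities of all tables with the same margins whose probability
    does not exceed the observed table's."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-12):
            total += px
    return min(total, 1.0)


class TestDeriveShoresShelves:
    def test_single_island_flanks(self):
        islands = GenomicFeatureSet.from_tuples("island", [("chr1", 10000, 10500)])
        shores, shelves = derive_shores_shelves(islands)
        assert shores.intervals["chr1"].tolist() == [[8500, 10000], [10500, 12000]]
        assert shelves.intervals["chr1"].tolist() == [[7000, 8500], [12000, 13500]]

    def test_left_clip_at_zero(self):
        islands = GenomicFeatureSet.from_tuples("island", [("chr1", 200, 700)])
        shores, shelves = derive_shores_shelves(islands)
        assert shores.intervals["chr1"][0].tolist() == [0, 200]
        # the whole left shelf is consumed by the clipped shore window
        assert (shelves.intervals["chr1"][:, 0] >= 700).all()

    def test_close_islands_matches_base_level_oracle(self):
        """Two islands 1 kb apart: per-base classification oracle.  A base
        is shore iff within 1.5 kb of an island but not in one; shelf iff
        within 3 kb but neither island nor shore."""
        tuples = [("chr1", 10000, 10500), ("chr1", 11500, 12000)]
        islands = GenomicFeatureSet.from_tuples("island", tuples)
        shores, shelves = derive_shores_shelves(islands)

        def near(pos, bp):
            return any(s - bp <= pos < e + bp for _, s, e in tuples)

        for pos in range(6000, 16500):
            in_island = near(pos, 0)
            in_shore = near(pos, 1500) and not in_island
            in_shelf = near(pos, 3000) and not in_island and not in_shore
            assert shores.contains("chr1", pos) == in_shore, pos
            assert shelves.contains("chr1", pos) == in_shelf, pos

    def test_disjointness_random_islands(self, rng):
        starts = np.sort(rng.choice(200_000, size=30, replace=False))
        tuples = [("chr2", int(s), int(s + rng.integers(200, 2000))) for s in starts]
        islands = GenomicFeatureSet.from_tuples("island", tuples)
        shores, shelves = derive_shores_shelves(islands)
        for pos in rng.choice(210_000, size=3000, replace=False):
            pos = int(pos)
            flags = [islands.contains("chr2", pos), shores.contains("chr2", pos),
                     shelves.contains("chr2", pos)]
            assert sum(flags) <= 1


class TestAnnotateProbes:
    def _ann(self, positions, chrom="chr1"):
        return ProbeAnnotation(pd.DataFrame({
            "probe_id": [f"cg{i}" for i in range(len(positions))],
            "chromosome": chrom,
            "position": positions,
        }))

    def test_island_and_shore_context(self):
        islands = GenomicFeatureSet.from_tuples("island", [("chr1", 10000, 10500)])
        shores, shelves = derive_shores_shelves(islands)
        # positions are 1-based: 10250 sits inside [10000,10500); 9000 in the left shore
        ann = self._ann([10250, 9000, 7500, 500])
        labels = annotate_probes(ann, [islands, shores, shelves])
        assert labels.loc["cg0", "island_context"] == "island"
        assert labels.loc["cg1", "island_context"] == "shore"
        assert labels.loc["cg2", "island_context"] == "shelf"
        assert labels.loc["cg3", "island_context"] == "open_sea"

    def test_matches_containment_scan_oracle(self, rng):
        starts = np.sort(rng.choice(100_000, size=15, replace=False))
        tuples = [("chr1", int(s), int(s + rng.integers(100, 1500))) for s in starts]
        islands = GenomicFeatureSet.from_tuples("island", tuples)
        positions = rng.integers(1, 110_000, size=400)
        ann = self._ann([int(p) for p in positions])
        labels = annotate_probes(ann, [islands])
        merged = islands.intervals["chr1"]
        for pid, pos in zip(ann.probe_ids, positions):
            expected = any(s <= pos - 1 < e for s, e in merged)
            assert bool(labels.loc[pid, "island"]) == expected

    def test_chromosome_mismatch_raises(self):
        islands = GenomicFeatureSet.from_tuples("island", [("1", 100, 200)])
        ann = self._ann([150], chrom="chr1")
        with pytest.raises(ValidationError, match="chromosome naming"):
            annotate_probes(ann, [islands])


class TestFisherEnrichment:
    def _labels(self, flags):
        return pd.DataFrame({"feat": flags},
                            index=[f"cg{i}" for i in range(len(flags))])

    def test_balanced_table_or_one_p_one(self):
        labels = self._labels([True] * 5 + [False] * 5 + [True] * 5 + [False] * 5)
        pred = [f"cg{i}" for i in range(10)]
        universe = [f"cg{i}" for i in range(20)]
        res = fisher_enrichment(pred, universe, labels)[0]
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p == pytest.approx(1.0)

    def test_extreme_table_matches_enumeration(self):
        labels = self._labels([True] * 10 + [False] * 10)
        pred = [f"cg{i}" for i in range(10)]
        universe = [f"cg{i}" for i in range(20)]
        res = fisher_enrichment(pred, universe, labels)[0]
        assert res.table.tolist() == [[10, 0], [0, 10]]
        assert res.p == pytest.approx(fisher_oracle(10, 0, 0, 10), abs=1e-10)

    @pytest.mark.parametrize("table", [
        (5, 5, 5, 5), (10, 0, 0, 10), (3, 17, 12, 48), (1, 0, 40, 120),
        (0, 9, 9, 0), (7, 13, 21, 59), (2, 2, 96, 100),
    ])
    def test_p_matches_enumeration_oracle(self, table):
        a, b, c, d = table
        _, p_scipy = stats.fisher_exact([[a, b], [c, d]])
        assert p_scipy == pytest.approx(fisher_oracle(a, b, c, d), abs=1e-10)
        labels = self._labels([True] * (a + c) + [False] * (b + d))
        pred = ([f"cg{i}" for i in range(a)]
                + [f"cg{i}" for i in range(a + c, a + c + b)])
        universe = [f"cg{i}" for i in range(a + b + c + d)]
        res = fisher_enrichment(pred, universe, labels)[0]
        assert res.p == pytest.approx(fisher_oracle(a, b, c, d), abs=1e-10)

    def test_doubling_preserves_or_shrinks_p(self):
        a, b, c, d = 8, 12, 30, 70
        labels1 = self._labels([True] * (a + c) + [False] * (b + d))
        pred1 = ([f"cg{i}" for i in range(a)]
                 + [f"cg{i}" for i in range(a + c, a + c + b)])
        res1 = fisher_enrichment(pred1, [f"cg{i}" for i in range(a + b + c + d)], labels1)[0]
        a2, b2, c2, d2 = 2 * a, 2 * b, 2 * c, 2 * d
        labels2 = self._labels([True] * (a2 + c2) + [False] * (b2 + d2))
        pred2 = ([f"cg{i}" for i in range(a2)]
                 + [f"cg{i}" for i in range(a2 + c2, a2 + c2 + b2)])
        res2 = fisher_enrichment(pred2, [f"cg{i}" for i in range(2 * (a + b + c + d))], labels2)[0]
        assert res2.odds_ratio == pytest.approx(res1.odds_ratio)
        assert res2.p < res1.p

    def test_universe_against_itself_or_one(self, rng):
        flags = rng.random(100) < 0.3
        labels = self._labels(list(flags))
        universe = [f"cg{i}" for i in range(100)]
        res = fisher_enrichment(universe, universe, labels)[0]
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p == pytest.approx(1.0)

    def test_predictor_outside_universe_raises(self):
        labels = self._labels([True, False])
        with pytest.raises(ValidationError):
            fisher_enrichment(["cgX"], ["cg0", "cg1"], labels)

    def test_empty_sets_raise(self):
        labels = self._labels([True, False])
        with pytest.raises(ValidationError):
            fisher_enrichment([], ["cg0"], labels)
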