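import math

import numpy as np
import pytest

from conftest import random_table
from spotlayer.hexbin import (
    HexGrid,
    aggregate_bins,
    bins_to_table,
    build_hex_grid,
    hex_vertices,
    point_to_hex,
    points_to_hex,
)
from spotlayer.model import CATEGORICAL, CONTINUOUS, SpotLayerError, SpotTable

SQRT3 = math.sqrt(3.0)


def brute_force_assign(x, y, q0, r0, grid, rings=2):
    """Independent oracle: nearest hex center among all candidates within
    ``rings`` rings of a starting guess."""
    best, best_d = None, np.inf
    for q in range(q0 - rings, q0 + rings + 1):
        for r in range(r0 - rings, r0 + rings + 1):
            cx, cy = grid.center(q, r)
            d = math.hypot(x - cx, y - cy)
            if d < best_d:
                best, best_d = (q, r), d
    return best, best_d


class TestBuildHexGrid:
    def test_width_formula(self):
        t = SpotTable(ids=["a", "b"], x=[0.0, 10.0], y=[0.0, 0.0])
        g = build_hex_grid(t, nbins_x=10)
        assert g.R == pytest.approx(1.0 / SQRT3)
        assert g.origin == (0.0, 0.0)

    def test_single_point_degenerate_extent(self):
        t = SpotTable(ids=["a"], x=[3.0], y=[4.0])
        g = build_hex_grid(t, nbins_x=5)
        assert g.R == pytest.approx(1.0 / SQRT3)

    def test_invalid_nbins_rejected(self, small_table):
        with pytest.raises(SpotLayerError):
            build_hex_grid(small_table, nbins_x=0)

    def test_empty_table_rejected(self):
        with pytest.raises(SpotLayerError):
            build_hex_grid(SpotTable(ids=[], x=[], y=[]), nbins_x=4)


class TestPointToHex:
    @pytest.mark.parametrize("q,r", [(0, 0), (2, -1), (-3, 5), (7, 7)])
    def test_center_maps_to_own_hex(self, q, r):
        grid = HexGrid(R=0.7, origin=(1.5, -2.0))
        cx, cy = grid.center(q, r)
        assert point_to_hex(cx, cy, grid) == (q, r)

    def test_non_finite_rejected(self):
        grid = HexGrid(R=1.0, origin=(0.0, 0.0))
        with pytest.raises(SpotLayerError):
            point_to_hex(float("nan"), 0.0, grid)

    def test_agrees_with_nearest_center_oracle(self, rng):
        grid = HexGrid(R=0.9, origin=(0.0, 0.0))
        xs = rng.uniform(0, 20, 2000)
        ys = rng.uniform(0, 20, 2000)
        qs, rs = points_to_hex(xs, ys, grid)
        for x, y, q, r in zip(xs, ys, qs, rs):
            (bq, br), bd = brute_force_assign(x, y, q, r, grid)
            cx, cy = grid.center(q, r)
            own_d = math.hypot(x - cx, y - cy)
            if own_d - bd > 1e-9:  # near-ties are don't-care
                assert (q, r) == (bq, br)

    def test_translation_equivariance(self, rng):
        """Shifting points and origin by the same exactly representable
        vector leaves every assignment unchanged."""
        shift = (13.25, -7.5)
        xs = rng.uniform(-5, 5, 500)
        ys = rng.uniform(-5, 5, 500)
        g1 = HexGrid(R=0.8, origin=(0.0, 0.0))
        g2 = HexGrid(R=0.8, origin=shift)
        q1, r1 = points_to_hex(xs, ys, g1)
        q2, r2 = points_to_hex(xs + shift[0], ys + shift[1], g2)
        assert np.array_equal(q1, q2) and np.array_equal(r1, r2)


class TestHexVertices:
    def test_pointy_top_first_vertex(self):
        grid = HexGrid(R=1.0, origin=(0.0, 0.0))
        v = hex_vertices((0, 0), grid)
        assert v[0] == pytest.approx((0.0, 1.0))

    def test_edges_equal_circumradius(self):
        grid = HexGrid(R=2.5, origin=(1.0, 1.0))
        v = hex_vertices((3, -2), grid)
        for a, b in zip(v, v[1:] + v[:1]):
            assert math.hypot(a[0] - b[0], a[1] - b[1]) == pytest.approx(2.5)

    def test_area_matches_shoelace_oracle(self):
        grid = HexGrid(R=1.3, origin=(0.0, 0.0))
        v = hex_vertices((2, 2), grid)
        area = 0.5 * abs(sum(a[0] * b[1] - b[0] * a[1]
                             for a, b in zip(v, v[1:] + v[:1])))
        assert abs(area - 1.5 * SQRT3 * 1.3 ** 2) < 1e-9


class TestAggregateBins:
    def grid(self):
        return HexGrid(R=1.0, origin=(0.0, 0.0))

    def test_single_point_bin(self):
        t = SpotTable(ids=["a"], x=[0.0], y=[0.0])
        t = t.with_annotation("v", CONTINUOUS, [7.0])
        t = t.with_annotation("g", CATEGORICAL, ["A"])
        (b,) = aggregate_bins(t, self.grid(), "v", "g")
        assert (b.count, b.mean_value, b.majority_label) == (1, 7.0, "A")

    def test_tie_breaks_lexicographically(self):
        t = SpotTable(ids=["a", "b"], x=[0.0, 0.1], y=[0.0, 0.0])
        t = t.with_annotation("v", CONTINUOUS, [1.0, 3.0])
        t = t.with_annotation("g", CATEGORICAL, ["B", "A"])
        (b,) = aggregate_bins(t, self.grid(), "v", "g")
        assert b.mean_value == 2.0 and b.majority_label == "A"

    def test_missing_label_counts_but_never_wins(self):
        t = SpotTable(ids=["a", "b", "c"], x=[0.0, 0.1, -0.1], y=[0.0, 0.0, 0.0])
        t = t.with_annotation("g", CATEGORICAL, [None, None, "Z"])
        (b,) = aggregate_bins(t, self.grid(), None, "g")
        assert b.count == 3 and b.majority_label == "Z"

    def test_all_missing_values_give_missing_aggregates(self):
        t = SpotTable(ids=["a"], x=[0.0], y=[0.0])
        t = t.with_annotation("v", CONTINUOUS, [np.nan])
        t = t.with_annotation("g", CATEGORICAL, [None])
        (b,) = aggregate_bins(t, self.grid(), "v", "g")
        assert b.mean_value is None and b.majority_label is None

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_direct_grouping_oracle(self, seed):
        t = random_table(np.random.default_rng(seed), n=200)
        grid = build_hex_grid(t, nbins_x=8)
        bins = aggregate_bins(t, grid, "value", "group")
        assert sum(b.count for b in bins) == t.n
        # partition: every id exactly once
        members = [i for b in bins for i in b.member_ids]
        assert sorted(members) == sorted(t.ids)
        # independent regrouping by scalar assignment
        q, r = points_to_hex(t.x, t.y, grid)
        cont = t.annotation("value").values
        cat = t.annotation("group").values
        for b in bins:
            idx = [i for i in range(t.n) if (q[i], r[i]) == b.axial]
            vals = [cont[i] for i in idx if not np.isnan(cont[i])]
            if vals:
                assert b.mean_value == pytest.approx(float(np.mean(vals)), abs=1e-9)
            else:
                assert b.mean_value is None
            freq = {}
            for i in idx:
                if cat[i] is not None:
                    freq[cat[i]] = freq.get(cat[i], 0) + 1
            if freq:
                best = max(freq.values())
                assert b.majority_label == min(l for l, c in freq.items() if c == best)

    def test_scaling_continuous_scales_means(self, rng):
        t = random_table(rng, n=150)
        grid = build_hex_grid(t, nbins_x=6)
        scaled = t.with_annotation("value", CONTINUOUS,
                                   3.0 * t.annotation("value").values)
        b1 = aggregate_bins(t, grid, "value", None)
        b2 = aggregate_bins(scaled, grid, "value", None)
        for a, b in zip(b1, b2):
            if a.mean_value is not None:
                assert b.mean_value == pytest.approx(3.0 * a.mean_value)

    def test_unknown_or_mistyped_column_rejected(self, small_table):
        grid = build_hex_grid(small_table, nbins_x=4)
        with pytest.raises(SpotLayerError):
            aggregate_bins(small_table, grid, "nope", None)
        with pytest.raises(SpotLayerError):
            aggregate_bins(small_table, grid, "domain", None)  # categorical as continuous


def test_bins_export_as_spot_table(rng):
    t = random_table(rng, n=100)
    grid = build_hex_grid(t, nbins_x=5)
    bins = aggregate_bins(t, grid, "value", "group")
    exported = bins_to_table(bins, grid)
    assert exported.n == len(bins)
    assert set(exported.annotations) == {"q", "r", "count", "mean", "majority"}
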