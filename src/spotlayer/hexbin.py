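"""Regular hexagonal binning of 2D point sets with per-hexagon aggregation.

Pointy-top hexagons on an axial (q, r) lattice: a hexagon's center sits at

    x = x0 + sqrt(3) * R * (q + r/2)
    y = y0 + 1.5 * R * r

for circumradius R and grid origin (x0, y0).  Point-to-hexagon assignment
inverts this to fractional axial coordinates, lifts to cube coordinates
(q, r, s = -q - r) and rounds each component to the nearest integer,
correcting the component with the largest rounding error so the cube
constraint q + r + s = 0 holds — the standard cube-rounding algorithm,
which returns the hexagon with the nearest center.

Each emitted bin summarizes its members by count, arithmetic mean of one
continuous variable (missing values excluded) and majority label of one
categorical variable (ties broken by lexicographically smallest label;
members with a missing label count toward the bin total but toward no
label's majority).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .model import (
    CATEGORICAL,
    CONTINUOUS,
    Annotation,
    NonFiniteCoordinateError,
    SpotLayerError,
    SpotTable,
)

SQRT3 = math.sqrt(3.0)


@dataclass(frozen=True)
class HexGrid:
    """A pointy-top hexagonal tiling: circumradius ``R`` and origin anchor."""

    R: float
    origin: Tuple[float, float]

    def __post_init__(self) -> None:
        if not (self.R > 0):
            raise SpotLayerError(f"hex circumradius must be positive, got {self.R}")

    def center(self, q: int, r: int) -> Tuple[float, float]:
        x0, y0 = self.origin
        return (x0 + SQRT3 * self.R * (q + r / 2.0), y0 + 1.5 * self.R * r)


@dataclass(frozen=True)
class HexBin:
    """Aggregates of the points falling in one hexagon."""

    axial: Tuple[int, int]
    count: int
    mean_value: Optional[float]
    majority_label: Optional[str]
    member_ids: Tuple[str, ...]


def build_hex_grid(table: SpotTable, nbins_x: int = 40) -> HexGrid:
    """Grid sized so ``nbins_x`` hexagon widths span the table's x-extent.

    Hex width w = (x_max - x_min) / nbins_x (w = 1 for a degenerate
    single-point extent); circumradius R = w / sqrt(3); origin anchored at
    (x_min, y_min).
    """
    if nbins_x < 1:
        raise SpotLayerError(f"nbins_x must be >= 1, got {nbins_x}")
    if table.n == 0:
        raise SpotLayerError("cannot build a hex grid over an empty table")
    xmin, xmax = float(table.x.min()), float(table.x.max())
    ymin = float(table.y.min())
    w = (xmax - xmin) / nbins_x
    if w <= 0:
        w = 1.0
    return HexGrid(R=w / SQRT3, origin=(xmin, ymin))


def points_to_hex(x: np.ndarray, y: np.ndarray, grid: HexGrid) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorized cube-rounding assignment of points to axial coordinates."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise NonFiniteCoordinateError("non-finite coordinate passed to hex assignment")
    x0, y0 = grid.origin
    rf = (y - y0) / (1.5 * grid.R)
    qf = (x - x0) / (SQRT3 * grid.R) - rf / 2.0
    sf = -qf - rf
    q = np.round(qf)
    r = np.round(rf)
    s = np.round(sf)
    dq = np.abs(q - qf)
    dr = np.abs(r - rf)
    ds = np.abs(s - sf)
    fix_q = (dq >= dr) & (dq >= ds)
    fix_r = ~fix_q & (dr >= ds)
    q = np.where(fix_q, -r - s, q)
    r = np.where(fix_r, -q - s, r)
    return q.astype(int), r.astype(int)


def point_to_hex(x: float, y: float, grid: HexGrid) -> Tuple[int, int]:
    """Axial coordinates of the hexagon whose center is nearest to (x, y)."""
    q, r = points_to_hex(np.array([x]), np.array([y]), grid)
    return int(q[0]), int(r[0])


def hex_vertices(axial: Tuple[int, int], grid: HexGrid) -> List[Tuple[float, float]]:
    """Six vertices of a pointy-top hexagon, counter-clockwise from the top.

    Vertices sit at angles 90deg, 150deg, ..., 30deg from the center at
    radius R, so the first vertex of hex (0, 0) on a unit grid anchored at
    the origin is (0, 1).
    """
    cx, cy = grid.center(*axial)
    out = []
    for k in range(6):
        a = math.radians(90 + 60 * k)
        out.append((cx + grid.R * math.cos(a), cy + grid.R * math.sin(a)))
    return out


def aggregate_bins(
    table: SpotTable,
    grid: HexGrid,
    continuous_var: Optional[str] = None,
    categorical_var: Optional[str] = None,
) -> List[HexBin]:
    """Assign every record to exactly one hexagon and aggregate per bin.

    Only non-empty bins are emitted, ordered by (r, q) for determinism.
    """
    cont: Optional[Annotation] = (
        table.annotation(continuous_var, CONTINUOUS) if continuous_var else None
    )
    cat: Optional[Annotation] = (
        table.annotation(categorical_var, CATEGORICAL) if categorical_var else None
    )
    q, r = points_to_hex(table.x, table.y, grid)
    groups: dict = {}
    for i in range(table.n):
        groups.setdefault((int(q[i]), int(r[i])), []).append(i)
    bins = []
    for key in sorted(groups, key=lambda k: (k[1], k[0])):
        idx = groups[key]
        mean_value = None
        if cont is not None:
            vals = cont.values[idx]
            vals = vals[~np.isnan(vals)]
            if vals.size:
                mean_value = float(vals.mean())
        majority = None
        if cat is not None:
            freq: dict = {}
            for i in idx:
                lab = cat.values[i]
                if lab is not None:
                    freq[lab] = freq.get(lab, 0) + 1
            if freq:
                best = max(freq.values())
                majority = min(l for l, c in freq.items() if c == best)
        bins.append(
            HexBin(
                axial=key,
                count=len(idx),
                mean_value=mean_value,
                majority_label=majority,
                member_ids=tuple(table.ids[i] for i in idx),
            )
        )
    return bins


def bins_to_table(bins: List[HexBin], grid: HexGrid) -> SpotTable:
    """Bins as a spot table (q, r, center, count, mean, majority) for
    inspection or CSV export through :func:`spotlayer.io.write_spot_table`."""
    centers = [grid.center(*b.axial) for b in bins]
    table = SpotTable(
        ids=[f"hex_{b.axial[0]}_{b.axial[1]}" for b in bins],
        x=[c[0] for c in centers],
        y=[c[1] for c in centers],
    )
    table = table.with_annotation("q", CONTINUOUS, [float(b.axial[0]) for b in bins])
    table = table.with_annotation("r", CONTINUOUS, [float(b.axial[1]) for b in bins])
    table = table.with_annotation("count", CONTINUOUS, [float(b.count) for b in bins])
    table = table.with_annotation(
        "mean", CONTINUOUS, [np.nan if b.mean_value is None else b.mean_value for b in bins]
    )
    table = table.with_annotation("majority", CATEGORICAL, [b.majority_label for b in bins])
    return table
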