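"""Deterministic generators for spot-array and embedding test data.

Two generators emulate the package's target use cases without any
download: a banded-domain spot lattice resembling laminar cortex
annotations on a spot-based spatial transcriptomics array (horizontal
bands L1..L6 + WM, with band-dependent joint expression of two genes),
and a 2D Gaussian-mixture embedding resembling a UMAP of discrete cell
clusters with one marker-enriched cluster.

One global seed drives a dedicated random stream per generated column, so
adding a column never perturbs existing columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .model import CATEGORICAL, CONTINUOUS, SpotLayerError, SpotTable, validate_spot_table

DEFAULT_BANDS = ("L1", "L2", "L3", "L4", "L5", "L6", "WM")
#: joint-expression enrichment per band; L6 most enriched, matching the
#: laminar colocalization structure the generator emulates
DEFAULT_MULTIPLIERS = (1.0, 1.0, 1.0, 1.0, 1.0, 4.0, 1.0)


@dataclass
class BandedDomainConfig:
    """Configuration of the banded spot-lattice generator.

    The lattice is hexagonally packed (offset rows) with ``center_spacing``
    between adjacent spot centers and spots of ``spot_diameter`` — the
    tight-packing regime where outline-based ground rendering matters.
    ``p0`` is the baseline probability that both genes are expressed in a
    spot; each band's joint rate is ``clip(p0 * multiplier, 0, 1)``.
    ``dropout`` zeroes an expressed gene with the given probability, after
    the joint draw.
    """

    n_cols: int = 50
    n_rows: int = 70
    center_spacing: float = 100.0
    spot_diameter: float = 55.0
    band_labels: Sequence[str] = DEFAULT_BANDS
    p0: float = 0.1
    multipliers: Sequence[float] = DEFAULT_MULTIPLIERS
    dropout: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cols < 1 or self.n_rows < 1:
            raise SpotLayerError("lattice dimensions must be positive")
        if not (0.0 <= self.p0 <= 1.0):
            raise SpotLayerError(f"p0 must be in [0, 1], got {self.p0}")
        if not (0.0 <= self.dropout <= 1.0):
            raise SpotLayerError(f"dropout must be in [0, 1], got {self.dropout}")
        if len(self.multipliers) != len(self.band_labels):
            raise SpotLayerError(
                f"{len(self.multipliers)} multipliers for {len(self.band_labels)} bands"
            )
        if any(m < 0 for m in self.multipliers):
            raise SpotLayerError("enrichment multipliers must be non-negative")
        if not (0 < self.spot_diameter < self.center_spacing):
            raise SpotLayerError("spot diameter must be positive and below center spacing")


def band_of_row(row: int, n_rows: int, n_bands: int) -> int:
    """Band index for a lattice row: equal row counts per band, remainder
    rows to the last band."""
    per = n_rows // n_bands
    return min(row // per, n_bands - 1) if per else n_bands - 1


def generate_banded_domains(config: Optional[BandedDomainConfig] = None, **kwargs) -> SpotTable:
    """Spots on an offset lattice with banded domains and band-enriched
    joint expression of two genes.

    Columns: categorical ``domain`` (band per horizontal stripe of rows)
    and continuous ``expr_A``, ``expr_B``.  Per spot, with the band's joint
    rate both genes are expressed; otherwise, with probability ``p0`` each
    (mutually exclusively), exactly one is.  Expressed magnitudes are drawn
    log-normal(0, 1); unexpressed genes are exactly 0, so a strict
    threshold at 0 recovers the configured joint rate.  Fully reproducible
    from ``config.seed``.
    """
    config = config or BandedDomainConfig(**kwargs)
    s = config.center_spacing
    rows = np.repeat(np.arange(config.n_rows), config.n_cols)
    cols = np.tile(np.arange(config.n_cols), config.n_rows)
    x = cols * s + (rows % 2) * (s / 2.0)
    y = rows * s * (math.sqrt(3.0) / 2.0)
    n = len(x)
    labels = list(config.band_labels)
    band_idx = np.array([band_of_row(r, config.n_rows, len(labels)) for r in rows])
    domain = np.array([labels[b] for b in band_idx], dtype=object)

    streams = [np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(k,)))
               for k in range(4)]
    rng_status, rng_a, rng_b, rng_drop = streams

    p_both = np.clip(config.p0 * np.asarray(config.multipliers, dtype=float), 0.0, 1.0)[band_idx]
    # conditional on not-both: A-only and B-only each with rate p0
    p_single = min(config.p0, 0.5)
    u = rng_status.random(n)
    rest = 1.0 - p_both
    both = u < p_both
    a_only = ~both & (u < p_both + rest * p_single)
    b_only = ~both & ~a_only & (u < p_both + rest * 2.0 * p_single)
    a_present = both | a_only
    b_present = both | b_only

    expr_a = np.where(a_present, rng_a.lognormal(0.0, 1.0, n), 0.0)
    expr_b = np.where(b_present, rng_b.lognormal(0.0, 1.0, n), 0.0)
    if config.dropout > 0:
        expr_a = np.where(rng_drop.random(n) < config.dropout, 0.0, expr_a)
        expr_b = np.where(rng_drop.random(n) < config.dropout, 0.0, expr_b)

    table = SpotTable(
        ids=[f"spot_{i:06d}" for i in range(n)],
        x=x.astype(float),
        y=y.astype(float),
        diameter=float(config.spot_diameter),
    )
    table = table.with_annotation("domain", CATEGORICAL, domain)
    table = table.with_annotation("expr_A", CONTINUOUS, expr_a)
    table = table.with_annotation("expr_B", CONTINUOUS, expr_b)
    return validate_spot_table(table)


def generate_embedding_mixture(
    n_points: int = 2000,
    k: int = 4,
    separation: float = 20.0,
    marker_cluster: int = 0,
    marker_shift: float = 3.0,
    seed: int = 0,
) -> SpotTable:
    """A 2D Gaussian mixture emulating an embedding of discrete clusters.

    ``k`` unit-spread components with centers on a circle of radius
    ``separation``; categorical column ``cluster`` and continuous column
    ``marker`` = standard-normal noise plus ``marker_shift`` in the marker
    cluster.  Reproducible from ``seed``.
    """
    if k < 1:
        raise SpotLayerError(f"cluster count must be >= 1, got {k}")
    if n_points < k:
        raise SpotLayerError(f"need at least k={k} points, got {n_points}")
    if not (0 <= marker_cluster < k):
        raise SpotLayerError(f"marker_cluster must be in [0, {k}), got {marker_cluster}")
    streams = [np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(k_,)))
               for k_ in range(3)]
    rng_assign, rng_coord, rng_marker = streams
    angles = 2.0 * np.pi * np.arange(k) / k
    centers = separation * np.column_stack([np.cos(angles), np.sin(angles)])
    assign = rng_assign.integers(0, k, size=n_points)
    coords = centers[assign] + rng_coord.standard_normal((n_points, 2))
    marker = rng_marker.standard_normal(n_points) + marker_shift * (assign == marker_cluster)
    width = len(str(k - 1))
    labels = np.array([f"c{a:0{width}d}" for a in assign], dtype=object)
    table = SpotTable(
        ids=[f"cell_{i:06d}" for i in range(n_points)],
        x=coords[:, 0],
        y=coords[:, 1],
    )
    table = table.with_annotation("cluster", CATEGORICAL, labels)
    table = table.with_annotation("marker", CONTINUOUS, marker)
    return validate_spot_table(table)


def add_highlight(table: SpotTable, rate: float = 0.01, seed: int = 0,
                  label: str = "hit", column: str = "highlight") -> SpotTable:
    """Mark a random fraction of records with a categorical highlight label
    (missing elsewhere) — a third variable for the symbol channel."""
    if not (0.0 <= rate <= 1.0):
        raise SpotLayerError(f"rate must be in [0, 1], got {rate}")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(99,)))
    hit = rng.random(table.n) < rate
    values = np.array([label if h else None for h in hit], dtype=object)
    return table.with_annotation(column, CATEGORICAL, values)
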