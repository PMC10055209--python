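"""Core data model: spot tables, aesthetic layers, figure specs, palettes.

The model is purely in-memory and rendering-free.  A :class:`SpotTable`
holds 2D records (spatial spots or embedding points) with typed annotation
columns; a :class:`FigureSpec` binds annotation columns to the three
aesthetic channels (*ground* outline, *fill* interior, *symbol* glyph) that
realize figure-ground layering on a spot map.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import matplotlib
import numpy as np
from matplotlib.colors import ListedColormap, to_hex

CATEGORICAL = "categorical"
CONTINUOUS = "continuous"

#: channels in canonical z-order (bottom to top)
CHANNELS = ("ground", "fill", "symbol")


class SpotLayerError(Exception):
    """Base class for all domain errors raised by this package."""


class DuplicateIdError(SpotLayerError):
    pass


class NonFiniteCoordinateError(SpotLayerError):
    pass


class LengthMismatchError(SpotLayerError):
    pass


class ColumnError(SpotLayerError):
    """Unknown column, or column of the wrong kind for an operation."""


class PaletteError(SpotLayerError):
    pass


class DuplicateChannelError(SpotLayerError):
    pass


@dataclass
class Annotation:
    """One typed annotation column.

    Categorical values are stored as an object array with ``None`` marking a
    missing label; continuous values as float64 with NaN marking missing.
    """

    kind: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in (CATEGORICAL, CONTINUOUS):
            raise SpotLayerError(f"unknown annotation kind {self.kind!r}")
        if self.kind == CONTINUOUS:
            self.values = np.asarray(self.values, dtype=float)
        else:
            vals = np.asarray(self.values, dtype=object)
            # normalize float-NaN placeholders to None for categorical data
            norm = np.empty(len(vals), dtype=object)
            for i, v in enumerate(vals):
                if v is None or (isinstance(v, float) and math.isnan(v)):
                    norm[i] = None
                else:
                    norm[i] = str(v)
            self.values = norm

    def labels(self) -> list:
        """Sorted non-missing labels of a categorical column."""
        if self.kind != CATEGORICAL:
            raise ColumnError("labels() requires a categorical column")
        return sorted({v for v in self.values if v is not None})

    def equals(self, other: "Annotation") -> bool:
        if self.kind != other.kind or len(self.values) != len(other.values):
            return False
        if self.kind == CONTINUOUS:
            a, b = self.values, other.values
            return bool(np.all((np.isnan(a) & np.isnan(b)) | (a == b)))
        return all(u == v for u, v in zip(self.values, other.values))


@dataclass
class SpotTable:
    """Records of spots/points with 2D coordinates and typed annotations.

    The same type serves spatial maps (coordinates in array units) and
    embedding plots (coordinates are embedding dimensions); the method is
    agnostic to what the 2D coordinate system means.

    Parameters
    ----------
    ids
        Unique record identifiers (coerced to str).
    x, y
        Finite coordinates, same units.
    diameter
        Optional spot render diameter in data units; scalar (one per table)
        or per-record array; strictly positive.
    annotations
        Mapping of column name to :class:`Annotation`.
    """

    ids: np.ndarray
    x: np.ndarray
    y: np.ndarray
    diameter: Optional[Union[float, np.ndarray]] = None
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ids = np.asarray([str(i) for i in np.asarray(self.ids).ravel()], dtype=object)
        self.x = np.asarray(self.x, dtype=float).ravel()
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.diameter is not None and not np.isscalar(self.diameter):
            self.diameter = np.asarray(self.diameter, dtype=float).ravel()

    @property
    def n(self) -> int:
        return len(self.ids)

    def annotation(self, name: str, kind: Optional[str] = None) -> Annotation:
        if name not in self.annotations:
            raise ColumnError(f"unknown annotation column {name!r}")
        ann = self.annotations[name]
        if kind is not None and ann.kind != kind:
            raise ColumnError(f"column {name!r} is {ann.kind}, expected {kind}")
        return ann

    def with_annotation(self, name: str, kind: str, values: Iterable) -> "SpotTable":
        """Return a copy with one annotation column added or replaced."""
        new = self.copy()
        ann = Annotation(kind, np.asarray(list(values) if not isinstance(values, np.ndarray) else values))
        if len(ann.values) != self.n:
            raise LengthMismatchError(
                f"annotation column {name!r} has length {len(ann.values)}, expected {self.n}"
            )
        new.annotations[name] = ann
        return new

    def copy(self) -> "SpotTable":
        diam = self.diameter
        if diam is not None and not np.isscalar(diam):
            diam = diam.copy()
        return SpotTable(
            ids=self.ids.copy(),
            x=self.x.copy(),
            y=self.y.copy(),
            diameter=diam,
            annotations={k: Annotation(a.kind, a.values.copy()) for k, a in self.annotations.items()},
        )

    def equals(self, other: "SpotTable") -> bool:
        if self.n != other.n or set(self.annotations) != set(other.annotations):
            return False
        if not (all(a == b for a, b in zip(self.ids, other.ids))
                and np.array_equal(self.x, other.x) and np.array_equal(self.y, other.y)):
            return False
        sd, od = self.diameter, other.diameter
        if (sd is None) != (od is None):
            return False
        if sd is not None:
            # scalar and constant per-record diameters describe the same spots
            a = np.broadcast_to(np.asarray(sd, dtype=float), (self.n,))
            b = np.broadcast_to(np.asarray(od, dtype=float), (self.n,))
            if not np.array_equal(a, b):
                return False
        return all(self.annotations[k].equals(other.annotations[k]) for k in self.annotations)


def validate_spot_table(table: SpotTable) -> SpotTable:
    """Validate all :class:`SpotTable` invariants; return the table unchanged.

    Raises
    ------
    DuplicateIdError, NonFiniteCoordinateError, LengthMismatchError,
    SpotLayerError
    """
    n = table.n
    if len(table.x) != n or len(table.y) != n:
        raise LengthMismatchError(
            f"coordinate length ({len(table.x)}, {len(table.y)}) != number of ids ({n})"
        )
    ids, counts = np.unique(table.ids.astype(str), return_counts=True)
    if np.any(counts > 1):
        dup = ids[counts > 1][0]
        raise DuplicateIdError(f"duplicate record id {dup!r}")
    if not (np.all(np.isfinite(table.x)) and np.all(np.isfinite(table.y))):
        bad = int(np.flatnonzero(~(np.isfinite(table.x) & np.isfinite(table.y)))[0])
        raise NonFiniteCoordinateError(f"non-finite coordinate at record {table.ids[bad]!r}")
    if table.diameter is not None:
        d = np.atleast_1d(np.asarray(table.diameter, dtype=float))
        if not np.isscalar(table.diameter) and d.size not in (1, n):
            raise LengthMismatchError(
                f"diameter has length {d.size}, expected 1 or {n}"
            )
        if not np.all(np.isfinite(d)) or np.any(d <= 0):
            raise SpotLayerError("diameter must be finite and strictly positive")
    for name, ann in table.annotations.items():
        if len(ann.values) != n:
            raise LengthMismatchError(
                f"annotation column {name!r} has length {len(ann.values)}, expected {n}"
            )
    return table


# --------------------------------------------------------------------------
# palettes


@dataclass
class Palette:
    """Deterministic value-to-color mapping.

    kind ``categorical``: an ordered ``label -> hex color`` mapping, injective
    up to the source palette's color count.  kind ``continuous``: a named
    colormap with an explicit ``(vmin, vmax)`` range; missing values get a
    dedicated neutral color instead of being dropped.
    """

    kind: str
    mapping: Optional[dict] = None
    cmap: Optional[str] = None
    vmin: Optional[float] = None
    vmax: Optional[float] = None
    missing_color: str = "#808080"

    def color_of(self, value) -> str:
        """Hex color for one value; missing values map to ``missing_color``."""
        if self.kind == CATEGORICAL:
            if value is None:
                return self.missing_color
            try:
                return self.mapping[value]
            except KeyError:
                raise PaletteError(f"label {value!r} not in palette") from None
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return self.missing_color
        cm = matplotlib.colormaps[self.cmap]
        if self.vmin == self.vmax:  # degenerate single-color scale
            return to_hex(cm(0.5))
        t = (float(value) - self.vmin) / (self.vmax - self.vmin)
        return to_hex(cm(min(max(t, 0.0), 1.0)))

    def colors_of(self, values: Sequence) -> list:
        return [self.color_of(v) for v in values]


def resolve_palette(labels: Sequence, palette_name: str = "tab10",
                    n_colors: Optional[int] = None) -> Palette:
    """Map category labels to distinct colors, deterministically.

    Labels are assigned colors in lexicographically sorted order, so the
    mapping depends only on the label set and palette name, never on row
    order.  Listed (qualitative) colormaps contribute their full color list;
    continuous colormaps are sampled at ``n_colors`` (default 10) evenly
    spaced points.

    Raises
    ------
    PaletteError
        If there are more labels than colors; supply a larger palette.
    """
    labels = sorted({str(l) for l in labels if l is not None})
    if not labels:
        raise PaletteError("cannot build a palette for an empty label set")
    try:
        cm = matplotlib.colormaps[palette_name]
    except KeyError:
        raise PaletteError(f"unknown palette {palette_name!r}") from None
    if isinstance(cm, ListedColormap) and n_colors is None:
        colors = [to_hex(c) for c in cm.colors]
    else:
        k = n_colors if n_colors is not None else 10
        colors = [to_hex(cm(t)) for t in np.linspace(0.0, 1.0, k)]
    if len(labels) > len(colors):
        raise PaletteError(
            f"{len(labels)} labels exceed the {len(colors)}-color palette "
            f"{palette_name!r}; supply a larger palette"
        )
    return Palette(kind=CATEGORICAL, mapping={l: colors[i] for i, l in enumerate(labels)})


def continuous_palette(vmin: float, vmax: float, cmap: str = "viridis",
                       missing_color: str = "#808080") -> Palette:
    """A continuous colormap scale over ``[vmin, vmax]``.

    ``vmin == vmax`` is allowed and degrades to a single-color scale.
    """
    if not (math.isfinite(vmin) and math.isfinite(vmax)) or vmin > vmax:
        raise PaletteError(f"invalid continuous range ({vmin}, {vmax})")
    if cmap not in matplotlib.colormaps:
        raise PaletteError(f"unknown colormap {cmap!r}")
    return Palette(kind=CONTINUOUS, cmap=cmap, vmin=float(vmin), vmax=float(vmax),
                   missing_color=missing_color)


# --------------------------------------------------------------------------
# layer and figure specs


@dataclass(frozen=True)
class LayerSpec:
    """One aesthetic binding: annotation column -> channel, with a scale.

    ``channel`` is one of ``ground`` (colored spot outline — the watercolor
    background layer), ``fill`` (spot interior — the figure layer) or
    ``symbol`` (glyph overlaid topmost).  Symbol layers carry a deterministic
    label -> glyph assignment in sorted label order.
    """

    channel: str
    variable: str
    scale: Palette
    glyph_map: Optional[tuple] = None  # tuple of (label, glyph) pairs

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise SpotLayerError(f"unknown channel {self.channel!r}")


@dataclass(frozen=True)
class HexFigureData:
    """Hexagon marks for an embedding figure: grid + aggregated bins + scales."""

    grid: object  # hexbin.HexGrid
    bins: tuple   # tuple of hexbin.HexBin
    fill_palette: Optional[Palette]
    boundary_palette: Optional[Palette]


@dataclass(frozen=True)
class FigureSpec:
    """An ordered stack of aesthetic layers over one coordinate system.

    Layer z-order is canonical — ground beneath fill beneath symbol — no
    matter in which order layers were added; at most one layer per channel.
    """

    data: SpotTable
    layer_map: Mapping[str, LayerSpec] = field(default_factory=dict)
    y_down: bool = False
    equal_aspect: bool = True
    title: Optional[str] = None
    hex_data: Optional[HexFigureData] = None

    @property
    def layers(self) -> tuple:
        """Layers in canonical z-order (ground, fill, symbol)."""
        return tuple(self.layer_map[c] for c in CHANNELS if c in self.layer_map)

    def layer(self, channel: str) -> Optional[LayerSpec]:
        return self.layer_map.get(channel)

    def with_layer(self, layer: LayerSpec) -> "FigureSpec":
        if layer.channel in self.layer_map:
            raise DuplicateChannelError(
                f"figure already has a {layer.channel} layer (variable "
                f"{self.layer_map[layer.channel].variable!r})"
            )
        new_map = dict(self.layer_map)
        new_map[layer.channel] = layer
        return dataclasses.replace(self, layer_map=new_map)
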