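"""Render figure specs to SVG/PNG/PDF with exact figure-ground geometry.

Marks are drawn in data units through the axes transform, so spot markers
keep their physical diameter relative to the array geometry (adjacent
spots touch exactly when the data says they do).  The ground channel is a
colored annulus of width ``ring_fraction x diameter`` around each spot —
the watercolor-effect outline — and the fill disc is shrunk to the ring's
inner radius so ring and disc tile the nominal diameter exactly, never
occluding one another.  Draw order is always ground < fill < symbol.

Each channel's marks are wrapped in an SVG group with a stable id
(``layer-ground``, ``layer-fill``, ``layer-symbol-*``, ``layer-hex``), so
vector output is machine-checkable; with ``deterministic=True`` output is
byte-identical across runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple, Union

import matplotlib
import numpy as np
from matplotlib import cm as _cm
from matplotlib import colors as mcolors
from matplotlib.collections import PatchCollection
from matplotlib.figure import Figure
from matplotlib.lines import Line2D
from matplotlib.patches import Annulus, Circle, Polygon

from . import hexbin as _hexbin
from .model import (
    CATEGORICAL,
    CHANNELS,
    CONTINUOUS,
    FigureSpec,
    SpotLayerError,
)

SUPPORTED_FORMATS = ("svg", "png", "pdf")

_HEX_DEFAULT_FILL = "#d9d9d9"
_HEX_DEFAULT_EDGE = "#404040"


class RenderError(SpotLayerError):
    pass


@dataclass
class RenderOptions:
    """Output options for :func:`render`.

    ``ring_fraction`` is the ground-outline width as a fraction of the spot
    diameter (0 < f < 0.5); ``deterministic`` strips timestamps/metadata and
    fixes internal hash salts so vector output is byte-reproducible.
    """

    format: Optional[str] = None  # inferred from the path suffix if None
    dpi: int = 150
    ring_fraction: float = 0.2
    figsize: Tuple[float, float] = (8.0, 8.0)
    legend: bool = True
    deterministic: bool = True
    hex_linewidth: float = 1.5
    symbol_size: float = 40.0  # glyph area in points^2

    def __post_init__(self) -> None:
        if not (0.0 < self.ring_fraction < 0.5):
            raise RenderError(
                f"ring_fraction must be in (0, 0.5), got {self.ring_fraction}"
            )
        if self.dpi < 36:
            raise RenderError(f"dpi must be >= 36, got {self.dpi}")
        if self.format is not None and self.format.lower() not in SUPPORTED_FORMATS:
            raise RenderError(
                f"unsupported format {self.format!r}; choose from {SUPPORTED_FORMATS}"
            )


@dataclass
class LegendBlock:
    """One legend block of the legend plan: swatches, glyphs or a colorbar."""

    channel: str
    variable: str
    kind: str  # "swatches" | "glyphs" | "colorbar"
    entries: List[Tuple[str, str]] = field(default_factory=list)
    cmap: Optional[str] = None
    vrange: Optional[Tuple[float, float]] = None


def compute_marker_geometry(diameter: float, transform, ring_fraction: float = 0.2):
    """Device-unit disc radius and ring width for a data-unit diameter.

    ``transform`` is a matplotlib data-to-device transform (or a plain
    scale factor).  Requires equal aspect: an anisotropic transform would
    render circular spots as ellipses, which is refused.
    """
    if np.isscalar(transform):
        sx = sy = float(transform)
    else:
        pts = np.asarray(transform.transform([(0.0, 0.0), (1.0, 0.0), (0.0, 1.0)]))
        sx = float(np.hypot(*(pts[1] - pts[0])))
        sy = float(np.hypot(*(pts[2] - pts[0])))
    if abs(sx - sy) > 1e-9 * max(sx, sy, 1.0):
        raise RenderError(
            f"non-equal-aspect axes (scale x={sx:g}, y={sy:g}): spot markers "
            "would render elliptical; use an equal-aspect figure"
        )
    return diameter / 2.0 * sx, ring_fraction * diameter * sx


def render_legends(spec: FigureSpec) -> List[LegendBlock]:
    """The legend plan: one block per active channel.

    Categorical entries list the observed labels in sorted order (not the
    palette's full color count); a continuous fill yields a colorbar block
    over the scale's (min, max).
    """
    blocks: List[LegendBlock] = []
    if spec.hex_data is not None:
        hd = spec.hex_data
        if hd.fill_palette is not None:
            blocks.append(LegendBlock(channel="fill", variable="mean", kind="colorbar",
                                      cmap=hd.fill_palette.cmap,
                                      vrange=(hd.fill_palette.vmin, hd.fill_palette.vmax)))
        if hd.boundary_palette is not None:
            labels = sorted({b.majority_label for b in hd.bins if b.majority_label is not None})
            blocks.append(LegendBlock(channel="ground", variable="majority", kind="swatches",
                                      entries=[(l, hd.boundary_palette.mapping[l]) for l in labels]))
        return blocks
    for channel in CHANNELS:
        layer = spec.layer(channel)
        if layer is None:
            continue
        ann = spec.data.annotation(layer.variable)
        if layer.scale.kind == CONTINUOUS:
            blocks.append(LegendBlock(channel=channel, variable=layer.variable,
                                      kind="colorbar", cmap=layer.scale.cmap,
                                      vrange=(layer.scale.vmin, layer.scale.vmax)))
        elif channel == "symbol":
            blocks.append(LegendBlock(channel=channel, variable=layer.variable,
                                      kind="glyphs", entries=list(layer.glyph_map)))
        else:
            labels = ann.labels()
            blocks.append(LegendBlock(channel=channel, variable=layer.variable,
                                      kind="swatches",
                                      entries=[(l, layer.scale.mapping[l]) for l in labels]))
    return blocks


def _default_diameter(spec: FigureSpec) -> np.ndarray:
    """Per-record diameters; defaults to 0.55x the median nearest-neighbor
    spacing when the table declares none (a spot-array-like fill factor)."""
    table = spec.data
    d = table.diameter
    if d is None:
        if table.n >= 2:
            from scipy.spatial import cKDTree

            pts = np.column_stack([table.x, table.y])
            dist, _ = cKDTree(pts).query(pts, k=2)
            spacing = float(np.median(dist[:, 1]))
            d = 0.55 * spacing if spacing > 0 else 1.0
        else:
            d = 1.0
    if np.isscalar(d):
        return np.full(table.n, float(d))
    return np.asarray(d, dtype=float)


def _infer_format(path: Path, options: RenderOptions) -> str:
    fmt = options.format or path.suffix.lstrip(".").lower()
    if fmt not in SUPPORTED_FORMATS:
        raise RenderError(
            f"unsupported format {fmt!r} for {path.name}; choose from {SUPPORTED_FORMATS}"
        )
    return fmt


def _draw_spot_layers(ax, spec: FigureSpec, options: RenderOptions) -> None:
    table = spec.data
    diam = _default_diameter(spec)
    ground = spec.layer("ground")
    fill = spec.layer("fill")
    symbol = spec.layer("symbol")
    if ground is not None:
        colors = ground.scale.colors_of(table.annotation(ground.variable).values)
        rings = [
            Annulus((table.x[i], table.y[i]), diam[i] / 2.0,
                    options.ring_fraction * diam[i])
            for i in range(table.n)
        ]
        pc = PatchCollection(rings, facecolors=colors, edgecolors="none", zorder=2)
        pc.set_gid("layer-ground")
        ax.add_collection(pc)
    if fill is not None:
        inner = diam / 2.0 - (options.ring_fraction * diam if ground is not None else 0.0)
        colors = fill.scale.colors_of(table.annotation(fill.variable).values)
        discs = [Circle((table.x[i], table.y[i]), inner[i]) for i in range(table.n)]
        pc = PatchCollection(discs, facecolors=colors, edgecolors="none", zorder=3)
        pc.set_gid("layer-fill")
        ax.add_collection(pc)
    if symbol is not None:
        values = table.annotation(symbol.variable).values
        for j, (label, glyph) in enumerate(symbol.glyph_map):
            mask = np.array([v == label for v in values])
            if not mask.any():
                continue
            sc = ax.scatter(table.x[mask], table.y[mask], marker=glyph,
                            c=symbol.scale.mapping[label], s=options.symbol_size,
                            zorder=4 + j)
            sc.set_gid(f"layer-symbol-{j}")
    pad = float(diam.max()) / 2.0 if table.n else 0.5
    _set_limits(ax, table.x, table.y, pad, spec.y_down)


def _draw_hex_layers(ax, spec: FigureSpec, options: RenderOptions) -> None:
    hd = spec.hex_data
    polys, facecolors, edgecolors = [], [], []
    for b in hd.bins:
        polys.append(Polygon(_hexbin.hex_vertices(b.axial, hd.grid), closed=True))
        if hd.fill_palette is not None:
            facecolors.append(hd.fill_palette.color_of(
                np.nan if b.mean_value is None else b.mean_value))
        else:
            facecolors.append(_HEX_DEFAULT_FILL)
        if hd.boundary_palette is not None and b.majority_label is not None:
            edgecolors.append(hd.boundary_palette.mapping[b.majority_label])
        elif hd.boundary_palette is not None:
            edgecolors.append(hd.boundary_palette.missing_color)
        else:
            edgecolors.append(_HEX_DEFAULT_EDGE)
    pc = PatchCollection(polys, facecolors=facecolors, edgecolors=edgecolors,
                         linewidths=options.hex_linewidth, zorder=2)
    pc.set_gid("layer-hex")
    ax.add_collection(pc)
    xs = np.array([v[0] for p in polys for v in p.get_xy()])
    ys = np.array([v[1] for p in polys for v in p.get_xy()])
    _set_limits(ax, xs, ys, hd.grid.R * 0.5, spec.y_down)


def _set_limits(ax, x, y, pad, y_down: bool) -> None:
    xmin, xmax = float(np.min(x)) - pad, float(np.max(x)) + pad
    ymin, ymax = float(np.min(y)) - pad, float(np.max(y)) + pad
    span = 0.02 * max(xmax - xmin, ymax - ymin, 1.0)
    ax.set_xlim(xmin - span, xmax + span)
    if y_down:
        ax.set_ylim(ymax + span, ymin - span)
    else:
        ax.set_ylim(ymin - span, ymax + span)


def _draw_legend_blocks(fig, ax, blocks: List[LegendBlock]) -> list:
    anchors = [1.00, 0.62, 0.28]
    n_legends = 0
    extra = []
    # a colorbar occupies the strip just right of the axes; push legends past it
    anchor_x = 1.18 if any(b.kind == "colorbar" for b in blocks) else 1.02
    for block in blocks:
        if block.kind == "colorbar":
            sm = _cm.ScalarMappable(
                norm=mcolors.Normalize(vmin=block.vrange[0], vmax=block.vrange[1]),
                cmap=block.cmap,
            )
            fig.colorbar(sm, ax=ax, label=block.variable, shrink=0.6, pad=0.02)
            continue
        handles = []
        for label, value in block.entries:
            if block.kind == "glyphs":
                handles.append(Line2D([], [], linestyle="", marker=value, color="#000000",
                                      label=label))
            elif block.channel == "ground":
                handles.append(Line2D([], [], linestyle="", marker="o",
                                      markerfacecolor="none", markeredgecolor=value,
                                      markeredgewidth=2.0, markersize=9, label=label))
            else:
                handles.append(Line2D([], [], linestyle="", marker="o",
                                      markerfacecolor=value, markeredgecolor="none",
                                      markersize=9, label=label))
        anchor_y = anchors[min(n_legends, len(anchors) - 1)]
        leg = ax.legend(handles=handles, title=block.variable, loc="upper left",
                        bbox_to_anchor=(anchor_x, anchor_y), frameon=False)
        ax.add_artist(leg)
        extra.append(leg)
        n_legends += 1
    return extra


def render(spec: FigureSpec, path: Union[str, Path],
           options: Optional[RenderOptions] = None) -> Path:
    """Render a figure spec to ``path`` (format from suffix or options).

    Spot specs draw one mark per record and active channel: a ground ring,
    a fill disc and/or a topmost glyph, each colored by its layer's scale.
    Hex specs draw one polygon per emitted bin with fill from the mean and
    boundary from the majority label.  One legend block per active channel.
    """
    options = options or RenderOptions()
    path = Path(path)
    fmt = _infer_format(path, options)
    if spec.hex_data is None:
        for layer in spec.layers:  # fail before drawing anything
            spec.data.annotation(layer.variable)

    rc = {}
    if options.deterministic:
        rc["svg.hashsalt"] = "spotlayer"
    with matplotlib.rc_context(rc):
        fig = Figure(figsize=options.figsize)
        ax = fig.add_subplot(111)
        if spec.equal_aspect:
            ax.set_aspect("equal", adjustable="box")
        if spec.hex_data is not None:
            _draw_hex_layers(ax, spec, options)
        else:
            _draw_spot_layers(ax, spec, options)
        if spec.title:
            ax.set_title(spec.title)
        extra_artists = []
        if options.legend:
            extra_artists = _draw_legend_blocks(fig, ax, render_legends(spec))
        metadata = None
        if options.deterministic:
            metadata = {"svg": {"Date": None},
                        "pdf": {"CreationDate": None},
                        "png": {"Software": None}}[fmt]
        try:
            fig.savefig(path, format=fmt, dpi=options.dpi, metadata=metadata,
                        bbox_inches="tight", bbox_extra_artists=extra_artists)
        except OSError as e:
            raise RenderError(f"cannot write {path}: {e}") from None
    return path
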