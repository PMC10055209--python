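"""Compose figure specifications by layering aesthetic channels.

The composition mirrors figure-ground layering: start from a bare plot of a
spot table, then bind one annotation column per channel — ``ground`` (spot
outline color, the perceptual background), ``fill`` (spot interior, the
figure) and ``symbol`` (glyph overlay for a third variable).  Specs are
immutable values; each ``add_*`` returns a new spec and the canonical
z-order (ground < fill < symbol) is imposed regardless of call order.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from . import hexbin as _hexbin
from .model import (
    CATEGORICAL,
    CONTINUOUS,
    ColumnError,
    FigureSpec,
    HexFigureData,
    LayerSpec,
    Palette,
    SpotTable,
    continuous_palette,
    resolve_palette,
    validate_spot_table,
)

DEFAULT_GLYPHS = ("+", "*", "x")


def make_plot(table: SpotTable, y_down: bool = False, equal_aspect: bool = True,
              title: Optional[str] = None) -> FigureSpec:
    """A figure spec with zero layers over a validated table.

    ``y_down`` flips the y-axis at render time (image-style coordinates, as
    produced by spot-array platforms); equal aspect defaults on so spatial
    geometry is not distorted.
    """
    return FigureSpec(data=validate_spot_table(table), y_down=y_down,
                      equal_aspect=equal_aspect, title=title)


def add_fill(spec: FigureSpec, variable: str, scale: Optional[Palette] = None,
             palette_name: str = "tab10", cmap: str = "viridis") -> FigureSpec:
    """Bind a column to the fill (figure) channel.

    Continuous columns get a colormap ranged over the observed (min, max);
    categorical columns get a deterministic label palette.
    """
    ann = spec.data.annotation(variable)
    if scale is None:
        if ann.kind == CONTINUOUS:
            finite = ann.values[~np.isnan(ann.values)]
            vmin, vmax = (float(finite.min()), float(finite.max())) if finite.size else (0.0, 1.0)
            scale = continuous_palette(vmin, vmax, cmap=cmap)
        else:
            scale = resolve_palette(ann.labels(), palette_name)
    return spec.with_layer(LayerSpec(channel="fill", variable=variable, scale=scale))


def add_ground(spec: FigureSpec, variable: str, palette_name: str = "tab10",
               scale: Optional[Palette] = None) -> FigureSpec:
    """Bind a categorical column to the ground channel.

    Ground renders as a colored outline ring around each spot (watercolor
    effect) and never occludes the fill; with no fill layer the spots are
    transparent-centered rings.
    """
    ann = spec.data.annotation(variable)
    if ann.kind != CATEGORICAL:
        raise ColumnError(
            f"ground channel requires a categorical column; {variable!r} is continuous"
        )
    if scale is None:
        scale = resolve_palette(ann.labels(), palette_name)
    return spec.with_layer(LayerSpec(channel="ground", variable=variable, scale=scale))


def add_symbol(spec: FigureSpec, variable: str,
               glyphs: Sequence[str] = DEFAULT_GLYPHS) -> FigureSpec:
    """Bind a categorical column to the symbol channel (topmost glyphs).

    Glyphs are assigned in sorted label order; records with a missing label
    draw no glyph.
    """
    ann = spec.data.annotation(variable)
    if ann.kind != CATEGORICAL:
        raise ColumnError(
            f"symbol channel requires a categorical column; {variable!r} is continuous"
        )
    labels = ann.labels()
    if len(labels) > len(glyphs):
        raise ColumnError(
            f"{len(labels)} labels exceed the {len(glyphs)}-glyph set for the symbol channel"
        )
    glyph_map = tuple((lab, glyphs[i]) for i, lab in enumerate(labels))
    scale = Palette(kind=CATEGORICAL, mapping={lab: "#000000" for lab in labels})
    return spec.with_layer(
        LayerSpec(channel="symbol", variable=variable, scale=scale, glyph_map=glyph_map)
    )


def categorize_coexpression(table: SpotTable, var_a: str, var_b: str,
                            thr_a: float = 0.0, thr_b: float = 0.0,
                            out_col: str = "coexpression") -> SpotTable:
    """Discretize two continuous columns into joint-expression categories.

    Per record: ``both`` if a > thr_a and b > thr_b; ``A_only`` if only
    a > thr_a; ``B_only`` if only b > thr_b; ``neither`` otherwise.
    Comparisons are strict, so the default thresholds of 0 mean "expressed
    at all" on count-scale data.  Records missing either value are
    categorized ``neither``.
    """
    a = table.annotation(var_a, CONTINUOUS).values
    b = table.annotation(var_b, CONTINUOUS).values
    complete = ~np.isnan(a) & ~np.isnan(b)
    pa = complete & (a > thr_a)
    pb = complete & (b > thr_b)
    labels = np.where(pa & pb, "both",
                      np.where(pa, "A_only", np.where(pb, "B_only", "neither")))
    return table.with_annotation(out_col, CATEGORICAL, labels.astype(object))


def hexbin_figure(table: SpotTable, nbins_x: int = 40,
                  continuous_var: Optional[str] = None,
                  categorical_var: Optional[str] = None,
                  cmap: str = "viridis", palette_name: str = "tab10",
                  y_down: bool = False) -> FigureSpec:
    """A figure whose marks are hexagon polygons over the binned table.

    Interior fill encodes the per-bin mean of ``continuous_var`` through a
    continuous colormap; the hexagon boundary encodes the bin's majority
    label of ``categorical_var`` through a categorical palette — the
    boundary plays the role convex hulls play in overlapping cluster
    annotations, without the membership ambiguity.
    """
    validate_spot_table(table)
    grid = _hexbin.build_hex_grid(table, nbins_x)
    bins = _hexbin.aggregate_bins(table, grid, continuous_var, categorical_var)
    fill_palette = None
    if continuous_var is not None:
        means = [b.mean_value for b in bins if b.mean_value is not None]
        vmin, vmax = (min(means), max(means)) if means else (0.0, 1.0)
        fill_palette = continuous_palette(vmin, vmax, cmap=cmap)
    boundary_palette = None
    if categorical_var is not None:
        labels = sorted({b.majority_label for b in bins if b.majority_label is not None})
        if labels:
            boundary_palette = resolve_palette(labels, palette_name)
    return FigureSpec(
        data=table,
        y_down=y_down,
        equal_aspect=True,
        hex_data=HexFigureData(grid=grid, bins=tuple(bins),
                               fill_palette=fill_palette,
                               boundary_palette=boundary_palette),
    )
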