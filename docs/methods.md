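# Methods

## The visualization model

spotlayer treats a 2D plot as an ordered stack of aesthetic layers over
one coordinate system. Each record (a spatial transcriptomics spot or an
embedding point) has an id, finite (x, y) coordinates in arbitrary data
units, an optional render diameter in those same units, and typed
annotation columns: *categorical* (finite label set, missing allowed) or
*continuous* (real, NaN = missing). Three channels can each be bound to
one column:

| channel | mark | role |
|---|---|---|
| ground  | annulus (ring) of width `ring_fraction x diameter` | background category via outline color (watercolor effect) |
| fill    | interior disc | the figure variable, categorical or continuous |
| symbol  | glyph (`+`, `*`, `x`) | sparse third variable, topmost |

The z-order ground < fill < symbol is canonical and independent of the
order in which layers are added; at most one layer per channel. The ground
ring and the fill disc exactly tile the nominal spot diameter: the ring is
an annulus with outer radius d/2 and width f·d (f = `ring_fraction`,
default 0.2, constrained to (0, 0.5)), and the disc is shrunk to radius
d/2 − f·d, so neither occludes the other and adjacent spots leave exactly
the gap the data dictates. All marks are drawn in data units through the
axes transform; non-equal-aspect axes are refused for spot markers because
circles would render elliptical.

Perceptually, the outline-only encoding relies on the watercolor effect:
a thin colored boundary induces the percept of a surface color, so the
background category reads as a coherent region even where spots are
densely packed and no inter-spot background is visible.

### Determinism

Color assignment for categorical scales sorts labels lexicographically and
maps them to a qualitative palette (default `tab10`, 10 colors; more
labels than colors is an error, not a silent wrap). Continuous scales use
a perceptually uniform colormap (default `viridis`) ranged over the
observed (min, max); a degenerate range (min = max) collapses to a single
color; missing values draw in a dedicated neutral gray rather than being
dropped, since dropped spots would distort a spatial map. With the
deterministic render flag (default on), SVG output is byte-identical
across runs: internal element ids are salted with a fixed string and
creation-date metadata is stripped.

## Hexagonal binning

Embedding overplotting is handled by tiling the plane with regular
pointy-top hexagons on an axial (q, r) lattice anchored at
(x_min, y_min), with centers

    x = x0 + sqrt(3) R (q + r/2),   y = y0 + 3/2 R r.

The grid is parameterized by `nbins_x` (default 40) hexagon widths across
the x-extent, so w = (x_max − x_min)/nbins_x and R = w/sqrt(3); a
single-point extent falls back to w = 1. Point assignment inverts the
center formula to fractional axial coordinates, lifts to cube coordinates
(q, r, s = −q − r), rounds each component and corrects the one with the
largest rounding error to restore q + r + s = 0. This returns the hexagon
with the nearest center; exact equidistance is resolved by the correction
rule itself, which we document as the canonical answer (the test oracle
treats distance differences below 1e-9 as don't-care).

Per bin: `count` (≥ 1 for emitted bins — empty bins are not emitted),
`mean_value` (arithmetic mean of the continuous variable, NaN excluded,
missing if all members are missing), and `majority_label` (most frequent
label; ties broken by lexicographically smallest; members with a missing
label count toward the bin total but toward no label). In the rendered
hex figure the interior encodes the mean through a continuous colormap
and the boundary encodes the majority label through a categorical
palette, each with its own legend.

## Coexpression categorization

Two continuous columns a, b with thresholds t_a, t_b map each record to
`both` (a > t_a and b > t_b), `A_only`, `B_only`, or `neither`; records
missing either value are `neither`. Comparisons are strict and thresholds
default to 0, i.e. "expressed at all" on count-scale data; for normalized
or log-scale expression the thresholds are parameters and should be set
to whatever the analysis defines as "expressed" — the package does not
guess a normalization.

## Synthetic data

The generators exist so every pipeline stage is testable without
downloads; they emulate structure, not transcriptome realism.

**Banded spot lattice.** Spots sit on an offset (hexagonally packed)
lattice with center spacing 100 and diameter 55 data units by default —
the tight-packing regime where outline-based ground rendering matters,
and where the minimum pairwise center distance exactly equals the
configured spacing. Rows split into horizontal bands of equal row count
(remainder to the last band), labeled L1–L6 and WM by default. Joint
expression of two genes is controlled per band: with probability
clip(p0 · multiplier_band) a spot expresses both genes; otherwise exactly
one gene with probability p0 each (mutually exclusive draw). Expressed
magnitudes are log-normal(0, 1) and unexpressed genes are exactly 0, so
strict thresholding at 0 recovers the configured joint rate; an optional
dropout rate zeroes expressed entries afterwards (default 0). Defaults
p0 = 0.1 with multipliers (1, 1, 1, 1, 1, 4, 1) make L6 the most
coexpression-enriched band (joint rate 0.4 versus 0.1 elsewhere), the
laminar structure the spatial use case is designed to exhibit.

**Embedding mixture.** k unit-spread 2D Gaussians with centers on a
circle of radius `separation` (default 20, so clusters are ~14 standard
deviations from the midpoint between adjacent centers and essentially
non-overlapping at k = 4); uniform cluster assignment; a `marker` column
of standard-normal noise plus `marker_shift` (default 3) in one cluster.

One global seed drives a dedicated `SeedSequence`-spawned stream per
generated column, so adding a column never perturbs existing ones.

What the generators do **not** emulate: spatial autocorrelation beyond
banding, count overdispersion, library-size variation, batch structure, or
realistic gene-gene correlation. Passing tests therefore demonstrate the
correctness of the binning, categorization and rendering contracts on
data with the right geometry and rates, not robustness to real-data noise.

## Numerical and design choices

- **Grid anchoring and bin count** are not dictated by the method; they
  are exposed (`nbins_x`, grid origin at the data minimum) and default to
  common hexbin-interface conventions.
- **Diameter default**: a table without a declared diameter renders spots
  at 0.55x the median nearest-neighbor spacing, mimicking a typical
  spot-array fill factor; declared diameters are never rescaled.
- **CSV typing**: headers carry `:cat`/`:num` suffixes on write; explicit
  column lists override on read; `""`, `NA`, `NaN` read as missing and
  missing writes as the empty string. Floats are written as shortest
  round-trippable decimals so write→read is the identity.
- **MTX convention**: 1-based indices on disk (MatrixMarket standard),
  0-based in memory; rows are features, columns barcodes; parsing is
  delegated to `scipy.io.mmread` with sidecar-length and non-negativity
  validation on top.
- **Raster outputs** (PNG) are validated by smoke tests only; all
  geometry, count, order and color assertions run on SVG, where
  antialiasing cannot blur exact checks.

## Problem sizes

The test suite and the acceptance script use 10,000 points for the
assignment oracle, 100 random tables for aggregation and round-trip
checks, 3,000 spots for the full render contract, 50,000 spots for rate
recovery (binomial 3-standard-error bands), and a 5,000-point 4-cluster
mixture for the hex figure — sizes at which binomial noise is well below
the effects being checked while the whole suite runs in seconds.

## Known limitations

- Only pointy-top hexagons; no flat-top or adaptive binning.
- Ground requires a categorical column; continuous backgrounds would need
  binning first.
- Legends are placed right of the axes with fixed anchors; very many
  blocks can collide vertically.
- SVG byte-determinism is guaranteed for a fixed matplotlib version only.
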