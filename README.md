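# spotlayer

Layered, figure-ground 2D visualizations for spot-based spatial
transcriptomics and embedding plots.

A recurring problem in spatial and single-cell analysis is showing several
variables on one 2D map: gene expression *and* the spatial domain each
capture spot belongs to, or cluster membership *and* a marker gene on a
UMAP. The usual answer — two plots side by side — forces the reader to
mentally align them. spotlayer instead assigns each variable its own
aesthetic channel on a single plot, exploiting figure-ground segmentation
from visual perception:

- **fill** — the spot's interior color carries the primary ("figure")
  variable, categorical or continuous;
- **ground** — a thin colored outline ring around each spot carries the
  background category (e.g. cortical layer). A thin boundary is enough to
  induce the percept of a surface color (the *watercolor effect*), so the
  background reads as a coherent region even when spots nearly touch;
- **symbol** — an optional glyph (`+`, `*`, `x`) overlaid topmost
  highlights a third, sparse variable.

Marks are drawn in data units, so spot diameters stay faithful to the
array geometry (e.g. 55 µm spots at 100 µm spacing never overlap), and
the z-order is always ground < fill < symbol.

For dense embeddings, spotlayer provides a hexagonal-binning mode: the
plane is tiled with regular pointy-top hexagons (axial coordinates; cube
rounding assigns each point to the hexagon with the nearest center), each
hexagon's interior encodes the mean of a continuous variable over its
members, and its **boundary** is colored by the majority category — an
unambiguous replacement for overlapping convex-hull cluster annotations.

## Worked example

Generate a synthetic cortex-like spot lattice (bands L1–L6 + white
matter, with joint expression of two genes enriched 4x in L6), categorize
per-spot coexpression, and summarize:

```python
import numpy as np
import spotlayer as sl

table = sl.generate_banded_domains(n_cols=50, n_rows=70, p0=0.1, seed=42)
table = sl.categorize_coexpression(table, "expr_A", "expr_B")

domains = table.annotation("domain").values
coexpr = table.annotation("coexpression").values
print(f"{table.n} spots")
for band in ("L1", "L2", "L3", "L4", "L5", "L6", "WM"):
    m = domains == band
    print(f"{band}: n={m.sum():4d}  both={np.mean(coexpr[m] == 'both'):.3f}")
```

which prints

```
3500 spots
L1: n= 500  both=0.116
L2: n= 500  both=0.082
L3: n= 500  both=0.120
L4: n= 500  both=0.084
L5: n= 500  both=0.126
L6: n= 500  both=0.418
WM: n= 500  both=0.090
```

The "both" fraction is the share of spots where both genes have counts
above 0; it sits near the configured base rate of 0.1 in every band
except L6, where the 4x enrichment multiplier drives it to ≈ 0.4. The
multi-dimensional map showing exactly this — domain as outline ring,
coexpression category as fill — is one composition chain away:

```python
spec = sl.make_plot(table, y_down=True)          # image-style y axis
spec = sl.add_ground(spec, "domain")             # watercolor outlines
spec = sl.add_fill(spec, "coexpression")         # figure layer
sl.render(spec, "cortex_map.svg")
```

The same from the shell, plus a hex-binned embedding figure:

```sh
spotlayer synth spatial --seed 42 --out spots.csv
spotlayer spatial --input spots.csv --coexpr expr_A,expr_B \
    --ground domain --fill coexpression --y-down --out cortex_map.svg

spotlayer synth embedding --seed 42 --out umap.csv
spotlayer hexbin --input umap.csv --nbins 30 \
    --mean marker --majority cluster --out umap_hex.svg
```

## Scope

Static figures only (SVG/PNG/PDF); spot- and point-based data on any 2D
coordinate system. No HDF5/AnnData ingestion, no faceting, no interactive
output, no image-based (segmentation) platforms.
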