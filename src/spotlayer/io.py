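"""Reading and writing spot tables (CSV/TSV) and sparse count matrices (MTX).

Column typing on disk follows a header-suffix convention: ``name:cat`` for
categorical and ``name:num`` for continuous columns, written by
:func:`write_spot_table` and recognized by :func:`read_spot_table`; explicit
column lists on read override the suffixes.  Missing values are written as
empty cells; ``""``, ``NA`` and ``NaN`` are accepted on read.  Coordinates
are never rescaled on read — marker sizing depends on data units.
"""

from __future__ import annotations

import difflib
import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .model import (
    CATEGORICAL,
    CONTINUOUS,
    Annotation,
    ColumnError,
    SpotLayerError,
    SpotTable,
    validate_spot_table,
)

logger = logging.getLogger(__name__)

MISSING_TOKENS = {"", "NA", "NaN"}

_SUFFIXES = {":cat": CATEGORICAL, ":num": CONTINUOUS}


class FormatError(SpotLayerError):
    """Malformed or inconsistent on-disk data."""


def _split_typed_header(name: str):
    for suf, kind in _SUFFIXES.items():
        if name.endswith(suf):
            return name[: -len(suf)], kind
    return name, None


def read_spot_table(
    path: Union[str, Path],
    id_col: str = "id",
    x_col: str = "x",
    y_col: str = "y",
    diameter_col: str = "diameter",
    categorical_cols: Optional[Sequence[str]] = None,
    continuous_cols: Optional[Sequence[str]] = None,
    delimiter: str = ",",
) -> SpotTable:
    """Read a delimited spot/point table into a validated :class:`SpotTable`.

    Typing comes from the ``:cat``/``:num`` header suffixes unless explicit
    ``categorical_cols``/``continuous_cols`` lists are given, which take
    precedence.  Undeclared, untyped columns are ignored with a logged
    notice.  ``diameter_col``, when present in the header, is read as the
    per-record render diameter.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    raw_cols = list(df.columns)
    base_of = {}
    kind_of = {}
    for raw in raw_cols:
        base, kind = _split_typed_header(raw)
        base_of[raw] = base
        if kind is not None:
            kind_of[base] = kind
    declared = {}
    for c in categorical_cols or ():
        declared[c] = CATEGORICAL
    for c in continuous_cols or ():
        if c in declared:
            raise ColumnError(f"column {c!r} declared both categorical and continuous")
        declared[c] = CONTINUOUS
    kind_of.update(declared)

    by_base = {base_of[raw]: raw for raw in raw_cols}
    for required, what in ((id_col, "id"), (x_col, "x"), (y_col, "y")):
        if required not in by_base:
            raise ColumnError(f"missing declared {what} column {required!r} in {path.name}")

    def numeric(raw: str, base: str) -> np.ndarray:
        cells = df[raw].to_numpy(dtype=object)
        out = np.empty(len(cells), dtype=float)
        for i, cell in enumerate(cells):
            s = str(cell).strip()
            if s in MISSING_TOKENS:
                out[i] = np.nan
                continue
            try:
                out[i] = float(s)
            except ValueError:
                raise FormatError(
                    f"unparsable numeric cell {s!r} in column {base!r} at data row {i + 1}"
                ) from None
        return out

    ids = df[by_base[id_col]].astype(str).to_numpy(dtype=object)
    x = numeric(by_base[x_col], x_col)
    y = numeric(by_base[y_col], y_col)
    diameter = None
    if diameter_col in by_base:
        d = numeric(by_base[diameter_col], diameter_col)
        diameter = float(d[0]) if len(set(d.tolist())) == 1 and len(d) else d

    reserved = {id_col, x_col, y_col, diameter_col}
    annotations = {}
    for raw in raw_cols:
        base = base_of[raw]
        if base in reserved:
            continue
        kind = kind_of.get(base)
        if kind is None:
            logger.info("ignoring undeclared column %r in %s", base, path.name)
            continue
        if kind == CONTINUOUS:
            annotations[base] = Annotation(CONTINUOUS, numeric(raw, base))
        else:
            vals = np.array(
                [None if str(c).strip() in MISSING_TOKENS else str(c) for c in df[raw]],
                dtype=object,
            )
            annotations[base] = Annotation(CATEGORICAL, vals)
    for c in declared:
        if c not in annotations and c not in reserved:
            raise ColumnError(f"missing declared column {c!r} in {path.name}")

    return validate_spot_table(
        SpotTable(ids=ids, x=x, y=y, diameter=diameter, annotations=annotations)
    )


def write_spot_table(table: SpotTable, path: Union[str, Path], delimiter: str = ",") -> None:
    """Write a spot table with typed headers so that reading it back
    reproduces an equal table (missing values become empty cells)."""
    path = Path(path)
    cols = {"id": table.ids, "x": table.x, "y": table.y}
    if table.diameter is not None:
        d = table.diameter
        cols["diameter:num"] = np.full(table.n, float(d)) if np.isscalar(d) else d
    for name, ann in table.annotations.items():
        suffix = ":num" if ann.kind == CONTINUOUS else ":cat"
        cols[f"{name}{suffix}"] = ann.values
    df = pd.DataFrame(cols)
    # repr-based float formatting: shortest round-trippable decimal
    for c in df.columns:
        if df[c].dtype == float:
            df[c] = df[c].map(lambda v: "" if np.isnan(v) else repr(float(v)))
    df = df.fillna("")
    df.to_csv(path, sep=delimiter, index=False)


# --------------------------------------------------------------------------
# sparse counts (MatrixMarket + sidecars)


@dataclass
class SparseCounts:
    """A features x barcodes sparse count matrix with name sidecars.

    On-disk MatrixMarket indices are 1-based; in memory everything is
    0-based.  Counts are non-negative.
    """

    matrix: scipy.sparse.coo_matrix
    feature_names: List[str]
    barcode_names: List[str]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_barcodes(self) -> int:
        return self.matrix.shape[1]

    def feature_vector(self, feature_name: str) -> np.ndarray:
        """Dense count vector over barcodes for one feature."""
        try:
            i = self.feature_names.index(feature_name)
        except ValueError:
            near = difflib.get_close_matches(feature_name, self.feature_names, n=3)
            hint = f"; nearest matches: {', '.join(near)}" if near else ""
            raise ColumnError(f"unknown feature {feature_name!r}{hint}") from None
        return np.asarray(self.matrix.tocsr()[i].todense()).ravel()


def _read_names(path: Union[str, Path]) -> List[str]:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        # sidecars may be single-column or TSV (name in first field)
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def read_sparse_counts(
    matrix_path: Union[str, Path],
    barcodes_path: Union[str, Path],
    features_path: Union[str, Path],
) -> SparseCounts:
    """Read a MatrixMarket coordinate matrix plus barcode/feature sidecars.

    Rows are features, columns are barcodes (the common genomics layout).
    Validates sidecar lengths against the declared dimensions and rejects
    negative counts.
    """
    matrix_path = Path(matrix_path)
    try:
        if matrix_path.suffix == ".gz":
            with gzip.open(matrix_path, "rb") as fh:
                m = scipy.io.mmread(fh)
        else:
            m = scipy.io.mmread(matrix_path)
    except ValueError as e:
        raise FormatError(f"malformed MatrixMarket file {matrix_path.name}: {e}") from None
    m = scipy.sparse.coo_matrix(m)
    features = _read_names(features_path)
    barcodes = _read_names(barcodes_path)
    if m.shape[0] != len(features):
        raise FormatError(
            f"features sidecar has {len(features)} names but matrix declares {m.shape[0]} rows"
        )
    if m.shape[1] != len(barcodes):
        raise FormatError(
            f"barcodes sidecar has {len(barcodes)} names but matrix declares {m.shape[1]} columns"
        )
    if m.nnz and m.data.min() < 0:
        raise FormatError("negative count in matrix")
    return SparseCounts(matrix=m, feature_names=features, barcode_names=barcodes)


def extract_feature(
    counts: SparseCounts,
    feature_name: str,
    table: SpotTable,
    column_name: Optional[str] = None,
) -> SpotTable:
    """Attach one feature's per-barcode count to a spot table as a new
    continuous column (0 where the matrix stores no entry).

    Every table id must appear among the barcode names.
    """
    vec = counts.feature_vector(feature_name)
    index = {b: i for i, b in enumerate(counts.barcode_names)}
    missing = [i for i in table.ids if i not in index]
    if missing:
        raise ColumnError(
            f"{len(missing)} table id(s) absent from barcodes, e.g. {missing[0]!r}"
        )
    values = np.array([vec[index[i]] for i in table.ids], dtype=float)
    return table.with_annotation(column_name or feature_name, CONTINUOUS, values)
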