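"""Readers and writers for the file formats the pipeline touches.

Counts travel as the standard 10x-style triplet (``matrix.mtx`` in Matrix
Market coordinate form with 1-based indices, plus ``features.tsv`` and
``barcodes.tsv``); spot geometry as a ``tissue_positions.csv`` table; region
annotation and niche labels as plain CSV.  Everything is validated on the way
in: the Visium array convention requires ``array_row`` and ``array_col`` to
share parity, counts must be non-negative integers, and companion files must
agree with the Matrix Market header.

Internally genes index rows and spots index columns (matching the on-disk
feature-by-barcode orientation); coordinates are 0-based in memory and 1-based
only inside the ``.mtx`` file, as the format requires.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "SpotGrid",
    "CountMatrix",
    "read_counts",
    "write_counts",
    "read_positions",
    "write_positions",
    "read_regions",
    "write_regions",
    "read_labels",
    "write_labels",
]

REGIONS = ("tumor", "benign", "unassigned")

POSITION_COLUMNS = ["barcode", "in_tissue", "array_row", "array_col", "slide_id"]


class FormatError(ValueError):
    """A file violated the expected on-disk format or an invariant."""


@dataclass
class SpotGrid:
    """Spot identities with slide and hex-array coordinates plus region labels.

    ``table`` is indexed by barcode (unique across slides) with columns
    ``slide_id``, ``array_row``, ``array_col``, ``in_tissue`` (bool) and
    ``region`` (one of tumor / benign / unassigned).  Spots with
    ``in_tissue == False`` are kept in the table but excluded from every
    analysis operation, mirroring Space Ranger's behaviour.
    """

    table: pd.DataFrame
    _pos_index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in ("slide_id", "array_row", "array_col", "in_tissue", "region") if c not in t.columns]
        if missing:
            raise FormatError(f"SpotGrid table missing columns: {missing}")
        if t.index.has_duplicates:
            dup = t.index[t.index.duplicated()].tolist()[:5]
            raise FormatError(f"duplicate barcodes in grid: {dup}")
        parity_bad = (t["array_row"].to_numpy() % 2) != (t["array_col"].to_numpy() % 2)
        if parity_bad.any():
            bad = t.index[parity_bad][0]
            raise FormatError(
                f"array_row/array_col parity violation at barcode {bad!r} "
                "(Visium convention: row and column indices share parity)"
            )
        key = pd.MultiIndex.from_frame(t[["slide_id", "array_row", "array_col"]])
        if key.has_duplicates:
            raise FormatError("duplicate (slide_id, array_row, array_col) positions")
        bad_region = set(t["region"]) - set(REGIONS)
        if bad_region:
            raise FormatError(f"unknown region labels: {sorted(bad_region)}")
        self._pos_index = {
            (s, int(r), int(c)): b
            for b, s, r, c in zip(t.index, t["slide_id"], t["array_row"], t["array_col"])
        }

    # -- convenience accessors -------------------------------------------------

    @property
    def barcodes(self) -> pd.Index:
        return self.table.index

    @property
    def analyzed(self) -> pd.Index:
        """Barcodes of in-tissue spots (the analysis universe)."""
        return self.table.index[self.table["in_tissue"].to_numpy()]

    def spot_at(self, slide_id: str, array_row: int, array_col: int):
        """Barcode at a lattice position, or None if no spot is there."""
        return self._pos_index.get((slide_id, int(array_row), int(array_col)))

    def region_of(self, barcode: str) -> str:
        return str(self.table.at[barcode, "region"])

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class CountMatrix:
    """Sparse non-negative integer gene-by-spot matrix of raw counts."""

    genes: list
    spots: list
    matrix: sp.csr_matrix  # shape (len(genes), len(spots))
    gene_meta: pd.DataFrame | None = None  # e.g. Ensembl IDs, carried only as metadata

    def __post_init__(self) -> None:
        self.matrix = sp.csr_matrix(self.matrix)
        if self.matrix.shape != (len(self.genes), len(self.spots)):
            raise FormatError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.genes)} genes x {len(self.spots)} spots"
            )
        if len(set(self.genes)) != len(self.genes):
            raise FormatError("duplicate gene symbols in CountMatrix")
        if len(set(self.spots)) != len(self.spots):
            raise FormatError("duplicate spot ids in CountMatrix")
        data = self.matrix.data
        if data.size:
            if np.any(data < 0):
                raise FormatError("negative count entries")
            if not np.all(np.equal(np.mod(data, 1), 0)):
                raise FormatError("non-integer count entries")

    def subset_spots(self, spot_ids) -> "CountMatrix":
        idx = pd.Index(self.spots).get_indexer(list(spot_ids))
        if (idx < 0).any():
            missing = [s for s, i in zip(spot_ids, idx) if i < 0][:5]
            raise KeyError(f"unknown spot ids: {missing}")
        return CountMatrix(list(self.genes), list(spot_ids), self.matrix[:, idx], self.gene_meta)

    def spot_totals(self) -> np.ndarray:
        return np.asarray(self.matrix.sum(axis=0)).ravel()


# ---------------------------------------------------------------------------
# counts triplet
# ---------------------------------------------------------------------------


def _dedupe_symbols(symbols: list[str]) -> list[str]:
    """Disambiguate duplicate gene symbols by suffixing .1, .2, ..."""
    seen: dict[str, int] = {}
    out = []
    for s in symbols:
        if s in seen:
            seen[s] += 1
            out.append(f"{s}.{seen[s]}")
        else:
            seen[s] = 0
            out.append(s)
    return out


def read_counts(mtx_path, features_path, barcodes_path) -> CountMatrix:
    """Read a 10x-style triplet into a :class:`CountMatrix`.

    ``features.tsv`` may have one column (symbol) or the 10x layout
    (id, symbol, ...); in the latter case column 2 supplies the symbol and
    column 1 is retained as metadata.  Duplicate symbols are suffixed.
    """
    for p in (mtx_path, features_path, barcodes_path):
        if not os.path.exists(p):
            raise FileNotFoundError(p)
    try:
        m = scipy.io.mmread(os.fspath(mtx_path))
    except Exception as e:  # malformed MTX
        raise FormatError(f"cannot parse Matrix Market file {mtx_path}: {e}") from e
    m = sp.coo_matrix(m)
    feats = pd.read_csv(features_path, sep="\t", header=None, dtype=str)
    bars = pd.read_csv(barcodes_path, sep="\t", header=None, dtype=str)
    if feats.shape[1] >= 2:
        symbols = feats.iloc[:, 1].tolist()
        meta = feats.rename(columns={0: "feature_id", 1: "symbol"})
    else:
        symbols = feats.iloc[:, 0].tolist()
        meta = None
    barcodes = bars.iloc[:, 0].tolist()
    if m.shape[0] != len(symbols):
        raise FormatError(
            f"matrix header declares {m.shape[0]} genes but features file has {len(symbols)}"
        )
    if m.shape[1] != len(barcodes):
        raise FormatError(
            f"matrix header declares {m.shape[1]} spots but barcodes file has {len(barcodes)}"
        )
    if m.data.size:
        if np.any(m.data < 0):
            raise FormatError("negative entry in counts matrix")
        if not np.all(np.equal(np.mod(m.data, 1), 0)):
            raise FormatError("non-integer entry in counts matrix")
    m = m.astype(np.int64)
    return CountMatrix(_dedupe_symbols(symbols), barcodes, m.tocsr(), meta)


def write_counts(m: CountMatrix, dir_path) -> dict:
    """Write ``matrix.mtx`` / ``features.tsv`` / ``barcodes.tsv`` under *dir_path*.

    Entries are emitted in column-major (spot-major) order so output is
    deterministic; indices in the .mtx are 1-based per the format.
    """
    os.makedirs(dir_path, exist_ok=True)
    paths = {
        "matrix": os.path.join(dir_path, "matrix.mtx"),
        "features": os.path.join(dir_path, "features.tsv"),
        "barcodes": os.path.join(dir_path, "barcodes.tsv"),
    }
    coo = m.matrix.tocoo()
    order = np.lexsort((coo.row, coo.col))
    with open(paths["matrix"], "w") as fh:
        fh.write("%%MatrixMarket matrix coordinate integer general\n")
        fh.write(f"{len(m.genes)} {len(m.spots)} {coo.nnz}\n")
        for i in order:
            fh.write(f"{coo.row[i] + 1} {coo.col[i] + 1} {int(coo.data[i])}\n")
    with open(paths["features"], "w") as fh:
        for g in m.genes:
            fh.write(f"{g}\n")
    with open(paths["barcodes"], "w") as fh:
        for b in m.spots:
            fh.write(f"{b}\n")
    return paths


# ---------------------------------------------------------------------------
# positions and regions
# ---------------------------------------------------------------------------


def read_positions(csv_path, regions_path=None) -> SpotGrid:
    """Read ``tissue_positions.csv`` (and optionally ``regions.csv``) into a grid.

    Required columns: barcode, in_tissue, array_row, array_col, slide_id.
    Region labels are joined from *regions_path* when given; barcodes absent
    from the regions table get region ``unassigned``.
    """
    df = pd.read_csv(csv_path, dtype={"barcode": str, "slide_id": str})
    missing = [c for c in POSITION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"positions file missing columns: {missing}")
    df = df.set_index("barcode")
    df["array_row"] = df["array_row"].astype(int)
    df["array_col"] = df["array_col"].astype(int)
    if (df["array_row"] < 0).any() or (df["array_col"] < 0).any():
        raise FormatError("negative array coordinates")
    df["in_tissue"] = df["in_tissue"].astype(int).astype(bool)
    if regions_path is not None:
        reg = pd.read_csv(regions_path, dtype=str)
        if not {"barcode", "region"} <= set(reg.columns):
            raise FormatError("regions file must have columns barcode, region")
        reg = reg.set_index("barcode")["region"]
        df["region"] = reg.reindex(df.index).fillna("unassigned")
    else:
        df["region"] = "unassigned"
    return SpotGrid(df[["slide_id", "array_row", "array_col", "in_tissue", "region"]])


def write_positions(grid: SpotGrid, csv_path) -> None:
    out = grid.table.reset_index()
    out = out.rename(columns={out.columns[0]: "barcode"})
    out["in_tissue"] = out["in_tissue"].astype(int)
    out[POSITION_COLUMNS].to_csv(csv_path, index=False)


def read_regions(csv_path) -> pd.Series:
    reg = pd.read_csv(csv_path, dtype=str)
    if not {"barcode", "region"} <= set(reg.columns):
        raise FormatError("regions file must have columns barcode, region")
    return reg.set_index("barcode")["region"]


def write_regions(grid: SpotGrid, csv_path) -> None:
    pd.DataFrame(
        {"barcode": grid.table.index, "region": grid.table["region"].to_numpy()}
    ).to_csv(csv_path, index=False)


# ---------------------------------------------------------------------------
# niche label tables
# ---------------------------------------------------------------------------


def write_labels(labels: pd.DataFrame, csv_path) -> None:
    """Write per-spot niche labels (barcode, label, stratum, score)."""
    out = labels.reset_index()
    out = out.rename(columns={out.columns[0]: "barcode"})
    out.to_csv(csv_path, index=False)


def read_labels(csv_path) -> pd.DataFrame:
    df = pd.read_csv(csv_path, dtype={"barcode": str})
    if "barcode" not in df.columns or "label" not in df.columns:
        raise FormatError("labels file must have columns barcode, label")
    return df.set_index("barcode")
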