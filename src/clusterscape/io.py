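"""Tabular input/output and the coordinate-conversion step feeding both backends.

Everything the pipeline touches on disk is plain CSV (RFC 4180, comma
delimiter, ``.`` decimal, UTF-8, mandatory header row).  Missing values are
accepted as empty cells or ``NA`` on read and written back as empty cells.

Three in-memory containers are defined here:

``GeneTable``
    Per-gene log2 fold-change and p-value across a stable list of
    conditions — the raw analytic input of the pipeline.
``PointCloud``
    Ordered point identifiers plus one (x, y[, z]) coordinate row each —
    the embedding substrate shared by every downstream stage.
``MetadataTable``
    Optional per-point display name, ordered hover fields and hyperlink,
    joined into the HTML viewer by id.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GeneTable",
    "PointCloud",
    "MetadataTable",
    "read_gene_table",
    "write_gene_table",
    "read_point_cloud",
    "write_point_cloud",
    "read_metadata_table",
    "convert_coordinates",
]

_MISSING_TOKENS = {"", "NA"}


@dataclass
class GeneTable:
    """Log2 fold-changes and p-values per gene across conditions.

    ``lfc`` and ``pval`` are DataFrames indexed by gene id with one column
    per condition (same index and columns in both); missing measurements
    are NaN.  Gene ids are unique, p-values lie in [0, 1].
    """

    lfc: pd.DataFrame
    pval: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.lfc.index.equals(self.pval.index):
            raise ValueError("lfc and pval tables must share one gene index")
        if list(self.lfc.columns) != list(self.pval.columns):
            raise ValueError("lfc and pval tables must share condition order")
        if self.lfc.index.has_duplicates:
            dups = self.lfc.index[self.lfc.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene_id values: {dups}")
        bad = (self.pval < 0) | (self.pval > 1)
        if bad.any().any():
            rows = self.pval.index[bad.any(axis=1)].tolist()
            raise ValueError(f"p-values outside [0, 1] for genes: {rows}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.lfc.index)

    @property
    def conditions(self) -> list[str]:
        return list(self.lfc.columns)

    @property
    def n_genes(self) -> int:
        return len(self.lfc.index)

    def equals(self, other: "GeneTable") -> bool:
        return self.lfc.equals(other.lfc) and self.pval.equals(other.pval)


@dataclass
class PointCloud:
    """Ordered ids with one 2- or 3-D coordinate row per id.

    2-D clouds keep z absent (shape (n, 2)); :func:`lift_to_3d` in the
    embedding module adds the z = 0 plane before 3-D-only operations.
    """

    ids: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.size == 0:
            self.coords = self.coords.reshape(0, self.coords.shape[1] if self.coords.ndim == 2 else 3)
        if self.coords.ndim != 2 or self.coords.shape[1] not in (2, 3):
            raise ValueError("coords must be an (n, 2) or (n, 3) array")
        if len(self.ids) != len(self.coords):
            raise ValueError("ids and coords must have equal length")
        if len(set(self.ids.tolist())) != len(self.ids):
            raise ValueError("duplicate ids in point cloud")
        if not np.all(np.isfinite(self.coords)):
            bad = self.ids[~np.isfinite(self.coords).all(axis=1)].tolist()
            raise ValueError(f"non-finite coordinates for ids: {bad}")

    @property
    def n_points(self) -> int:
        return len(self.ids)

    @property
    def dims(self) -> int:
        return self.coords.shape[1]

    def equals(self, other: "PointCloud") -> bool:
        return (
            self.dims == other.dims
            and list(self.ids) == list(other.ids)
            and np.array_equal(self.coords, other.coords)
        )


@dataclass
class MetadataTable:
    """Per-id display fields for the interactive viewer.

    ``table`` is indexed by point id.  A ``display_name`` column provides
    the hover header; a ``hyperlink`` column (optional) carries a URL
    opened on click; every other column is a hover field, shown in column
    order.
    """

    table: pd.DataFrame
    hover_fields: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ValueError("duplicate ids in metadata table")
        if not self.hover_fields:
            self.hover_fields = [
                c for c in self.table.columns if c not in ("display_name", "hyperlink")
            ]

    def get(self, point_id: str) -> dict | None:
        if point_id not in self.table.index:
            return None
        row = self.table.loc[point_id]
        name = row.get("display_name")
        link = row.get("hyperlink")
        return {
            "display_name": str(name) if pd.notna(name) else str(point_id),
            "hover_fields": [
                (f, "" if pd.isna(row[f]) else str(row[f])) for f in self.hover_fields
            ],
            "hyperlink": str(link) if (link is not None and pd.notna(link) and str(link)) else None,
        }


def _read_csv(path) -> pd.DataFrame:
    return pd.read_csv(
        path, dtype=str, keep_default_na=False, skip_blank_lines=True, encoding="utf-8"
    )


def _to_float(series: pd.Series, column: str) -> pd.Series:
    # float() is correctly rounded (unlike pandas' fast numeric parser),
    # which keeps write->read round-trips bit-exact at 17 significant digits
    cleaned = series.where(~series.isin(_MISSING_TOKENS), other=None)
    try:
        return cleaned.astype(float)
    except (ValueError, TypeError):
        for row, value in enumerate(cleaned):
            if value is None:
                continue
            try:
                float(value)
            except ValueError:
                raise ValueError(
                    f"non-numeric value {series.iloc[row]!r} in column {column!r} "
                    f"at data row {row}"
                ) from None
        raise


def read_gene_table(path, lfc_columns: list[str], pval_columns: list[str]) -> GeneTable:
    """Read a gene × condition table of log2FC and p-value columns.

    ``lfc_columns`` and ``pval_columns`` are paired by position; condition
    names follow ``lfc_columns``.  The first column of the file is taken
    as the gene id unless a ``gene_id`` column is present.
    """
    if len(lfc_columns) != len(pval_columns):
        raise ValueError("lfc_columns and pval_columns must pair up one-to-one")
    raw = _read_csv(path)
    id_col = "gene_id" if "gene_id" in raw.columns else raw.columns[0]
    for col in [id_col, *lfc_columns, *pval_columns]:
        if col not in raw.columns:
            raise KeyError(f"missing column {col!r} in {path}")
    if raw[id_col].duplicated().any():
        dups = raw[id_col][raw[id_col].duplicated()].tolist()
        raise ValueError(f"duplicate gene_id values: {dups}")
    index = pd.Index(raw[id_col], name="gene_id")
    lfc = pd.DataFrame(
        {c: _to_float(raw[c], c).to_numpy() for c in lfc_columns}, index=index
    )
    pval = pd.DataFrame(
        {c: _to_float(raw[c], c).to_numpy() for c in pval_columns}, index=index
    )
    bad = (pval < 0) | (pval > 1)
    if bad.any().any():
        row = int(np.flatnonzero(bad.any(axis=1).to_numpy())[0])
        raise ValueError(
            f"p-value outside [0, 1] at data row {row} (gene {index[row]!r})"
        )
    pval.columns = lfc.columns = pd.Index(lfc_columns)
    return GeneTable(lfc=lfc, pval=pval)


def write_gene_table(table: GeneTable, path, pval_suffix: str = "_pval") -> None:
    """Write a GeneTable to CSV with lfc columns followed by paired p-value columns."""
    out = pd.DataFrame(index=table.lfc.index)
    for cond in table.conditions:
        out[cond] = table.lfc[cond]
    for cond in table.conditions:
        out[cond + pval_suffix] = table.pval[cond]
    out.to_csv(path, index=True, na_rep="", float_format="%.17g", encoding="utf-8")


def read_point_cloud(path, dims: int = 3) -> PointCloud:
    """Read an ``id,x,y[,z]`` coordinate CSV into an ordered PointCloud."""
    if dims not in (2, 3):
        raise ValueError("dims must be 2 or 3")
    raw = _read_csv(path)
    needed = ["id", "x", "y"] + (["z"] if dims == 3 else [])
    for col in needed:
        if col not in raw.columns:
            raise KeyError(f"missing column {col!r} in {path} (dims={dims})")
    if raw["id"].duplicated().any():
        dups = raw["id"][raw["id"].duplicated()].tolist()
        raise ValueError(f"duplicate ids: {dups}")
    axes = needed[1:]
    coords = np.column_stack([_to_float(raw[c], c).to_numpy() for c in axes])
    finite = np.isfinite(coords).all(axis=1)
    if not finite.all():
        bad = raw["id"][~finite].tolist()
        raise ValueError(f"non-finite coordinates for ids: {bad}")
    return PointCloud(ids=raw["id"].to_numpy(dtype=object), coords=coords)


def write_point_cloud(cloud: PointCloud, path, labels=None) -> None:
    """Write a PointCloud as ``id,x,y[,z][,cluster]`` at full float precision."""
    cols = {"id": cloud.ids}
    for i, axis in enumerate("xyz"[: cloud.dims]):
        cols[axis] = cloud.coords[:, i]
    frame = pd.DataFrame(cols)
    if labels is not None:
        missing = set(cloud.ids.tolist()) - set(labels.ids.tolist())
        if missing:
            raise ValueError(f"labels missing ids: {sorted(missing)}")
        mapping = labels.to_dict()
        frame["cluster"] = [mapping[i] for i in cloud.ids]
    frame.to_csv(path, index=False, float_format="%.17g", encoding="utf-8")


def read_metadata_table(path) -> MetadataTable:
    """Read an id-keyed metadata CSV (columns beyond id/display_name/hyperlink become hover fields)."""
    raw = _read_csv(path)
    id_col = "id" if "id" in raw.columns else raw.columns[0]
    if raw[id_col].duplicated().any():
        raise ValueError("duplicate ids in metadata table")
    table = raw.set_index(id_col)
    table = table.where(~table.isin(_MISSING_TOKENS), other=np.nan)
    return MetadataTable(table=table)


# Axis convention: embeddings are z-up; Blender is natively z-up so the
# blenderview mapping is the identity, while the HTML renderer is y-up so
# htmlview maps (x, y, z) -> (x, z, -y).  Both mappings are isometries.
_TARGETS = ("htmlview", "blenderview")


def convert_coordinates(raw: PointCloud, target: str, inverse: bool = False) -> PointCloud:
    """Map a 3-D cloud into a backend's axis convention (or back with ``inverse``).

    ``blenderview`` keeps (x, y, z); ``htmlview`` emits (x, z, -y) so the
    viewer's vertical matches the embedding's z axis.  2-D input is
    rejected: lift it to z = 0 first.
    """
    if target not in _TARGETS:
        raise ValueError(f"unknown target {target!r}; expected one of {_TARGETS}")
    if raw.dims != 3:
        raise ValueError("convert_coordinates requires 3D coordinates; apply lift_to_3d first")
    x, y, z = raw.coords[:, 0], raw.coords[:, 1], raw.coords[:, 2]
    if target == "blenderview":
        coords = raw.coords.copy()
    elif not inverse:
        coords = np.column_stack([x, z, -y])
    else:
        coords = np.column_stack([x, -z, y])
    return PointCloud(ids=raw.ids.copy(), coords=coords)
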