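"""Cell-table data model and spatial graph construction.

The central object is :class:`CellTable`, a validated per-cell record table
with sample group, sample (donor), image, xy coordinates and an annotated
cell type (CT).  All spatial structure used downstream — Delaunay
triangulations, k-NN lists, distance-thresholded (epsilon-radius) graphs —
is derived from it per image; graphs never span images.

A cellular neighborhood (CN) labeling is a dense integer ``pandas.Series``
aligned to the table's cell ids.  A *CN instance* is a maximal connected
component of same-label cells under the per-image Delaunay graph.
"""

from __future__ import annotations

import math
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Delaunay, QhullError
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "SchemaError",
    "DegenerateGeometryError",
    "CellTable",
    "NeighborGraph",
    "CNInstancePartition",
    "FrequencyTable",
    "load_cell_table",
    "build_delaunay",
    "build_delaunay_graphs",
    "build_knn",
    "build_radius_graph",
    "cn_instances",
    "frequency_table",
    "check_labeling",
    "relabel_dense",
    "stack_graphs",
]

REQUIRED_COLUMNS = ("group", "sample", "image", "x", "y", "cell_type")


class SchemaError(ValueError):
    """Raised when an input table is missing required columns."""


class DegenerateGeometryError(ValueError):
    """Raised when an image has too few or collinear cells to triangulate."""


class CellTable:
    """Validated per-cell table.

    Parameters
    ----------
    df
        DataFrame indexed by unique cell id with columns
        ``group, sample, image, x, y, cell_type``.  Coordinates must be
        finite, cell types non-null.
    n_dropped
        Number of input rows rejected during loading (missing coordinate
        or cell type), kept for reporting.
    """

    def __init__(self, df: pd.DataFrame, n_dropped: int = 0):
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"cell table missing required columns: {missing}")
        if len(df) == 0:
            raise ValueError("cell table is empty")
        if not df.index.is_unique:
            raise ValueError("cell ids are not unique")
        xy = df[["x", "y"]].to_numpy(float)
        if not np.isfinite(xy).all():
            raise ValueError("non-finite coordinates in cell table")
        if df["cell_type"].isna().any():
            raise ValueError("missing cell types in cell table")
        self.df = df
        self.n_dropped = int(n_dropped)

    # -- basic accessors -------------------------------------------------
    @property
    def cell_ids(self) -> pd.Index:
        return self.df.index

    @property
    def n_cells(self) -> int:
        return len(self.df)

    @property
    def cell_types(self) -> list:
        """Sorted CT vocabulary T."""
        return sorted(self.df["cell_type"].unique().tolist())

    @property
    def images(self) -> list:
        return sorted(self.df["image"].unique().tolist())

    @property
    def donors(self) -> list:
        return sorted(self.df["sample"].unique().tolist())

    def image_view(self, image_id) -> pd.DataFrame:
        sub = self.df[self.df["image"] == image_id]
        if len(sub) == 0:
            raise KeyError(f"no cells in image {image_id!r}")
        return sub

    def coords(self, image_id) -> tuple[pd.Index, np.ndarray]:
        sub = self.image_view(image_id)
        return sub.index, sub[["x", "y"]].to_numpy(float)

    def __len__(self) -> int:
        return self.n_cells

    def __repr__(self) -> str:
        return (
            f"CellTable({self.n_cells} cells, {len(self.images)} images, "
            f"{len(self.cell_types)} cell types)"
        )


def load_cell_table(
    source,
    column_map: dict | None = None,
    delimiter: str = ",",
) -> CellTable:
    """Read a cell table from delimited text.

    ``column_map`` maps the canonical names
    ``group, sample, image, x, y, cell_type`` (and optionally ``cell_id``)
    to the column names present in the file.  Rows lacking a coordinate or
    a cell type are dropped; the count is recorded on the returned table.
    """
    raw = pd.read_csv(source, sep=delimiter)
    column_map = dict(column_map or {})
    rename = {column_map.get(k, k): k for k in REQUIRED_COLUMNS}
    missing = [src for src in rename if src not in raw.columns]
    if missing:
        raise SchemaError(f"input is missing columns: {missing}")
    df = raw.rename(columns=rename)
    id_col = column_map.get("cell_id", "cell_id")
    if id_col in df.columns:
        df = df.set_index(id_col)
        df.index.name = "cell_id"
    else:
        df.index = pd.RangeIndex(len(df), name="cell_id")
    df["x"] = pd.to_numeric(df["x"], errors="coerce")
    df["y"] = pd.to_numeric(df["y"], errors="coerce")
    ok = df["x"].notna() & df["y"].notna() & df["cell_type"].notna()
    n_dropped = int((~ok).sum())
    df = df.loc[ok, list(REQUIRED_COLUMNS)]
    if len(df) == 0:
        raise ValueError("no valid rows in input cell table")
    return CellTable(df, n_dropped=n_dropped)


@dataclass
class NeighborGraph:
    """Per-image spatial adjacency in CSR layout over cell positions.

    ``indices[indptr[i]:indptr[i+1]]`` are the positional neighbors of the
    i-th cell of the image (positions index into ``cell_ids``).  Delaunay
    and radius graphs are symmetric; k-NN lists are directed.  No
    self-loops.
    """

    image_id: object
    kind: str
    cell_ids: pd.Index
    indptr: np.ndarray
    indices: np.ndarray
    weights: np.ndarray | None = None
    params: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.cell_ids)

    def neighbors(self, pos: int) -> np.ndarray:
        return self.indices[self.indptr[pos] : self.indptr[pos + 1]]

    def neighbors_of(self, cell_id) -> list:
        pos = self.cell_ids.get_loc(cell_id)
        return [self.cell_ids[j] for j in self.neighbors(pos)]

    @property
    def adjacency(self) -> dict:
        """cell_id -> list of neighbor cell ids."""
        return {cid: self.neighbors_of(cid) for cid in self.cell_ids}

    @property
    def n_edges(self) -> int:
        """Undirected edge count for symmetric kinds, arc count for knn."""
        arcs = len(self.indices)
        return arcs // 2 if self.kind in ("delaunay", "radius") else arcs

    @property
    def mean_degree(self) -> float:
        return len(self.indices) / max(self.n, 1)

    def to_scipy(self) -> csr_matrix:
        data = self.weights if self.weights is not None else np.ones(len(self.indices))
        return csr_matrix((data, self.indices, self.indptr), shape=(self.n, self.n))


def _csr_from_pairs(n: int, pairs: np.ndarray, weights: np.ndarray | None = None):
    """Symmetric CSR from an array of undirected (i, j) pairs."""
    if len(pairs) == 0:
        indptr = np.zeros(n + 1, dtype=np.int64)
        return indptr, np.array([], dtype=np.int64), (None if weights is None else np.array([]))
    src = np.concatenate([pairs[:, 0], pairs[:, 1]])
    dst = np.concatenate([pairs[:, 1], pairs[:, 0]])
    w = None if weights is None else np.concatenate([weights, weights])
    order = np.lexsort((dst, src))
    src, dst = src[order], dst[order]
    if w is not None:
        w = w[order]
    counts = np.bincount(src, minlength=n)
    indptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
    return indptr, dst.astype(np.int64), w


def _jitter_duplicates(xy: np.ndarray, cell_ids: pd.Index) -> np.ndarray:
    """Deterministically perturb exact duplicate coordinates.

    Offsets are 1e-9 of the bounding-box diagonal, keyed by a CRC32 hash of
    the cell id, so triangulation is well defined while stored coordinates
    stay untouched.
    """
    _, inv, counts = np.unique(xy, axis=0, return_inverse=True, return_counts=True)
    dup = counts[inv] > 1
    if not dup.any():
        return xy
    diag = float(np.linalg.norm(xy.max(axis=0) - xy.min(axis=0)))
    scale = 1e-9 * (diag if diag > 0 else 1.0)
    out = xy.copy()
    for i in np.flatnonzero(dup):
        h = zlib.crc32(repr(cell_ids[i]).encode())
        u = (h % 10**9) / 10**9
        v = ((h // 7) % 10**9) / 10**9
        out[i, 0] += scale * (u - 0.5)
        out[i, 1] += scale * (v - 0.5)
    return out


def build_delaunay(cells: CellTable, image_id) -> NeighborGraph:
    """Delaunay triangulation adjacency of one image."""
    ids, xy = cells.coords(image_id)
    if len(ids) < 3:
        raise DegenerateGeometryError(
            f"image {image_id!r} has {len(ids)} cells; need >= 3 for Delaunay"
        )
    xy = _jitter_duplicates(xy, ids)
    try:
        tri = Delaunay(xy)
    except QhullError as err:
        raise DegenerateGeometryError(
            f"degenerate geometry (collinear cells?) in image {image_id!r}"
        ) from err
    simp = tri.simplices
    pairs = np.concatenate([simp[:, [0, 1]], simp[:, [1, 2]], simp[:, [0, 2]]])
    pairs = np.unique(np.sort(pairs, axis=1), axis=0)
    indptr, indices, _ = _csr_from_pairs(len(ids), pairs)
    return NeighborGraph(image_id, "delaunay", ids, indptr, indices)


def build_delaunay_graphs(cells: CellTable) -> dict:
    """Delaunay graph for every image of the table."""
    return {img: build_delaunay(cells, img) for img in cells.images}


def _tie_stable_nearest(xy: np.ndarray, m: int, chunk: int = 512):
    """Indices of the m nearest points for each row, self excluded.

    Exact distance ties are broken toward the lower row position (rows are
    in cell-id order).  Chunked O(n^2) — intended for desk-scale images.
    """
    n = len(xy)
    m = min(m, n - 1)
    out = np.empty((n, m), dtype=np.int64)
    pos = np.arange(n)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        d = np.linalg.norm(xy[start:stop, None, :] - xy[None, :, :], axis=2)
        d[np.arange(stop - start), pos[start:stop]] = np.inf  # exclude self
        order = np.lexsort((np.broadcast_to(pos, d.shape), d), axis=1)
        out[start:stop] = order[:, :m]
    return out


def build_knn(cells: CellTable, image_id, m: int) -> NeighborGraph:
    """Directed k-NN adjacency: each cell's min(m, n-1) nearest others."""
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    ids, xy = cells.coords(image_id)
    n = len(ids)
    if n < 2:
        raise DegenerateGeometryError(f"image {image_id!r} has a single cell")
    nn = _tie_stable_nearest(xy, m)
    k = nn.shape[1]
    indptr = np.arange(0, (n + 1) * k, k, dtype=np.int64)
    return NeighborGraph(image_id, "knn", ids, indptr, nn.ravel(), params={"m": m})


def build_radius_graph(
    cells: CellTable,
    image_id,
    eps: float | None = None,
    target_mean_degree: float | None = None,
) -> NeighborGraph:
    """Symmetric graph joining all pairs at distance <= eps.

    Exactly one of ``eps`` / ``target_mean_degree`` must be given.  With a
    target mean degree d, eps is the smallest pairwise-distance value whose
    graph reaches mean degree >= d (exact search over the sorted O(n^2)
    pairwise distances).  ``eps=inf`` yields the complete per-image graph.
    """
    if (eps is None) == (target_mean_degree is None):
        raise ValueError("give exactly one of eps / target_mean_degree")
    ids, xy = cells.coords(image_id)
    n = len(ids)
    if n < 2:
        raise DegenerateGeometryError(f"image {image_id!r} has a single cell")
    dist = pdist(xy)
    if target_mean_degree is not None:
        d = float(target_mean_degree)
        if d <= 0:
            raise ValueError("target mean degree must be > 0")
        srt = np.sort(dist)
        need = math.ceil(d * n / 2)  # edges needed for mean degree >= d
        if need > len(srt):
            warnings.warn(
                f"image {image_id!r}: no eps achieves mean degree {d}; "
                "falling back to complete graph"
            )
            eps = float(srt[-1])
        else:
            # smallest candidate distance whose inclusive count >= need
            uniq = np.unique(srt)
            counts = np.searchsorted(srt, uniq, side="right")
            eps = float(uniq[np.searchsorted(counts, need)])
    eps = float(eps)
    iu, ju = np.triu_indices(n, k=1)
    keep = squareform(dist)[iu, ju] <= eps if np.isfinite(eps) else np.ones(len(iu), bool)
    pairs = np.stack([iu[keep], ju[keep]], axis=1)
    dvals = squareform(dist)[pairs[:, 0], pairs[:, 1]] if len(pairs) else np.array([])
    indptr, indices, w = _csr_from_pairs(n, pairs, dvals)
    g = NeighborGraph(
        image_id, "radius", ids, indptr, indices, weights=w,
        params={"eps": eps, "target_mean_degree": target_mean_degree},
    )
    g.params["mean_degree"] = g.mean_degree
    return g


# -- labelings and instances ---------------------------------------------

def check_labeling(cells: CellTable, labeling: pd.Series) -> pd.Series:
    """Validate a CN labeling: integer label for every cell of the table."""
    if not cells.cell_ids.isin(labeling.index).all():
        missing = cells.cell_ids.difference(labeling.index)
        raise ValueError(f"labeling missing {len(missing)} cells")
    lab = labeling.reindex(cells.cell_ids)
    if lab.isna().any():
        raise ValueError("labeling contains missing values")
    return lab.astype(np.int64)


def relabel_dense(labeling: pd.Series) -> pd.Series:
    """Map labels onto 0..k-1 preserving their sorted order."""
    uniq = np.sort(labeling.unique())
    lut = {int(v): i for i, v in enumerate(uniq)}
    return labeling.map(lut).astype(np.int64)


@dataclass
class CNInstancePartition:
    """Maximal connected same-label components under per-image graphs."""

    instance_of: pd.Series  # cell_id -> instance_id
    info: pd.DataFrame      # index instance_id; columns image, cn, size

    @property
    def n_instances(self) -> int:
        return len(self.info)

    def size_per_cell(self) -> pd.Series:
        """Size of the instance each cell belongs to."""
        return self.instance_of.map(self.info["size"]).astype(np.int64)


def cn_instances(labeling: pd.Series, graphs: dict) -> CNInstancePartition:
    """Connected components of same-label edges, per image.

    ``graphs`` maps image id to that image's (typically Delaunay)
    NeighborGraph.  Images never merge.
    """
    instance_ids = {}
    rows = []
    offset = 0
    for img in sorted(graphs, key=repr):
        g = graphs[img]
        lab = labeling.reindex(g.cell_ids)
        if lab.isna().any():
            raise ValueError(f"labeling missing cells of image {img!r}")
        lab = lab.to_numpy(np.int64)
        adj = g.to_scipy().tocoo()
        same = lab[adj.row] == lab[adj.col]
        masked = csr_matrix(
            (np.ones(int(same.sum())), (adj.row[same], adj.col[same])),
            shape=(g.n, g.n),
        )
        n_comp, comp = connected_components(masked, directed=False)
        for c in range(n_comp):
            members = comp == c
            rows.append((offset + c, img, int(lab[members][0]), int(members.sum())))
        for cid, c in zip(g.cell_ids, comp):
            instance_ids[cid] = offset + int(c)
        offset += n_comp
    info = pd.DataFrame(rows, columns=["instance_id", "image", "cn", "size"])
    info = info.set_index("instance_id")
    inst = pd.Series(instance_ids, name="instance_id")
    return CNInstancePartition(inst, info)


# -- frequency tables -----------------------------------------------------

@dataclass
class FrequencyTable:
    """CT frequency marginals and per-donor / per-donor-per-CN conditionals.

    ``overall`` is F(t); ``per_donor`` F^d(t) (donors x T, rows sum to 1);
    ``per_donor_cn`` F_n^d(t) (MultiIndex (donor, cn) x T, rows sum to 1
    for nonempty (d, n)).  ``counts`` keeps the underlying integer tables.
    """

    overall: pd.Series
    per_donor: pd.DataFrame | None = None
    per_donor_cn: pd.DataFrame | None = None
    counts: dict | None = None


def frequency_table(
    cells: CellTable,
    labeling: pd.Series | None = None,
    donor_col: str = "sample",
) -> FrequencyTable:
    """Compute F(t), F^d(t) and (with a labeling) F_n^d(t) from a table."""
    df = cells.df
    ct_counts = df["cell_type"].value_counts().sort_index()
    overall = ct_counts / ct_counts.sum()
    donor_ct = pd.crosstab(df[donor_col], df["cell_type"])
    per_donor = donor_ct.div(donor_ct.sum(axis=1), axis=0)
    per_donor_cn = None
    counts = {"C": len(df), "Ct": ct_counts}
    if labeling is not None:
        lab = check_labeling(cells, labeling)
        tmp = df.assign(cn=lab.to_numpy())
        dcn_ct = pd.crosstab([tmp[donor_col], tmp["cn"]], tmp["cell_type"])
        per_donor_cn = dcn_ct.div(dcn_ct.sum(axis=1), axis=0)
        cn_ct = pd.crosstab(tmp["cn"], tmp["cell_type"])
        counts["Cn"] = cn_ct.sum(axis=1)
        counts["Cnt"] = cn_ct
    return FrequencyTable(overall, per_donor, per_donor_cn, counts)


def stack_graphs(cells: CellTable, graphs: dict):
    """Concatenate per-image graphs into one CSR over the table's row order.

    Returns ``(indptr, indices)`` with indices positional in
    ``cells.df`` row order; used by the spatially regularized clustering
    and the smoothers.
    """
    pos_of = pd.Series(np.arange(cells.n_cells), index=cells.cell_ids)
    nbr_lists = [()] * cells.n_cells
    for img, g in graphs.items():
        gpos = pos_of.reindex(g.cell_ids).to_numpy(np.int64)
        for i in range(g.n):
            nbr_lists[gpos[i]] = gpos[g.neighbors(i)]
    indptr = np.zeros(cells.n_cells + 1, dtype=np.int64)
    indptr[1:] = np.cumsum([len(v) for v in nbr_lists])
    indices = np.concatenate([np.asarray(v, dtype=np.int64) for v in nbr_lists]) \
        if cells.n_cells else np.array([], dtype=np.int64)
    return indptr, indices
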