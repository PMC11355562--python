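"""Cellular-neighborhood identification.

Three methods, all clustering pooled across images so CN labels are
comparable between samples:

* **CC** — each cell is represented by the CT histogram over its nearest
  ``m`` points (itself included) and cells are clustered by plain k-means.
* **CF-IDF** — per-image Louvain communities on a distance-weighted
  epsilon-radius graph; each community's CT frequency vector is rescaled
  by the log inverse dataset-wide CT frequency (the "inverse dataset
  frequency" factor) and communities are clustered by k-means; cells
  inherit their community's CN.
* **CNE** (cellular neighbor embedding) — each cell is represented by
  distance-weighted CT densities under a per-cell Gaussian whose bandwidth
  is calibrated to a target perplexity (t-SNE style), IDF-rescaled, and
  clustered by spatially regularized k-means in which a cell pays a
  penalty for choosing a centroid far from its Delaunay neighbors'
  centroids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist
from sklearn.cluster import kmeans_plusplus

from .tissue import (
    CellTable,
    FrequencyTable,
    NeighborGraph,
    build_delaunay_graphs,
    build_radius_graph,
    frequency_table,
    relabel_dense,
)

__all__ = [
    "CellRepresentation",
    "GaussianBandwidths",
    "IdentificationResult",
    "overall_ct_frequencies",
    "cc_representations",
    "cne_bandwidths",
    "cne_representations",
    "spatially_regularized_kmeans",
    "identify_cc",
    "identify_cne",
    "cfidf_weighted_graph",
    "identify_cfidf",
]


@dataclass
class CellRepresentation:
    """Nonnegative per-cell feature vectors over the CT vocabulary."""

    values: pd.DataFrame  # index cell_id, columns CT vocabulary
    stage: str = "normalized"  # "raw_density" | "normalized"

    def __post_init__(self):
        if (self.values.to_numpy() < -1e-12).any():
            raise ValueError("cell representations must be nonnegative")


def overall_ct_frequencies(cells: CellTable) -> FrequencyTable:
    """Dataset-wide CT frequencies F(t), all images pooled."""
    return frequency_table(cells)


# ---------------------------------------------------------------------------
# CC
# ---------------------------------------------------------------------------

def cc_representations(cells: CellTable, m: int) -> CellRepresentation:
    """CT histogram over each cell's nearest m points, itself included.

    ``m`` counts total points (self plus m-1 others).  Exact distance ties
    at the cutoff are broken toward the lower cell id.  Rows are
    l1-normalized.
    """
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    vocab = cells.cell_types
    code = {t: i for i, t in enumerate(vocab)}
    ct_codes = cells.df["cell_type"].map(code).to_numpy(np.int64)
    pos_of = pd.Series(np.arange(cells.n_cells), index=cells.cell_ids)
    out = np.zeros((cells.n_cells, len(vocab)))
    from .tissue import _tie_stable_nearest

    for img in cells.images:
        ids, xy = cells.coords(img)
        gpos = pos_of.reindex(ids).to_numpy(np.int64)
        n = len(ids)
        m_img = m
        if m > n:
            warnings.warn(f"m={m} exceeds image {img!r} size {n}; clamped")
            m_img = n
        nn = _tie_stable_nearest(xy, m_img - 1) if m_img > 1 else np.empty((n, 0), np.int64)
        window = np.concatenate([np.arange(n)[:, None], nn], axis=1)
        cts = ct_codes[gpos[window]]
        for i in range(n):
            out[gpos[i]] = np.bincount(cts[i], minlength=len(vocab))
    out /= out.sum(axis=1, keepdims=True)
    return CellRepresentation(
        pd.DataFrame(out, index=cells.cell_ids, columns=vocab), stage="normalized"
    )


# ---------------------------------------------------------------------------
# CNE: perplexity-adaptive Gaussian bandwidths
# ---------------------------------------------------------------------------

@dataclass
class GaussianBandwidths:
    """Per-cell Gaussian bandwidths calibrated to a target perplexity.

    ``dist`` holds clamped distances, one row per cell in table order:
    column 0 is the self distance (clamped up to the nearest-neighbor
    distance) followed by up to ``cap`` neighbor distances; missing
    neighbors are padded with +inf.  ``neighbor_ct`` holds the CT code of
    each entry (self first).  ``sigma`` is NaN for cells with no
    neighbor in their image.
    """

    cell_ids: pd.Index
    dist: np.ndarray          # (n, cap+1) clamped distances
    neighbor_ct: np.ndarray   # (n, cap+1) CT codes, -1 pad
    sigma: np.ndarray         # (n,)
    perp: float
    cap: int
    vocab: list
    convention: str = "tsne"
    flags: pd.DataFrame = field(default_factory=pd.DataFrame)

    def densities(self) -> np.ndarray:
        """Unnormalized Gaussian kernel values q_{y|x} (n, cap+1)."""
        with np.errstate(invalid="ignore", over="ignore"):
            q = np.exp(-self.dist**2 / (2.0 * self.sigma[:, None] ** 2))
        q[~np.isfinite(self.dist)] = 0.0
        return q

    def conditional(self) -> np.ndarray:
        """Normalized p_{y|x}; rows sum to 1 where sigma is defined."""
        q = self.densities()
        s = q.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            return np.where(s > 0, q / s, 0.0)


def _perplexity_of(dist: np.ndarray, sigma: np.ndarray, convention: str) -> np.ndarray:
    """Achieved perplexity per row for given bandwidths (vectorized)."""
    finite = np.isfinite(dist)
    with np.errstate(invalid="ignore", divide="ignore"):
        logq = -(dist**2) / (2.0 * sigma[:, None] ** 2)
    logq[~finite] = -np.inf
    mx = logq.max(axis=1, keepdims=True)
    q = np.exp(logq - mx)
    s = q.sum(axis=1, keepdims=True)
    p = q / s
    with np.errstate(invalid="ignore", divide="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    h_nats = -plogp.sum(axis=1)
    if convention == "tsne":
        return np.exp2(h_nats / np.log(2.0))  # 2 ** H_bits
    if convention == "printed":
        return h_nats  # the entropy value itself, in nats
    raise ValueError(f"unknown perplexity convention {convention!r}")


def cne_bandwidths(
    cells: CellTable,
    perp: float,
    cap: int = 30,
    convention: str = "tsne",
    tol: float = 1e-5,
) -> GaussianBandwidths:
    """Solve each cell's Gaussian bandwidth for a target perplexity.

    Each cell's kernel support is its ``cap`` nearest other cells in the
    same image plus itself; its self distance is clamped up to the
    nearest-neighbor distance (so the self term never dominates).  The
    bandwidth is found by bisection on the monotone perplexity curve; an
    infeasible target is clamped to the achievable range with a warning,
    and cells whose perplexity curve is flat (all support points
    equidistant) are flagged and assigned the mean support distance.

    The default convention solves ``2**H2(p) = perp`` with the entropy in
    bits (the t-SNE convention, effective-neighbor scale up to cap+1);
    ``convention="printed"`` instead solves ``sum p ln(1/p) = perp``,
    whose achievable ceiling is only ln(cap+1).
    """
    if perp <= (1.0 if convention == "tsne" else 0.0):
        raise ValueError("perplexity target too small")
    if cap < 1:
        raise ValueError("cap must be >= 1")
    n = cells.n_cells
    vocab = cells.cell_types
    code = {t: i for i, t in enumerate(vocab)}
    ct_codes = cells.df["cell_type"].map(code).to_numpy(np.int64)
    pos_of = pd.Series(np.arange(n), index=cells.cell_ids)

    dist = np.full((n, cap + 1), np.inf)
    nct = np.full((n, cap + 1), -1, dtype=np.int64)
    lonely = np.zeros(n, dtype=bool)
    for img in cells.images:
        ids, xy = cells.coords(img)
        gpos = pos_of.reindex(ids).to_numpy(np.int64)
        n_img = len(ids)
        if n_img == 1:
            lonely[gpos[0]] = True
            nct[gpos[0], 0] = ct_codes[gpos[0]]
            dist[gpos[0], 0] = 0.0
            continue
        k = min(cap + 1, n_img)  # self + up to cap others
        tree = cKDTree(xy)
        d, j = tree.query(xy, k=k)
        d, j = np.atleast_2d(d), np.atleast_2d(j)
        # drop the self column (distance 0, index == row)
        self_col = j == np.arange(n_img)[:, None]
        # keep first k-1 non-self entries per row
        for row in range(n_img):
            others = np.flatnonzero(~self_col[row])[: k - 1]
            dd = d[row, others]
            dmin = dd[0]
            dist[gpos[row], 0] = dmin  # clamped self distance
            dist[gpos[row], 1 : 1 + len(dd)] = np.maximum(dd, dmin)
            nct[gpos[row], 0] = ct_codes[gpos[row]]
            nct[gpos[row], 1 : 1 + len(dd)] = ct_codes[gpos[j[row, others]]]

    sigma = np.full(n, np.nan)
    flat = np.zeros(n, dtype=bool)
    clamped = np.zeros(n, dtype=bool)
    active = ~lonely
    if active.any():
        D = dist[active]
        finite = np.isfinite(D)
        n_support = finite.sum(axis=1)
        meand = np.where(finite, D, 0.0).sum(axis=1) / n_support
        meand = np.maximum(meand, 1e-300)
        # feasible range of the perplexity curve
        big = meand * 1e12
        small = meand * 1e-12
        lo_val = _perplexity_of(D, small, convention)
        hi_val = _perplexity_of(D, big, convention)
        flat_a = (hi_val - lo_val) < tol
        target = np.clip(perp, lo_val + tol, hi_val)
        clamped_a = ~np.isclose(target, perp) & ~flat_a
        if clamped_a.any():
            warnings.warn(
                f"perplexity target {perp} infeasible for {int(clamped_a.sum())} "
                "cells; clamped to the achievable range"
            )
        lo = small.copy()
        hi = big.copy()
        for _ in range(200):
            mid = np.sqrt(lo * hi)
            val = _perplexity_of(D, mid, convention)
            too_low = val < target
            lo = np.where(too_low, mid, lo)
            hi = np.where(too_low, hi, mid)
        sig = np.sqrt(lo * hi)
        sig[flat_a] = meand[flat_a]
        sigma[active] = sig
        flat[active] = flat_a
        clamped[active] = clamped_a

    flags = pd.DataFrame(
        {"flat": flat, "clamped": clamped, "no_neighbors": lonely},
        index=cells.cell_ids,
    )
    return GaussianBandwidths(
        cells.cell_ids, dist, nct, sigma, perp, cap, vocab, convention, flags
    )


def cne_representations(
    bw: GaussianBandwidths, freqs: FrequencyTable, idf: bool = True
) -> CellRepresentation:
    """Distance-weighted CT frequency vectors from calibrated kernels.

    f_t(x) sums the unnormalized Gaussian densities of the support cells
    of CT t (self included); rows are l1-normalized and, with
    ``idf=True``, multiplied element-wise by ln(1/F(t)).  A degenerate
    single-CT vocabulary makes every IDF-scaled vector zero; it is
    reported with a warning rather than an error.
    """
    n, width = bw.dist.shape
    d = len(bw.vocab)
    F = freqs.overall.reindex(bw.vocab).to_numpy(float)
    if np.any(~(F > 0)):
        raise ValueError("overall frequency must be positive for every CT")
    q = bw.densities()
    # cells with no neighbors: one-hot of own CT
    lonely = bw.flags["no_neighbors"].to_numpy()
    q[lonely, 0] = 1.0
    out = np.zeros((n, d))
    valid = bw.neighbor_ct >= 0
    rows = np.repeat(np.arange(n), width).reshape(n, width)
    np.add.at(out, (rows[valid], bw.neighbor_ct[valid]), q[valid])
    norms = out.sum(axis=1, keepdims=True)
    assert (norms > 0).all(), "self term guarantees a positive row sum"
    out = out / norms
    if idf:
        idf_w = np.log(1.0 / F)
        if np.allclose(idf_w, 0.0):
            warnings.warn("single-CT vocabulary: IDF-scaled representations are all zero")
        out = out * idf_w[None, :]
    return CellRepresentation(
        pd.DataFrame(out, index=bw.cell_ids, columns=bw.vocab),
        stage="normalized" if idf else "raw_density",
    )


# ---------------------------------------------------------------------------
# spatially regularized k-means
# ---------------------------------------------------------------------------

def _stack_positional(index: pd.Index, graphs: dict | None):
    """CSR neighbor arrays positional in ``index`` order, or None."""
    if graphs is None:
        return None, None
    pos_of = pd.Series(np.arange(len(index)), index=index)
    lists = [np.array([], dtype=np.int64)] * len(index)
    for g in graphs.values():
        gpos = pos_of.reindex(g.cell_ids).to_numpy(np.int64)
        for i in range(g.n):
            lists[gpos[i]] = gpos[g.neighbors(i)]
    indptr = np.zeros(len(index) + 1, dtype=np.int64)
    indptr[1:] = np.cumsum([len(v) for v in lists])
    indices = np.concatenate(lists) if len(index) else np.array([], dtype=np.int64)
    return indptr, indices


def _assignment_cost(
    X: np.ndarray,
    centers: np.ndarray,
    labels: np.ndarray,
    indptr: np.ndarray | None,
    indices: np.ndarray | None,
    lam: float,
) -> np.ndarray:
    """Per-cell, per-cluster assignment objective.

    ``cost[x, n] = ||f(x) - c_n||^2 + (lam/|G_x|) *
    sum_{y in G_x} ||c_n - c_{labels[y]}||^2`` with neighbor labels taken
    as given (synchronous update); cells without neighbors get no
    regularization term.
    """
    from scipy.sparse import csr_matrix

    cost = cdist(X, centers, "sqeuclidean")
    if lam > 0 and indptr is not None:
        n, k = len(X), len(centers)
        deg = np.diff(indptr).astype(float)
        safe_deg = np.where(deg > 0, deg, 1.0)
        D = cdist(centers, centers, "sqeuclidean")
        S = csr_matrix((np.ones(len(indices)), indices, indptr), shape=(n, n)) @ csr_matrix(
            (np.ones(n), (np.arange(n), labels)), shape=(n, k)
        )
        cost = cost + lam * (S.toarray() / safe_deg[:, None]) @ D
    return cost


def spatially_regularized_kmeans(
    reps: CellRepresentation | pd.DataFrame,
    graphs: dict | None,
    k: int,
    lam: float = 0.25,
    seed: int = 0,
    max_iter: int = 300,
) -> pd.Series:
    """k-means with a neighbor-label coherence penalty.

    The assignment of cell x minimizes ``||f(x)-c_n||^2 +
    (lam/|G_x|) * sum_{y in G_x} ||c_n - c_{n_y}||^2`` where neighbor
    labels n_y are taken from the previous iteration (synchronous
    update).  ``lam=0`` (graphs may then be None) reduces to standard
    Lloyd k-means from the same k-means++ init.  Ties break toward the
    lower CN index.  Returns a densely relabeled Series.
    """
    X = reps.values.to_numpy(float) if isinstance(reps, CellRepresentation) else reps.to_numpy(float)
    index = reps.values.index if isinstance(reps, CellRepresentation) else reps.index
    n = len(X)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds number of cells {n}")
    if lam > 0 and graphs is None:
        raise ValueError("graphs are required when lam > 0")
    indptr, indices = _stack_positional(index, graphs) if lam > 0 else (None, None)
    centers, _ = kmeans_plusplus(X, n_clusters=k, random_state=seed)
    labels = np.argmin(cdist(X, centers, "sqeuclidean"), axis=1)

    for _ in range(max_iter):
        # centroid update from current labels; empty clusters re-seeded
        # to the point farthest from its centroid
        for c in range(k):
            mask = labels == c
            if mask.any():
                centers[c] = X[mask].mean(axis=0)
        d2 = cdist(X, centers, "sqeuclidean")
        for c in range(k):
            if not (labels == c).any():
                far = int(np.argmax(d2[np.arange(n), labels]))
                centers[c] = X[far]
                d2[:, c] = ((X - centers[c]) ** 2).sum(axis=1)
        cost = _assignment_cost(X, centers, labels, indptr, indices, lam)
        new_labels = np.argmin(cost, axis=1)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
    return relabel_dense(pd.Series(labels, index=index, name="cn"))


# ---------------------------------------------------------------------------
# top-level identification methods
# ---------------------------------------------------------------------------

@dataclass
class IdentificationResult:
    """A CN labeling plus the representation that produced it.

    The representation is retained because smoothing re-uses it (a cell in
    a small CN instance adopts the label of its most similar
    large-instance neighbor).
    """

    labeling: pd.Series
    representation: CellRepresentation
    params: dict


def identify_cc(cells: CellTable, k: int, m: int, seed: int = 0) -> IdentificationResult:
    """CC: nearest-m CT histograms clustered by plain k-means."""
    reps = cc_representations(cells, m)
    labeling = spatially_regularized_kmeans(reps, None, k, lam=0.0, seed=seed)
    return IdentificationResult(labeling, reps, {"method": "cc", "k": k, "m": m, "seed": seed})


def identify_cne(
    cells: CellTable,
    k: int,
    perp: float = 15.0,
    lam: float = 0.25,
    cap: int = 30,
    seed: int = 0,
    convention: str = "tsne",
) -> IdentificationResult:
    """CNE: perplexity-calibrated density representations, IDF scaling,
    spatially regularized k-means over pooled images."""
    bw = cne_bandwidths(cells, perp, cap=cap, convention=convention)
    freqs = overall_ct_frequencies(cells)
    reps = cne_representations(bw, freqs)
    graphs = build_delaunay_graphs(cells) if lam > 0 else None
    labeling = spatially_regularized_kmeans(reps, graphs, k, lam=lam, seed=seed)
    return IdentificationResult(
        labeling, reps,
        {"method": "cne", "k": k, "perp": perp, "lam": lam, "cap": cap, "seed": seed},
    )


# ---------------------------------------------------------------------------
# CF-IDF
# ---------------------------------------------------------------------------

def cfidf_weighted_graph(cells: CellTable, image_id, eps: float) -> NeighborGraph:
    """Distance-weighted epsilon-radius graph for one image.

    Edge weight ``w = log2(1 / (0.005 + d_hat))`` where ``d_hat`` is the
    edge length divided by the image's mean pairwise distance.  Weights
    that come out negative (very long edges) are clipped at zero, with a
    warning reporting how many.
    """
    g = build_radius_graph(cells, image_id, eps=eps)
    _, xy = cells.coords(image_id)
    from scipy.spatial.distance import pdist

    mean_d = float(pdist(xy).mean())
    if mean_d <= 0:
        raise ValueError(f"image {image_id!r} has zero mean pairwise distance")
    d_hat = g.weights / mean_d
    w = np.log2(1.0 / (0.005 + d_hat))
    n_neg = int((w < 0).sum())
    if n_neg:
        warnings.warn(f"image {image_id!r}: {n_neg} negative edge weights clipped to 0")
    g.weights = np.clip(w, 0.0, None)
    g.params["mean_pairwise_distance"] = mean_d
    return g


def identify_cfidf(
    cells: CellTable, k: int, eps: float, r: float, seed: int = 0
) -> IdentificationResult:
    """CF-IDF: Louvain communities on weighted graphs, IDF-scaled community
    CT frequencies, community-level k-means; cells inherit their
    community's CN."""
    import networkx as nx

    if k < 2:
        raise ValueError("k must be >= 2")
    freqs = overall_ct_frequencies(cells)
    vocab = cells.cell_types
    idf_w = np.log(1.0 / freqs.overall.reindex(vocab).to_numpy(float))
    if np.allclose(idf_w, 0.0):
        warnings.warn("single-CT vocabulary: all community representations are zero")

    comm_reps, comm_members = [], []
    for img in cells.images:
        g = cfidf_weighted_graph(cells, img, eps)
        G = nx.Graph()
        G.add_nodes_from(range(g.n))
        coo = g.to_scipy().tocoo()
        for i, j, w in zip(coo.row, coo.col, coo.data):
            if i < j:
                G.add_edge(int(i), int(j), weight=float(w))
        comms = nx.community.louvain_communities(
            G, weight="weight", resolution=r, seed=int(seed)
        )
        cts = cells.df.loc[g.cell_ids, "cell_type"].to_numpy()
        for members in sorted(comms, key=lambda s: min(s)):
            members = sorted(members)
            ids = g.cell_ids[members]
            counts = pd.Series(cts[members]).value_counts()
            vec = counts.reindex(vocab).fillna(0.0).to_numpy(float)
            vec = vec / vec.sum() * idf_w
            comm_reps.append(vec)
            comm_members.append(ids)
    if len(comm_reps) < k:
        raise ValueError(
            f"only {len(comm_reps)} communities found, fewer than k={k}; "
            "try a higher Louvain resolution r"
        )
    comm_df = pd.DataFrame(comm_reps, columns=vocab)
    comm_labels = spatially_regularized_kmeans(
        CellRepresentation(comm_df), None, k, lam=0.0, seed=seed
    )
    labels = pd.Series(0, index=cells.cell_ids, dtype=np.int64, name="cn")
    rep_rows = np.zeros((cells.n_cells, len(vocab)))
    pos_of = pd.Series(np.arange(cells.n_cells), index=cells.cell_ids)
    for c, ids in enumerate(comm_members):
        labels.loc[ids] = int(comm_labels.iloc[c])
        rep_rows[pos_of.reindex(ids).to_numpy(np.int64)] = comm_df.iloc[c].to_numpy()
    reps = CellRepresentation(
        pd.DataFrame(rep_rows, index=cells.cell_ids, columns=vocab)
    )
    return IdentificationResult(
        relabel_dense(labels), reps,
        {"method": "cfidf", "k": k, "eps": eps, "r": r, "seed": seed},
    )
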