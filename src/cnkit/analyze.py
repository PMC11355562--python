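"""Downstream CT-CN and CN-CN analyses.

CT-CN side: a CT-by-CN position weight matrix (PWM) of log-odds
enrichment scores; per-(CT, CN) donor-group linear models for
differential enrichment; and a non-negative Tucker decomposition of the
donor-stacked CT-CN joint-distribution tensor into CT / CN / tissue
modules.

CN-CN side: an inter-CN communication network from permutation-tested
canonical correlations of donor-level CT frequencies; a spatial-context
(SC) map assigning each cell the minimal CN set covering >90% of its 100
nearest neighbors; and assembly rules over the CN-instance adjacency
graph (cnX -> cnX-cnY when most cnX instances touch a cnY instance,
cnX -> cnXnotY when most touch none).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.spatial import cKDTree

from .tissue import (
    CellTable,
    CNInstancePartition,
    FrequencyTable,
    check_labeling,
    cn_instances,
)

__all__ = [
    "ct_enrichment_pwm",
    "differential_ct_enrichment",
    "build_ctcn_tensor",
    "TuckerModules",
    "tensor_decompose",
    "max_canonical_correlation",
    "inter_cn_network",
    "SpatialContextMap",
    "spatial_context_map",
    "instance_adjacency",
    "MotifRuleSet",
    "assembly_rules",
]


# ---------------------------------------------------------------------------
# CT enrichment PWM
# ---------------------------------------------------------------------------

def ct_enrichment_pwm(labeling: pd.Series, cells: CellTable) -> pd.DataFrame:
    """Log-odds CT enrichment scores per CN.

    ``score[t, n] = log2((|C_nt| + F(t)) / (|C_n| + 1)) - log2 F(t)``;
    the F(t)/+1 pseudocounts keep empty CNs finite.  Returns a CT x CN
    DataFrame with ``attrs['cn_names']`` naming each CN after its
    top-scoring CT and ``attrs['cn_fraction']`` the per-CN cell fraction.
    """
    lab = check_labeling(cells, labeling)
    vocab = cells.cell_types
    joint = pd.crosstab(cells.df["cell_type"], lab.to_numpy()).reindex(vocab).fillna(0.0)
    F = joint.sum(axis=1) / joint.to_numpy().sum()
    cn_sizes = joint.sum(axis=0)
    score = np.log2(joint.add(F, axis=0).div(cn_sizes + 1.0, axis=1)).sub(
        np.log2(F), axis=0
    )
    score.index.name = "cell_type"
    score.columns.name = "cn"
    score.attrs["cn_names"] = {int(n): str(score[n].idxmax()) for n in score.columns}
    score.attrs["cn_fraction"] = (cn_sizes / cn_sizes.sum()).to_dict()
    return score


# ---------------------------------------------------------------------------
# differential CT enrichment
# ---------------------------------------------------------------------------

def differential_ct_enrichment(
    freqs: FrequencyTable,
    group: set,
    cts: list | None = None,
    cns: list | None = None,
) -> pd.DataFrame:
    """Per-(CT, CN) donor-level linear models of CT frequency in a CN.

    For each CT t and CN n, fits by ordinary least squares over donors d

        log2 F_n^d(t) = b0 + b1 * 1[d in group] + b2 * log2 F^d(t)

    and reports the group coefficient b1 with its two-sided p-value.
    Donors with a zero frequency on either side are dropped from that fit
    (log undefined) and counted.  Rows with fewer than 3 usable donors, a
    single-arm design, or no residual degrees of freedom are flagged
    unusable with no p-value.
    """
    if freqs.per_donor_cn is None or freqs.per_donor is None:
        raise ValueError("frequency table lacks per-donor / per-donor-CN frequencies")
    donors = freqs.per_donor.index
    if not set(group) & set(donors):
        raise ValueError("target group shares no donors with the frequency table")
    all_cns = sorted(freqs.per_donor_cn.index.get_level_values(1).unique())
    cns = all_cns if cns is None else list(cns)
    cts = list(freqs.overall.index) if cts is None else list(cts)
    rows = []
    for n in cns:
        sub = freqs.per_donor_cn.xs(n, level=1)
        for t in cts:
            y_raw = sub[t] if t in sub.columns else pd.Series(dtype=float)
            x2_raw = freqs.per_donor[t]
            common = y_raw.index.intersection(x2_raw.index)
            y_raw, x2_raw = y_raw.loc[common], x2_raw.loc[common]
            ok = (y_raw > 0) & (x2_raw > 0)
            n_dropped = int(len(donors) - ok.sum())
            d_used = common[ok]
            rec = {
                "cell_type": t, "cn": n, "beta0": np.nan, "beta1": np.nan,
                "beta2": np.nan, "pvalue": np.nan,
                "n_donors_used": int(ok.sum()), "n_donors_dropped": n_dropped,
                "usable": False,
            }
            if ok.sum() >= 3:
                ind = np.array([1.0 if d in group else 0.0 for d in d_used])
                if 0.0 < ind.mean() < 1.0:
                    X = sm.add_constant(
                        np.column_stack([ind, np.log2(x2_raw[ok].to_numpy(float))])
                    )
                    yv = np.log2(y_raw[ok].to_numpy(float))
                    if len(yv) > np.linalg.matrix_rank(X):
                        fit = sm.OLS(yv, X).fit()
                        rec.update(
                            beta0=float(fit.params[0]), beta1=float(fit.params[1]),
                            beta2=float(fit.params[2]), pvalue=float(fit.pvalues[1]),
                            usable=True,
                        )
            rows.append(rec)
    out = pd.DataFrame(rows)
    # supplementary BH column over usable rows; never used for gating
    usable = out["usable"] & out["pvalue"].notna()
    if usable.any():
        p = out.loc[usable, "pvalue"].to_numpy()
        m = len(p)
        order = np.argsort(p)
        adj = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
        bh = np.full(m, np.nan)
        bh[order] = np.clip(adj, 0, 1)
        out.loc[usable, "pvalue_bh"] = bh
    else:
        out["pvalue_bh"] = np.nan
    return out


# ---------------------------------------------------------------------------
# tensor decomposition
# ---------------------------------------------------------------------------

def build_ctcn_tensor(
    labeling: pd.Series, cells: CellTable, donors: list | None = None,
    donor_col: str = "sample",
):
    """Donor-stacked CT-CN joint distribution tensor X (|T| x |N| x |D|).

    ``X[t, n, d]`` is the fraction of donor d's cells that are of CT t
    and in CN n; each donor slice sums to 1.  Donors without labeled
    cells are excluded with a warning.
    """
    lab = check_labeling(cells, labeling)
    vocab = cells.cell_types
    cn_levels = sorted(np.unique(lab.to_numpy()))
    donors = cells.df[donor_col].unique().tolist() if donors is None else list(donors)
    keep, slices = [], []
    for d in donors:
        mask = (cells.df[donor_col] == d).to_numpy()
        if not mask.any():
            warnings.warn(f"donor {d!r} has no cells; excluded from tensor")
            continue
        joint = pd.crosstab(
            cells.df.loc[mask, "cell_type"], lab.to_numpy()[mask]
        ).reindex(index=vocab, columns=cn_levels).fillna(0.0)
        slices.append(joint.to_numpy(float) / mask.sum())
        keep.append(d)
    X = np.stack(slices, axis=2)
    return X, {"cell_types": vocab, "cns": cn_levels, "donors": keep}


@dataclass
class TuckerModules:
    """Non-negative Tucker factors: CT modules A, CN modules B, tissue
    modules C and the core of interaction strengths."""

    core: np.ndarray          # (P, Q, R)
    ct_factors: np.ndarray    # (|T|, P)
    cn_factors: np.ndarray    # (|N|, Q)
    tissue_factors: np.ndarray  # (|D|, R)
    ranks: tuple
    rel_error: float
    n_iter: int

    def reconstruct(self) -> np.ndarray:
        return np.einsum(
            "pqr,tp,nq,dr->tnd",
            self.core, self.ct_factors, self.cn_factors, self.tissue_factors,
        )

    def interaction_strengths(self, threshold: float = 0.1) -> np.ndarray:
        """Core rescaled to max 1 within each tissue-module slice;
        entries at or below ``threshold`` are zeroed for display."""
        out = self.core.copy()
        for r in range(out.shape[2]):
            mx = out[:, :, r].max()
            if mx > 0:
                out[:, :, r] /= mx
        out[out <= threshold] = 0.0
        return out


def _unfold(X: np.ndarray, mode: int) -> np.ndarray:
    return np.moveaxis(X, mode, 0).reshape(X.shape[mode], -1)


def tensor_decompose(
    X: np.ndarray,
    ranks: tuple = (6, 6, 2),
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-12,
) -> TuckerModules:
    """Non-negative Tucker decomposition by multiplicative updates.

    Factors are initialized from the absolute leading singular vectors of
    the mode unfoldings (a nonnegative HOSVD-style start, deterministic;
    ``seed`` only perturbs degenerate zero factors), then factors and
    core are refined with Lee-Seung-style multiplicative updates until
    the relative reconstruction error stalls below ``tol`` or
    ``max_iter``.  Ranks exceeding a tensor dimension are clamped with a
    warning.
    """
    X = np.asarray(X, float)
    if (X < 0).any():
        raise ValueError("tensor must be nonnegative")
    ranks = tuple(int(r) for r in ranks)
    clamped = tuple(min(r, s) for r, s in zip(ranks, X.shape))
    if clamped != ranks:
        warnings.warn(f"ranks {ranks} clamped to tensor shape -> {clamped}")
    P, Q, R = clamped
    rng = np.random.default_rng(seed)
    eps = 1e-12

    factors = []
    for mode, r in enumerate((P, Q, R)):
        U, _, _ = np.linalg.svd(_unfold(X, mode), full_matrices=False)
        A = np.abs(U[:, :r])
        dead = A.sum(axis=0) < eps
        if dead.any():
            A[:, dead] = rng.random((A.shape[0], int(dead.sum())))
        factors.append(A)
    A, B, C = factors
    core = np.einsum("tnd,tp,nq,dr->pqr", X, A, B, C)
    core = np.clip(core, eps, None)

    normX = np.linalg.norm(X)
    prev = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        # factor updates
        for mode in range(3):
            mats = [A, B, C]
            W = np.einsum("pqr,nq,dr->pnd", core, B, C) if mode == 0 else (
                np.einsum("pqr,tp,dr->qtd", core, A, C) if mode == 1 else
                np.einsum("pqr,tp,nq->rtn", core, A, B)
            )
            Wm = W.reshape(W.shape[0], -1)  # (rank, rest)
            Xm = _unfold(X, mode)
            M = mats[mode]
            num = Xm @ Wm.T
            den = M @ (Wm @ Wm.T) + eps
            M *= num / den
            mats[mode] = M
            A, B, C = mats
        # core update
        num = np.einsum("tnd,tp,nq,dr->pqr", X, A, B, C)
        AtA, BtB, CtC = A.T @ A, B.T @ B, C.T @ C
        den = np.einsum("pqr,sp,tq,ur->stu", core, AtA, BtB, CtC) + eps
        core *= num / den
        rec = np.einsum("pqr,tp,nq,dr->tnd", core, A, B, C)
        err = np.linalg.norm(X - rec) / (normX + eps)
        if abs(prev - err) < tol:
            break
        prev = err
    return TuckerModules(core, A, B, C, clamped, float(err), it)


# ---------------------------------------------------------------------------
# inter-CN communication network
# ---------------------------------------------------------------------------

def max_canonical_correlation(X: np.ndarray, Y: np.ndarray) -> float:
    """Largest canonical correlation between column sets X and Y.

    Columns are centered; the correlation is the largest singular value
    of Qx^T Qy for orthonormal column bases Qx, Qy (rank-truncated), the
    classical CCA solution.  Zero-variance blocks give 0.
    """

    def _basis(M):
        M = M - M.mean(axis=0, keepdims=True)
        U, s, _ = np.linalg.svd(M, full_matrices=False)
        rank = int((s > max(M.shape) * np.finfo(float).eps * (s[0] if len(s) else 0)).sum())
        return U[:, :rank]

    Qx, Qy = _basis(np.asarray(X, float)), _basis(np.asarray(Y, float))
    if Qx.shape[1] == 0 or Qy.shape[1] == 0:
        return 0.0
    s = np.linalg.svd(Qx.T @ Qy, compute_uv=False)
    return float(np.clip(s[0], 0.0, 1.0))


def inter_cn_network(
    freqs: FrequencyTable,
    donors: list | None = None,
    target_cts: list | None = None,
    n_perm: int = 1000,
    p_threshold: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation-tested canonical correlations between CN pairs.

    For CNs (n1, n2) the donor-by-CT frequency blocks F_n1^d(t) and
    F_n2^d(t) (t in the target CT set) are compared by their largest
    canonical correlation; significance comes from ``n_perm`` donor-row
    permutations of the second block with the add-one p-value estimator.
    Returns all pairs with columns ``cca, pvalue, strength (1-p), edge``;
    edges satisfy p < ``p_threshold``.  Fig-style display customarily
    keeps strengths > 0.9.
    """
    if freqs.per_donor_cn is None:
        raise ValueError("frequency table lacks per-donor-CN frequencies")
    all_donors = sorted(freqs.per_donor_cn.index.get_level_values(0).unique(), key=repr)
    donors = all_donors if donors is None else list(donors)
    if len(donors) < 3:
        raise ValueError("need at least 3 donors for the permutation test")
    cts = list(freqs.overall.index) if target_cts is None else list(target_cts)
    if len(donors) <= len(cts):
        warnings.warn(
            "no more donors than target CTs: unpermuted canonical correlation "
            "saturates at 1; rely on the permutation p-value"
        )
    cns = sorted(freqs.per_donor_cn.index.get_level_values(1).unique())
    blocks = {}
    for n in cns:
        sub = freqs.per_donor_cn.xs(n, level=1).reindex(index=donors, columns=cts)
        blocks[n] = sub.fillna(0.0).to_numpy(float)
    rng = np.random.default_rng(seed)
    rows = []
    for n1, n2 in itertools.combinations(cns, 2):
        Xb, Yb = blocks[n1], blocks[n2]
        obs = max_canonical_correlation(Xb, Yb)
        b = 0
        for _ in range(n_perm):
            perm = rng.permutation(len(donors))
            if max_canonical_correlation(Xb, Yb[perm]) >= obs - 1e-12:
                b += 1
        p = (b + 1) / (n_perm + 1)
        rows.append(
            {"cn1": n1, "cn2": n2, "cca": obs, "pvalue": p,
             "strength": 1.0 - p, "edge": p < p_threshold}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CN combination map (spatial contexts)
# ---------------------------------------------------------------------------

@dataclass
class SpatialContextMap:
    """Per-cell minimal CN combinations and the surviving SC inventory."""

    sc_of: pd.Series            # cell_id -> tuple of CN labels (sorted) or None
    sc_counts: pd.Series        # SC tuple -> cell count (surviving SCs)
    subset_edges: list          # (smaller SC, larger SC) subset relations
    top: list                   # largest SCs (up to 20), by count
    params: dict = field(default_factory=dict)


def spatial_context_map(
    labeling: pd.Series,
    cells: CellTable,
    coverage: float = 0.9,
    window: int = 100,
    min_frac: float = 1e-5,
) -> SpatialContextMap:
    """Assign each cell its minimal covering CN set (spatial context).

    A cell's window is its nearest ``window`` cells in the same image
    (all of them when the image is smaller).  The SC is the smallest CN
    set whose combined window frequency strictly exceeds ``coverage``;
    CN labels are added in order of decreasing window count (ties toward
    the lower label), which yields the minimal set and makes it unique up
    to the documented tie rule.  SCs holding fewer than ``min_frac`` of
    all cells are dropped (their cells report None).
    """
    lab = check_labeling(cells, labeling)
    assign = {}
    for img in cells.images:
        ids, xy = cells.coords(img)
        n = len(ids)
        lv = lab.reindex(ids).to_numpy(np.int64)
        k = min(window + 1, n)
        tree = cKDTree(xy)
        _, nbr = tree.query(xy, k=k)
        nbr = np.atleast_2d(nbr)
        for i in range(n):
            others = nbr[i][nbr[i] != i][: window]
            counts = np.bincount(lv[others])
            order = np.lexsort((np.arange(len(counts)), -counts))
            tot = counts.sum()
            acc, chosen = 0, []
            for c in order:
                if counts[c] == 0:
                    break
                chosen.append(int(c))
                acc += counts[c]
                if acc > coverage * tot:
                    break
            assign[ids[i]] = tuple(sorted(chosen)) if acc > coverage * tot else None
    sc_series = pd.Series(assign, name="sc").reindex(cells.cell_ids)
    counts = sc_series.dropna().value_counts()
    floor = min_frac * cells.n_cells
    surviving = counts[counts >= floor]
    sc_series[~sc_series.isin(surviving.index)] = None
    edges = [
        (a, b)
        for a, b in itertools.permutations(surviving.index, 2)
        if set(a) < set(b)
    ]
    top = list(surviving.index[:20])
    return SpatialContextMap(
        sc_series, surviving, edges, top,
        {"coverage": coverage, "window": window, "min_frac": min_frac},
    )


# ---------------------------------------------------------------------------
# assembly rules
# ---------------------------------------------------------------------------

def instance_adjacency(
    labeling: pd.Series, graphs: dict, instances: CNInstancePartition | None = None
) -> dict:
    """Per-image CN-instance adjacency.

    Two instances are adjacent iff some Delaunay edge joins their cells
    (a deterministic, resolution-free surrogate for adjacency of
    rasterized instance masks).  Returns image ->
    ``{"cn_of": {instance: cn}, "edges": set of instance pairs}``.
    """
    inst = instances if instances is not None else cn_instances(labeling, graphs)
    out = {}
    for img, g in graphs.items():
        iv = inst.instance_of.reindex(g.cell_ids).to_numpy(np.int64)
        coo = g.to_scipy().tocoo()
        a, b = iv[coo.row], iv[coo.col]
        diff = a != b
        edges = {(int(min(x, y)), int(max(x, y))) for x, y in zip(a[diff], b[diff])}
        info = inst.info[inst.info["image"] == img]
        out[img] = {"cn_of": info["cn"].to_dict(), "edges": edges}
    return out


@dataclass
class MotifRuleSet:
    """One- to two-CN assembly rules with their supports."""

    per_image: pd.DataFrame   # image, source, kind, target, support, n_instances
    conserved: pd.DataFrame   # rules present in >= conserved_fraction of images
    params: dict


def assembly_rules(
    adjacency: dict,
    support: float = 0.7,
    min_instances: int = 5,
    conserved_fraction: float = 1.0,
) -> MotifRuleSet:
    """Extract cnX -> cnX-cnY / cnX -> cnXnotY rules per image.

    For each source CN X with at least ``min_instances`` instances in an
    image and each other CN Y present there: the rule cnX -> cnX-cnY
    holds when the fraction of X instances adjacent to at least one Y
    instance is >= ``support``; cnX -> cnXnotY when the fraction adjacent
    to none is >= ``support``.  Conserved rules must hold in at least
    ``conserved_fraction`` of the images (default: all).
    """
    rows = []
    for img, data in adjacency.items():
        cn_of = data["cn_of"]
        nbrs = {}
        for a, b in data["edges"]:
            nbrs.setdefault(a, set()).add(b)
            nbrs.setdefault(b, set()).add(a)
        by_cn = {}
        for iid, cn in cn_of.items():
            by_cn.setdefault(cn, []).append(iid)
        for x, x_insts in by_cn.items():
            if len(x_insts) < min_instances:
                continue
            for y in by_cn:
                if y == x:
                    continue
                adj_count = sum(
                    1 for iid in x_insts
                    if any(cn_of[j] == y for j in nbrs.get(iid, ()))
                )
                frac = adj_count / len(x_insts)
                if frac >= support:
                    rows.append((img, x, "adjacent", y, frac, len(x_insts)))
                if 1.0 - frac >= support:
                    rows.append((img, x, "not_adjacent", y, 1.0 - frac, len(x_insts)))
    per_image = pd.DataFrame(
        rows, columns=["image", "source", "kind", "target", "support", "n_instances"]
    )
    n_images = len(adjacency)
    if len(per_image):
        grp = per_image.groupby(["source", "kind", "target"]).agg(
            n_images_with_rule=("image", "nunique"),
            min_support=("support", "min"),
        ).reset_index()
        conserved = grp[grp["n_images_with_rule"] >= conserved_fraction * n_images]
    else:
        conserved = pd.DataFrame(
            columns=["source", "kind", "target", "n_images_with_rule", "min_support"]
        )
    return MotifRuleSet(
        per_image, conserved.reset_index(drop=True),
        {"support": support, "min_instances": min_instances,
         "conserved_fraction": conserved_fraction},
    )
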