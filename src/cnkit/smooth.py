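"""Post-identification CN smoothing.

Two techniques:

* **Naive smoothing** — cells sitting in CN instances smaller than ``s``
  adopt the label of the Delaunay neighbor that belongs to a large
  (size >= s) instance and has the most similar representation under
  cosine similarity.  One simultaneous pass over the original labeling.
* **HMRF** — a hidden Markov random field with CTs as emissions and CN
  labels as hidden states on an epsilon-radius graph, solved by EM: the
  E-step re-estimates the empirical emission table P(CT | CN) from the
  current labels, the M-step reassigns every cell (synchronously) to
  ``argmax_n P(CT=t_x | CN=n) * exp(beta * #{neighbors with label n})``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .identify import CellRepresentation
from .tissue import (
    CellTable,
    build_radius_graph,
    check_labeling,
    cn_instances,
    relabel_dense,
)

__all__ = ["naive_smooth", "HmrfModel", "hmrf_smooth"]

log = logging.getLogger(__name__)


def naive_smooth(
    labeling: pd.Series,
    reps: CellRepresentation | pd.DataFrame,
    graphs: dict,
    s: int = 3,
    iterate: bool = False,
) -> pd.Series:
    """Reassign cells of small CN instances to their most similar
    large-instance Delaunay neighbor.

    Instance sizes and neighbor labels are all taken from the *original*
    labeling (one simultaneous pass): cells whose instance has size >= s
    are untouched; a small-instance cell adopts the label of the neighbor
    y maximizing cosine(f(x), f(y)) among neighbors in instances of size
    >= s; with no qualifying neighbor it keeps its label (count logged).
    Zero-norm representations are skipped as candidates.  ``iterate=True``
    repeats passes to a fixed point.
    """
    R = reps.values if isinstance(reps, CellRepresentation) else reps
    current = labeling.copy()
    while True:
        inst = cn_instances(current, graphs)
        sizes = inst.size_per_cell()
        new = current.copy()
        n_stuck = 0
        for img, g in graphs.items():
            lab = current.reindex(g.cell_ids).to_numpy(np.int64)
            sz = sizes.reindex(g.cell_ids).to_numpy(np.int64)
            X = R.reindex(g.cell_ids).to_numpy(float)
            norms = np.linalg.norm(X, axis=1)
            for i in np.flatnonzero(sz < s):
                nbrs = g.neighbors(i)
                ok = nbrs[(sz[nbrs] >= s) & (norms[nbrs] > 0)]
                if len(ok) == 0 or norms[i] == 0:
                    n_stuck += 1
                    continue
                cos = (X[ok] @ X[i]) / (norms[ok] * norms[i])
                new.loc[g.cell_ids[i]] = int(lab[ok[int(np.argmax(cos))]])
        if n_stuck:
            log.info("naive_smooth: %d small-instance cells had no qualifying neighbor", n_stuck)
        if not iterate or new.equals(current):
            return new
        current = new


@dataclass
class HmrfModel:
    """Fitted HMRF state: emission table and the graph it was solved on."""

    emission: pd.DataFrame  # |T| x |N|, columns sum to 1 for nonempty CNs
    beta: float
    graphs: dict
    labeling: pd.Series
    converged: bool
    n_iter: int


def _emission_table(ct_codes: np.ndarray, labels: np.ndarray, n_ct: int, k: int):
    """Empirical P(CT=t | CN=n) as a (n_ct, k) array; empty CNs all-zero."""
    counts = np.zeros((n_ct, k))
    np.add.at(counts, (ct_codes, labels), 1.0)
    totals = counts.sum(axis=0)
    with np.errstate(invalid="ignore"):
        return np.where(totals > 0, counts / totals, 0.0), totals


def hmrf_smooth(
    labeling: pd.Series,
    cells: CellTable,
    beta: float = 9.0,
    target_mean_degree: float = 5.0,
    max_iter: int = 100,
    graphs: dict | None = None,
    return_model: bool = False,
):
    """EM label smoothing under a Potts-coupled emission model.

    Alternates the empirical emission estimate with a synchronous
    maximization sweep; terminates when no label changes or after
    ``max_iter`` sweeps.  CNs emptied mid-run drop out of the argmax.
    With ``beta=0`` a single sweep reduces to the per-cell emission
    argmax, independent of geometry.  Ties break toward the lower CN
    index.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    lab = check_labeling(cells, labeling)
    if graphs is None:
        graphs = {
            img: build_radius_graph(cells, img, target_mean_degree=target_mean_degree)
            for img in cells.images
        }
    vocab = cells.cell_types
    code = {t: i for i, t in enumerate(vocab)}
    ct_codes = cells.df["cell_type"].map(code).to_numpy(np.int64)
    pos_of = pd.Series(np.arange(cells.n_cells), index=cells.cell_ids)
    # positional neighbor arrays aligned to table order
    from .tissue import stack_graphs

    indptr, indices = stack_graphs(cells, graphs)
    labels = lab.reindex(cells.cell_ids).to_numpy(np.int64)
    k = int(labels.max()) + 1

    converged = False
    it = 0
    # beta=0 decouples cells from geometry: a single sweep realizes the
    # per-cell emission argmax of the input labeling and is returned as is
    n_sweeps = 1 if beta == 0 else max_iter
    for it in range(1, n_sweeps + 1):
        emission, totals = _emission_table(ct_codes, labels, len(vocab), k)
        alive = totals > 0
        # neighbor label counts (n, k)
        nbr_counts = np.zeros((cells.n_cells, k))
        src = np.repeat(np.arange(cells.n_cells), np.diff(indptr))
        np.add.at(nbr_counts, (src, labels[indices]), 1.0)
        with np.errstate(divide="ignore"):
            log_em = np.log(emission[ct_codes, :])  # (n, k)
        score = log_em + beta * nbr_counts
        score[:, ~alive] = -np.inf
        new_labels = np.argmax(score, axis=1)
        if np.array_equal(new_labels, labels):
            converged = True
            break
        labels = new_labels
    out = relabel_dense(pd.Series(labels, index=cells.cell_ids, name="cn"))
    if return_model:
        emission, totals = _emission_table(
            ct_codes, out.to_numpy(np.int64), len(vocab), int(out.max()) + 1
        )
        model = HmrfModel(
            pd.DataFrame(emission, index=vocab), float(beta), graphs, out, converged, it
        )
        return out, model
    return out
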