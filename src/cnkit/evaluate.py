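"""CN quality metrics: purity, granularity, and labeling agreement.

*Purity* is the Shannon entropy of CT conditioned on CN (bits), pooled
over all images — 0 when every CN is a single CT, and equal to the
dataset CT entropy when all cells share one CN.  *Granularity* is the
mean CN instance size, total cells divided by the number of connected
same-label Delaunay components.  Labelings are compared with NMI under
the arithmetic-mean normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import normalized_mutual_info_score

from .tissue import CellTable, check_labeling, cn_instances

__all__ = [
    "EvaluationRecord",
    "mean_cn_entropy",
    "mean_cn_instance_size",
    "nmi",
    "evaluate_labeling",
]


def mean_cn_entropy(labeling: pd.Series, cells: CellTable) -> float:
    """H(CT | CN) in bits: sum_{n,t} (|C_nt|/|C|) log2(|C_n|/|C_nt|)."""
    lab = check_labeling(cells, labeling)
    joint = pd.crosstab(lab.to_numpy(), cells.df["cell_type"]).to_numpy(float)
    total = joint.sum()
    cn_sizes = joint.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(joint > 0, joint / total * np.log2(cn_sizes / joint), 0.0)
    return float(terms.sum())


def mean_cn_instance_size(labeling: pd.Series, graphs: dict) -> float:
    """Average cells per CN instance: |C| / number of instances."""
    inst = cn_instances(labeling, graphs)
    return float(inst.info["size"].sum() / inst.n_instances)


def nmi(a: pd.Series, b: pd.Series) -> float:
    """Normalized mutual information between two labelings of the same
    cells (arithmetic-mean normalization); 1.0 for identical partitions,
    invariant to label permutation."""
    if not a.index.sort_values().equals(b.index.sort_values()):
        raise ValueError("labelings cover different cell sets")
    bb = b.reindex(a.index)
    score = normalized_mutual_info_score(
        a.to_numpy(), bb.to_numpy(), average_method="arithmetic"
    )
    return float(np.clip(score, 0.0, 1.0))  # guard roundoff above 1


@dataclass
class EvaluationRecord:
    """One row of the purity/granularity evaluation surface."""

    method: str
    mean_cn_entropy: float
    mean_cn_instance_size: float
    smoothing: str = "none"
    params: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "method": self.method,
            "smoothing": self.smoothing,
            "mean_cn_entropy": self.mean_cn_entropy,
            "mean_cn_instance_size": self.mean_cn_instance_size,
            **{f"param_{k}": v for k, v in self.params.items()},
        }


def evaluate_labeling(
    labeling: pd.Series,
    cells: CellTable,
    graphs: dict,
    method: str = "unknown",
    smoothing: str = "none",
    params: dict | None = None,
) -> EvaluationRecord:
    """Purity and granularity of one labeling, pooled over images."""
    return EvaluationRecord(
        method,
        mean_cn_entropy(labeling, cells),
        mean_cn_instance_size(labeling, graphs),
        smoothing,
        dict(params or {}),
    )
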