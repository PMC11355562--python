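"""Planted-CN tissue simulator.

Generates ground-truth-labeled cell tables so every pipeline stage is
testable without external imaging data.  Each image is a rectangle with
cells sampled uniformly; planted CN regions are the Voronoi cells of
per-CN seed points (or regular grid blocks); each region emits CTs from
its CN's categorical profile, optionally corrupted by resampling a
fraction ``noise`` of cells uniformly over the vocabulary.

Defaults emulate a small multiplexed-imaging experiment: a few thousand
cells per image, a handful of CN regions whose CT profiles are dominated
by disjoint CT subsets (pairwise total-variation distance well above
0.5), and 10% CT noise.  What the simulator does *not* reproduce —
segmentation error, spatially varying cell density within a region,
continuous CT gradients — is documented in the methods note.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tissue import CellTable, FrequencyTable

__all__ = ["SyntheticTissueSpec", "simulate_tissue", "make_group_contrast"]


@dataclass
class SyntheticTissueSpec:
    """Study conditions for one simulated tissue.

    ``profiles`` is a (K x |T|) row-stochastic matrix; when None, a
    disjoint-dominated default is built: with T = 2K cell types, CN k
    puts ``dominant_mass`` (0.8) on its own two CTs and spreads the rest
    uniformly, giving pairwise total-variation distance >= 0.5 for any
    K >= 2.  ``seeds_per_cn`` Voronoi seeds are drawn per CN per image.
    """

    n_cells: int = 2000
    n_cns: int = 4
    width: float = 1000.0
    height: float = 1000.0
    n_images: int = 1
    n_donors: int = 1
    n_groups: int = 1
    cell_types: list | None = None
    profiles: np.ndarray | None = None
    dirichlet_alpha: float | None = None
    dominant_mass: float = 0.8
    noise: float = 0.1
    layout: str = "voronoi"  # or "grid"
    seeds_per_cn: int = 1
    region_rates: tuple | None = None  # per-CN relative cell density
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.noise <= 1.0:
            raise ValueError("noise rate must be in [0, 1]")
        if self.n_cells < self.n_cns:
            raise ValueError("need at least one cell per planted CN")
        if self.region_rates is not None:
            rates = np.asarray(self.region_rates, float)
            if len(rates) != self.n_cns or (rates <= 0).any():
                raise ValueError("region_rates needs one positive rate per CN")

    def resolve_profiles(self, rng: np.random.Generator):
        """Vocabulary and the (K x |T|) profile matrix actually used."""
        K = self.n_cns
        if self.profiles is not None:
            prof = np.asarray(self.profiles, float)
            if prof.shape[0] != K:
                raise ValueError("profiles must have one row per CN")
            if not np.allclose(prof.sum(axis=1), 1.0) or (prof < 0).any():
                raise ValueError("profiles must be row-stochastic")
            vocab = self.cell_types or [f"ct{j}" for j in range(prof.shape[1])]
            return list(vocab), prof
        if self.dirichlet_alpha is not None:
            vocab = self.cell_types or [f"ct{j}" for j in range(2 * K)]
            return list(vocab), rng.dirichlet(
                [self.dirichlet_alpha] * len(vocab), size=K
            )
        vocab = self.cell_types or [f"ct{j}" for j in range(2 * K)]
        nT = len(vocab)
        per_cn = max(nT // K, 1)
        prof = np.full((K, nT), (1.0 - self.dominant_mass) / max(nT - per_cn, 1))
        for k in range(K):
            own = slice(k * per_cn, (k + 1) * per_cn)
            prof[k, own] = self.dominant_mass / per_cn
        return list(vocab), prof / prof.sum(axis=1, keepdims=True)


def simulate_tissue(spec: SyntheticTissueSpec):
    """Draw a cell table with planted CN ground truth.

    Returns ``(CellTable, pd.Series)`` — the table and the planted
    labeling.  Fully deterministic given ``spec.seed``.  Regions that
    receive no cells are dropped from the ground-truth vocabulary with a
    warning.
    """
    rng = np.random.default_rng(spec.seed)
    vocab, prof = spec.resolve_profiles(rng)
    K, nT = prof.shape
    rows, truth = [], []
    donors = [f"d{i}" for i in range(spec.n_donors)]
    groups = [f"g{i}" for i in range(spec.n_groups)]
    cid = 0
    for im in range(spec.n_images):
        donor = donors[im % spec.n_donors]
        group = groups[(im % spec.n_donors) % spec.n_groups]

        def _place(n):
            pts = rng.uniform([0, 0], [spec.width, spec.height], size=(n, 2))
            if spec.layout == "voronoi":
                d2 = ((pts[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
                region = seed_cn[np.argmin(d2, axis=1)]
            elif spec.layout == "grid":
                cols = int(np.ceil(np.sqrt(K)))
                gx = np.minimum((pts[:, 0] / spec.width * cols).astype(int), cols - 1)
                rows_n = int(np.ceil(K / cols))
                gy = np.minimum((pts[:, 1] / spec.height * rows_n).astype(int), rows_n - 1)
                region = np.minimum(gy * cols + gx, K - 1)
            else:
                raise ValueError(f"unknown layout {spec.layout!r}")
            return pts, region

        seeds = rng.uniform(
            [0, 0], [spec.width, spec.height], size=(K * spec.seeds_per_cn, 2)
        )
        seed_cn = np.repeat(np.arange(K), spec.seeds_per_cn)
        xy, cn = _place(spec.n_cells)
        if spec.region_rates is not None:
            # rejection-sample until the exact cell count is reached, so
            # denser regions keep proportionally more of their draws
            accept_p = np.asarray(spec.region_rates, float)
            accept_p = accept_p / accept_p.max()
            kept_xy, kept_cn = [], []
            n_kept = 0
            while n_kept < spec.n_cells:
                pts, region = _place(spec.n_cells)
                keep = rng.random(spec.n_cells) < accept_p[region]
                kept_xy.append(pts[keep])
                kept_cn.append(region[keep])
                n_kept += int(keep.sum())
            xy = np.concatenate(kept_xy)[: spec.n_cells]
            cn = np.concatenate(kept_cn)[: spec.n_cells]
        present = np.unique(cn)
        if len(present) < K:
            warnings.warn(
                f"image {im}: {K - len(present)} planted CN region(s) received no cells"
            )
        ct_idx = np.array([rng.choice(nT, p=prof[c]) for c in cn])
        flip = rng.random(spec.n_cells) < spec.noise
        ct_idx[flip] = rng.integers(0, nT, size=int(flip.sum()))
        for i in range(spec.n_cells):
            rows.append(
                (f"c{cid}", group, donor, f"img{im}", xy[i, 0], xy[i, 1], vocab[ct_idx[i]])
            )
            truth.append(int(cn[i]))
            cid += 1
    df = pd.DataFrame(
        rows, columns=["cell_id", "group", "sample", "image", "x", "y", "cell_type"]
    ).set_index("cell_id")
    table = CellTable(df)
    return table, pd.Series(truth, index=df.index, name="cn")


@dataclass
class GroupContrast:
    """Planted donor-level frequency tables for group-contrast analyses."""

    freqs: FrequencyTable
    coefficients: pd.DataFrame  # per (cell_type, cn): beta0, beta1, beta2
    group: set                  # donors in the target group


def make_group_contrast(
    n_cns: int = 3,
    cell_types: list | None = None,
    n_donors_in: int = 5,
    n_donors_out: int = 5,
    beta: tuple = (-2.0, 1.0, 0.8),
    noise_sd: float = 0.0,
    seed: int = 0,
    differential: list | None = None,
) -> GroupContrast:
    """Generate donor frequency tables following the differential model.

    Per-donor CT frequencies F^d(t) are Dirichlet-sampled; per-donor,
    per-CN frequencies follow ``log2 F_n^d(t) = b0 + b1*1[d in D] +
    b2*log2 F^d(t) (+ Gaussian noise)``.  ``differential`` optionally
    restricts the (cell_type, cn) pairs that carry b1 (others get b1=0).
    Frequencies that would exceed 1 are renormalized with a warning.
    Returns the tables together with the planted coefficients.
    """
    rng = np.random.default_rng(seed)
    vocab = cell_types or [f"ct{j}" for j in range(4)]
    donors_in = [f"din{i}" for i in range(n_donors_in)]
    donors_out = [f"dout{i}" for i in range(n_donors_out)]
    donors = donors_in + donors_out
    per_donor = pd.DataFrame(
        rng.dirichlet([5.0] * len(vocab), size=len(donors)),
        index=pd.Index(donors, name="sample"), columns=vocab,
    )
    b0, b1, b2 = beta
    coef_rows = []
    recs = {}
    for n in range(n_cns):
        for t in vocab:
            eff = b1 if differential is None or (t, n) in differential else 0.0
            coef_rows.append({"cell_type": t, "cn": n, "beta0": b0, "beta1": eff, "beta2": b2})
            for d in donors:
                lg = (
                    b0
                    + eff * (1.0 if d in donors_in else 0.0)
                    + b2 * np.log2(per_donor.loc[d, t])
                    + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                )
                recs[(d, n, t)] = 2.0**lg
    per_donor_cn = pd.Series(recs).unstack()
    per_donor_cn.index.names = ["sample", "cn"]
    row_sums = per_donor_cn.sum(axis=1)
    over = row_sums > 1.0
    if over.any():
        warnings.warn(
            f"{int(over.sum())} (donor, CN) rows exceeded total frequency 1; renormalized"
        )
        per_donor_cn.loc[over] = per_donor_cn.loc[over].div(row_sums[over], axis=0)
    overall = per_donor.mean(axis=0)
    overall = overall / overall.sum()
    freqs = FrequencyTable(overall, per_donor, per_donor_cn)
    return GroupContrast(freqs, pd.DataFrame(coef_rows), set(donors_in))
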