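# Methods

This note documents the models implemented in cnkit, the defaults that
matter, the numerical choices made where the design was genuinely open,
and what the synthetic benchmark does and does not establish.

## Data model

A cell table holds one row per segmented, cell-typed cell: sample group,
sample (donor), image, continuous `x`/`y` coordinates (unit-agnostic;
all distances Euclidean), and a categorical cell type (CT). A CN
labeling assigns every cell an integer neighborhood label `n_x ∈ {0..k−1}`.
A *CN instance* is a maximal connected component of same-label cells
under the per-image Delaunay graph; spatial graphs never span images.

Graph kinds: Delaunay (symmetric), k-NN (directed neighbor lists, exact
distance ties broken toward the lower cell id), and ε-radius (symmetric,
optionally distance-weighted). When a target mean degree *d* is given
instead of ε, ε is the smallest pairwise-distance value whose inclusive
graph reaches mean degree ≥ *d*, found exactly over the sorted O(n²)
pairwise distances — adequate at the image sizes this package targets
(10³–10⁴ cells per image). Exact duplicate coordinates are jittered by
10⁻⁹ of the bounding-box diagonal, keyed by a hash of the cell id, only
for triangulation; stored coordinates are untouched.

## CN identification

All three methods cluster *pooled* across images so CN labels are
comparable between samples.

**CC.** The nearest-*m* window counts *m* total points including the
cell itself (the natural reading of "its neighbors including itself");
histograms are ℓ1-normalized. Typical *m*: 10 for ~2k-cell images, 20
for very large ones.

**CF-IDF.** Edge weights are `log2(1/(0.005 + d̂))` where `d̂` is the
edge length divided by the image's **mean pairwise distance**. The
normalization denominator is a documented package choice: it makes `d̂`
dimensionless and weights comparable across images of different physical
scales; the 0.005 floor caps the weight near 7.64 as distance → 0, and
weights that come out negative (edges much longer than the image mean)
are clipped to zero with a warning count. Louvain runs per image with a
fixed seed and user resolution *r*; communities are represented by their
CT frequency vector times `ln(1/F(t))` and clustered (unweighted by
community size) into k CNs.

**CNE.** Per cell, the kernel support is its 30 nearest same-image
cells plus itself; the self distance is clamped up to the
nearest-neighbor distance so the self term cannot dominate. The
bandwidth σ_x solves `2^{H₂(p)} = perp` with H₂ the Shannon entropy of
the normalized kernel in bits — the t-SNE convention, on the
effective-neighbor scale with ceiling cap + 1 = 31. A variant that
equates the natural-log entropy *value* itself with the target is
available via `convention="printed"`; its ceiling is only ln 31 ≈ 3.43,
which is incompatible with the useful perp range of 10–20, hence the
bits convention as default. The solver is a 200-step bisection on the
monotone perplexity curve (achieved perplexity within 1e-5 of target for
feasible targets; infeasible targets are clamped to the achievable range
with a warning; cells whose support points are all equidistant have a
flat curve and are flagged, receiving the mean support distance as σ).

Representations are ℓ1-normalized and multiplied by `ln(1/F(t))`. A
single-CT vocabulary makes every IDF weight zero; this degenerate case
is reported, not hidden.

**Spatially regularized k-means.** Initialization is k-means++ with the
supplied seed. Each iteration updates centroids as assigned means, then
reassigns every cell synchronously using *previous-iteration* neighbor
labels in the penalty term `(λ/|G_x|) Σ_y ‖c_n − c_{n_y}‖²` (λ = 0.25
default; G_x from Delaunay). Ties break toward the lower CN index;
empty clusters are re-seeded to the point farthest from its centroid;
convergence is zero label changes (max 300 iterations). With λ = 0 the
loop is exactly Lloyd k-means and reproduces scikit-learn's labels from
a shared init.

## Smoothing

**Naive smoothing** is one simultaneous pass: instance sizes and
candidate labels are all taken from the input labeling, so cells in
instances of size ≥ s (s = 3 default) are provably untouched, and
results do not depend on cell visitation order. A small-instance cell
adopts the label of its most cosine-similar Delaunay neighbor among
those in large instances ("most similar" per the method's textual
definition — i.e., argmax cosine similarity); cells with no qualifying
neighbor keep their label and are counted. The representation used is
whichever produced the labeling (CC histograms, CF-IDF community
vectors broadcast to member cells, CNE density vectors); externally
produced labelings require a representation to be supplied. An optional
`iterate=True` repeats passes to a fixed point.

**HMRF.** Emissions P(CT|CN) are re-estimated from the current labels
at every E-step (the alternation is written as a per-iteration pair, so
re-estimation each sweep is the faithful reading). The M-step is
synchronous; β = 9 and an ε-radius graph at mean degree 5 are the
defaults. β = 0 is special-cased to a single sweep, realizing the
per-cell emission argmax of the *input* labeling — the documented
degenerate limit. CNs emptied mid-run drop out of the argmax.
Synchronous updates can oscillate; the loop returns the last labeling
and a convergence flag after at most 100 sweeps.

## Evaluation

Mean CN entropy is `Σ_{n,t} (|C_nt|/|C|) · log2(|C_n|/|C_nt|)` in bits,
pooled over images, with 0·log terms as 0; it is 0 iff every CN is a
single CT and equals the dataset CT entropy when one CN holds all
cells. Mean CN instance size is `|C| /` (number of instances). NMI uses
the arithmetic-mean normalization (stated here because several
conventions exist) and is clipped to [0, 1] against floating-point
overshoot.

## Downstream analyses

- **PWM**: `score[t,n] = log2((|C_nt| + F(t))/(|C_n| + 1)) − log2 F(t)`;
  the pseudocounts (+F(t) numerator, +1 denominator, exactly as defined)
  keep empty CNs finite. CNs are named by their top-scoring CT.
- **Differential enrichment**: per-(CT, CN) OLS over donors of
  `log2 F_n^d(t)` on the group indicator and `log2 F^d(t)`. Donors with
  zero frequency on either side are dropped from that fit (log
  undefined) and counted; rows with < 3 usable donors, a single-arm
  design, or no residual degrees of freedom are flagged unusable. Raw
  p-values are reported (the conventional 0.05/0.1 gates are raw); a
  Benjamini–Hochberg column is emitted as supplementary output and never
  gates anything.
- **Tensor modules**: the CT×CN×donor tensor of donor-normalized joint
  distributions is factorized by non-negative Tucker decomposition,
  written in-package: nonnegative-HOSVD initialization (absolute leading
  singular vectors of the mode unfoldings — deterministic, and exact on
  exactly factorizable tensors) followed by multiplicative updates.
  Default ranks (6, 6, 2). Interaction strengths are the core rescaled
  to max 1 within each tissue-module slice, displayed above 0.1 — the
  rescaling pins down an otherwise scale-free threshold.
- **Inter-CN network**: largest canonical correlation between two CNs'
  donor×CT frequency blocks, computed in closed form (orthonormal bases
  via rank-truncated SVD, then the top singular value of their cross
  product). Significance by donor-row permutation with the add-one
  estimator `(b+1)/(n_perm+1)`, which is super-uniform under
  exchangeability; edges at p < 0.1, display threshold 0.9 on strength
  1 − p. When donors do not outnumber target CTs the unpermuted
  correlation saturates at 1 and a warning directs users to the
  permutation p-value.
- **Spatial contexts**: windows are the 100 nearest same-image cells
  (all of them in smaller images). Adding CNs in decreasing window-count
  order (count ties toward the lower label) until coverage strictly
  exceeds 90% yields the minimum-cardinality covering set, so minimality
  needs no search; the tie rule makes assignments deterministic. SCs
  below 0.001% of total cells are dropped; subset relations among the
  survivors and the 20 largest are reported for map construction.
- **Assembly rules**: instance adjacency is defined by Delaunay edges
  between instances — a deterministic, resolution-free surrogate for
  adjacency of rasterized instance masks (the raster route depends on a
  pixel size the cell table does not carry). Rules cnX → cnX-cnY
  (≥ 70% of cnX instances touch a cnY instance) and cnX → cnXnotY
  (≥ 70% touch none) require ≥ 5 source instances. "Conserved" rules
  hold in every image by default; a fraction flag relaxes this.

## Synthetic tissues

The simulator plants K Voronoi (or grid-block) CN regions per image,
samples cell locations uniformly (exact cell counts; per-region rate
multipliers can induce density inhomogeneity to exercise CNE's adaptive
bandwidths), and draws CTs from per-CN categorical profiles with a
uniform resampling corruption at rate ρ. The default profiles give each
CN 80% mass on its own two CTs (pairwise total-variation distance
≥ 0.73 at K = 4); the default benchmark tissue is one image of 2,000
cells, K = 4, ρ = 0.1 — small enough for the whole recovery loop to run
in seconds, large enough for stable NMI. `make_group_contrast`
generates donor-level frequency tables exactly from the differential
linear model (default planted coefficients (−2, 1, 0.8), chosen so
frequency rows stay valid without renormalization) for calibration and
exact-recovery checks.

What passing on these tissues does **not** show: robustness to
segmentation error, to CT misannotation structured by space, to
continuous CT gradients without region boundaries, or to the
hundreds-of-thousands-of-cells regime of whole-slide images (the O(n²)
per-image steps — radius-graph ε search, tie-stable k-NN — are exact
desk-scale constructions, not streaming implementations).

## Numerical choices and limitations

- Bisection and the perplexity curve are evaluated in a numerically
  guarded softmax (max-subtraction); padded neighbors carry +inf
  distance and zero density.
- All stochastic components (k-means++ init, Louvain, simulator,
  permutation tests) take explicit integer seeds; identical inputs and
  seeds reproduce identical labelings bit-for-bit.
- The k-means community clustering in CF-IDF weighs every community
  equally regardless of its cell count; weighting by size is a
  plausible alternative that would bias centroids toward large
  communities.
- HMRF with large β can lock into the initial label geometry; the
  emission factor then matters little and the method behaves as a
  majority filter.
- The Tucker solver uses multiplicative updates, which converge to a
  stationary point, not a certified global optimum; the deterministic
  HOSVD-style init makes runs reproducible but a poor local optimum is
  possible on adversarial tensors.
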