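# cnkit

Cellular-neighborhood (CN) analysis for annotated multiplexed tissue
images (CODEX-style data). Given a per-cell table — sample group, sample
(donor), image, `x`/`y` coordinates and an annotated cell type (CT) —
cnkit identifies CNs, smooths them, scores them, and runs the standard
downstream CT–CN and CN–CN analyses. A planted-CN tissue simulator makes
every stage testable without external data.

## Who it is for

Labs doing spatial tissue profiling who already have segmented,
cell-typed images and want to ask: *which recurrent local CT
compositions (niches) exist in this tissue, and how do they differ
between patient groups?*

## Methods at a glance

**Identification** (clustering pooled across images, so CN labels are
comparable between samples):

- **CC** — each cell is represented by the CT histogram over its nearest
  *m* cells (itself included) and cells are clustered by k-means.
- **CF-IDF** — Louvain communities on a per-image distance-weighted
  ε-radius graph (edge weight `log2(1/(0.005 + d̂))` with `d̂` the
  normalized edge length); each community's CT frequency vector is
  rescaled by `ln(1/F(t))` — the log inverse dataset-wide CT frequency,
  down-weighting globally common CTs — then communities are clustered by
  k-means and cells inherit their community's CN.
- **CNE** (cellular neighbor embedding) — each cell *x* gets a vector
  `f_t(x) = Σ_{y} exp(−d(x,y)²/2σ_x²)` summing Gaussian densities of its
  30 nearest neighbors (plus a distance-clamped self term) per CT, with
  σ_x calibrated per cell so the t-SNE-style perplexity of the kernel
  equals a target `perp` (the effective-neighbor count). After ℓ1
  normalization and IDF rescaling, cells are clustered by *spatially
  regularized k-means*: assignment of cell *x* minimizes
  `‖f(x) − c_n‖² + (λ/|G_x|) Σ_{y∈G_x} ‖c_n − c_{n_y}‖²` over Delaunay
  neighbors `G_x` (λ = 0.25 by default), encouraging spatially coherent
  labels.

**Smoothing**:

- **Naive smoothing** — cells in CN instances (connected same-label
  Delaunay components) smaller than *s* = 3 adopt the label of their most
  cosine-similar neighbor residing in a large instance; one simultaneous
  pass.
- **HMRF** — EM on a hidden Markov random field with CTs as emissions
  and CN labels as hidden states on an ε-radius graph (mean degree 5):
  each sweep reassigns every cell to
  `argmax_n P(t_x|n) · exp(β · #{neighbors labeled n})` (β = 9 default).

**Evaluation** — purity = mean CN entropy `H(CT|CN)` in bits;
granularity = mean CN instance size; labeling agreement = NMI
(arithmetic-mean normalization).

**Analysis** — CT-enrichment PWM (log-odds with pseudocounts);
differential CT enrichment (per-(CT, CN) donor-level OLS
`log2 F_n^d(t) = β0 + β1·1[d∈D] + β2·log2 F^d(t)`); non-negative Tucker
decomposition of the donor-stacked CT×CN×donor tensor into CT/CN/tissue
modules; inter-CN communication network (permutation-tested canonical
correlations of donor CT frequencies); spatial-context map (minimal CN
set covering >90% of each cell's 100 nearest neighbors); assembly rules
over the CN-instance adjacency graph.

## Worked example

```python
from cnkit import (identify_cne, naive_smooth, nmi, mean_cn_entropy,
                   mean_cn_instance_size, build_delaunay_graphs, ct_enrichment_pwm)
from cnkit.synthetic import SyntheticTissueSpec, simulate_tissue

cells, truth = simulate_tissue(
    SyntheticTissueSpec(n_cells=2000, n_cns=4, noise=0.1, seed=0))
res = identify_cne(cells, k=4, perp=15.0, seed=0)
graphs = build_delaunay_graphs(cells)
smoothed = naive_smooth(res.labeling, res.representation, graphs, s=3)

print(f"NMI vs planted CNs:        {nmi(smoothed, truth):.3f}")
print(f"mean CN entropy (bits):    {mean_cn_entropy(smoothed, cells):.3f}")
print(f"mean CN instance size:     {mean_cn_instance_size(smoothed, graphs):.1f}")
print("CN names by top CT:       ", ct_enrichment_pwm(smoothed, cells).attrs["cn_names"])
```

prints

```
NMI vs planted CNs:        0.919
mean CN entropy (bits):    2.253
mean CN instance size:     333.3
CN names by top CT:        {0: 'ct3', 1: 'ct5', 2: 'ct6', 3: 'ct1'}
```

The simulated tissue plants four Voronoi CN regions whose CT profiles
put 80% of their mass on disjoint CT pairs, then corrupts 10% of CTs.
NMI 0.919 means the recovered, smoothed labeling agrees closely with the
planted one; the entropy reflects the mixed profiles (each CN genuinely
emits several CTs); instance size 333 shows smoothing produced large
contiguous regions rather than salt-and-pepper labels; and each CN is
named after its most enriched CT.

The same workflow is available from the shell:

```bash
cnkit simulate --n-cells 2000 --k 4 --seed 0 --out cells.csv
cnkit identify --method cne --k 4 --perp 15 --seed 0 --in cells.csv --out labeled.csv
cnkit smooth --method naive --in labeled.csv --out smoothed.csv
cnkit evaluate --in smoothed.csv --out metrics.csv
cnkit analyze --task enrichment --in smoothed.csv --out enr
cnkit visualize --in smoothed.csv --image img0 --out voronoi.csv
```

or as a single YAML-configured pipeline (`cnkit pipeline --config
run.yaml --outdir out/`), which writes a JSON run manifest for
reproducibility.

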