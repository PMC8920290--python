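# mifspat

Spatial statistics for the tumor immune microenvironment (TIME) measured by
multiplex immunofluorescence (mIF). Given per-cell coordinates and marker
calls (HALO-style exports: CD3, CD8, FOXP3, ... with a tumor/stroma
compartment), `mifspat` quantifies how strongly immune cells cluster — or
co-occur across cell types — within each tissue sample, and links those
spatial measures, together with cell abundance, to overall survival across
a cohort. It is aimed at biostatisticians analysing mIF studies on tissue
microarrays (TMAs) or intra-tumoral regions of interest (ROIs).

## The statistic

Cell locations are treated as a spatial point process over the convex hull
W of all measured cells of a sample (area A). Clustering of a phenotype is
measured with edge-corrected Ripley's K:

    K̂(r) = A / (n(n−1)) · Σᵢ Σ_{j≠i} w_ij · 1{d(pᵢ, pⱼ) < r}

with `translation` or `isotropic` edge-correction weights w_ij ≥ 1, and a
bivariate (cross) form K̂₁₂(r) = A/(n₁n₂) · ΣΣ w_ij · 1{d < r} for
co-occurrence of two phenotypes around "anchor" cells. Under complete
spatial randomness (CSR), E[K(r)] = πr².

TMA cores, however, contain folds and tears — regions where no cell could
be measured — so πr² is a biased CSR reference. `mifspat` instead builds an
**empirical CSR null**: holding every cell location (and hence every hole)
fixed, the positive labels are reassigned uniformly at random (counts
preserved, 100 permutations by default) and K̂ is recomputed each time. The
per-sample spatial measure is the

    degree of clustering = K̂_observed(r) − mean of the permuted K̂(r)

at r = 30 µm: positive for clustering, negative for regularity.

Downstream, samples are grouped by abundance (% positive cells) ×
clustering degree — `None/LL/LH/HL/HH`, or `AAN/APN/PAN/PPL/PPH` for
bivariate co-occurrence — using constrained optimal cut-points (10-fold
cross-validated log-rank grid search, every group ≥ 10 samples), and the
groups enter Cox proportional-hazards models with age and stage covariates
and a cluster-robust variance over subjects with repeated samples. A
likelihood-ratio test compares the 5-group (spatial) model against the
abundance-only coarsening.

## Worked example

```python
import numpy as np
from mifspat import (simulate_points, convex_hull_window, ripley_k_univariate,
                     empirical_csr_univariate, degree_of_clustering, theoretical_csr)

# clustered sample: Thomas-process CD3+ cells over a uniform background
sample = simulate_points(
    window=(1000.0, 1000.0), lambda_bg=7e-4,
    positivity=("thomas", 5e-5, 6.0, 15.0),   # kappa /um^2, mean offspring, sigma um
    seed=11,
)
cells = sample.coords()
window = convex_hull_window(cells)
positives = cells[sample.positive_mask("CD3")]
k_obs = ripley_k_univariate(positives, window, [30.0], "translation")
null = empirical_csr_univariate(sample, "CD3", window=window, r_grid=30.0,
                                n_perm=100, seed=11)
deg = degree_of_clustering(k_obs, null, 30.0)
print(f"observed K(30):    {deg.k_observed:8.1f} um^2")
print(f"permutation CSR:   {deg.csr_mean:8.1f} um^2  (theoretical pi r^2 = {theoretical_csr([30.0])[0]:.1f})")
print(f"degree of clustering: {deg.degree:8.1f} um^2")
```

prints

```
observed K(30):     13423.2 um^2
permutation CSR:     3800.8 um^2  (theoretical pi r^2 = 2827.4)
degree of clustering:   9622.4 um^2
```

The 956-cell sample carries 291 CD3+ cells (30.4%) laid down by a Thomas
cluster process, so the observed K(30) far exceeds its CSR reference: the
degree of ~9600 µm² says that, within 30 µm of a typical CD3+ cell, about
9600/πr² ≈ 3.4× more CD3+ neighbours are found than label-shuffling of the
same cell locations would produce. Note the permutation CSR mean (3800.8)
itself exceeds πr² (2827.4): the clustered geometry of the measured cells is
inherited by the null, which is exactly what makes the degree robust to
uneven tissue.

## Command line

```sh
mifspat simulate --config cfg.yaml --out sim/          # synthetic cohort + truth
mifspat degree   --config cfg.yaml --cells sim/cells.tsv --out degree.tsv
mifspat bias     --config cfg.yaml --cells sim/cells.tsv --out bias.tsv
mifspat survival --config cfg.yaml --degree degree.tsv \
                 --clinical sim/clinical.tsv --out surv/
```

The YAML config must set an explicit `seed`; identical config + inputs give
bit-identical outputs. `degree` writes one row per sample × phenotype
(abundance, observed K, CSR mean, degree, estimability); `bias` tabulates
theoretical-vs-permuted CSR per sample; `survival` writes cut-points, group
assignments, Cox hazard ratios with robust CIs, and the spatial-vs-abundance
likelihood-ratio p-value.

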