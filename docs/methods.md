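# Methods

## Model and estimators

Cell locations within one tissue sample are modelled as a realisation of a
planar point process observed over a convex window W. W is taken to be the
convex hull of *all* measured cells of the sample (any marker status): the
tissue region is defined by where cells could be measured at all, not by
where the positive cells happen to lie. Hulls are computed with Qhull;
fewer than three non-collinear cells is a degenerate window and the sample
is flagged not estimable.

Ripley's K for a phenotype (a strict conjunction of marker flags, e.g.
CD3+FOXP3+) with n positive cells is estimated as

    K̂(r) = A / (n(n−1)) · Σᵢ Σ_{j≠i} w_ij · 1{d(pᵢ,pⱼ) < r},

and the cross-type (bivariate) form for n₁ anchor and n₂ other cells as
K̂₁₂(r) = A/(n₁n₂) · Σ_{i∈anchors} Σ_{j∈others} w_ij · 1{d < r}. The
indicator is strict (`<`); ties at exactly r are excluded. The univariate
estimator requires n ≥ 2, the bivariate one n₁, n₂ ≥ 1; below these the
quantity is reported as *not estimable*, which is a different outcome from
K̂ = 0.

Edge-correction weights w_ij ≥ 1 compensate for neighbourhood area lost
outside W:

* **translation** — w_ij = |W| / |W ∩ (W + (pⱼ − pᵢ))|, evaluated by
  polygon intersection (Shapely, vectorised over pairs). Symmetric in the
  displacement, hence the translation-corrected bivariate K is exactly
  symmetric in its two point sets.
* **isotropic** — the reciprocal of the fraction of the circle centred at
  the anchor pᵢ with radius d(pᵢ,pⱼ) whose circumference lies inside W.
  For a convex polygon this is exact: each window edge whose line cuts the
  circle excludes one arc (half-width arccos(h/d) about the outward
  normal, h = distance from pᵢ to the edge line), and the union of the
  excluded arcs is measured by interval merging. Asymmetric: the ring is
  drawn about the anchor.

Directional weights are capped at the number of points in the pattern, a
guard against near-zero arc fractions for cells sitting on the window
boundary. In the regimes used here (r = 30 µm in ~1 mm fields) the cap
essentially never binds.

Under complete spatial randomness (CSR) E[K(r)] = πr² ≈ 2827.4 µm² at
r = 30. Weights only need evaluating for pairs closer than max r, so pair
search uses a k-d tree and K̂ is exact, not approximate; a brute-force
double loop reproduces it to floating-point accuracy in the test suite.

## Permutation CSR null and the degree of clustering

TMA cores commonly contain folds and tears: regions where no cells could
be measured. The convex hull then overstates the area the cells could
occupy and the theoretical πr² *underestimates* K under CSR, which would
masquerade as spatial clustering. The empirical null avoids this by
conditioning on the observed geometry:

1. fix all cell locations, the window, and therefore all pairwise
   distances and edge weights (they are computed once and shared);
2. draw n_pos locations uniformly without replacement from all cells of
   the (compartment-filtered) sample — a random relabelling that preserves
   the positive/negative counts;
3. evaluate K̂ on the drawn set; repeat n_perm = 100 times;
4. the mean of the permuted K̂ values is the CSR estimate for *this*
   sample's geometry, and

   degree of clustering = K̂_observed(r) − mean_perm K̂(r).

The bivariate null reassigns both labels jointly to disjoint location sets
with counts preserved. All randomness flows from an explicit integer seed;
per-sample child seeds are derived from the run seed and the sample id (a
CRC32 mix), so results are independent of sample ordering and bit
reproducible. Analyses can be restricted to the tumor (or stromal)
compartment before any of this; the permutation then only involves the
cells of that compartment.

Samples with exactly one positive cell have no defined univariate degree;
in the grouping stage they are assigned the Low-clustering level (a single
cell cannot exhibit clustering) and carry an `estimable = False` flag for
sensitivity analyses.

## Abundance × clustering groups and survival

Per sample: abundance = 100·n_pos/n_total (%). Univariate groups:
`None` (abundance 0), else {L,H}×{L,H} by abundance ≥ a_cut and degree ≥
d_cut (ties go High). Bivariate co-occurrence groups: `AAN/APN/PAN` by
absence/presence of each type (present = at least one cell), `PPL/PPH` by
the degree cut when both are present.

Cut-points are chosen by a constrained, cross-validated optimal cut-point
search. Folds (default 10) partition *subjects*, not samples, so a
subject's repeated samples never inform the cuts applied to them. Within a
fold's training set the candidate grid consists of midpoints between
consecutive unique observed values (per dimension, thinned to ≤ 50 by
quantile subsampling); a candidate pair is feasible only if each of
LL/LH/HL/HH keeps ≥ 10 nonzero-abundance training samples (zero-abundance
samples form the None group and do not constrain the grid). Each feasible
pair is scored by the 5-group log-rank chi-square on the training samples
— the operationalisation of "largest difference in the survival curves" —
and the final cuts are the per-dimension medians of the fold optima. The
log-rank statistic is implemented in vectorised form for grid-search
speed and is checked against lifelines in the tests. Note the optimal
cut-point objective is flat near its optimum: cuts a few grid steps apart
often differ by a single relabelled boundary sample, so recovery of
generating cut-points should be judged in label space, not by the raw cut
values.

Survival association uses Cox proportional-hazards models (lifelines) on
per-sample rows: group indicators (reference = `None`, hazard ratio 1 by
construction), age at diagnosis (linear, years) and stage (I reference,
indicator terms for II–IV). Repeated samples per subject are handled with
the cluster-robust (sandwich) variance; the overall group test is the
robust Wald chi-square of all group coefficients jointly (4 df with five
populated groups). lifelines exposes the sandwich variance only through
per-coefficient standard errors, so the full robust covariance is rebuilt
from the model's delta-beta residuals (verified to reproduce lifelines'
robust standard errors exactly).

The spatial-information test compares the 5-group model against its
abundance-only coarsening (`None/Low/High`; `PPL+PPH → PP` in the
bivariate scheme) by a likelihood-ratio test on *unweighted* partial
likelihoods with df = the difference in indicator counts (2 univariate):
likelihood ratios are undefined for sandwich-variance fits, so the LRT
sets the clustering aside and is reported alongside the robust Wald test.
With repeated correlated samples the unweighted LRT is anticonservative —
see Limitations.

## Synthetic data generator

The generator produces every regime the pipeline must handle, with ground
truth recorded:

* **CSR regime** — cells homogeneous Poisson (default ~600–1000 cells per
  1000×1000 µm field, matching mIF cell densities), positivity independent
  Bernoulli at 1–30%.
* **Clustered regime** — positives from a Thomas process (parents Poisson
  with intensity κ, offspring Poisson(µ) displaced N(0, σ²), default
  σ = 15 µm) superposed on a uniform negative background. Thomas was
  chosen because its K has a closed form, K(r) = πr² + (1 − e^{−r²/4σ²})/κ,
  giving an analytic oracle; the K of the positives-plus-background
  superposition follows from the mixture formula, and random thinning
  (what the permutation does) preserves K. Parents are simulated on a 4σ
  padded window so boundary clusters are not thinned.
* **Holes** — discs with radii uniform on 40–90 µm punched at random
  centres until a target fraction of the window is covered (union area
  tracked exactly via polygon operations). Real tears are irregular, but
  disc unions reproduce the intensity inhomogeneity that matters.
* **Cohorts** — default 90 subjects × 3 samples (the scale of a typical
  TMA/ROI mIF study). Each subject draws a true group; samples realise it
  (abundance uniform in 0.4–1.5% for Low, 3–8% for High around a 2%
  generating cut; CSR vs Thomas labelling around a degree cut of 500 µm²).
  Survival is exponential with log-hazard = 0.02·(age−58) + stage effects
  (0/0.25/0.7/1.1) + group log-HR, baseline rate 0.0175/month (median ~40
  months), independent uniform censoring on 6–120 months — proportional
  hazards hold by construction, so Cox recovery is well posed. Default
  group log-HRs (0, −0.25, −0.8, −1.9, −0.7 for None/LL/LH/HL/HH) emulate
  the qualitative pattern where high-abundance/low-clustering patients
  fare best. A summary-level variant draws abundance and degree directly
  from the group-conditional distributions, skipping the spatial
  simulation; it exists so that calibration and power studies over
  hundreds of cohorts stay cheap, and its distributions sit strictly on
  the correct side of the generating cuts (≥ 4σ for the High-degree
  group).

What the generator does not emulate: segmentation or phenotype-calling
errors, intensity thresholds, anisotropic or irregular tears,
non-proportional hazards, informative censoring. Passing tests therefore
demonstrate correctness of the estimators and calibration of the
statistics under the stated models, not robustness to those artefacts.

## Numerical choices and validation conditions

* Radii are interpreted in microns everywhere; pixel inputs are converted
  at read time (default 0.4977 µm/pixel). The analysis radius defaults to
  r = 30 µm, with arbitrary diagnostic grids available.
* Windows estimated as the convex hull of the data carry a small negative
  bias in K̂ for uniform patterns (the hull hugs the points; ≈ −1.7% of
  πr² at n = 1000, shrinking like log n / n). The degree statistic is
  insensitive — observed and permuted K share the window — but checks of
  the analytic CSR limit use ROI-like samples with the known rectangular
  window, where E[K̂] = πr² holds exactly.
* Edge-correction agreement (the translation-vs-isotropic correlation) is
  assessed on positive-cell patterns at 1–30% positivity with hull windows
  from all cells, i.e. the situation the method is used in; when K is
  instead computed on the full window-defining point set the differential
  boundary-weight noise is relatively larger and the correlation drops to
  ≈ 0.96.
* Type-I calibration of the survival stage is verified on null cohorts of
  250 subjects × 1 sample: the LRT's reference distribution assumes
  independent likelihood contributions, and the Wald chi-square is an
  asymptotic test. At the default 90-subject scale both tests are mildly
  anticonservative (the 4-df Wald rejects at ~9% for a nominal 5% even
  without repeated samples), and with three identical survival rows per
  subject the unweighted LRT rejects far above nominal — which is why the
  cluster-robust Wald is the primary group test and the LRT is reported
  alongside it.
* Cut-point ties in the grid search break deterministically toward the
  first candidate in grid order; fold assignment and the permutation null
  are seeded, so identical seeds give identical folds, cuts and nulls.
* Degenerate inputs: all-positive samples yield a zero-variance null
  (warned); empty compartments, < 2 positive cells or degenerate hulls
  propagate `estimable = False` rows rather than aborting a cohort run.

## Limitations

* The isotropic correction is exact only for convex windows; non-convex
  (alpha-shape) windows and inhomogeneous-K estimators are out of scope.
* The permutation null conditions on the measured cell locations; it
  corrects for where cells could not be *measured*, not for biological
  inhomogeneity of the underlying tissue.
* Optimal cut-points are data-driven and inherit the known type-I
  inflation of cut-point selection; the cross-validated, constrained
  search mitigates but does not eliminate it.
* Hazard-ratio recovery and coverage were demonstrated under proportional
  hazards with exponential baselines; the Cox stage itself makes the usual
  proportional-hazards assumption on real data.
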