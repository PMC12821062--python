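# Methods

This note documents the models, defaults and numerical choices behind
`phenostable`, what the synthetic cohort generator does and does not
emulate, and the known limitations of the procedure.

## The clustering objective

The pipeline's core is discriminative clustering by generalized mutual
information (GEMINI) in its one-vs-all maximum-mean-discrepancy form.
Soft assignments come from a linear softmax head p(y|x) = softmax(Wᵀx+b);
the score of an assignment τ under a kernel Gram matrix K is

    MMD_k² = τ_kᵀKτ_k/s_k² − 2τ_kᵀK1/(n·s_k) + 1ᵀK1/n²,
    GEMINI(τ; K) = Σ_k (s_k/n)·√max(MMD_k², 0),   s_k = Σ_i τ_ik.

Empty clusters contribute zero.  Two degenerate assignments score
exactly zero — the uniform assignment and the single-cluster assignment
— because each cluster-conditional distribution then equals the marginal.
The GEMINI family offers several divergences (MMD, Wasserstein) and
aggregations (one-vs-all, one-vs-one); one-vs-all MMD is used here
because it is the cheapest, has a closed-form gradient, and with a linear
kernel reduces to the distance between cluster mean and grand mean, which
makes it directly auditable by hand.  The head is a plain linear softmax
(no hidden layers): deterministic, interpretable, and sufficient for the
tabular, z-scaled inputs this pipeline consumes.

**Kernel.** Default linear (on z-scaled features).  An RBF kernel with a
fixed or median-heuristic bandwidth is available; the median heuristic
sets σ to the median pairwise Euclidean distance.

## Sparse training and feature selection

Feature selection is integrated through a group penalty λ·Σ_j‖W_j·‖₂ over
input-feature rows of W.  Training is full-batch proximal gradient
ascent: a gradient step on the GEMINI score (backpropagated analytically
through the softmax) followed by block soft-thresholding of each feature
row, which yields exact zeros.  Settings:

- step size 0.05, fixed; 600 iterations at λ = 0, then 300 per
  subsequent path point, warm-started;
- penalty path: 0 followed by 14 geometric points from 0.002 to 0.3
  (on z-scaled features with the linear kernel the relevant score
  gradients are O(1), which pins this λ range);
- selection tolerance: a feature is selected when ‖W_j·‖₂ > 1e-4
  (the prox makes discarded rows exactly 0, so this only guards
  round-off);
- the returned model is the *last* (sparsest) path point whose GEMINI
  score is ≥ 0.9 of the unpenalized maximum.

The iteration budget matters: with too few iterations per path point the
score collapses spuriously at moderate λ and the 90%-retention rule stops
early, returning dense models whose chance-correlated noise features then
survive ensemble frequency counting.  The defaults above were set so the
per-model score is converged at every path point at the pipeline's
design size (n ≈ 350, p ≈ 95, 10 clusters).

Across-model variation in the ensemble is random initialization only
(W ~ N(0, 0.1), seeded per model); data, kernel and path are shared.
Ensemble-level selection frequency counts *variables*: one-hot columns of
a categorical variable are OR-ed into their parent before counting, and
the "top-selected" set uses a strict > 0.9 threshold over kept models.

Numerical guards: a cancellation floor treats MMD² residuals below
1e-12·max(1, mean|K|) as zero (the estimator is a difference of like-sized
terms, so the uniform assignment would otherwise return √ε noise); a
non-finite score aborts the run, reporting the offending λ and seed.

## Stability over visits, consensus, merging

A model's stability is measured by assigning the follow-up visits (Dr)
with the model's own softmax predictor and comparing to the patient's
first-visit cluster: visit-wise accuracy pools all follow-up visits;
patient-wise accuracy averages per-patient match fractions, removing the
imbalance between patients with one and with seven follow-ups.  Models
with patient-wise accuracy ≥ 0.9 × best are kept; the best model is kept
by construction, so filtering can never empty the ensemble.

Consensus aggregates the kept models' first-visit labelings into the
co-assignment matrix M (entries are multiples of 1/m for m kept models).
PAC is the fraction of patient pairs with co-assignment strictly inside
(0.1, 0.9); strict bounds make a unanimous ensemble give PAC = 0.  PAC is
computed over the *filtered* models, and the run manifest records that
choice.  The final fine partition is average-linkage agglomeration on
1 − M cut at k_fine = 10 (deterministic; labels ordered by decreasing
size, ties broken by first appearance).  Fine clusters are merged to
k_coarse = 5 phenogroups by repeatedly fusing the two closest centroids
(means of the scaled top-selected features) and replacing them by their
size-weighted mean.  Size weighting respects cluster mass; the unweighted
variant would over-value singleton outlier clusters.

A caveat established by the test suite's permutation experiment: when
every model in the ensemble is internally stable (small within-patient
noise), the stability filter keeps essentially the whole ensemble, and
destroying the visit structure (shuffling follow-up rows across patients)
collapses accuracy to chance (≈ 1/k_fine) but does *not* reliably raise
PAC — the permuted branch keeps a small, arbitrary subset of models, and
PAC over few labelings is biased downward because co-assignment
frequencies quantize to multiples of 1/m.  PAC comparisons are therefore
only meaningful between consensus matrices built from similar numbers of
models; the pipeline reports the number used alongside the score.

## Deployment classifier

Multinomial logistic regression (L2, lbfgs) over the top-selected
variables, standardized internally; the regularization strength is chosen
from 7 log-spaced values (1e-3…1e3) by stratified 5-fold cross-validated
macro-F1 (macro because the phenogroups are imbalanced and small clusters
matter clinically), with a 2.5/97.5 fold-percentile interval; the final
model is refit on all first visits.  Classes with fewer members than
folds reduce the fold count with a warning.  Missing inputs — the
motivating case is C-reactive protein, often unavailable at the point of
care — are imputed with the training means on the raw scale before
standardization; imputation provably never changes the prediction of a
complete record.  Per-class weights are reported normalized so absolute
values sum to 100, preserving sign.

## Outcomes

- **Severity**: peak aortic jet velocity (cm/s) graded mild
  [200, 300), moderate [300, 400), severe ≥ 400.  The conventional
  printed bins (200–290, 300–390, ≥400) leave 290–300 and 390–400
  unassigned because the measurements are conventionally rounded; the gap
  values are assigned to the lower class.  Values < 200 cm/s fall outside
  the cohort definition and are rejected.
- **Group comparisons**: Kruskal-Wallis omnibus for continuous variables
  with pairwise two-sided Mann-Whitney flags at p < 0.05, reported only
  when the omnibus test is significant; chi-squared for categoricals.  No
  multiplicity correction is applied to the pairwise flags (they are
  descriptive table annotations, not confirmatory tests).  All-identical
  values give p = 1 by convention.
- **Progression**: per-patient annualized change (last − baseline)/Δt of
  a designated variable; single-visit patients are excluded; per-cluster
  median [IQR] with the comparison machinery above.
- **Survival**: Kaplan-Meier and (multivariate) log-rank via lifelines;
  Cox proportional hazards with the coarse cluster as a categorical
  predictor (largest cluster = reference) adjusted for age, sex and
  baseline severity; the proportional-hazards assumption is checked with
  the scaled-Schoenfeld-residual test (rank time transform).  The
  composite endpoint is time to first of death or valve replacement; the
  death-only endpoint treats valve replacement as censoring — a formal
  competing-risks model is deliberately out of scope.

## The synthetic cohort generator

The generator emulates the *structural* assumptions of the pipeline, not
any real cohort's marginals:

- A patient's latent profile is the cluster mean plus a unit-SD Gaussian
  patient effect; visits add cluster-specific drift × time plus Gaussian
  noise with SD `within_patient_sd` (in units of the patient-level SD,
  so 0.1 means visits move a tenth of the between-patient spread).
- Only the first `n_informative` variables are cluster-dependent.
  Informative continuous means are ± separation/2 sign patterns, redrawn
  until every cluster pair differs on at least a third of the informative
  features — without that constraint a random draw can leave two clusters
  differing on a single feature and the nominal per-feature separation is
  not delivered.  Informative binaries use 0.15/0.85 per-cluster rates;
  informative multilevels use sharp Dirichlet(0.5) level probabilities.
  Categorical values are drawn once per patient and held fixed across
  visits.
- Visits are yearly with ± 3 months of uniform jitter (the exact spacing
  distribution of a real cohort is not modelled).
- Missingness is MCAR per variable at configurable rates; identifiers,
  visit fields and outcomes are never blanked.  Missing-not-at-random
  mechanisms are out of scope, so passing tests say nothing about
  complete-case bias under informative missingness.
- Death and valve replacement are competing exponential processes with a
  shared per-cluster log-hazard-ratio vector (an optional separate vector
  for death), censored by an independent exponential.  Defaults
  (death 0.025/yr, replacement 0.075/yr, censoring 0.08/yr) put the
  death and composite event fractions near 19% and 54% over a ~7-year
  horizon, the regime of a contemporary AS cohort.  Default cohort shape:
  349 patients, 5 clusters with weights (0.23, 0.16, 0.13, 0.34, 0.14),
  87 variables encoding to 95 features, 1–8 visits per patient.
- Two continuous variables carry per-cluster drift (defaults 0.5 SD/yr
  for cluster 1 vs 0.1–0.15 elsewhere), mimicking one fast-progressing
  phenogroup.

Everything is driven by one integer seed; identical config gives
byte-identical CSV output.

What passing tests on this generator do **not** show: recovery under
realistic feature correlations (features are independent within cluster),
under informative missingness, or at the signal-to-noise ratio of real
echocardiographic data.  The generator's separation parameter is the
single knob that moves the problem between trivial and impossible, and
results are always reported at a stated separation.

## Problem sizes used in the tests

The test suite and acceptance script run the full pipeline on a
350-patient cohort (5 clusters, separation 4 SD on 10 of 95 variables,
within-patient SD 0.1) with a 24-model ensemble — the ensemble count is a
scaled-down version of the 120-model default, keeping the whole suite in
the minutes range; hazard-ratio recovery uses 2000-patient replicates.
Design parameters of the pipeline itself (10 fine clusters, 5 coarse,
0.05 missingness screen, 0.9 retention, 0.9 selection frequency, PAC
bounds 0.1/0.9) are the study defaults throughout.

## Known limitations

- The GEMINI optimization is non-convex; different seeds reach different
  local optima.  The ensemble-consensus design treats that variation as
  signal, but single-model outputs should not be interpreted alone.
- Average-linkage consensus at k_fine = 10 can isolate singleton clusters
  of ambiguous patients; the centroid merge then spends a coarse slot on
  them.  With a well-converged ensemble this is rare, but a coarse
  cluster of size ~1 in real output signals an unstable patient, not a
  phenogroup.
- The deployment model inherits any instability of the consensus labels;
  its cross-validated F1 measures agreement with those labels, not
  clinical validity.
- The severity grading, annualization and endpoint conventions are those
  of aortic-stenosis practice; applying the pipeline to another disease
  area requires revisiting the outcomes module, not the clustering core.
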