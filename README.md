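# phenostable

Stable-over-time phenogrouping of longitudinal clinical cohorts.

`phenostable` implements an unsupervised pipeline for discovering patient
phenogroups in longitudinal tabular data — the motivating application is
asymptomatic aortic stenosis (AS), where mixed clinical, laboratory and
echocardiographic variables are collected at yearly follow-up visits and
the clinically meaningful subgroups are assumed *stable in time*: a
patient belongs to one phenogroup, and a good clustering should place all
of a patient's visits in the same cluster.  It is written for
biostatisticians and clinical ML researchers who want a reproducible,
testable implementation of the full procedure, including a synthetic
cohort generator that stands in for non-public study data.

## The method

1. **Split.** The cohort is split into first visits (`Df`, one row per
   patient) and all subsequent visits (`Dr`).  Variables with more than
   5% missing first-visit values are excluded; remaining rows are
   complete-case filtered; mixed-type variables are one-hot encoded and
   z-scaled with parameters fitted on `Df` only.

2. **Sparse GEMINI ensemble.** Discriminative clustering maximizes the
   generalized mutual information (GEMINI) in its one-vs-all MMD form.
   With soft assignments τ ∈ ℝ^{n×K} from a linear softmax head
   p(y=k|x) = softmax(Wᵀx + b), cluster masses s_k = Σ_i τ_ik and a
   kernel Gram matrix K:

       MMD_k² = τ_kᵀKτ_k / s_k² − 2 τ_kᵀK1 / (n s_k) + 1ᵀK1 / n²
       GEMINI = Σ_k (s_k/n) · √max(MMD_k², 0)

   i.e. the mass-weighted kernel distance between each cluster's
   distribution and the whole-cohort distribution (with a linear kernel,
   exactly the distance between the cluster mean and the grand mean).
   A group-lasso penalty λ·Σ_j‖W_j·‖₂ over input-feature rows performs
   integrated feature selection along an increasing penalty path; the
   retained model is the sparsest one keeping ≥ 90% of the unpenalized
   score.  The run is repeated (default 120 models, 10 clusters each)
   from different random initializations.

3. **Stability filtering.** Each model assigns `Dr`; the patient's
   first-visit cluster serves as the reference label.  Visit-wise and
   patient-wise accuracies are reported and models within 90% of the best
   patient-wise accuracy are kept.

4. **Consensus.** Kept models' first-visit labelings form a patient ×
   patient co-assignment matrix M, summarized by PAC (the proportion of
   pairs co-clustered strictly between 10% and 90% of the time; lower is
   more stable).  Average-linkage agglomeration on 1 − M cut at 10 gives
   fine clusters, which are merged to 5 coarse phenogroups by repeatedly
   fusing the closest (size-weighted) centroids in selected-feature
   space.

5. **Deployment.** Because consensus clustering cannot place unseen
   patients, a grid-searched multinomial logistic regression maps the
   top-selected variables (those chosen by > 90% of kept models) to the
   coarse phenogroups, with training-mean imputation for missing inputs
   and per-class weights normalized so absolute values sum to 100%.

6. **Outcomes.** Phenogroups are characterized by AS severity classes
   (V_peak 200–290 mild / 300–390 moderate / ≥ 400 cm/s severe),
   annualized progression rates ((last − baseline)/Δt), Kruskal-Wallis /
   chi-squared comparisons with pairwise flags, Kaplan-Meier curves with
   log-rank tests, and Cox proportional-hazards models adjusted for age,
   sex and baseline V_peak with scaled-Schoenfeld diagnostics.

## Worked example

```bash
python examples/02_cluster_pipeline.py
```

```
models kept:          8/8
visit-wise accuracy:  96.3%
patient-wise accuracy:96.1%
PAC:                  33.1%  (lower = more stable consensus)
top-selected vars:    ['cont_000', 'cont_002', 'cont_003', 'cont_004', 'cont_005', 'cont_010']
ARI vs planted groups:1.000  (1.0 = exact recovery)
```

On a 200-patient synthetic cohort with 3 planted phenogroups, all 8
clustering models keep ≥ 96% of follow-up visits in their first-visit
cluster, the consensus has moderate ambiguity (PAC 33%), the frequency
rule recovers the informative variables (plus one spurious), and the
merged phenogroups match the planted ones exactly (adjusted Rand index
1.0).  The other examples cover cohort simulation
(`01_simulate_cohort.py`), the deployable classifier with mean-imputed
inputs (`03_deploy_classifier.py`) and phenogroup characterization —
progression, Kaplan-Meier/log-rank, adjusted Cox (`04_outcomes.py`).

A thin CLI wraps the same stages:

```bash
phenostable simulate --seed 42 --out cohort.csv
phenostable run-all --cohort cohort.csv --out results/
phenostable predict --model results/deployment_model.json --data new_patients.csv --out predictions.csv
```

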