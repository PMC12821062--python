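"""Train and use the deployable cluster assigner.

Consensus clustering cannot place an unseen patient, so the pipeline ends
with a multinomial logistic regression over the top-selected variables.
This example fits it on pipeline output, shows the cross-validated
macro-F1, the per-class normalized weights, and a prediction for a new
patient with one missing input (mean-imputed).
"""

import numpy as np

from phenostable import (
    PipelineConfig,
    SimConfig,
    generate_cohort,
    normalized_weights,
    predict_cluster,
    run_pipeline,
)

sim = SimConfig(
    n_patients=200,
    n_clusters_true=3,
    cluster_weights=(0.45, 0.35, 0.2),
    n_continuous=20,
    n_binary=0,
    n_multilevel=0,
    n_informative=6,
    cluster_mean_separation=5.0,
    progression_rates=(0.5, 0.15, 0.1),
    cluster_log_hazard_ratios=(0.7, 0.0, 0.0),
    seed=42,
)
table = generate_cohort(sim)
result = run_pipeline(
    table, sim.variables(), PipelineConfig(n_models=8, n_clusters=6, k_fine=6, k_coarse=3)
)
model = result.deployment

print(f"inputs:        {model.feature_names}")
print(f"cv macro-F1:   {model.cv_f1:.3f}  (95% fold interval "
      f"{model.cv_f1_ci[0]:.3f}-{model.cv_f1_ci[1]:.3f})")
print(f"train accuracy:{model.train_accuracy:.1%}")

w = normalized_weights(model)
for cls, vec in w.items():
    top = np.argsort(-np.abs(vec))[:3]
    desc = ", ".join(f"{model.feature_names[j]}: {vec[j]:+.0f}%" for j in top)
    print(f"cluster {cls} driven by {desc}")

# a new patient: first input unavailable -> imputed with the training mean
x = result.split.Df.values[0].copy()
x_model = x[[result.split.Df.feature_names.index(f) for f in model.feature_names]]
x_model = model.imputation_means + 0.0 * x_model  # start from an average patient
x_model[0] = np.nan
label, probs = predict_cluster(x_model, model)
print(f"new patient -> cluster {label[0]} with probabilities {np.round(probs[0], 3)}")
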