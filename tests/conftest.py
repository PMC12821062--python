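"""Shared fixtures: small cohorts for unit tests and one full pipeline run
on the planted-phenogroup study design, shared by the acceptance tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from phenostable.pipeline import PipelineConfig, run_pipeline
from phenostable.simulate import SimConfig, VariableSpec, generate_cohort


def planted_config(**overrides) -> SimConfig:
    """Planted-cluster study design: 350 patients, 5 equal clusters separated
    by 4 SD on 10 informative variables among 95, small within-patient noise."""
    base = dict(
        n_patients=350,
        n_clusters_true=5,
        cluster_weights=(0.2,) * 5,
        n_continuous=95,
        n_binary=0,
        n_multilevel=0,
        n_informative=10,
        cluster_mean_separation=4.0,
        within_patient_sd=0.1,
        progression_rates=(0.5, 0.15, 0.15, 0.1, 0.1),
        seed=0,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def planted_cohort():
    cfg = planted_config()
    return cfg, generate_cohort(cfg)


@pytest.fixture(scope="session")
def pipeline_run(planted_cohort):
    """Full pipeline (24-model ensemble) on the planted cohort."""
    cfg, table = planted_cohort
    result = run_pipeline(table, cfg.variables(), PipelineConfig(n_models=24, base_seed=0))
    true = (
        table[table.visit_index == 0]
        .set_index("patient_id")["true_cluster"]
        .loc[result.split.Df.patient_ids]
        .to_numpy()
    )
    return cfg, table, result, true


@pytest.fixture()
def toy_variables() -> list[VariableSpec]:
    return [
        VariableSpec("height", "continuous"),
        VariableSpec("weight", "continuous"),
        VariableSpec("smoker", "binary"),
        VariableSpec("grade", "categorical", ("A", "B", "C")),
    ]


@pytest.fixture()
def toy_table() -> pd.DataFrame:
    """Four patients, mixed visit counts, one missing first-visit value."""
    rows = [
        # pid, visit, time, height, weight, smoker, grade
        ("P1", 0, 0.0, 170.0, 70.0, 0, "A"),
        ("P1", 1, 1.0, 171.0, 71.0, 0, "A"),
        ("P2", 0, 0.0, 160.0, 60.0, 1, "B"),
        ("P2", 1, 1.1, 161.0, np.nan, 1, "B"),
        ("P2", 2, 2.0, 162.0, 62.0, 1, "B"),
        ("P3", 0, 0.0, 180.0, np.nan, 0, "C"),
        ("P4", 0, 0.0, 175.0, 75.0, 1, "A"),
        ("P4", 1, 0.9, 176.0, 76.0, 1, "A"),
    ]
    df = pd.DataFrame(
        rows,
        columns=["patient_id", "visit_index", "visit_time", "height", "weight", "smoker", "grade"],
    )
    df["true_cluster"] = 0
    df["event_time"] = 5.0
    df["event_death"] = 0
    df["event_avr"] = 0
    return df
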