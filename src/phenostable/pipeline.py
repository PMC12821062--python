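"""End-to-end pipeline orchestration, configuration and run manifests.

Stages (each also exposed as a CLI subcommand): simulate -> preprocess +
ensemble clustering -> stability filtering -> consensus + merge ->
deployment model -> outcomes.  All randomness flows from explicit seeds
in the configuration; rerunning with the same config reproduces every
artifact byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import deploy, gemini, outcomes, stability
from .preprocess import SplitDataset, build_split
from .simulate import RESERVED_COLUMNS, SimConfig, VariableSpec


@dataclass
class PipelineConfig:
    """Defaults mirror the study regime: 5% missingness screen, 120 models
    of 10 clusters each, 90% stability retention, PAC bounds (0.1, 0.9),
    merge to 5 phenogroups, >90% feature-frequency rule."""

    max_missing_fraction: float = 0.05
    n_models: int = 120
    n_clusters: int = 10
    kernel: str = "linear"
    kernel_bandwidth: float | str = "median-heuristic"
    penalty_path: tuple[float, ...] | None = None
    base_seed: int = 0
    retention: float = 0.9
    k_fine: int = 10
    k_coarse: int = 5
    pac_lower: float = 0.1
    pac_upper: float = 0.9
    selection_threshold: float = 0.9
    deploy_folds: int = 5
    deploy_grid: tuple[float, ...] | None = None
    deploy_seed: int = 0
    endpoints: tuple[str, ...] = ("death", "composite")
    adjust_covariates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0 <= self.max_missing_fraction < 1:
            raise ValueError("max_missing_fraction must lie in [0, 1)")
        if not 0 < self.retention <= 1:
            raise ValueError("retention must lie in (0, 1]")
        if not 0 < self.selection_threshold < 1:
            raise ValueError("selection_threshold must lie in (0, 1)")
        if not 0 <= self.pac_lower < self.pac_upper <= 1:
            raise ValueError("pac bounds must satisfy 0 <= lower < upper <= 1")
        if self.k_coarse > self.k_fine:
            raise ValueError("k_coarse must be <= k_fine")

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = [x.item() if hasattr(x, "item") else x for x in v]
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        raw = yaml.safe_load(text) or {}
        for k, v in raw.items():
            if isinstance(v, list):
                raw[k] = tuple(v)
        return cls(**raw)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    split: SplitDataset
    retained_variables: list[str]
    ensemble: gemini.EnsembleResult
    reports: list[stability.StabilityReport]
    kept: list[int]
    consensus: stability.ConsensusMatrix
    merged: stability.MergedClustering
    selection_frequency: dict[str, float]
    top_variables: list[str]
    deployment: deploy.DeploymentModel | None
    manifest: dict = field(default_factory=dict)

    @property
    def coarse_by_patient(self) -> dict[str, int]:
        return dict(zip(self.split.Df.patient_ids, map(int, self.merged.coarse_labels)))


def run_pipeline(
    table: pd.DataFrame,
    variables: list[VariableSpec],
    config: PipelineConfig | None = None,
    fit_deployment_model: bool = True,
) -> PipelineResult:
    """Run the full stable-phenogrouping pipeline on a cohort table."""
    cfg = config or PipelineConfig()
    t0 = time.perf_counter()
    # clustering stages must not see outcome columns (blinding contract)
    clustering_vars = [v for v in variables if v.name not in RESERVED_COLUMNS]
    split, retained = build_split(table, clustering_vars, cfg.max_missing_fraction)

    kernel = gemini.KernelSpec(cfg.kernel, cfg.kernel_bandwidth)
    ens = gemini.run_ensemble(
        split.Df,
        split.Dr,
        n_models=cfg.n_models,
        n_clusters=cfg.n_clusters,
        kernel=kernel,
        penalty_path=cfg.penalty_path,
        base_seed=cfg.base_seed,
    )
    if not ens.models:
        raise RuntimeError("every clustering run failed")

    reports = stability.stability_reports(ens.models, split.Df, split.Dr)
    kept = stability.filter_models(reports, cfg.retention)

    labelings = [ens.df_assignments[i].hard for i in kept]
    cm = stability.coassignment_matrix(labelings, split.Df.patient_ids)
    pac_value = stability.pac(cm, cfg.pac_lower, cfg.pac_upper)
    fine = stability.consensus_partition(cm, cfg.k_fine)

    kept_models = [ens.models[i] for i in kept]
    freq = gemini.feature_selection_frequency(kept_models)
    top = gemini.top_selected(freq, cfg.selection_threshold)
    sel_vars = top or [v for v, f in freq.items() if f > 0]
    if not top:
        warnings.warn(
            "no variable passed the selection-frequency threshold; "
            "merging on all ever-selected variables",
            stacklevel=2,
        )
    X_sel = split.Df.restrict_to_variables(sel_vars)
    merged = stability.merge_to_coarse(fine, X_sel, cfg.k_coarse)

    deployment = None
    if fit_deployment_model:
        deployment = deploy.fit_deployment(
            X_sel,
            merged.coarse_labels,
            folds=cfg.deploy_folds,
            grid=cfg.deploy_grid,
            seed=cfg.deploy_seed,
        )

    manifest = {
        "config_hash": cfg.config_hash(),
        "base_seed": cfg.base_seed,
        "n_patients_df": split.Df.n_rows,
        "n_visits_dr": split.Dr.n_rows,
        "n_features": len(split.Df.feature_names),
        "n_variables_retained": len(retained),
        "n_models": cfg.n_models,
        "n_models_failed": len(ens.failures),
        "n_models_kept": len(kept),
        "visit_wise_accuracy_kept": float(
            np.mean([reports[i].visit_wise_accuracy for i in kept])
        ),
        "patient_wise_accuracy_kept": float(
            np.mean([reports[i].patient_wise_accuracy for i in kept])
        ),
        "pac": pac_value,
        "pac_models": "filtered",
        "top_selected_variables": top,
        "deployment_cv_f1": None if deployment is None else deployment.cv_f1,
        "wall_time_s": round(time.perf_counter() - t0, 2),
    }
    return PipelineResult(
        split=split,
        retained_variables=retained,
        ensemble=ens,
        reports=reports,
        kept=kept,
        consensus=cm,
        merged=merged,
        selection_frequency=freq,
        top_variables=top,
        deployment=deployment,
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# stage I/O helpers used by the CLI


def write_labels(result: PipelineResult, path: str | Path) -> None:
    pd.DataFrame(
        {
            "patient_id": result.split.Df.patient_ids,
            "fine_cluster": result.merged.fine_labels,
            "coarse_cluster": result.merged.coarse_labels,
        }
    ).to_csv(path, index=False)


def write_consensus(result: PipelineResult, path: str | Path) -> None:
    pd.DataFrame(
        result.consensus.M,
        index=result.consensus.patient_ids,
        columns=result.consensus.patient_ids,
    ).to_csv(path)


def write_manifest(result: PipelineResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(result.manifest, indent=2))


def survival_frame(
    table: pd.DataFrame, coarse_by_patient: dict[str, int],
    covariate_vars: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Per-patient survival rows (first visit) joined with coarse labels.

    ``event_death`` marks death as the first event; the composite event is
    death or valve replacement, whichever comes first.
    """
    first = table[table["visit_index"] == 0].set_index("patient_id")
    rows = []
    for pid, cluster in coarse_by_patient.items():
        r = first.loc[pid]
        row = {
            "patient_id": pid,
            "cluster": cluster,
            "time": float(r["event_time"]),
            "event_death": int(r["event_death"]),
            "event_composite": int(r["event_death"] or r["event_avr"]),
        }
        for v in covariate_vars:
            row[v] = r[v]
        rows.append(row)
    return pd.DataFrame(rows)
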