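"""Synthetic longitudinal cohort generator with planted phenogroups.

Emulates the structure of a prospective valvular-disease cohort: a few
hundred patients, mixed-type clinical/echocardiographic variables, yearly
follow-up visits, a latent phenogroup that is constant across a patient's
visits, cluster-dependent progression of designated variables, MCAR
missingness, and cluster-dependent exponential event hazards (death and
valve replacement as competing processes, plus independent censoring).

The generator is the test bed for every downstream stage: the phenogroup
is written to the table (``true_cluster``) so recovery can be scored.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: columns that are bookkeeping/outcomes, never clustering variables
RESERVED_COLUMNS = (
    "patient_id",
    "visit_index",
    "visit_time",
    "true_cluster",
    "event_time",
    "event_death",
    "event_avr",
)


@dataclass
class VariableSpec:
    """One cohort variable: its name, type and (for categoricals) levels."""

    name: str
    kind: str  # "continuous" | "binary" | "categorical"
    levels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary", "categorical"):
            raise ValueError(f"unknown variable kind {self.kind!r}")
        if self.kind == "categorical" and len(self.levels) < 3:
            raise ValueError("categorical variables need >= 3 levels")


@dataclass
class SimConfig:
    """Parameters of the planted-phenogroup cohort simulation.

    Continuous variables are unit-SD Gaussian within cluster; the first
    ``n_informative`` variables (in variable order: continuous, binary,
    multilevel) carry cluster-dependent means or level probabilities, the
    rest are pure noise.  ``cluster_mean_separation`` is expressed in
    within-cluster standard deviations per informative feature.
    """

    n_patients: int = 349
    n_clusters_true: int = 5
    cluster_weights: tuple[float, ...] = (0.23, 0.16, 0.13, 0.34, 0.14)
    n_continuous: int = 75
    n_binary: int = 8
    n_multilevel: int = 4
    multilevel_levels: int = 3
    n_informative: int = 18
    cluster_mean_separation: float = 4.0
    visit_count_range: tuple[int, int] = (1, 8)
    within_patient_sd: float = 0.1
    n_progression: int = 2
    progression_rates: tuple[float, ...] = (0.5, 0.15, 0.15, 0.1, 0.1)
    missing_fraction_per_variable: tuple[float, ...] | None = None
    baseline_hazard: float = 0.025
    avr_hazard: float = 0.075
    cluster_log_hazard_ratios: tuple[float, ...] = (0.69, 0.0, 0.0, 0.0, 0.26)
    death_log_hazard_ratios: tuple[float, ...] | None = None
    censoring_rate: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.n_clusters_true < 1:
            raise ValueError("counts must be positive")
        if len(self.cluster_weights) != self.n_clusters_true:
            raise ValueError("cluster_weights length must equal n_clusters_true")
        if abs(sum(self.cluster_weights) - 1.0) > 1e-6:
            raise ValueError("cluster_weights must sum to 1")
        if any(w < 0 for w in self.cluster_weights):
            raise ValueError("cluster_weights must be nonnegative")
        if self.visit_count_range[0] < 1:
            raise ValueError("visit_count_range min must be >= 1")
        if self.visit_count_range[1] < self.visit_count_range[0]:
            raise ValueError("visit_count_range must be (min, max) with min <= max")
        if self.within_patient_sd < 0:
            raise ValueError("within_patient_sd must be >= 0")
        if self.n_informative > self.n_variables:
            raise ValueError("n_informative exceeds variable count")
        if len(self.progression_rates) != self.n_clusters_true:
            raise ValueError("progression_rates must have one entry per cluster")
        if len(self.cluster_log_hazard_ratios) != self.n_clusters_true:
            raise ValueError("cluster_log_hazard_ratios must have one entry per cluster")
        if self.missing_fraction_per_variable is not None:
            fr = self.missing_fraction_per_variable
            if len(fr) != self.n_variables:
                raise ValueError("missing fractions must align with variables")
            if any(f < 0 or f >= 1 for f in fr):
                raise ValueError("missing fractions must lie in [0, 1)")

    @property
    def n_variables(self) -> int:
        return self.n_continuous + self.n_binary + self.n_multilevel

    def variables(self) -> list[VariableSpec]:
        """Declared variable metadata in generation order."""
        out = [VariableSpec(f"cont_{i:03d}", "continuous") for i in range(self.n_continuous)]
        out += [VariableSpec(f"bin_{i:02d}", "binary") for i in range(self.n_binary)]
        levels = tuple(chr(ord("A") + j) for j in range(self.multilevel_levels))
        out += [
            VariableSpec(f"cat_{i:02d}", "categorical", levels)
            for i in range(self.n_multilevel)
        ]
        return out

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimConfig":
        raw = json.loads(text)
        for key, value in raw.items():
            if isinstance(value, list):
                raw[key] = tuple(value)
        return cls(**raw)


def _cluster_means(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-cluster means for continuous variables, separated on informative ones.

    Informative means are +/- separation/2 sign patterns.  Patterns are
    redrawn until every cluster pair differs on at least a third of the
    informative continuous features, so "separation" really is delivered
    per informative feature for every pair (a random draw can otherwise
    leave two clusters differing on a single feature).
    """
    n_inf_cont = min(cfg.n_informative, cfg.n_continuous)
    means = np.zeros((cfg.n_clusters_true, cfg.n_continuous))
    if n_inf_cont == 0:
        return means
    min_hamming = max(1, -(-n_inf_cont // 3))
    for _ in range(10_000):
        signs = rng.choice([-0.5, 0.5], size=(cfg.n_clusters_true, n_inf_cont))
        diffs = (signs[:, None, :] != signs[None, :, :]).sum(axis=2)
        np.fill_diagonal(diffs, n_inf_cont)
        if diffs.min() >= min_hamming:
            break
    else:
        raise RuntimeError(
            "could not draw cluster sign patterns with the required separation; "
            "increase n_informative or reduce n_clusters_true"
        )
    means[:, :n_inf_cont] = signs * cfg.cluster_mean_separation
    return means


def _categorical_probs(
    cfg: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cluster Bernoulli p (binary) and level probabilities (multilevel)."""
    n_inf_bin = int(np.clip(cfg.n_informative - cfg.n_continuous, 0, cfg.n_binary))
    p_bin = np.full((cfg.n_clusters_true, cfg.n_binary), 0.3)
    if n_inf_bin:
        p_bin[:, :n_inf_bin] = rng.choice([0.15, 0.85], size=(cfg.n_clusters_true, n_inf_bin))
    n_inf_cat = int(
        np.clip(cfg.n_informative - cfg.n_continuous - cfg.n_binary, 0, cfg.n_multilevel)
    )
    k = cfg.multilevel_levels
    p_cat = np.full((cfg.n_clusters_true, cfg.n_multilevel, k), 1.0 / k)
    if n_inf_cat:
        p_cat[:, :n_inf_cat, :] = rng.dirichlet(
            np.full(k, 0.5), size=(cfg.n_clusters_true, n_inf_cat)
        )
    return p_bin, p_cat


def generate_cohort(config: SimConfig) -> pd.DataFrame:
    """Simulate a longitudinal cohort table with planted phenogroups.

    One row per patient-visit.  A patient's latent profile is the cluster
    mean plus a unit-SD patient random effect; each visit adds the
    cluster-specific drift times visit time plus ``within_patient_sd``
    noise.  Categorical values are drawn once per patient from per-cluster
    level probabilities and held fixed across visits.  Event times are
    competing exponentials (death, valve replacement) with cluster
    log-hazard-ratios, censored by an independent exponential.

    Fully reproducible: identical config (including seed) gives an
    identical table.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    variables = cfg.variables()
    means = _cluster_means(cfg, rng)
    p_bin, p_cat = _categorical_probs(cfg, rng)

    clusters = rng.choice(
        cfg.n_clusters_true, size=cfg.n_patients, p=np.asarray(cfg.cluster_weights)
    )
    n_visits = rng.integers(
        cfg.visit_count_range[0], cfg.visit_count_range[1] + 1, size=cfg.n_patients
    )

    drift = np.zeros((cfg.n_clusters_true, cfg.n_continuous))
    n_prog = min(cfg.n_progression, cfg.n_continuous)
    for c in range(cfg.n_clusters_true):
        drift[c, :n_prog] = cfg.progression_rates[c]

    death_lhr = (
        np.asarray(cfg.death_log_hazard_ratios)
        if cfg.death_log_hazard_ratios is not None
        else np.asarray(cfg.cluster_log_hazard_ratios)
    )
    avr_lhr = np.asarray(cfg.cluster_log_hazard_ratios)

    rows: list[dict] = []
    for p in range(cfg.n_patients):
        c = int(clusters[p])
        latent = means[c] + rng.normal(0.0, 1.0, size=cfg.n_continuous)
        bin_vals = (rng.random(cfg.n_binary) < p_bin[c]).astype(int)
        cat_vals = [
            variables[cfg.n_continuous + cfg.n_binary + j].levels[
                rng.choice(cfg.multilevel_levels, p=p_cat[c, j])
            ]
            for j in range(cfg.n_multilevel)
        ]
        t_death = rng.exponential(1.0 / (cfg.baseline_hazard * np.exp(death_lhr[c])))
        t_avr = rng.exponential(1.0 / (cfg.avr_hazard * np.exp(avr_lhr[c])))
        t_cens = rng.exponential(1.0 / cfg.censoring_rate)
        event_time = min(t_death, t_avr, t_cens)
        event_death = int(t_death <= t_avr and t_death <= t_cens)
        event_avr = int(not event_death and t_avr <= t_cens)

        for v in range(int(n_visits[p])):
            t = 0.0 if v == 0 else v + rng.uniform(-0.25, 0.25)
            cont = latent + drift[c] * t + rng.normal(
                0.0, cfg.within_patient_sd, size=cfg.n_continuous
            )
            row = {
                "patient_id": f"P{p:04d}",
                "visit_index": v,
                "visit_time": round(t, 4),
                "true_cluster": c,
                "event_time": round(event_time, 4),
                "event_death": event_death,
                "event_avr": event_avr,
            }
            for i in range(cfg.n_continuous):
                row[variables[i].name] = cont[i]
            for i in range(cfg.n_binary):
                row[variables[cfg.n_continuous + i].name] = int(bin_vals[i])
            for j in range(cfg.n_multilevel):
                row[variables[cfg.n_continuous + cfg.n_binary + j].name] = cat_vals[j]
            rows.append(row)

    table = pd.DataFrame(rows)
    assert (table.groupby("patient_id")["true_cluster"].nunique() == 1).all()
    return table


def inject_missingness(table: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Blank values MCAR at per-variable rates; ids/visits/outcomes untouched.

    Uses a seed derived from ``config.seed`` so generation and missingness
    are independently reproducible.
    """
    if config.missing_fraction_per_variable is None:
        return table.copy()
    fractions = config.missing_fraction_per_variable
    variables = config.variables()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    out = table.copy()
    for spec, frac in zip(variables, fractions):
        if frac == 0:
            continue
        mask = rng.random(len(out)) < frac
        col = out[spec.name]
        if col.dtype.kind in "iu":  # keep NA-able dtype for int columns
            out[spec.name] = col.astype("float64")
        out.loc[mask, spec.name] = np.nan
    return out


def write_cohort(
    table: pd.DataFrame, config: SimConfig, csv_path: str | Path
) -> None:
    """Write the cohort CSV (empty cell = missing) plus a JSON config sidecar."""
    csv_path = Path(csv_path)
    table.to_csv(csv_path, index=False, na_rep="")
    sidecar = csv_path.with_suffix(".json")
    meta = {
        "config": dataclasses.asdict(config),
        "variables": [dataclasses.asdict(v) for v in config.variables()],
    }
    sidecar.write_text(json.dumps(meta, indent=2))


def read_cohort(csv_path: str | Path) -> tuple[pd.DataFrame, list[VariableSpec]]:
    """Read a cohort CSV and its sidecar's variable metadata."""
    csv_path = Path(csv_path)
    table = pd.read_csv(csv_path)
    sidecar = csv_path.with_suffix(".json")
    meta = json.loads(sidecar.read_text())
    variables = [
        VariableSpec(v["name"], v["kind"], tuple(v["levels"]))
        for v in meta["variables"]
    ]
    return table, variables
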