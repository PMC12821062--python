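"""Variable screening, complete-case filtering, visit split, encoding, scaling.

The pipeline trains its clustering on first visits only, so missingness is
screened on first-visit rows, the scaler is fitted on the first-visit
matrix (Df) and then applied unchanged to the subsequent-visit matrix
(Dr) — follow-up visits never leak into the scaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .simulate import RESERVED_COLUMNS, VariableSpec


@dataclass
class FeatureMatrix:
    """Encoded (optionally scaled) design matrix with aligned row metadata."""

    values: np.ndarray  # (n_rows, n_features)
    feature_names: list[str]
    variable_of: list[str]  # parent variable of each encoded column
    patient_ids: list[str]
    visit_indices: np.ndarray
    center: np.ndarray | None = None  # per-feature scaling params (fitted on Df)
    scale: np.ndarray | None = None

    def __post_init__(self) -> None:
        n, p = self.values.shape
        if len(self.feature_names) != p or len(self.variable_of) != p:
            raise ValueError("feature metadata length mismatch")
        if len(self.patient_ids) != n or len(self.visit_indices) != n:
            raise ValueError("row metadata length mismatch")
        if np.isnan(self.values).any():
            raise ValueError("FeatureMatrix must not contain missing values")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    def restrict_to_variables(self, variables: list[str]) -> "FeatureMatrix":
        """Keep only encoded columns belonging to the given parent variables."""
        keep = [j for j, v in enumerate(self.variable_of) if v in set(variables)]
        if not keep:
            raise ValueError("no encoded columns match the requested variables")
        return replace(
            self,
            values=self.values[:, keep],
            feature_names=[self.feature_names[j] for j in keep],
            variable_of=[self.variable_of[j] for j in keep],
            center=None if self.center is None else self.center[keep],
            scale=None if self.scale is None else self.scale[keep],
        )


@dataclass
class SplitDataset:
    """First-visit matrix Df (one row per patient) and follow-up matrix Dr."""

    Df: FeatureMatrix
    Dr: FeatureMatrix

    def __post_init__(self) -> None:
        df_patients = self.Df.patient_ids
        if len(set(df_patients)) != len(df_patients):
            raise ValueError("Df must contain one row per patient")
        if not set(self.Dr.patient_ids) <= set(df_patients):
            raise ValueError("Dr contains patients absent from Df")


def screen_variables(
    table: pd.DataFrame,
    variables: list[VariableSpec],
    max_missing_fraction: float = 0.05,
) -> list[str]:
    """Variables whose first-visit missing fraction is <= the threshold.

    Retention uses <= (a variable with *more than* the threshold missing is
    excluded). Order of the input variable list is preserved.
    """
    if not 0 <= max_missing_fraction < 1:
        raise ValueError("max_missing_fraction must lie in [0, 1)")
    first = table[table["visit_index"] == 0]
    retained = [
        v.name
        for v in variables
        if first[v.name].isna().mean() <= max_missing_fraction
    ]
    if not retained:
        raise ValueError("screening removed every variable; raise the threshold")
    return retained


def complete_case_filter(table: pd.DataFrame, variables: list[str]) -> pd.DataFrame:
    """Drop visit rows missing any retained variable; drop patients whose
    first visit is dropped (they cannot enter Df)."""
    missing = [v for v in variables if v not in table.columns]
    if missing:
        raise KeyError(f"variables not in table: {missing}")
    keep_rows = table[variables].notna().all(axis=1)
    kept = table[keep_rows]
    first_ok = set(kept.loc[kept["visit_index"] == 0, "patient_id"])
    out = kept[kept["patient_id"].isin(first_ok)].reset_index(drop=True)
    if out.empty:
        warnings.warn("complete-case filtering removed every row", stacklevel=2)
    return out


def split_first_vs_rest(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Row split into first visits (Df) and subsequent visits (Dr)."""
    if "visit_index" not in table.columns:
        raise KeyError("table lacks a visit_index column")
    no_first = set(table["patient_id"]) - set(
        table.loc[table["visit_index"] == 0, "patient_id"]
    )
    if no_first:
        raise ValueError(f"patients without a first visit: {sorted(no_first)[:5]}")
    df = table[table["visit_index"] == 0].reset_index(drop=True)
    dr = table[table["visit_index"] >= 1].reset_index(drop=True)
    return df, dr


def encode_features(
    table: pd.DataFrame, variables: list[VariableSpec]
) -> FeatureMatrix:
    """Mixed-type rows -> numeric design matrix.

    Continuous variables pass through; binaries become one 0/1 column;
    k-level categoricals (k > 2) become k one-hot columns named
    ``var=level``.  Column order is deterministic: declared variable
    order, then declared level order.  An undeclared categorical level is
    an error (it would silently break the one-hot contract).
    """
    columns: list[np.ndarray] = []
    names: list[str] = []
    parents: list[str] = []
    for spec in variables:
        col = table[spec.name]
        if spec.kind == "continuous":
            columns.append(col.to_numpy(dtype=float))
            names.append(spec.name)
            parents.append(spec.name)
        elif spec.kind == "binary":
            vals = col.to_numpy(dtype=float)
            bad = set(np.unique(vals[~np.isnan(vals)])) - {0.0, 1.0}
            if bad:
                raise ValueError(f"binary variable {spec.name} has levels {bad}")
            columns.append(vals)
            names.append(spec.name)
            parents.append(spec.name)
        else:
            observed = set(col.dropna().astype(str))
            unseen = observed - set(spec.levels)
            if unseen:
                raise ValueError(
                    f"variable {spec.name}: unseen level(s) {sorted(unseen)}"
                )
            for level in spec.levels:
                onehot = (col.astype(str) == level).astype(float)
                onehot[col.isna()] = np.nan
                columns.append(onehot.to_numpy())
                names.append(f"{spec.name}={level}")
                parents.append(spec.name)
    values = np.column_stack(columns) if columns else np.empty((len(table), 0))
    return FeatureMatrix(
        values=values,
        feature_names=names,
        variable_of=parents,
        patient_ids=table["patient_id"].tolist(),
        visit_indices=table["visit_index"].to_numpy(dtype=int),
    )


def decode_levels(fm: FeatureMatrix, variable: str, levels: list[str]) -> list[str]:
    """Invert a one-hot block back to level labels (round-trip check)."""
    cols = [fm.feature_names.index(f"{variable}={lv}") for lv in levels]
    block = fm.values[:, cols]
    return [levels[int(np.argmax(row))] for row in block]


def fit_scaler(Df: FeatureMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature (center, scale) = (mean, population SD) fitted on Df.

    Zero-variance columns get scale 1 (with a warning): they stay as
    centred zeros instead of dividing by zero.
    """
    if Df.n_rows == 0:
        raise ValueError("cannot fit a scaler on an empty matrix")
    center = Df.values.mean(axis=0)
    scale = Df.values.std(axis=0, ddof=0)
    zero = scale == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero-variance feature(s); scale set to 1",
            stacklevel=2,
        )
        scale = np.where(zero, 1.0, scale)
    return center, scale


def apply_scaler(
    fm: FeatureMatrix, params: tuple[np.ndarray, np.ndarray]
) -> FeatureMatrix:
    """Apply Df-fitted (center, scale) to any matrix; records the params."""
    center, scale = params
    if (scale <= 0).any():
        raise ValueError("scale must be positive")
    return replace(
        fm,
        values=(fm.values - center) / scale,
        center=np.asarray(center, dtype=float),
        scale=np.asarray(scale, dtype=float),
    )


def build_split(
    table: pd.DataFrame,
    variables: list[VariableSpec],
    max_missing_fraction: float = 0.05,
) -> tuple[SplitDataset, list[str]]:
    """Screen -> complete-case -> split -> encode -> scale (Df-fitted).

    Returns the scaled SplitDataset and the retained variable names.
    Outcome and bookkeeping columns are never encoded (clustering is
    blinded to outcomes by construction).
    """
    variables = [v for v in variables if v.name not in RESERVED_COLUMNS]
    retained = screen_variables(table, variables, max_missing_fraction)
    specs = [v for v in variables if v.name in set(retained)]
    filtered = complete_case_filter(table, retained)
    df_rows, dr_rows = split_first_vs_rest(filtered)
    Df = encode_features(df_rows, specs)
    Dr = encode_features(dr_rows, specs)
    params = fit_scaler(Df)
    return SplitDataset(Df=apply_scaler(Df, params), Dr=apply_scaler(Dr, params)), retained


def annualize_progression(times: np.ndarray, values: np.ndarray) -> float:
    """Annualized change: (last - baseline) / (years between them).

    Requires >= 2 non-missing observations; returns NaN otherwise (the
    patient is excluded from progression analysis).
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    ok = ~np.isnan(values)
    times, values = times[ok], values[ok]
    if len(values) < 2:
        return float("nan")
    order = np.argsort(times)
    t0, t1 = times[order[0]], times[order[-1]]
    if t1 - t0 <= 0:
        raise ValueError("follow-up time span must be positive")
    return float((values[order[-1]] - values[order[0]]) / (t1 - t0))
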