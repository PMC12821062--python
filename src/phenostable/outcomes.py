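"""Phenogroup characterization: severity, group tests, progression, survival.

Implements the downstream clinical read-out of the clustering: stenosis
severity classes from peak jet velocity, Kruskal-Wallis / chi-squared
comparisons with pairwise significance flags, annualized progression
rates by cluster, Kaplan-Meier curves with log-rank tests, and Cox
proportional-hazards regression for cluster membership adjusted for age,
sex and baseline severity, with a scaled-Schoenfeld-residual check of
the proportional-hazards assumption.  Survival machinery is lifelines;
rank tests are scipy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test, proportional_hazard_test
from scipy import stats

from .preprocess import annualize_progression


def classify_severity(v_peak: float) -> str:
    """Stenosis severity from peak aortic jet velocity (cm/s).

    mild 200-290, moderate 300-390, severe >= 400; the unprinted gaps
    (290-300, 390-400) are assigned to the lower class (< 300 mild,
    < 400 moderate) — the printed bins reflect rounding.  Values below
    200 fall outside the cohort entry criterion and are rejected.
    """
    if v_peak < 200:
        raise ValueError(f"v_peak {v_peak} cm/s is below the cohort entry criterion")
    if v_peak < 300:
        return "mild"
    if v_peak < 400:
        return "moderate"
    return "severe"


@dataclass
class ComparisonRow:
    variable: str
    kind: str  # "continuous" | "categorical"
    per_cluster: dict[int, str]  # formatted median [IQR] or n (%)
    omnibus_p: float
    pairwise_flags: list[tuple[int, int]] = field(default_factory=list)


def _fmt_median_iqr(values: np.ndarray) -> str:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return f"{med:.2f} [{q1:.2f}-{q3:.2f}]"


def compare_clusters(
    values_by_cluster: dict[int, np.ndarray],
    kind: str = "continuous",
    variable: str = "",
    alpha: float = 0.05,
) -> ComparisonRow:
    """One comparison-table row: omnibus test plus pairwise flags.

    Continuous: Kruskal-Wallis omnibus, pairwise two-sided rank-sum
    flagged at p < alpha (flags reported only when the omnibus test is
    itself significant).  Categorical (values = level labels): chi-squared
    omnibus on the cluster x level table, pairwise chi-squared flags.
    All-identical values give p = 1 by convention.
    """
    clusters = sorted(values_by_cluster)
    if len(clusters) < 2:
        raise ValueError("need at least two clusters")
    groups = [np.asarray(values_by_cluster[c]) for c in clusters]
    if kind == "continuous":
        per = {c: _fmt_median_iqr(g) for c, g in zip(clusters, groups)}
        if len(np.unique(np.concatenate(groups))) == 1:
            p = 1.0
        else:
            p = float(stats.kruskal(*groups).pvalue)
    elif kind == "categorical":
        levels = sorted(set(np.concatenate([g.astype(str) for g in groups])))
        table = np.array(
            [[np.sum(g.astype(str) == lv) for lv in levels] for g in groups]
        )
        per = {
            c: ", ".join(
                f"{lv}: {n} ({100 * n / max(len(g), 1):.0f}%)"
                for lv, n in zip(levels, row)
            )
            for c, g, row in zip(clusters, groups, table)
        }
        if len(levels) == 1:
            p = 1.0
        else:
            p = float(stats.chi2_contingency(table[:, table.sum(axis=0) > 0]).pvalue)
    else:
        raise ValueError(f"unknown variable kind {kind!r}")

    flags: list[tuple[int, int]] = []
    if p < alpha:
        for a, b in combinations(clusters, 2):
            ga, gb = values_by_cluster[a], values_by_cluster[b]
            if kind == "continuous":
                if len(np.unique(np.concatenate([ga, gb]))) == 1:
                    continue
                pp = float(stats.mannwhitneyu(ga, gb, alternative="two-sided").pvalue)
            else:
                lv = sorted(set(np.concatenate([np.asarray(ga).astype(str),
                                                np.asarray(gb).astype(str)])))
                if len(lv) == 1:
                    continue
                t = np.array(
                    [[np.sum(np.asarray(g).astype(str) == l) for l in lv]
                     for g in (ga, gb)]
                )
                pp = float(stats.chi2_contingency(t).pvalue)
            if pp < alpha:
                flags.append((a, b))
    return ComparisonRow(variable, kind, per, p, flags)


def km_estimate(times: np.ndarray, events: np.ndarray) -> pd.DataFrame:
    """Kaplan-Meier product-limit curve as a step-function table."""
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(times, dtype=float), np.asarray(events, dtype=int))
    sf = kmf.survival_function_
    return pd.DataFrame(
        {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
    )


def km_at(times: np.ndarray, events: np.ndarray, t: float) -> float:
    """Survival probability S(t) from the product-limit estimator."""
    curve = km_estimate(times, events)
    idx = curve["time"] <= t
    return float(curve.loc[idx, "survival"].iloc[-1]) if idx.any() else 1.0


def logrank(
    times: np.ndarray, events: np.ndarray, groups: np.ndarray
) -> tuple[float, float]:
    """Multivariate log-rank test; chi-squared with (#groups - 1) df."""
    groups = np.asarray(groups)
    for g in np.unique(groups):
        if not np.any(groups == g):  # pragma: no cover - np.unique precludes
            raise ValueError(f"empty group {g}")
    res = multivariate_logrank_test(
        np.asarray(times, dtype=float), groups, np.asarray(events, dtype=int)
    )
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CoxResult:
    summary: pd.DataFrame  # HR, CI, p per term
    reference_cluster: int
    schoenfeld_p: dict[str, float]  # PH-diagnostic p per covariate
    converged: bool = True


def cox_adjusted(
    data: pd.DataFrame,
    endpoint: str = "composite",
    covariates: tuple[str, ...] = ("age", "sex", "v_peak_baseline"),
    cluster_col: str = "cluster",
    time_col: str = "time",
    event_col: str | None = None,
) -> CoxResult:
    """Cox PH for cluster membership adjusted for clinical covariates.

    ``data``: one row per patient with time/event columns (event column
    defaults to ``event_<endpoint>``), covariates, and a cluster label.
    The largest cluster is the reference; cluster terms enter as
    indicators.  The proportional-hazards assumption is checked via the
    scaled Schoenfeld residual test (p per covariate; small p flags a
    time-varying effect).
    """
    event_col = event_col or f"event_{endpoint}"
    for col in (time_col, event_col, cluster_col, *covariates):
        if col not in data.columns:
            raise KeyError(f"missing column {col}")
    counts = data[cluster_col].value_counts()
    reference = counts.index[0]
    design = data[[time_col, event_col, *covariates]].copy()
    terms = []
    for lab in sorted(counts.index):
        if lab == reference:
            continue
        name = f"cluster_{lab}"
        design[name] = (data[cluster_col] == lab).astype(float)
        terms.append(name)
    cph = CoxPHFitter()
    try:
        cph.fit(design, duration_col=time_col, event_col=event_col)
        converged = True
    except Exception as exc:  # non-convergence / separation: report, don't crash
        warnings.warn(f"Cox fit failed: {exc}", stacklevel=2)
        return CoxResult(
            summary=pd.DataFrame(), reference_cluster=int(reference),
            schoenfeld_p={}, converged=False,
        )
    summ = cph.summary[["exp(coef)", "exp(coef) lower 95%",
                        "exp(coef) upper 95%", "p"]].copy()
    summ.columns = ["HR", "HR_lower", "HR_upper", "p"]
    ph = proportional_hazard_test(cph, design, time_transform="rank")
    sch = {str(ix): float(ph.summary.loc[ix, "p"].iloc[0])
           if hasattr(ph.summary.loc[ix, "p"], "iloc")
           else float(ph.summary.loc[ix, "p"])
           for ix in summ.index}
    return CoxResult(summary=summ, reference_cluster=int(reference),
                     schoenfeld_p=sch, converged=converged)


def progression_by_cluster(
    table: pd.DataFrame,
    coarse_labels: dict[str, int],
    variable: str,
    time_col: str = "visit_time",
) -> tuple[pd.DataFrame, ComparisonRow]:
    """Per-cluster annualized progression of one variable.

    Uses the (last - baseline)/years rule per patient; single-visit
    patients contribute nothing.  Returns per-patient rates plus a
    comparison row (median [IQR] per cluster, omnibus + pairwise flags).
    """
    rates = []
    for pid, sub in table.groupby("patient_id"):
        if pid not in coarse_labels:
            continue
        r = annualize_progression(sub[time_col].to_numpy(), sub[variable].to_numpy())
        if np.isnan(r):
            continue
        rates.append({"patient_id": pid, "cluster": coarse_labels[pid], "rate": r})
    rate_df = pd.DataFrame(rates)
    if rate_df.empty:
        raise ValueError("no patient has two or more visits with this variable")
    by_cluster = {
        int(c): g["rate"].to_numpy() for c, g in rate_df.groupby("cluster")
    }
    if len(by_cluster) < 2:
        warnings.warn(
            "fewer than two clusters have multi-visit patients; "
            "no between-cluster comparison",
            stacklevel=2,
        )
        row = ComparisonRow(
            f"delta_{variable}", "continuous",
            {c: _fmt_median_iqr(v) for c, v in by_cluster.items()}, float("nan"),
        )
        return rate_df, row
    row = compare_clusters(by_cluster, kind="continuous", variable=f"delta_{variable}")
    return rate_df, row
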