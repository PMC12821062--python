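"""Severity classes, between-cluster tests, Kaplan-Meier/log-rank, adjusted
Cox with Schoenfeld diagnostics, and progression-by-cluster."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phenostable.outcomes import (
    classify_severity,
    compare_clusters,
    cox_adjusted,
    km_at,
    km_estimate,
    logrank,
    progression_by_cluster,
)


class TestSeverity:
    @pytest.mark.parametrize(
        "v, expected",
        [
            (250, "mild"),
            (344, "moderate"),
            (400, "severe"),
            (290, "mild"),
            (295, "mild"),      # unprinted gap -> lower class
            (300, "moderate"),
            (395, "moderate"),  # unprinted gap -> lower class
            (1000, "severe"),
        ],
    )
    def test_bins(self, v, expected):
        assert classify_severity(v) == expected

    def test_below_entry_criterion_rejected(self):
        with pytest.raises(ValueError):
            classify_severity(180)

    def test_total_and_monotone(self):
        order = {"mild": 0, "moderate": 1, "severe": 2}
        grades = [order[classify_severity(v)] for v in range(200, 600, 5)]
        assert grades == sorted(grades)


class TestCompareClusters:
    def test_strong_shift_detected(self):
        rng = np.random.default_rng(0)
        row = compare_clusters(
            {1: rng.normal(0, 1, 50), 2: rng.normal(3, 1, 50)},
            kind="continuous",
            variable="x",
        )
        assert row.omnibus_p < 0.001
        assert (1, 2) in row.pairwise_flags

    def test_identical_values_p_one(self):
        row = compare_clusters(
            {1: np.full(10, 2.0), 2: np.full(8, 2.0)}, kind="continuous"
        )
        assert row.omnibus_p == 1.0 and row.pairwise_flags == []

    def test_flags_only_when_omnibus_significant(self):
        rng = np.random.default_rng(1)
        row = compare_clusters(
            {1: rng.normal(size=20), 2: rng.normal(size=20), 3: rng.normal(size=20)},
            kind="continuous",
        )
        if row.omnibus_p >= 0.05:
            assert row.pairwise_flags == []

    def test_categorical_chi2(self):
        row = compare_clusters(
            {1: np.array(["a"] * 40 + ["b"] * 10), 2: np.array(["a"] * 10 + ["b"] * 40)},
            kind="categorical",
        )
        assert row.omnibus_p < 0.001
        assert (1, 2) in row.pairwise_flags

    def test_null_type_one_error_calibrated(self):
        """Under identical distributions the omnibus p is ~uniform: the
        rejection rate at alpha=.05 stays near .05 over 300 replicates."""
        rng = np.random.default_rng(2)
        rejections = 0
        reps = 300
        for _ in range(reps):
            row = compare_clusters(
                {1: rng.normal(size=25), 2: rng.normal(size=25), 3: rng.normal(size=25)},
                kind="continuous",
            )
            rejections += row.omnibus_p < 0.05
        assert 0.01 <= rejections / reps <= 0.10


class TestKaplanMeier:
    def test_product_limit_by_hand(self):
        """Times (1,2,3), events (1,0,1): S(1) = 2/3, S(3) = 0."""
        t = np.array([1.0, 2.0, 3.0])
        e = np.array([1, 0, 1])
        assert km_at(t, e, 1.0) == pytest.approx(2 / 3)
        assert km_at(t, e, 3.0) == pytest.approx(0.0)

    def test_no_events_flat_one(self):
        curve = km_estimate(np.array([1.0, 2.0, 3.0]), np.zeros(3))
        np.testing.assert_allclose(curve["survival"], 1.0)

    def test_all_events_step_fractions(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.ones(4)
        assert km_at(t, e, 2.0) == pytest.approx(0.5)


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        e = np.array([1, 1, 0, 1, 1, 0])
        g = np.array([1, 1, 1, 2, 2, 2])
        stat, p = logrank(t, e, g)
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_null_pvalues_uniform(self):
        """Two iid exponential groups: log-rank p-values pass a KS test of
        uniformity over 400 replicates."""
        rng = np.random.default_rng(3)
        pvals = []
        for _ in range(400):
            t = rng.exponential(1.0, size=60)
            g = np.repeat([1, 2], 30)
            _, p = logrank(t, np.ones(60), g)
            pvals.append(p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(4)
        t = np.concatenate([rng.exponential(1.0, 100), rng.exponential(3.0, 100)])
        g = np.repeat([1, 2], 100)
        _, p = logrank(t, np.ones(200), g)
        assert p < 0.001


def survival_cohort(n=2000, log_hr=np.log(2.0), seed=0):
    """Two-cluster exponential survival with noise covariates."""
    rng = np.random.default_rng(seed)
    cluster = rng.integers(1, 3, size=n)
    lam = 0.1 * np.exp(np.where(cluster == 2, log_hr, 0.0))
    t_event = rng.exponential(1.0 / lam)
    t_cens = rng.exponential(1.0 / 0.05, size=n)
    return pd.DataFrame(
        {
            "time": np.minimum(t_event, t_cens),
            "event_composite": (t_event <= t_cens).astype(int),
            "cluster": cluster,
            "age": rng.normal(70, 8, n),
            "sex": rng.integers(0, 2, n),
            "v_peak_baseline": rng.normal(280, 40, n),
        }
    )


class TestCox:
    def test_recovers_planted_hazard_ratio(self):
        data = survival_cohort()
        res = cox_adjusted(data, endpoint="composite")
        # cluster 1 vs 2: whichever is larger is the reference
        term = [ix for ix in res.summary.index if ix.startswith("cluster_")][0]
        hr = res.summary.loc[term, "HR"]
        hr = hr if res.reference_cluster == 1 else 1 / hr
        assert 1.7 <= hr <= 2.3

    def test_symmetric_data_hr_one(self):
        """Clusters with identical time/event patterns: HR exactly 1."""
        t = np.array([1.0, 2.0, 3.0, 4.0] * 2)
        e = np.array([1, 1, 0, 1] * 2)
        data = pd.DataFrame(
            {
                "time": t,
                "event_composite": e,
                "cluster": np.repeat([1, 2], 4),
                "age": 70.0,
                "sex": 1.0,
                "v_peak_baseline": 280.0,
            }
        )
        # constant covariates are dropped to avoid a degenerate fit
        res = cox_adjusted(data, endpoint="composite", covariates=())
        term = [ix for ix in res.summary.index if ix.startswith("cluster_")][0]
        assert res.summary.loc[term, "HR"] == pytest.approx(1.0, abs=1e-6)

    def test_schoenfeld_flags_time_varying_effect(self):
        """Weibull groups with different shapes violate proportionality; the
        scaled-Schoenfeld test should flag the group term at n=2000."""
        rng = np.random.default_rng(5)
        n = 1000
        t = np.concatenate(
            [rng.weibull(0.6, n) * 2.0, rng.weibull(1.8, n) * 2.0]
        )
        data = pd.DataFrame(
            {
                "time": t + 1e-4,
                "event_composite": np.ones(2 * n, dtype=int),
                "cluster": np.repeat([1, 2], n),
                "age": rng.normal(70, 8, 2 * n),
                "sex": rng.integers(0, 2, 2 * n),
                "v_peak_baseline": rng.normal(280, 40, 2 * n),
            }
        )
        res = cox_adjusted(data, endpoint="composite")
        term = [ix for ix in res.schoenfeld_p if ix.startswith("cluster_")][0]
        assert res.schoenfeld_p[term] < 0.05

    def test_missing_column_rejected(self):
        with pytest.raises(KeyError):
            cox_adjusted(pd.DataFrame({"time": [1.0]}), endpoint="composite")


class TestProgression:
    def _cohort(self, drift_by_cluster, n_per=30, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        pid = 0
        for cluster, drift in enumerate(drift_by_cluster, start=1):
            for _ in range(n_per):
                base = rng.normal(300, 10)
                for v, t in enumerate([0.0, 1.0, 2.0]):
                    rows.append(
                        {
                            "patient_id": f"P{pid:04d}",
                            "visit_index": v,
                            "visit_time": t,
                            "v_peak": base + drift * t + rng.normal(0, 1),
                        }
                    )
                pid += 1
        labels = {
            f"P{i:04d}": 1 + i // n_per for i in range(n_per * len(drift_by_cluster))
        }
        return pd.DataFrame(rows), labels

    def test_zero_drift_medians_near_zero(self):
        table, labels = self._cohort([0.0, 0.0])
        rates, _ = progression_by_cluster(table, labels, "v_peak")
        assert abs(rates.groupby("cluster")["rate"].median()).max() < 1.0

    def test_fast_cluster_flagged(self):
        """One cluster progressing at 20 units/yr vs 5 elsewhere shows up as
        a significant pairwise difference."""
        table, labels = self._cohort([20.0, 5.0, 5.0])
        rates, row = progression_by_cluster(table, labels, "v_peak")
        med = rates.groupby("cluster")["rate"].median()
        assert med[1] > med[2] and med[1] > med[3]
        assert row.omnibus_p < 0.001
        assert (1, 2) in row.pairwise_flags and (1, 3) in row.pairwise_flags

    def test_single_visit_patients_excluded(self):
        table, labels = self._cohort([5.0])
        solo = pd.DataFrame(
            [{"patient_id": "SOLO", "visit_index": 0, "visit_time": 0.0, "v_peak": 300.0}]
        )
        labels["SOLO"] = 1
        with pytest.warns(UserWarning, match="fewer than two clusters"):
            rates, _ = progression_by_cluster(pd.concat([table, solo]), labels, "v_peak")
        assert "SOLO" not in set(rates.patient_id)
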