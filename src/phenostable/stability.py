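"""Stability filtering, consensus clustering, PAC and coarse merging.

A clustering run is "stable over time" when the follow-up visits of a
patient land in the same cluster as the patient's first visit.  Each
ensemble model assigns both first visits (Df) and follow-up visits (Dr);
the first-visit cluster plays the role of a ground-truth label for the
patient's remaining visits, giving a visit-wise accuracy (over visits)
and a patient-wise accuracy (mean of per-patient match fractions, which
removes the imbalance between patients with many and few visits).
Models within ``retention`` (default 90%) of the best patient-wise
accuracy are kept; the kept models' first-visit labelings are aggregated
into a patient x patient co-assignment matrix, summarized by PAC (the
proportion of ambiguous pairs, co-clustered strictly between 10% and 90%
of the time), cut into fine clusters by average-linkage agglomeration,
and finally merged into coarse phenogroups by repeatedly fusing the two
closest (size-weighted) centroids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .gemini import ClusterModel
from .preprocess import FeatureMatrix


@dataclass
class StabilityReport:
    model_index: int
    visit_wise_accuracy: float
    patient_wise_accuracy: float
    kept: bool = False
    threshold_used: float = float("nan")


@dataclass
class ConsensusMatrix:
    M: np.ndarray
    patient_ids: list[str]
    n_models_used: int
    pac: float = float("nan")
    pac_bounds: tuple[float, float] = (0.1, 0.9)

    def __post_init__(self) -> None:
        if not np.allclose(self.M, self.M.T):
            raise ValueError("consensus matrix must be symmetric")
        if not np.allclose(np.diag(self.M), 1.0):
            raise ValueError("consensus matrix diagonal must be 1")


@dataclass
class MergedClustering:
    fine_labels: np.ndarray  # 1..k_fine per Df patient
    merge_map: dict[int, int]  # fine label -> coarse label (1..k_coarse)
    centroids: dict[int, np.ndarray]  # fine label -> mean selected-feature vector
    coarse_labels: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        fine_set = set(np.unique(self.fine_labels))
        if set(self.merge_map) != fine_set:
            raise ValueError("merge_map must cover every fine label")
        coarse = sorted(set(self.merge_map.values()))
        if coarse != list(range(1, len(coarse) + 1)):
            raise ValueError("coarse labels must be 1..k")
        self.coarse_labels = np.array([self.merge_map[f] for f in self.fine_labels])


def visit_accuracies(
    first_visit_labels: dict[str, int],
    subsequent_labels: dict[str, list[int]],
) -> tuple[float, float]:
    """Visit-wise and patient-wise agreement of follow-up clusters with the
    first-visit cluster.  Patients without follow-up visits are excluded
    from both metrics."""
    per_patient: list[float] = []
    matches = 0
    total = 0
    for pid, labels in subsequent_labels.items():
        if pid not in first_visit_labels:
            raise KeyError(f"patient {pid} has follow-up visits but no first visit")
        if not labels:
            continue
        ref = first_visit_labels[pid]
        m = sum(1 for lab in labels if lab == ref)
        matches += m
        total += len(labels)
        per_patient.append(m / len(labels))
    if total == 0:
        raise ValueError("no subsequent visits: stability is undefined")
    return matches / total, float(np.mean(per_patient))


def stability_reports(
    models: list[ClusterModel],
    Df: FeatureMatrix,
    Dr: FeatureMatrix,
) -> list[StabilityReport]:
    """Score every model's over-time stability from its own predictions."""
    reports = []
    dr_by_patient: dict[str, list[int]] = {}
    for i, m in enumerate(models):
        first = dict(zip(Df.patient_ids, m.predict(Df).hard))
        dr_hard = m.predict(Dr).hard
        dr_by_patient = {}
        for pid, lab in zip(Dr.patient_ids, dr_hard):
            dr_by_patient.setdefault(pid, []).append(int(lab))
        vw, pw = visit_accuracies(first, dr_by_patient)
        reports.append(StabilityReport(i, vw, pw))
    return reports


def filter_models(
    reports: list[StabilityReport], retention: float = 0.9
) -> list[int]:
    """Keep models whose patient-wise accuracy is within ``retention`` of the
    best: threshold = retention * max(patient_wise).  The best model is
    always kept, so the ensemble never empties."""
    if not reports:
        raise ValueError("no stability reports")
    if not 0 < retention <= 1:
        raise ValueError("retention must lie in (0, 1]")
    best = max(r.patient_wise_accuracy for r in reports)
    threshold = retention * best
    kept = []
    for r in reports:
        r.threshold_used = threshold
        r.kept = r.patient_wise_accuracy >= threshold
        if r.kept:
            kept.append(r.model_index)
    return kept


def coassignment_matrix(
    labelings: list[np.ndarray], patient_ids: list[str]
) -> ConsensusMatrix:
    """Fraction of labelings in which each patient pair shares a cluster."""
    if not labelings:
        raise ValueError("need at least one labeling")
    n = len(patient_ids)
    M = np.zeros((n, n))
    for labels in labelings:
        labels = np.asarray(labels)
        if len(labels) != n:
            raise ValueError("labeling length does not match patient set")
        M += (labels[:, None] == labels[None, :]).astype(float)
    M /= len(labelings)
    np.fill_diagonal(M, 1.0)
    return ConsensusMatrix(M=M, patient_ids=list(patient_ids), n_models_used=len(labelings))


def pac(cm: ConsensusMatrix, lower: float = 0.1, upper: float = 0.9) -> float:
    """Proportion of ambiguous pairs: co-assignment strictly inside
    (lower, upper).  Strict bounds make unanimous consensus give PAC 0."""
    if not 0 <= lower < upper <= 1:
        raise ValueError("need 0 <= lower < upper <= 1")
    iu = np.triu_indices(cm.M.shape[0], k=1)
    vals = cm.M[iu]
    p = float(np.mean((vals > lower) & (vals < upper)))
    cm.pac = p
    cm.pac_bounds = (lower, upper)
    return p


def consensus_partition(cm: ConsensusMatrix, k: int = 10) -> np.ndarray:
    """Average-linkage agglomeration on dissimilarity 1 - M, cut at k.

    Deterministic; returned labels are 1..k ordered by decreasing cluster
    size (ties broken by first appearance).
    """
    n = cm.M.shape[0]
    if k > n:
        raise ValueError("k exceeds the number of patients")
    D = 1.0 - cm.M
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    raw = fcluster(Z, t=k, criterion="maxclust")
    order = sorted(
        np.unique(raw),
        key=lambda lab: (-int(np.sum(raw == lab)), int(np.argmax(raw == lab))),
    )
    remap = {old: new + 1 for new, old in enumerate(order)}
    return np.array([remap[lab] for lab in raw])


def merge_to_coarse(
    fine_labels: np.ndarray,
    X_selected: np.ndarray | FeatureMatrix,
    target_k: int = 5,
) -> MergedClustering:
    """Merge fine clusters to coarse phenogroups by closest centroids.

    Centroids are per-fine-cluster means of the scaled selected features;
    the two centroids at minimal Euclidean distance are fused into their
    size-weighted mean until ``target_k`` remain.
    """
    if isinstance(X_selected, FeatureMatrix):
        X_selected = X_selected.values
    fine_labels = np.asarray(fine_labels)
    labels = sorted(int(l) for l in np.unique(fine_labels))
    if target_k < 1:
        raise ValueError("target_k must be >= 1")
    if target_k > len(labels):
        raise ValueError("target_k exceeds the number of fine clusters")
    centroids = {
        lab: X_selected[fine_labels == lab].mean(axis=0) for lab in labels
    }
    groups: dict[int, list[int]] = {lab: [lab] for lab in labels}  # key -> fine members
    sizes = {lab: int(np.sum(fine_labels == lab)) for lab in labels}
    cur = {lab: centroids[lab].copy() for lab in labels}
    wts = dict(sizes)
    while len(groups) > target_k:
        keys = sorted(groups)
        best, bd = None, np.inf
        for i, a in enumerate(keys):
            for bkey in keys[i + 1 :]:
                d = float(np.linalg.norm(cur[a] - cur[bkey]))
                if d < bd - 1e-12:
                    bd, best = d, (a, bkey)
        a, bkey = best
        wa, wb = wts[a], wts[bkey]
        cur[a] = (wa * cur[a] + wb * cur[bkey]) / (wa + wb)
        wts[a] = wa + wb
        groups[a] = groups[a] + groups[bkey]
        del groups[bkey], cur[bkey], wts[bkey]
    merge_map: dict[int, int] = {}
    # coarse labels 1..k ordered by total member count (largest first)
    ordered = sorted(groups, key=lambda kk: (-wts[kk], kk))
    for new, key in enumerate(ordered, start=1):
        for fine in groups[key]:
            merge_map[fine] = new
    return MergedClustering(
        fine_labels=fine_labels, merge_map=merge_map, centroids=centroids
    )
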