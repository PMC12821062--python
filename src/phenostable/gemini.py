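"""Sparse GEMINI discriminative clustering with integrated feature selection.

GEMINI (generalized mutual information) scores a soft clustering by how
far the cluster-conditional data distributions sit from the marginal data
distribution.  The one-vs-all MMD flavour used here measures that
discrepancy with the kernel maximum mean discrepancy: with soft
assignments tau (n x K), cluster masses s_k = sum_i tau_ik and
proportions pi_k = s_k / n,

    MMD_k^2 = tau_k' K tau_k / s_k^2
              - 2 tau_k' K 1 / (n s_k)
              + 1' K 1 / n^2
    score   = sum_k pi_k sqrt(max(MMD_k^2, 0)).

With a linear kernel MMD_k is exactly the Euclidean distance between the
cluster-k (soft) mean and the grand mean, which makes the estimator easy
to cross-check by hand.

The clustering head is a linear softmax p(y|x) = softmax(W'x + b).  A
group penalty lambda * sum_j ||W_j.||_2 over input-feature rows drives
whole features out of the model; training follows an increasing penalty
path with warm starts (proximal gradient ascent, so discarded rows are
exactly zero) and returns the sparsest model that still retains at least
``retain_fraction`` of the unpenalized GEMINI score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .preprocess import FeatureMatrix

SELECTION_TOL = 1e-4  # ||W_j.||_2 above this counts as "selected" (scaled features)


@dataclass
class KernelSpec:
    kind: str = "linear"  # "linear" | "rbf"
    bandwidth: float | str = "median-heuristic"

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "rbf"):
            raise ValueError(f"unknown kernel {self.kind!r}")
        if isinstance(self.bandwidth, str):
            if self.bandwidth != "median-heuristic":
                raise ValueError("bandwidth must be positive or 'median-heuristic'")
        elif self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")


@dataclass
class Assignment:
    """Row-stochastic soft assignments and their argmax hard labels."""

    soft: np.ndarray

    def __post_init__(self) -> None:
        if not np.allclose(self.soft.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("soft assignment rows must sum to 1")

    @property
    def hard(self) -> np.ndarray:
        return self.soft.argmax(axis=1)


@dataclass
class ClusterModel:
    """One seeded sparse-GEMINI run: linear softmax head + selected features."""

    W: np.ndarray  # (n_features, n_clusters)
    b: np.ndarray  # (n_clusters,)
    feature_names: list[str]
    variable_of: list[str]
    n_clusters: int
    seed: int
    penalty_used: float
    training_log: list[dict] = field(default_factory=list)

    @property
    def selected_features(self) -> list[str]:
        norms = np.linalg.norm(self.W, axis=1)
        return [f for f, nm in zip(self.feature_names, norms) if nm > SELECTION_TOL]

    @property
    def selected_variables(self) -> list[str]:
        """Parent variables with any selected encoded column (order preserved)."""
        sel = set(self.selected_features)
        out: list[str] = []
        for f, v in zip(self.feature_names, self.variable_of):
            if f in sel and v not in out:
                out.append(v)
        return out

    def predict(self, X: np.ndarray | FeatureMatrix) -> Assignment:
        if isinstance(X, FeatureMatrix):
            X = X.values
        return Assignment(soft=_softmax(X @ self.W + self.b))

    def to_dict(self) -> dict:
        return {
            "W": self.W.tolist(),
            "b": self.b.tolist(),
            "feature_names": self.feature_names,
            "variable_of": self.variable_of,
            "n_clusters": self.n_clusters,
            "seed": self.seed,
            "penalty_used": self.penalty_used,
            "selected_features": self.selected_features,
            "training_log": self.training_log,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClusterModel":
        return cls(
            W=np.asarray(d["W"], dtype=float),
            b=np.asarray(d["b"], dtype=float),
            feature_names=list(d["feature_names"]),
            variable_of=list(d["variable_of"]),
            n_clusters=int(d["n_clusters"]),
            seed=int(d["seed"]),
            penalty_used=float(d["penalty_used"]),
            training_log=list(d.get("training_log", [])),
        )


def _softmax(Z: np.ndarray) -> np.ndarray:
    Z = Z - Z.max(axis=1, keepdims=True)
    E = np.exp(Z)
    return E / E.sum(axis=1, keepdims=True)


def compute_kernel(X: np.ndarray | FeatureMatrix, spec: KernelSpec) -> np.ndarray:
    """Gram matrix of the (scaled) data under the requested kernel."""
    if isinstance(X, FeatureMatrix):
        X = X.values
    if X.shape[0] == 0:
        raise ValueError("empty data matrix")
    if spec.kind == "linear":
        return X @ X.T
    d = pdist(X)
    sigma = float(np.median(d)) if spec.bandwidth == "median-heuristic" else float(spec.bandwidth)
    if sigma <= 0:
        sigma = 1.0  # all points identical; any bandwidth gives K = 1
    sq = squareform(d) ** 2
    return np.exp(-sq / (2.0 * sigma**2))


def gemini_ova_mmd(soft: np.ndarray | Assignment, K: np.ndarray) -> float:
    """One-vs-all MMD GEMINI score of a soft assignment under kernel K."""
    tau = soft.soft if isinstance(soft, Assignment) else np.asarray(soft, dtype=float)
    n = tau.shape[0]
    if K.shape != (n, n):
        raise ValueError("kernel / assignment dimension mismatch")
    s = tau.sum(axis=0)
    c = K.sum(axis=1)  # K 1
    total = float(c.sum())  # 1' K 1
    # cancellation floor: mmd2 is a difference of O(K) terms, so residuals
    # of order eps * |K| are numerically zero
    floor = 1e-12 * max(1.0, abs(total) / n**2)
    score = 0.0
    for k in range(tau.shape[1]):
        if s[k] <= 0:
            continue  # empty cluster contributes 0
        tk = tau[:, k]
        mmd2 = (tk @ K @ tk) / s[k] ** 2 - 2.0 * (tk @ c) / (n * s[k]) + total / n**2
        if mmd2 < floor:
            mmd2 = 0.0
        score += (s[k] / n) * math.sqrt(mmd2)
    return float(score)


def _score_and_grad(tau: np.ndarray, K: np.ndarray, Kc: np.ndarray, total: float):
    """GEMINI score and its gradient with respect to tau.

    d MMD_k^2 / d tau_ik = 2 (K tau_k)_i / s_k^2 - 2 A_k / s_k^3
                           - 2 (K1)_i / (n s_k) + 2 B_k / (n s_k^2)
    and the pi_k sqrt(.) wrapper adds m_k / n plus the chain term.
    """
    n, Kc_ = tau.shape[0], Kc
    s = tau.sum(axis=0)
    G = np.zeros_like(tau)
    score = 0.0
    KT = K @ tau  # (n, K)
    for k in range(tau.shape[1]):
        if s[k] <= 1e-12:
            continue
        tk = tau[:, k]
        A = float(tk @ KT[:, k])
        B = float(tk @ Kc_)
        mmd2 = A / s[k] ** 2 - 2.0 * B / (n * s[k]) + total / n**2
        m = math.sqrt(max(mmd2, 0.0))
        score += (s[k] / n) * m
        if m <= 1e-12:
            continue
        dmmd2 = (
            2.0 * KT[:, k] / s[k] ** 2
            - 2.0 * A / s[k] ** 3
            - 2.0 * Kc_ / (n * s[k])
            + 2.0 * B / (n * s[k] ** 2)
        )
        G[:, k] = m / n + (s[k] / n) * dmmd2 / (2.0 * m)
    return score, G


def fit_sparse_gemini(
    Df: FeatureMatrix,
    n_clusters: int = 10,
    kernel: KernelSpec | None = None,
    penalty_path: tuple[float, ...] | None = None,
    seed: int = 0,
    *,
    retain_fraction: float = 0.9,
    step: float = 0.05,
    n_iter_init: int = 600,
    n_iter_path: int = 300,
) -> ClusterModel:
    """Train a sparse GEMINI clustering head along an increasing penalty path.

    Full-batch proximal gradient ascent with fixed step and iteration
    budget per path point, warm-started.  The seed controls only the
    initialization of W; everything else is deterministic.  The returned
    model is the last (sparsest) path point whose GEMINI score is at
    least ``retain_fraction`` of the unpenalized maximum.
    """
    if n_clusters < 2:
        raise ValueError("n_clusters must be >= 2")
    kernel = kernel or KernelSpec()
    X = Df.values
    n, p = X.shape
    if penalty_path is None:
        penalty_path = (0.0, *np.geomspace(0.002, 0.3, 14))
    if any(b < a for a, b in zip(penalty_path, penalty_path[1:])):
        raise ValueError("penalty_path must be non-decreasing")
    K = compute_kernel(X, kernel)
    Kc = K.sum(axis=1)
    total = float(Kc.sum())

    rng = np.random.default_rng(seed)
    W = rng.normal(0.0, 0.1, size=(p, n_clusters))
    b = np.zeros(n_clusters)

    log: list[dict] = []
    snapshots: list[tuple[float, np.ndarray, np.ndarray, float]] = []
    for i, lam in enumerate(penalty_path):
        iters = n_iter_init if i == 0 else n_iter_path
        for _ in range(iters):
            tau = _softmax(X @ W + b)
            score, G = _score_and_grad(tau, K, Kc, total)
            if not math.isfinite(score):
                raise FloatingPointError(
                    f"sparse GEMINI diverged at penalty {lam:g} (seed {seed})"
                )
            # backprop through softmax: dL/dZ = tau * (G - rowsum(tau*G))
            inner = (tau * G).sum(axis=1, keepdims=True)
            dZ = tau * (G - inner)
            W = W + step * (X.T @ dZ)
            b = b + step * dZ.sum(axis=0)
            if lam > 0:  # block soft-threshold per input-feature row
                norms = np.linalg.norm(W, axis=1, keepdims=True)
                shrink = np.maximum(0.0, 1.0 - step * lam / np.maximum(norms, 1e-12))
                W = W * shrink
        tau = _softmax(X @ W + b)
        score = gemini_ova_mmd(tau, K)
        n_sel = int((np.linalg.norm(W, axis=1) > SELECTION_TOL).sum())
        log.append({"penalty": float(lam), "score": float(score), "n_selected": n_sel})
        snapshots.append((float(lam), W.copy(), b.copy(), float(score)))

    best_unpen = snapshots[0][3]
    chosen = snapshots[0]
    for snap in snapshots:
        if snap[3] >= retain_fraction * best_unpen:
            chosen = snap  # path is increasing in lambda -> last qualifying = sparsest
    lam, W, b, _ = chosen
    return ClusterModel(
        W=W,
        b=b,
        feature_names=list(Df.feature_names),
        variable_of=list(Df.variable_of),
        n_clusters=n_clusters,
        seed=seed,
        penalty_used=lam,
        training_log=log,
    )


@dataclass
class EnsembleResult:
    models: list[ClusterModel]
    df_assignments: list[Assignment]
    dr_assignments: list[Assignment]
    failures: list[dict] = field(default_factory=list)


def run_ensemble(
    Df: FeatureMatrix,
    Dr: FeatureMatrix,
    n_models: int = 120,
    n_clusters: int = 10,
    kernel: KernelSpec | None = None,
    penalty_path: tuple[float, ...] | None = None,
    base_seed: int = 0,
    **fit_kwargs,
) -> EnsembleResult:
    """Repeat sparse GEMINI with seeds base_seed..base_seed+n_models-1.

    Models differ only by the random initialization their seed selects.
    A model that diverges is recorded as a failure; the rest continue.
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    models, dfa, dra, failures = [], [], [], []
    for i in range(n_models):
        seed = base_seed + i
        try:
            m = fit_sparse_gemini(
                Df, n_clusters, kernel, penalty_path, seed, **fit_kwargs
            )
        except FloatingPointError as exc:
            failures.append({"seed": seed, "error": str(exc)})
            continue
        models.append(m)
        dfa.append(m.predict(Df))
        dra.append(m.predict(Dr))
    return EnsembleResult(models, dfa, dra, failures)


def feature_selection_frequency(models: list[ClusterModel]) -> dict[str, float]:
    """Per-variable selection proportion across models.

    One-hot columns are OR-ed into their parent variable before counting:
    a variable counts as selected by a model if any of its encoded
    columns survived the penalty.
    """
    if not models:
        raise ValueError("need at least one model")
    order: list[str] = []
    for v in models[0].variable_of:
        if v not in order:
            order.append(v)
    counts = {v: 0 for v in order}
    for m in models:
        for v in m.selected_variables:
            counts[v] += 1
    return {v: counts[v] / len(models) for v in order}


def top_selected(
    frequencies: dict[str, float], threshold: float = 0.9
) -> list[str]:
    """Variables selected by strictly more than `threshold` of models."""
    return [v for v, f in frequencies.items() if f > threshold]
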