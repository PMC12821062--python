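"""Independent brute-force oracles used to cross-check the implementation.

These re-derive the estimators from their definitions with explicit loops
and share no code with the package internals.
"""

from __future__ import annotations

import math

import numpy as np


def gemini_ova_mmd_bruteforce(tau: np.ndarray, K: np.ndarray) -> float:
    """Double-loop evaluation of the one-vs-all MMD GEMINI estimator.

    For each cluster k with mass s_k = sum_i tau_ik:
      MMD_k^2 = sum_ij tau_ik tau_jk K_ij / s_k^2
                - 2 sum_ij tau_ik K_ij / (n s_k)
                + sum_ij K_ij / n^2
    and the score is sum_k (s_k/n) sqrt(max(MMD_k^2, 0)).
    """
    n, n_clusters = tau.shape
    total = 0.0
    for i in range(n):
        for j in range(n):
            total += K[i, j]
    score = 0.0
    for k in range(n_clusters):
        s = 0.0
        for i in range(n):
            s += tau[i, k]
        if s <= 0:
            continue
        a = 0.0
        b = 0.0
        for i in range(n):
            for j in range(n):
                a += tau[i, k] * tau[j, k] * K[i, j]
                b += tau[i, k] * K[i, j]
        mmd2 = a / s**2 - 2.0 * b / (n * s) + total / n**2
        score += (s / n) * math.sqrt(max(mmd2, 0.0))
    return score


def nearest_centroid_labels(X: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Assign each row to the closest centroid (Euclidean)."""
    d = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    return d.argmin(axis=1)
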