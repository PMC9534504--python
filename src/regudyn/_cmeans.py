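"""Minimal fuzzy c-means (Bezdek) used for temporal regulon clustering.

Standard alternating optimization of the fuzzy partition objective
``J = sum_i sum_c u_ic^m ||x_i - v_c||^2`` with fuzzifier ``m`` and multiple
seeded restarts; the best restart by objective is returned.
"""

from __future__ import annotations

import numpy as np

__all__ = ["fuzzy_cmeans"]


def _run_once(
    X: np.ndarray, k: int, m: float, rng: np.random.Generator, max_iter: int, tol: float
) -> tuple[np.ndarray, np.ndarray, float]:
    n = X.shape[0]
    U = rng.dirichlet(np.ones(k), size=n)  # n x k memberships
    prev_obj = np.inf
    for _ in range(max_iter):
        Um = U**m
        centers = (Um.T @ X) / Um.sum(axis=0)[:, None]
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        d2 = np.maximum(d2, 1e-12)
        inv = d2 ** (-1.0 / (m - 1.0))
        U = inv / inv.sum(axis=1, keepdims=True)
        obj = float((U**m * d2).sum())
        if abs(prev_obj - obj) < tol:
            break
        prev_obj = obj
    return U, centers, obj


def fuzzy_cmeans(
    X: np.ndarray,
    k: int,
    m: float = 2.0,
    n_restarts: int = 100,
    max_iter: int = 300,
    tol: float = 1e-9,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cluster rows of ``X`` into ``k`` fuzzy clusters.

    Returns ``(memberships, centers, hard_labels)`` of the best restart.
    """
    X = np.asarray(X, dtype=float)
    if k < 1 or k > X.shape[0]:
        raise ValueError(f"k must lie in [1, n_rows], got {k} for {X.shape[0]} rows")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        U, centers, obj = _run_once(X, k, m, rng, max_iter, tol)
        if best is None or obj < best[2]:
            best = (U, centers, obj)
    U, centers, _ = best
    return U, centers, U.argmax(axis=1)
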