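"""Shared fixtures and independent brute-force oracles.

The oracles here intentionally avoid the package's own vectorized code
paths: dense reconstruction goes through explicit outer products, pairwise
metrics through double loops, so the tests compare two genuinely different
computations.
"""

from __future__ import annotations

import numpy as np
import pytest

from countcp import KruskalModel, SparseCountTensor


def dense_from_model(model: KruskalModel) -> np.ndarray:
    """Materialize the full Poisson-parameter tensor via outer products."""
    M = np.zeros(model.shape)
    for r in range(model.rank):
        comp = model.weights[r]
        outer = model.factors[0][:, r]
        for A in model.factors[1:]:
            outer = np.multiply.outer(outer, A[:, r])
        M = M + comp * outer
    return M


def dense_from_tensor(X: SparseCountTensor) -> np.ndarray:
    D = np.zeros(X.shape)
    for idx, v in zip(X.indices, X.values):
        D[tuple(idx)] = v
    return D


def dense_poisson_loss(X_dense: np.ndarray, M_dense: np.ndarray, eps: float = 1e-10) -> float:
    loss = M_dense.sum()
    obs = X_dense > 0
    loss -= float(np.sum(X_dense[obs] * np.log(np.maximum(M_dense[obs], eps))))
    return float(loss)


def random_model(rng, shape, rank, low=0.1, high=1.0) -> KruskalModel:
    weights = rng.uniform(0.5, 2.0, size=rank)
    factors = [rng.uniform(low, high, size=(I, rank)) for I in shape]
    return KruskalModel(weights, factors)


def random_tensor(rng, shape, density=0.5, max_count=9) -> SparseCountTensor:
    D = rng.integers(0, max_count + 1, size=shape)
    D[rng.random(shape) > density] = 0
    idx = np.argwhere(D > 0)
    if idx.size == 0:
        D[tuple(0 for _ in shape)] = 1
        idx = np.argwhere(D > 0)
    vals = D[tuple(idx.T)]
    return SparseCountTensor(tuple(shape), idx.astype(np.int64), vals.astype(np.int64))


def brute_force_angular(A: np.ndarray, threshold: float) -> float:
    total = 0.0
    R = A.shape[1]
    for p in range(R):
        for r in range(p + 1, R):
            np_, nr = np.linalg.norm(A[:, p]), np.linalg.norm(A[:, r])
            cos = 0.0 if np_ == 0 or nr == 0 else float(A[:, p] @ A[:, r] / (np_ * nr))
            total += max(0.0, cos - threshold) ** 2
    return total


def kkt_project_l1_ball(v: np.ndarray, s: float) -> np.ndarray:
    """Independent projection oracle: KKT search over the threshold tau.

    w(tau) = max(v - tau, 0); tau = 0 if already feasible, otherwise the
    root of sum(w(tau)) = s found by bisection.
    """
    w0 = np.maximum(v, 0.0)
    if w0.sum() <= s:
        return w0
    lo, hi = 0.0, float(np.max(v))
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if np.maximum(v - mid, 0.0).sum() > s:
            lo = mid
        else:
            hi = mid
    return np.maximum(v - 0.5 * (lo + hi), 0.0)


def pairwise_auc(y: np.ndarray, scores: np.ndarray) -> float:
    pos = scores[np.asarray(y) == 1]
    neg = scores[np.asarray(y) == 0]
    wins = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1.0
            elif sp == sn:
                wins += 0.5
    return wins / (len(pos) * len(neg))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
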