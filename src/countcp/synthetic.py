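"""Planted-model generators for end-to-end testing without external data.

The generator plants a nonnegative Kruskal model with controllable column
sparsity and pairwise overlap, Poisson-samples a sparse count tensor from
it, and optionally draws binary entity labels from a logistic model on the
first-mode factor rows. Defaults emulate the desk-scale study conditions
used throughout the test suite: a 30x30x30 rank-3 model carrying a total
count mass of 5e4. A seasonal fixture shaped like a regions x weeks x
years influenza search-volume tensor (12 x 52 x 11) with unimodal winter
bumps in the week mode is also provided.

Poisson sampling is exact and sparse: component r contributes
``N_r ~ Poisson(lambda_r * prod_n sum(a_r^(n)))`` events, each placed
independently per mode by the categorical distribution given by the
normalized factor column (Poisson superposition + thinning). Cells with
zero mean are never touched and the dense tensor is never materialized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .tensor import KruskalModel, SparseCountTensor

__all__ = [
    "SyntheticSpec",
    "generate_model",
    "sample_tensor",
    "generate_labels",
    "flu_fixture",
]

_MAX_EVENTS = 100_000_000  # refuse absurd sampling requests


@dataclass(frozen=True)
class SyntheticSpec:
    """Conditions for a planted instance.

    ``sparsity`` is the fraction of zero entries per dense column part;
    ``scale`` the total count mass (lambda_r = scale / R); ``overlap`` an
    upper bound on the planted pairwise column cosines per mode;
    ``theta_true`` optional length-(R+1) logistic coefficients for labels.
    """

    shape: tuple[int, ...] = (30, 30, 30)
    rank: int = 3
    sparsity: float = 0.3
    scale: float = 5e4
    overlap: float = 0.5
    theta_true: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        if any(s <= 0 for s in self.shape):
            raise ValueError("shape must be positive")
        if self.rank < 1:
            raise ValueError("rank must be >= 1")
        if not 0.0 <= self.sparsity < 1.0:
            raise ValueError("sparsity must lie in [0, 1)")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.overlap < 0:
            raise ValueError("overlap must be >= 0")


def _disjoint_support_columns(I: int, R: int, rng) -> np.ndarray:
    """Columns with mutually disjoint supports (pairwise cosine exactly 0)."""
    if I < R:
        raise ValueError(f"cannot build {R} disjoint supports in {I} rows")
    perm = rng.permutation(I)
    groups = np.array_split(perm, R)
    A = np.zeros((I, R))
    for r, g in enumerate(groups):
        A[g, r] = rng.uniform(0.5, 1.5, size=g.size)
    return A / A.sum(axis=0)


def _dense_sparse_columns(I: int, R: int, sparsity: float, rng) -> np.ndarray:
    A = rng.uniform(0.1, 1.0, size=(I, R))
    n_zero = int(round(sparsity * I))
    n_zero = min(n_zero, I - 1)  # keep at least one nonzero per column
    for r in range(R):
        if n_zero:
            A[rng.choice(I, size=n_zero, replace=False), r] = 0.0
    return A / A.sum(axis=0)


def _max_pairwise_cosine(A: np.ndarray) -> float:
    norms = np.linalg.norm(A, axis=0)
    safe = np.where(norms > 0, norms, 1.0)
    C = (A / safe).T @ (A / safe)
    np.fill_diagonal(C, 0.0)
    return float(C.max()) if A.shape[1] > 1 else 0.0


def generate_model(spec: SyntheticSpec) -> KruskalModel:
    """Plant a nonnegative Kruskal model honoring the overlap cap.

    Each mode's columns are an l1-normalized blend of a disjoint-support
    (orthogonal) part and a dense-with-zeros part; the blend weight is
    shrunk toward the orthogonal part until all pairwise cosines are at or
    below ``spec.overlap``. Raises if the cap cannot be met in a bounded
    number of shrink steps. ``overlap = 0`` uses the purely disjoint
    construction, so cosines vanish exactly.
    """
    rng = np.random.default_rng(spec.seed)
    R = spec.rank
    factors = []
    for I in spec.shape:
        dense = _dense_sparse_columns(I, R, spec.sparsity, rng)
        if R == 1 or _max_pairwise_cosine(dense) <= spec.overlap:
            factors.append(dense)
            continue
        ortho = _disjoint_support_columns(I, R, rng)
        if spec.overlap == 0:
            factors.append(ortho)
            continue
        alpha, accepted = 1.0, None
        for _ in range(80):
            alpha *= 0.8
            A = (1.0 - alpha) * ortho + alpha * dense
            A = A / A.sum(axis=0)
            if _max_pairwise_cosine(A) <= spec.overlap:
                accepted = A
                break
        if accepted is None:
            raise ValueError(
                f"could not plant columns with pairwise cosine <= {spec.overlap}"
            )
        factors.append(accepted)
    weights = np.full(R, spec.scale / R)
    return KruskalModel(weights, factors)


def sample_tensor(model: KruskalModel, seed: int = 0) -> SparseCountTensor:
    """Draw each cell independently from Poisson(m_i), stored sparsely."""
    rng = np.random.default_rng(seed)
    R = model.rank
    col_sums = np.stack([A.sum(axis=0) for A in model.factors])  # (N, R)
    rates = model.weights * col_sums.prod(axis=0)
    if rates.sum() > _MAX_EVENTS:
        raise ValueError(f"expected event count {rates.sum():.3g} exceeds guard")
    all_idx = []
    for r in range(R):
        n_events = int(rng.poisson(rates[r])) if rates[r] > 0 else 0
        if n_events == 0:
            continue
        coords = np.empty((n_events, model.ndim), dtype=np.int64)
        for n, A in enumerate(model.factors):
            p = A[:, r] / col_sums[n, r]
            coords[:, n] = rng.choice(A.shape[0], size=n_events, p=p)
        all_idx.append(coords)
    if not all_idx:
        return SparseCountTensor(
            model.shape, np.empty((0, model.ndim), dtype=np.int64),
            np.empty(0, dtype=np.int64),
        )
    coords = np.concatenate(all_idx, axis=0)
    uniq, counts = np.unique(coords, axis=0, return_counts=True)
    return SparseCountTensor(model.shape, uniq, counts.astype(np.int64))


def generate_labels(A1: np.ndarray, theta_true, seed: int = 0) -> np.ndarray:
    """Bernoulli labels ``y_i ~ sigma(theta . [a_i; 1])`` on mode-0 rows."""
    A1 = np.asarray(A1, dtype=np.float64)
    theta = np.asarray(theta_true, dtype=np.float64)
    if theta.shape != (A1.shape[1] + 1,):
        raise ValueError("theta_true must have length R + 1")
    rng = np.random.default_rng(seed)
    p = expit(A1 @ theta[:-1] + theta[-1])
    return (rng.random(A1.shape[0]) < p).astype(np.int64)


def flu_fixture(
    seed: int = 0,
    *,
    peak_weeks: tuple[int, ...] = (47, 51, 8),
    bump_width: float = 3.0,
    scale: float = 5e4,
):
    """A 12 regions x 52 weeks x 11 years seasonal fixture.

    Rank-3 planted model whose week-mode columns are circular Gaussian
    bumps centered on ``peak_weeks`` (0-based; defaults sit in the winter
    window spanning roughly week 48 through week 13), Poisson-sampled.
    Returns ``(model, tensor)``.
    """
    shape = (12, 52, 11)
    R = len(peak_weeks)
    rng = np.random.default_rng(seed)
    regions = _dense_sparse_columns(shape[0], R, 0.4, rng)
    weeks = np.zeros((shape[1], R))
    for r, peak in enumerate(peak_weeks):
        j = np.arange(shape[1])
        d = np.minimum(np.abs(j - peak), shape[1] - np.abs(j - peak))
        weeks[:, r] = np.exp(-0.5 * (d / bump_width) ** 2)
    weeks = weeks / weeks.sum(axis=0)
    years = _dense_sparse_columns(shape[2], R, 0.0, rng)
    model = KruskalModel(np.full(R, scale / R), [regions, weeks, years])
    return model, sample_tensor(model, seed=seed + 1)
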