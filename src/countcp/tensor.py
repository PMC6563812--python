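"""Sparse count tensors and Kruskal (CP) models.

A count tensor is stored in coordinate form: an ``(nnz, N)`` integer index
array plus a vector of strictly positive integer counts; zeros are implicit.
A Kruskal model is the familiar ``[[lambda; A^(0), ..., A^(N-1)]]``
parameterization of a CP decomposition, here constrained to nonnegative
weights and factors so the reconstructed tensor is a valid field of Poisson
means.

The fitting loss is the Poisson negative log-likelihood up to a data-only
constant, ``sum_i m_i - sum_i x_i log m_i`` (the generalized KL divergence),
which is appropriate for counts where a Gaussian least-squares loss is not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EPS_FLOOR",
    "SparseCountTensor",
    "KruskalModel",
    "reconstruct_entry",
    "reconstruct_entries",
    "model_block_sum",
    "poisson_loss",
    "normalize",
    "absorb_weights",
    "kr_row",
    "kr_rows",
]

# Floor applied inside log(m) so a transiently zeroed factor row during SGD
# never produces -inf; see poisson_loss.
EPS_FLOOR = 1e-10


@dataclass(frozen=True)
class SparseCountTensor:
    """An N-way tensor of nonnegative integer counts in coordinate form.

    Parameters
    ----------
    shape : tuple of int
        Extent of each mode, all positive. At least three modes.
    indices : ndarray of shape (nnz, N)
        0-based integer coordinates, one row per stored (nonzero) cell.
        Rows must be unique.
    values : ndarray of shape (nnz,)
        Strictly positive integer counts.
    """

    shape: tuple[int, ...]
    indices: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        object.__setattr__(self, "shape", shape)
        if len(shape) < 3:
            raise ValueError(f"need at least 3 modes, got shape {shape}")
        if any(s <= 0 for s in shape):
            raise ValueError(f"all mode sizes must be positive, got {shape}")
        idx = np.asarray(self.indices, dtype=np.int64)
        if idx.ndim != 2 and idx.size == 0:
            idx = idx.reshape(0, len(shape))
        if idx.ndim != 2 or idx.shape[1] != len(shape):
            raise ValueError(
                f"indices must be (nnz, {len(shape)}), got {idx.shape}"
            )
        val = np.asarray(self.values)
        if val.shape != (idx.shape[0],):
            raise ValueError("values must be 1-D with one entry per index row")
        if val.size and not np.issubdtype(val.dtype, np.integer):
            rounded = np.rint(val)
            if not np.array_equal(rounded, val):
                raise ValueError("values must be integers")
            val = rounded
        val = val.astype(np.int64, copy=False)
        if np.any(val <= 0):
            raise ValueError("stored values must be strictly positive")
        if idx.size:
            if idx.min() < 0:
                raise ValueError("negative index")
            if np.any(idx >= np.asarray(shape, dtype=np.int64)):
                raise ValueError("index out of bounds for shape")
            if len(np.unique(idx, axis=0)) != idx.shape[0]:
                raise ValueError("duplicate index tuples")
        object.__setattr__(self, "indices", idx)
        object.__setattr__(self, "values", val)

    @property
    def ndim(self) -> int:
        return len(self.shape)

    @property
    def nnz(self) -> int:
        return int(self.indices.shape[0])

    def total(self) -> int:
        """Sum of all counts."""
        return int(self.values.sum()) if self.nnz else 0

    @classmethod
    def from_entries(
        cls,
        indices,
        values,
        shape=None,
        *,
        sum_duplicates: bool = False,
    ) -> "SparseCountTensor":
        """Build a tensor, optionally merging duplicate coordinates by summing."""
        idx = np.atleast_2d(np.asarray(indices, dtype=np.int64))
        val = np.asarray(values, dtype=np.int64)
        if idx.size == 0:
            if shape is None:
                raise ValueError("shape required for an empty tensor")
            idx = idx.reshape(0, len(shape))
        if sum_duplicates and idx.shape[0]:
            uniq, inv = np.unique(idx, axis=0, return_inverse=True)
            if uniq.shape[0] != idx.shape[0]:
                merged = np.zeros(uniq.shape[0], dtype=np.int64)
                np.add.at(merged, inv.ravel(), val)
                idx, val = uniq, merged
        if shape is None:
            shape = tuple(int(m) + 1 for m in idx.max(axis=0))
        keep = val != 0
        if not np.all(keep):
            idx, val = idx[keep], val[keep]
        return cls(tuple(shape), idx, val)


@dataclass
class KruskalModel:
    """Nonnegative CP model ``M = [[lambda; A^(0), ..., A^(N-1)]]``.

    ``weights`` is the length-R vector of component weights lambda_r and
    ``factors[n]`` is the I_n x R nonnegative factor matrix of mode n. Cell
    ``i`` of the modeled tensor is ``m_i = sum_r lambda_r prod_n A^(n)[i_n, r]``.
    """

    weights: np.ndarray
    factors: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.ndim != 1:
            raise ValueError("weights must be a vector")
        self.factors = [np.asarray(A, dtype=np.float64) for A in self.factors]
        R = self.rank
        for n, A in enumerate(self.factors):
            if A.ndim != 2 or A.shape[1] != R:
                raise ValueError(f"factor {n} must have {R} columns")
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")
        for n, A in enumerate(self.factors):
            if np.any(A < 0):
                raise ValueError(f"factor {n} has negative entries")

    @property
    def rank(self) -> int:
        return int(self.weights.shape[0])

    @property
    def ndim(self) -> int:
        return len(self.factors)

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(A.shape[0] for A in self.factors)

    def copy(self) -> "KruskalModel":
        return KruskalModel(self.weights.copy(), [A.copy() for A in self.factors])


def _check_index(model: KruskalModel, index) -> np.ndarray:
    idx = np.asarray(index, dtype=np.int64)
    if idx.shape != (model.ndim,):
        raise ValueError(f"index must have {model.ndim} entries")
    shape = model.shape
    for n, i in enumerate(idx):
        if not 0 <= i < shape[n]:
            raise IndexError(f"index {i} out of range for mode {n} of size {shape[n]}")
    return idx


def reconstruct_entry(model: KruskalModel, index) -> float:
    """Model value ``m_i = sum_r lambda_r prod_n A^(n)[i_n, r]`` at one cell."""
    idx = _check_index(model, index)
    prod = model.weights.copy()
    for n, A in enumerate(model.factors):
        prod *= A[idx[n], :]
    return float(prod.sum())


def reconstruct_entries(model: KruskalModel, indices: np.ndarray) -> np.ndarray:
    """Vectorized model values at an ``(B, N)`` array of cell coordinates."""
    idx = np.asarray(indices, dtype=np.int64)
    if idx.ndim != 2 or idx.shape[1] != model.ndim:
        raise ValueError(f"indices must be (B, {model.ndim})")
    prod = np.broadcast_to(model.weights, (idx.shape[0], model.rank)).copy()
    for n, A in enumerate(model.factors):
        prod *= A[idx[:, n], :]
    return prod.sum(axis=1)


def _normalize_ranges(model: KruskalModel, ranges) -> list[tuple[int, int]]:
    if len(ranges) != model.ndim:
        raise ValueError("one range per mode required")
    out = []
    for n, (lo, hi) in enumerate(ranges):
        lo, hi = int(lo), int(hi)
        if lo < 0 or hi > model.shape[n]:
            raise IndexError(f"range ({lo}, {hi}) out of bounds for mode {n}")
        out.append((lo, hi))
    return out


def model_block_sum(model: KruskalModel, ranges) -> float:
    """Exact ``sum_{i in block} m_i`` over a hyper-rectangle of cells.

    Computed in closed form as ``sum_r lambda_r prod_n S_n[r]`` where
    ``S_n[r]`` is the column-r sum of ``A^(n)`` over the block's mode-n rows;
    never materializes the dense tensor. Empty ranges give 0.
    """
    ranges = _normalize_ranges(model, ranges)
    acc = model.weights.copy()
    for n, (lo, hi) in enumerate(ranges):
        if hi <= lo:
            return 0.0
        acc *= model.factors[n][lo:hi, :].sum(axis=0)
    return float(acc.sum())


def poisson_loss(X: SparseCountTensor, model: KruskalModel, *, eps: float = EPS_FLOOR) -> float:
    """Generalized KL divergence ``sum_i m_i - sum_{x_i>0} x_i log m_i``.

    The linear term runs over every cell (closed form); the log term only
    over stored nonzeros. ``m`` is floored at ``eps`` inside the log so the
    loss stays finite; the value itself may be negative for counts > 1.
    """
    if X.shape != model.shape:
        raise ValueError(f"shape mismatch: tensor {X.shape} vs model {model.shape}")
    lin = model_block_sum(model, [(0, s) for s in X.shape])
    if X.nnz == 0:
        return lin
    m = reconstruct_entries(model, X.indices)
    return float(lin - (X.values * np.log(np.maximum(m, eps))).sum())


def normalize(
    model: KruskalModel,
    designated_mode: int = 0,
    *,
    skip_modes=(),
) -> KruskalModel:
    """Rescale so every column of every non-designated mode has unit l1 norm.

    The absorbed scale multiplies the weight vector, leaving every
    reconstructed entry unchanged. An all-zero column in a non-designated
    mode cannot be normalized: it is left as zeros and the corresponding
    weight is set to 0 (with a warning), which reconstructs identically.
    Modes in ``skip_modes`` (e.g. simplex-projected modes whose scale is
    pinned by the projection) are left untouched.
    """
    N = model.ndim
    if not 0 <= designated_mode < N:
        raise ValueError(f"designated_mode must be in [0, {N})")
    weights = model.weights.copy()
    factors = [A.copy() for A in model.factors]
    skip = set(skip_modes) | {designated_mode}
    for n in range(N):
        if n in skip:
            continue
        s = factors[n].sum(axis=0)
        zero = s <= 0.0
        if np.any(zero & (weights > 0)):
            warnings.warn(
                f"all-zero column(s) {np.flatnonzero(zero).tolist()} in mode {n}; "
                "setting their weights to 0",
                RuntimeWarning,
                stacklevel=2,
            )
            weights[zero] = 0.0
        safe = np.where(zero, 1.0, s)
        factors[n] /= safe
        weights *= safe
        weights[zero] = 0.0
    return KruskalModel(weights, factors)


def absorb_weights(model: KruskalModel, designated_mode: int = 0) -> KruskalModel:
    """Fold the weight vector into the designated mode, leaving weights = 1."""
    factors = [A.copy() for A in model.factors]
    factors[designated_mode] = factors[designated_mode] * model.weights
    return KruskalModel(np.ones(model.rank), factors)


def kr_row(model: KruskalModel, exclude_mode: int, index) -> np.ndarray:
    """Row of the Khatri-Rao product ``A^(-n)`` addressed by ``index``.

    This is the elementwise product over all modes except ``exclude_mode``
    of each factor's row at the corresponding coordinate; dotted with
    ``weights * A^(n)[i_n, :]`` it reproduces ``reconstruct_entry``.
    """
    idx = _check_index(model, index)
    out = np.ones(model.rank)
    for n, A in enumerate(model.factors):
        if n == exclude_mode:
            continue
        out *= A[idx[n], :]
    return out


def kr_rows(model: KruskalModel, exclude_mode: int, indices: np.ndarray) -> np.ndarray:
    """Vectorized ``kr_row`` for a ``(B, N)`` coordinate array; returns (B, R)."""
    idx = np.asarray(indices, dtype=np.int64)
    out = np.ones((idx.shape[0], model.rank))
    for n, A in enumerate(model.factors):
        if n == exclude_mode:
            continue
        out *= A[idx[:, n], :]
    return out
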