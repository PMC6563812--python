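"""Per-block stochastic gradients and Adam updates.

The fitting objective is the Poisson loss plus the weighted regularizers,
optimized by alternating over modes. For one tensor block and mode n the
gradient with respect to the block's mode-n factor rows splits into

* a **linear term** ``prod_{k != n} S_k[r]`` (``S_k[r]`` = column-r sum of
  ``A^(k)`` over the block's mode-k range) — the derivative of
  ``sum_i m_i`` — which is computed exactly in closed form for all cells of
  the block, observed or not;
* a **ratio term** ``sum_i (x_i / m_i) * kr_row(i)`` — the derivative of
  ``-sum x_i log m_i`` — estimated from a minibatch of the block's
  nonzeros, rescaled by (block nonzeros / batch size) so it is unbiased;
* the active regularizer gradients (angular, ridge, and on mode 0 the
  logistic supervision term with theta held fixed).

Updates use standard bias-corrected Adam followed by clipping to the
nonnegative orthant; simplex-mode columns are then projected onto the
l1-ball and an optional top-k hard threshold is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .regularizers import (
    RegularizerConfig,
    angular_grad,
    hard_threshold,
    logistic_grad_rows,
    project_l1_ball,
)
from .tensor import EPS_FLOOR, KruskalModel, SparseCountTensor, kr_rows, reconstruct_entries

__all__ = ["FitConfig", "AdamState", "mode_gradient", "adam_step", "fit_block"]

ADAM_B1 = 0.9
ADAM_B2 = 0.999
ADAM_EPS = 1e-8


@dataclass(frozen=True)
class FitConfig:
    """Everything the fitting loop needs besides the data.

    ``learning_rate``, ``batch_size`` and the regularizer defaults follow
    the published tuning (1e-4 and 200). With ``step_scaling="mode_mean"``
    (default) the Adam step for mode n is ``learning_rate`` times the mean
    absolute entry of ``A^(n)`` at the start of the epoch, making the step
    size scale-free — necessary because the component weights are absorbed
    into the designated mode, whose entries can be orders of magnitude
    larger than the l1-normalized modes. ``inner_iters`` is the number of
    SGD iterations each worker runs per block visit.
    """

    rank: int
    regularizers: RegularizerConfig = field(default_factory=RegularizerConfig)
    learning_rate: float = 1e-4
    batch_size: int = 200
    inner_iters: int = 10
    max_epochs: int = 100
    n_workers: int = 1
    tol: float = 1e-4
    seed: int = 0
    designated_mode: int = 0
    step_scaling: str = "mode_mean"
    shuffle_strata: bool = False

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError("rank must be >= 1")
        for name in ("learning_rate", "batch_size", "n_workers", "tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.inner_iters < 0 or self.max_epochs < 0:
            raise ValueError("inner_iters and max_epochs must be >= 0")
        if self.step_scaling not in ("mode_mean", "none"):
            raise ValueError("step_scaling must be 'mode_mean' or 'none'")


@dataclass
class AdamState:
    """First/second-moment accumulators shadowing one parameter block."""

    m: np.ndarray
    v: np.ndarray
    t: int = 0

    @classmethod
    def zeros(cls, shape) -> "AdamState":
        return cls(np.zeros(shape), np.zeros(shape), 0)

    def copy(self) -> "AdamState":
        return AdamState(self.m.copy(), self.v.copy(), self.t)


def adam_step(state: AdamState, grad: np.ndarray, params: np.ndarray, lr: float):
    """One bias-corrected Adam update, then clip parameters to >= 0.

    Returns ``(new_state, new_params)``; inputs are not mutated.
    """
    if grad.shape != params.shape or grad.shape != state.m.shape:
        raise ValueError("shape mismatch between grad, params, and state")
    t = state.t + 1
    m = ADAM_B1 * state.m + (1.0 - ADAM_B1) * grad
    v = ADAM_B2 * state.v + (1.0 - ADAM_B2) * grad * grad
    m_hat = m / (1.0 - ADAM_B1**t)
    v_hat = v / (1.0 - ADAM_B2**t)
    new_params = params - lr * m_hat / (np.sqrt(v_hat) + ADAM_EPS)
    np.maximum(new_params, 0.0, out=new_params)
    return AdamState(m, v, t), new_params


def mode_gradient(
    X_block: SparseCountTensor,
    model: KruskalModel,
    mode: int,
    block_ranges,
    *,
    reg: RegularizerConfig | None = None,
    minibatch: np.ndarray | None = None,
    labels: np.ndarray | None = None,
    theta: np.ndarray | None = None,
    eps: float = EPS_FLOOR,
) -> np.ndarray:
    """Objective gradient w.r.t. the block's mode-``mode`` factor rows.

    ``X_block`` holds the block's nonzeros with *global* coordinates;
    ``block_ranges`` is one half-open range per mode. ``minibatch`` is an
    array of positions into ``X_block``'s entries, or None for the exact
    full-batch gradient. ``labels`` is a full-length {0,1}/-1(unlabeled)
    vector for mode 0 and ``theta`` the fixed logistic coefficients.
    Component weights are assumed absorbed (weights all ones).
    """
    reg = reg or RegularizerConfig()
    lo, hi = block_ranges[mode]
    n_rows = hi - lo
    R = model.rank
    grad = np.zeros((n_rows, R))
    if n_rows == 0:
        return grad

    # exact linear term: same for every row of the block
    lin = model.weights.copy()
    empty = False
    for k, (klo, khi) in enumerate(block_ranges):
        if k == mode:
            continue
        if khi <= klo:
            empty = True
            break
        lin *= model.factors[k][klo:khi, :].sum(axis=0)
    if not empty:
        grad += lin[None, :]

    # stochastic ratio term from the block's nonzeros
    nnz = X_block.nnz
    if nnz:
        if minibatch is None:
            pos = np.arange(nnz)
            scale = 1.0
        else:
            pos = np.asarray(minibatch, dtype=np.int64)
            scale = nnz / pos.size if pos.size else 0.0
        if len(pos):
            idx = X_block.indices[pos]
            x = X_block.values[pos].astype(np.float64)
            m = np.maximum(reconstruct_entries(model, idx), eps)
            contrib = (x / m)[:, None] * (kr_rows(model, mode, idx) * model.weights)
            ratio = np.zeros((n_rows, R))
            np.add.at(ratio, idx[:, mode] - lo, contrib)
            grad -= scale * ratio

    A = model.factors[mode]
    if reg.beta_angular > 0:
        grad += reg.beta_angular * angular_grad(A, reg.angular_threshold)[lo:hi, :]
    if reg.beta_l2 > 0:
        grad += reg.beta_l2 * A[lo:hi, :]
    if mode == 0 and reg.beta_supervision > 0 and labels is not None and theta is not None:
        lab = np.asarray(labels)
        rows = np.arange(lo, hi)
        mask = lab[rows] >= 0
        if np.any(mask):
            rr = rows[mask]
            grad[rr - lo, :] += logistic_grad_rows(
                A[rr, :], lab[rr], theta, reg.beta_supervision
            )
    return grad


def fit_block(
    X_block: SparseCountTensor,
    model: KruskalModel,
    block_ranges,
    config: FitConfig,
    rng: np.random.Generator,
    *,
    adam: dict[int, AdamState] | None = None,
    labels: np.ndarray | None = None,
    theta: np.ndarray | None = None,
    step_scale: np.ndarray | None = None,
):
    """Run ``inner_iters`` SGD iterations on one block.

    Each iteration samples a minibatch (with replacement) of the block's
    nonzeros, then round-robins over the modes: gradient, Adam step,
    simplex projection / hard threshold where configured. Only the factor
    rows inside ``block_ranges`` are touched. Returns
    ``(slices, adam_states)`` where ``slices[mode]`` is the updated row
    block for that mode.

    A block with no nonzeros still receives the exact linear-term gradient,
    which only shrinks the factors (documented behavior).
    """
    reg = config.regularizers
    N = model.ndim
    work = model.copy()
    if adam is None:
        adam = {}
    states = {
        n: (adam[n].copy() if n in adam else AdamState.zeros(
            (block_ranges[n][1] - block_ranges[n][0], model.rank)))
        for n in range(N)
    }
    if step_scale is None:
        step_scale = np.ones(N)
    nnz = X_block.nnz
    batch = min(config.batch_size, nnz) if nnz else 0
    for _ in range(config.inner_iters):
        minibatch = rng.integers(0, nnz, size=batch) if nnz else None
        full = minibatch is not None and nnz <= config.batch_size
        for n in range(N):
            lo, hi = block_ranges[n]
            if hi <= lo:
                continue
            grad = mode_gradient(
                X_block, work, n, block_ranges,
                reg=reg,
                minibatch=None if (minibatch is None or full) else minibatch,
                labels=labels, theta=theta,
            )
            lr = config.learning_rate * float(step_scale[n])
            states[n], new_slice = adam_step(states[n], grad, work.factors[n][lo:hi, :], lr)
            if n in reg.simplex_modes:
                for r in range(model.rank):
                    new_slice[:, r] = project_l1_ball(new_slice[:, r], reg.simplex_radius)
            if reg.hard_threshold_k is not None:
                for r in range(model.rank):
                    new_slice[:, r] = hard_threshold(new_slice[:, r], reg.hard_threshold_k)
            work.factors[n][lo:hi, :] = new_slice
    slices = {n: work.factors[n][block_ranges[n][0]:block_ranges[n][1], :].copy()
              for n in range(N)}
    return slices, states
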