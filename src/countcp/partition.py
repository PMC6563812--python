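"""Block partition and strata schedule for distributed SGD on tensors.

With ``d`` workers each mode is split into ``d`` near-equal index ranges,
giving ``d^N`` blocks for an N-way tensor. A *stratum* is a set of ``d``
blocks that share no index range in any mode, so SGD updates on the blocks
of one stratum touch disjoint factor-matrix rows and can run in parallel
with results identical to a serial sweep. The diagonal scheme below groups
the ``d^N`` blocks into ``d^(N-1)`` strata that cover every block exactly
once: stratum ``(s_1, ..., s_{N-1})`` assigns worker ``i`` the block whose
mode-0 range index is ``i`` and whose mode-k range index is
``(i + s_k) mod d`` for k >= 1. For the 3-way reference case with d = 2
this yields 8 blocks in 4 strata of 2 blocks each.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .tensor import SparseCountTensor

__all__ = ["Block", "PartitionPlan", "build_partition", "assign_entries"]


@dataclass(frozen=True)
class Block:
    """One tensor block: a half-open index range per mode, plus an id."""

    block_id: int
    ranges: tuple[tuple[int, int], ...]
    range_indices: tuple[int, ...]  # which of the d ranges this block uses, per mode

    def contains(self, index) -> bool:
        return all(lo <= i < hi for i, (lo, hi) in zip(index, self.ranges))


@dataclass(frozen=True)
class PartitionPlan:
    """Partition of an N-way tensor into ``d^N`` blocks and ``d^(N-1)`` strata."""

    shape: tuple[int, ...]
    d: int
    boundaries: tuple[tuple[int, ...], ...]  # per mode, length d+1
    blocks: tuple[Block, ...]
    strata: tuple[tuple[int, ...], ...]  # per stratum, the d block ids

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def n_strata(self) -> int:
        return len(self.strata)

    def describe(self) -> str:
        """Plain-text rendering of the plan for logs and debugging."""
        lines = [f"partition of {self.shape} for d={self.d}: "
                 f"{self.n_blocks} blocks, {self.n_strata} strata"]
        for n, b in enumerate(self.boundaries):
            lines.append(f"  mode {n} boundaries: {list(b)}")
        for s, ids in enumerate(self.strata):
            parts = ", ".join(
                f"b{bid}{[tuple(r) for r in self.blocks[bid].ranges]}" for bid in ids
            )
            lines.append(f"  stratum {s}: {parts}")
        return "\n".join(lines)


def build_partition(shape, d: int) -> PartitionPlan:
    """Build the block partition and diagonal strata schedule.

    Mode-n boundaries sit at ``floor(i * I_n / d)`` for i = 0..d, giving
    near-equal ranges when d does not divide I_n (ranges may be empty when
    d exceeds a mode size). Raises if ``d < 1``.
    """
    shape = tuple(int(s) for s in shape)
    N = len(shape)
    if N < 3:
        raise ValueError("need at least 3 modes")
    if d < 1:
        raise ValueError("worker count d must be >= 1")
    boundaries = tuple(
        tuple(int(np.floor(i * I / d)) for i in range(d + 1)) for I in shape
    )
    # enumerate all d^N blocks, indexed by their per-mode range indices
    block_of: dict[tuple[int, ...], int] = {}
    blocks: list[Block] = []
    for ridx in itertools.product(range(d), repeat=N):
        rng = tuple(
            (boundaries[n][ridx[n]], boundaries[n][ridx[n] + 1]) for n in range(N)
        )
        block_of[ridx] = len(blocks)
        blocks.append(Block(len(blocks), rng, ridx))
    strata: list[tuple[int, ...]] = []
    for offsets in itertools.product(range(d), repeat=N - 1):
        ids = []
        for worker in range(d):
            ridx = (worker,) + tuple((worker + s) % d for s in offsets)
            ids.append(block_of[ridx])
        strata.append(tuple(ids))
    return PartitionPlan(shape, d, boundaries, tuple(blocks), tuple(strata))


def assign_entries(X: SparseCountTensor, plan: PartitionPlan) -> dict[int, np.ndarray]:
    """Map each stored nonzero to the unique block containing it.

    Returns ``{block_id: entry_row_positions}`` (positions into ``X.indices``);
    blocks with no entries map to empty arrays. Half-open ranges make the
    assignment unambiguous, and every entry lands in exactly one block.
    """
    if X.shape != plan.shape:
        raise ValueError("tensor shape does not match plan")
    d = plan.d
    N = X.ndim
    # per-mode range index of every entry via searchsorted on the boundaries
    ridx = np.empty((X.nnz, N), dtype=np.int64)
    for n in range(N):
        inner = np.asarray(plan.boundaries[n][1:-1], dtype=np.int64)
        ridx[:, n] = np.searchsorted(inner, X.indices[:, n], side="right")
    # linearize the per-mode range indices to a block key
    key = np.zeros(X.nnz, dtype=np.int64)
    for n in range(N):
        key = key * d + ridx[:, n]
    # block ids were created in itertools.product order, which is exactly
    # the mixed-radix order of (range indices) base d
    out: dict[int, np.ndarray] = {b.block_id: None for b in plan.blocks}
    order = np.argsort(key, kind="stable")
    sorted_key = key[order]
    bounds = np.searchsorted(sorted_key, np.arange(plan.n_blocks + 1))
    for bid in range(plan.n_blocks):
        out[bid] = order[bounds[bid]:bounds[bid + 1]]
    return out
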