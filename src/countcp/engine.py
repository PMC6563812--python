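"""Epoch/stratum scheduling loop with a pluggable worker pool.

One epoch visits every stratum of the block partition once (so every block
exactly once). Within a stratum the blocks touch disjoint factor rows, so
they are dispatched to an executor — serial or process-pool — with the
guarantee that the merged result is bit-identical either way: every block
task reads a snapshot of the model taken at the start of the stratum, uses
a seed derived from (master seed, epoch, stratum, block), and writes only
its own row ranges. After each epoch the factors are gathered, the
non-designated modes are l1-renormalized for identifiability (scale
absorbed into the component weights, then re-absorbed into the designated
mode), the supervision coefficients are refit if labels are present, and
convergence is checked on the relative change of the full objective.
"""

from __future__ import annotations

import logging
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field

import numpy as np

from .evaluate import SupervisionModel, as_label_array, fit_theta
from .optimize import AdamState, FitConfig, fit_block
from .partition import PartitionPlan, assign_entries, build_partition
from .regularizers import (
    angular_value,
    l2_value,
    logistic_values,
    project_l1_ball,
)
from .tensor import (
    KruskalModel,
    SparseCountTensor,
    absorb_weights,
    normalize,
    poisson_loss,
)

__all__ = [
    "FitHistory",
    "FitResult",
    "SerialExecutor",
    "ProcessExecutor",
    "run_stratum",
    "fit",
]

logger = logging.getLogger(__name__)

THETA_RIDGE = 1e-4  # ridge used when refitting the supervision coefficients


class SerialExecutor:
    """Runs block tasks in order in the calling process."""

    def map(self, fn, payloads):
        return [fn(p) for p in payloads]

    def close(self) -> None:
        pass


class ProcessExecutor:
    """Dispatches block tasks to a process pool.

    Because every task is a pure function of its payload, results are
    bit-identical to :class:`SerialExecutor`.
    """

    def __init__(self, n_workers: int):
        self.n_workers = n_workers
        self._pool: ProcessPoolExecutor | None = None

    def _ensure(self) -> ProcessPoolExecutor:
        if self._pool is None:
            self._pool = ProcessPoolExecutor(max_workers=self.n_workers)
        return self._pool

    def map(self, fn, payloads):
        return list(self._ensure().map(fn, payloads))

    def close(self) -> None:
        if self._pool is not None:
            self._pool.shutdown()
            self._pool = None


@dataclass
class FitHistory:
    """Per-epoch objective and penalty trace.

    ``records`` holds one dict per completed epoch with keys
    ``epoch, objective, poisson_loss, angular, l2, logistic, steps``.
    """

    initial_objective: float = float("nan")
    records: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def as_dataframe(self):
        import pandas as pd

        cols = ["epoch", "objective", "poisson_loss", "angular", "l2", "logistic", "steps"]
        return pd.DataFrame(self.records, columns=cols)

    def to_csv(self, path) -> None:
        self.as_dataframe().to_csv(path, index=False)


@dataclass
class FitResult:
    model: KruskalModel
    supervision: SupervisionModel | None
    history: FitHistory
    converged: bool = False


def _block_task(payload):
    """Top-level worker body (picklable): run fit_block on one block."""
    (bid, X_block, model, ranges, config, seed_key, states, labels, theta, step_scale) = payload
    rng = np.random.default_rng(seed_key)
    slices, new_states = fit_block(
        X_block, model, ranges, config, rng,
        adam=states, labels=labels, theta=theta, step_scale=step_scale,
    )
    return bid, slices, new_states


def _objective_parts(X, model, reg, labels, theta):
    loss = poisson_loss(X, model)
    ang = sum(angular_value(A, reg.angular_threshold) for A in model.factors) \
        if reg.beta_angular > 0 else 0.0
    l2 = sum(l2_value(A, 1.0) for A in model.factors) if reg.beta_l2 > 0 else 0.0
    logi = 0.0
    if reg.beta_supervision > 0 and labels is not None and theta is not None:
        mask = labels >= 0
        if np.any(mask):
            rows = (model.factors[0] * model.weights)[mask]
            logi = logistic_values(rows, labels[mask], theta, 1.0)
    obj = loss + reg.beta_angular * ang + reg.beta_l2 * l2 + reg.beta_supervision * logi
    return obj, loss, reg.beta_angular * ang, reg.beta_l2 * l2, reg.beta_supervision * logi


def run_stratum(
    plan: PartitionPlan,
    stratum_index: int,
    block_tensors: dict[int, SparseCountTensor],
    model: KruskalModel,
    config: FitConfig,
    executor,
    *,
    adam: dict | None = None,
    epoch: int = 0,
    labels: np.ndarray | None = None,
    theta: np.ndarray | None = None,
    step_scale: np.ndarray | None = None,
):
    """Process every block of one stratum and merge the updated slices.

    All blocks read the same model snapshot, so serial and parallel
    execution (and any block order) produce identical results. If the
    executor fails, the stratum is retried serially.
    """
    if adam is None:
        adam = {}
    payloads = []
    for bid in plan.strata[stratum_index]:
        block = plan.blocks[bid]
        states = {
            n: adam.get((n, block.range_indices[n]))
            for n in range(len(plan.shape))
        }
        states = {n: s for n, s in states.items() if s is not None}
        seed_key = [config.seed, epoch, stratum_index, bid]
        payloads.append((
            bid, block_tensors[bid], model, block.ranges, config,
            seed_key, states, labels, theta, step_scale,
        ))
    try:
        results = executor.map(_block_task, payloads)
    except Exception:  # pragma: no cover - depends on runtime failures
        logger.warning("executor failed on stratum %d; retrying serially", stratum_index)
        results = [_block_task(p) for p in payloads]
    new_model = model.copy()
    new_adam = dict(adam)
    for bid, slices, states in results:
        block = plan.blocks[bid]
        for n, sl in slices.items():
            lo, hi = block.ranges[n]
            new_model.factors[n][lo:hi, :] = sl
            new_adam[(n, block.range_indices[n])] = states[n]
    return new_model, new_adam


def _initial_model(X: SparseCountTensor, config: FitConfig, rng) -> KruskalModel:
    """Seeded uniform(0,1) factors, l1-normalized off the designated mode,
    with the designated mode rescaled so the model's total mass matches the
    observed total count (component weights start absorbed, all ones)."""
    R = config.rank
    reg = config.regularizers
    factors = [rng.uniform(size=(I, R)) for I in X.shape]
    model = KruskalModel(np.ones(R), factors)
    model = normalize(model, config.designated_mode, skip_modes=reg.simplex_modes)
    model = absorb_weights(model, config.designated_mode)
    total = X.total()
    if total > 0:
        from .tensor import model_block_sum

        current = model_block_sum(model, [(0, s) for s in X.shape])
        if current > 0:
            model.factors[config.designated_mode] *= total / current
    for n in reg.simplex_modes:
        A = model.factors[n]
        for r in range(R):
            A[:, r] = project_l1_ball(A[:, r], reg.simplex_radius)
    return model


def fit(
    X: SparseCountTensor,
    config: FitConfig,
    labels=None,
    *,
    executor=None,
    callback=None,
) -> FitResult:
    """Fit the constrained Poisson CP model by stratified block SGD.

    ``labels`` may be a dict ``{mode-0 index: 0/1}`` or a full-length array
    with -1 marking unlabeled entities; when present, logistic supervision
    coefficients are refit on the current mode-0 factor after every epoch
    and returned in the :class:`SupervisionModel`. ``callback(epoch, model,
    theta)`` is invoked after each epoch with the absorbed-weight model.

    Returns the normalized model (weights extracted, non-designated and
    non-simplex columns summing to one), the supervision model if labels
    were given, and the per-epoch history. ``max_epochs = 0`` returns the
    seeded initialization untouched.
    """
    reg = config.regularizers
    rng = np.random.default_rng(config.seed)
    model = _initial_model(X, config, rng)

    label_arr = as_label_array(labels, X.shape[0]) if labels is not None else None
    theta = None
    if label_arr is not None and reg.beta_supervision >= 0:
        mask = label_arr >= 0
        theta = fit_theta(
            (model.factors[0] * model.weights)[mask], label_arr[mask], ridge=THETA_RIDGE
        )

    plan = build_partition(X.shape, config.n_workers)
    entry_pos = assign_entries(X, plan)
    block_tensors = {
        bid: SparseCountTensor(X.shape, X.indices[pos], X.values[pos])
        for bid, pos in entry_pos.items()
    }
    adam: dict = {}

    own_executor = executor is None
    if executor is None:
        executor = SerialExecutor() if config.n_workers == 1 else ProcessExecutor(config.n_workers)

    history = FitHistory()
    obj0, *_ = _objective_parts(X, model, reg, label_arr, theta)
    history.initial_objective = obj0
    prev_obj = obj0
    converged = False
    steps = 0
    try:
        for epoch in range(config.max_epochs):
            if config.step_scaling == "mode_mean":
                step_scale = np.array([
                    float(np.mean(np.abs(A))) or 1.0 for A in model.factors
                ])
            else:
                step_scale = np.ones(model.ndim)
            order = np.arange(plan.n_strata)
            if config.shuffle_strata:
                np.random.default_rng([config.seed, epoch, 2**16 + 1]).shuffle(order)
            for s_idx in order:
                model, adam = run_stratum(
                    plan, int(s_idx), block_tensors, model, config, executor,
                    adam=adam, epoch=epoch, labels=label_arr, theta=theta,
                    step_scale=step_scale,
                )
                steps += config.inner_iters * config.n_workers
            # enforce the l1-ball on whole columns of simplex modes (block
            # slices alone only bound each chunk when d > 1)
            for n in reg.simplex_modes:
                A = model.factors[n]
                for r in range(config.rank):
                    A[:, r] = project_l1_ball(A[:, r], reg.simplex_radius)
            model = absorb_weights(
                normalize(model, config.designated_mode, skip_modes=reg.simplex_modes),
                config.designated_mode,
            )
            if label_arr is not None:
                mask = label_arr >= 0
                theta = fit_theta(
                    (model.factors[0] * model.weights)[mask],
                    label_arr[mask],
                    ridge=THETA_RIDGE,
                )
            obj, loss, ang, l2, logi = _objective_parts(X, model, reg, label_arr, theta)
            if not np.isfinite(obj):
                raise RuntimeError(
                    f"non-finite objective {obj} at epoch {epoch}; aborting"
                )
            history.records.append({
                "epoch": epoch, "objective": obj, "poisson_loss": loss,
                "angular": ang, "l2": l2, "logistic": logi, "steps": steps,
            })
            logger.info(
                "epoch %d: objective=%.6g loss=%.6g angular=%.3g l2=%.3g logistic=%.3g",
                epoch, obj, loss, ang, l2, logi,
            )
            if callback is not None:
                callback(epoch, model.copy(), None if theta is None else theta.copy())
            if abs(obj - prev_obj) / max(1.0, abs(prev_obj)) < config.tol:
                converged = True
                prev_obj = obj
                break
            prev_obj = obj
    finally:
        if own_executor:
            executor.close()

    final = normalize(model, config.designated_mode, skip_modes=reg.simplex_modes)
    supervision = None
    if label_arr is not None:
        supervision = SupervisionModel(theta=theta, labels=label_arr)
    return FitResult(model=final, supervision=supervision, history=history,
                     converged=converged)
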