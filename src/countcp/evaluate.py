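"""Supervision on the first mode and evaluation metrics.

Provides the ridge-stabilized logistic fit used to refit the supervision
coefficients each epoch, the rank-based AUC, the average-overlap
diversity metric (mean pairwise cosine similarity of components over a set
of modes — lower means more distinct components), a permutation- and
scale-invariant factor match score for recovery benchmarks, and the
fold-in protocol for scoring held-out first-mode entities: their factor
rows are estimated with all other modes frozen, so held-out prediction
never leaks test counts into the decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.special import expit
from scipy.stats import rankdata

from .tensor import EPS_FLOOR, KruskalModel, SparseCountTensor

__all__ = [
    "SupervisionModel",
    "as_label_array",
    "fit_theta",
    "entity_scores",
    "auc",
    "average_overlap",
    "factor_match_score",
    "stratified_split",
    "fold_in_rows",
    "holdout_auc",
]


@dataclass
class SupervisionModel:
    """Logistic coefficients (weights + intercept) and the mode-0 labels."""

    theta: np.ndarray
    labels: np.ndarray  # full length, -1 = unlabeled

    @property
    def rank(self) -> int:
        return int(self.theta.shape[0]) - 1


def as_label_array(labels, n_entities: int) -> np.ndarray:
    """Normalize labels to an int array of length ``n_entities``.

    Accepts a dict ``{entity index: 0/1}`` or an array; -1 marks unlabeled
    entities. Any other value is rejected.
    """
    out = np.full(n_entities, -1, dtype=np.int64)
    if isinstance(labels, dict):
        for i, y in labels.items():
            out[int(i)] = int(y)
    else:
        arr = np.asarray(labels, dtype=np.int64)
        if arr.shape != (n_entities,):
            raise ValueError(f"labels must have length {n_entities}")
        out = arr.copy()
    if not np.all(np.isin(out, (-1, 0, 1))):
        raise ValueError("labels must be 0, 1, or -1 (unlabeled)")
    return out


def fit_theta(A1: np.ndarray, y: np.ndarray, ridge: float = 1e-4,
              *, tol: float = 1e-8, max_iter: int = 200) -> np.ndarray:
    """Ridge-penalized logistic regression of labels on factor rows.

    Damped Newton iterations on the objective
    ``sum_i log(1 + exp(-y_i z_i)) + (ridge/2) ||w||^2`` (intercept
    unpenalized) until the gradient norm drops below ``tol``. Returns the
    length-(R+1) vector [weights; intercept]. Raises if only one class is
    present — the caller must supply at least one example of each class.
    """
    A1 = np.atleast_2d(np.asarray(A1, dtype=np.float64))
    y = np.asarray(y, dtype=np.float64)
    classes = np.unique(y)
    if not np.all(np.isin(classes, (0.0, 1.0))) or classes.size < 2:
        raise ValueError(
            "fit_theta needs labels in {0,1} with at least one example of "
            "each class; got classes " + repr(classes.tolist())
        )
    n, R = A1.shape
    X = np.hstack([A1, np.ones((n, 1))])
    pen = np.full(R + 1, ridge)
    pen[-1] = 0.0
    theta = np.zeros(R + 1)

    def objective(th):
        z = X @ th
        sgn = 2.0 * y - 1.0
        return float(np.logaddexp(0.0, -sgn * z).sum() + 0.5 * (pen * th * th).sum())

    obj = objective(theta)
    for _ in range(max_iter):
        p = expit(X @ theta)
        grad = X.T @ (p - y) + pen * theta
        if np.linalg.norm(grad) < tol:
            break
        w = np.maximum(p * (1.0 - p), 1e-10)
        H = (X * w[:, None]).T @ X + np.diag(pen + 1e-12)
        step = np.linalg.solve(H, grad)
        t = 1.0
        for _ in range(50):
            cand = theta - t * step
            cand_obj = objective(cand)
            if cand_obj <= obj:
                theta, obj = cand, cand_obj
                break
            t *= 0.5
        else:  # pragma: no cover - pathological line search failure
            break
    return theta


def entity_scores(rows: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Predicted outcome probabilities for factor rows under ``theta``."""
    rows = np.atleast_2d(np.asarray(rows, dtype=np.float64))
    theta = np.asarray(theta, dtype=np.float64)
    return expit(rows @ theta[:-1] + theta[-1])


def auc(y: np.ndarray, scores: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) area under the ROC curve; ties half-credit."""
    y = np.asarray(y)
    scores = np.asarray(scores, dtype=np.float64)
    if y.shape != scores.shape:
        raise ValueError("labels and scores must align")
    pos = y == 1
    neg = y == 0
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _col_cosines(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    na = np.linalg.norm(A, axis=0)
    nb = np.linalg.norm(B, axis=0)
    sa = np.where(na > 0, na, 1.0)
    sb = np.where(nb > 0, nb, 1.0)
    C = (A / sa).T @ (B / sb)
    C[na <= 0, :] = 0.0
    C[:, nb <= 0] = 0.0
    return C


def average_overlap(model: KruskalModel, modes=(1, 2)) -> float:
    """Mean pairwise cosine similarity of components over the given modes.

    ``sum_{r1 < r2} sum_{n in modes} cos(a_r1^(n), a_r2^(n)) / (R (R - 1))``
    — for the default two modes this is the mean cosine over all component
    pairs and both modes, so with nonnegative factors it lies in [0, 1].
    Requires R >= 2 (no pairs otherwise); zero columns contribute cosine 0.
    """
    R = model.rank
    if R < 2:
        raise ValueError("average overlap needs rank >= 2")
    total = 0.0
    for n in modes:
        C = _col_cosines(model.factors[n], model.factors[n])
        total += float(np.triu(C, k=1).sum())
    return total / (R * (R - 1))


def factor_match_score(true_model: KruskalModel, est_model: KruskalModel) -> float:
    """Permutation/scale-invariant similarity of two Kruskal models in [0, 1].

    Maximizes over component matchings the mean over components of the
    product across modes of column cosine similarities, using the optimal
    assignment. Equals 1 iff the estimate reproduces every component
    direction up to permutation and positive rescaling.
    """
    if true_model.rank != est_model.rank:
        raise ValueError("rank mismatch")
    if true_model.shape != est_model.shape:
        raise ValueError("shape mismatch")
    M = np.ones((true_model.rank, est_model.rank))
    for At, Ae in zip(true_model.factors, est_model.factors):
        M *= _col_cosines(At, Ae)
    rows, cols = linear_sum_assignment(-M)
    return float(M[rows, cols].mean())


def stratified_split(labels: np.ndarray, test_frac: float = 0.2, seed: int = 0):
    """Class-stratified split of labeled entity indices.

    Returns ``(train_idx, test_idx)`` over entities with labels 0/1;
    unlabeled (-1) entities belong to neither side.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train, test = [], []
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        n_test = max(1, int(round(test_frac * idx.size))) if idx.size else 0
        test.append(idx[:n_test])
        train.append(idx[n_test:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


def fold_in_rows(
    X: SparseCountTensor,
    model: KruskalModel,
    entities: np.ndarray,
    *,
    n_iters: int = 50,
) -> np.ndarray:
    """Estimate mode-0 factor rows for ``entities`` with other modes frozen.

    Each row minimizes the Poisson loss of the entity's observed slice via
    multiplicative KL updates (monotone, nonnegativity-preserving):
    ``a_r <- a_r * (sum_e (x_e / m_e) K_er) / D_r`` where ``K`` is the
    Khatri-Rao row of the frozen modes at each observed cell and
    ``D_r = w_r * prod_{n >= 1} sum(A^(n)[:, r])``. Rows are at the same
    (weight-absorbed) scale as the fitted mode-0 factor.
    """
    entities = np.asarray(entities, dtype=np.int64)
    R = model.rank
    D = model.weights.copy()
    for n in range(1, model.ndim):
        D *= model.factors[n].sum(axis=0)
    D = np.maximum(D, EPS_FLOOR)
    out = np.zeros((entities.size, R))
    ent_col = X.indices[:, 0] if X.nnz else np.empty(0, dtype=np.int64)
    for j, i in enumerate(entities):
        sel = np.flatnonzero(ent_col == i)
        if sel.size == 0:
            continue
        idx = X.indices[sel]
        x = X.values[sel].astype(np.float64)
        K = np.ones((sel.size, R))
        for n in range(1, model.ndim):
            K *= model.factors[n][idx[:, n], :]
        K *= model.weights
        a = np.full(R, x.sum() / max(float(D.sum()), EPS_FLOOR))
        for _ in range(n_iters):
            m = np.maximum(K @ a, EPS_FLOOR)
            a = a * (K.T @ (x / m)) / D
        out[j] = a
    return out


def holdout_auc(
    X: SparseCountTensor,
    labels,
    config,
    *,
    test_frac: float = 0.2,
    split_seed: int = 0,
    executor=None,
):
    """Held-out AUC under the fold-in protocol.

    Splits labeled entities 80/20 stratified by class, refits the
    decomposition on the tensor restricted to non-test entities, estimates
    test-entity rows by fold-in, scores them with the trained supervision
    coefficients, and returns ``(auc, fit_result)``.
    """
    from . import engine  # local import: engine depends on this module

    label_arr = as_label_array(labels, X.shape[0])
    train_lab, test_lab = stratified_split(label_arr, test_frac, split_seed)
    test_set = np.zeros(X.shape[0], dtype=bool)
    test_set[test_lab] = True

    keep_entities = np.flatnonzero(~test_set)
    remap = -np.ones(X.shape[0], dtype=np.int64)
    remap[keep_entities] = np.arange(keep_entities.size)
    keep = ~test_set[X.indices[:, 0]] if X.nnz else np.empty(0, dtype=bool)
    idx = X.indices[keep].copy()
    idx[:, 0] = remap[idx[:, 0]]
    X_train = SparseCountTensor(
        (keep_entities.size,) + X.shape[1:], idx, X.values[keep]
    )
    result = engine.fit(X_train, config, labels=label_arr[keep_entities],
                        executor=executor)
    # score held-out entities against the absorbed-scale factors
    from .tensor import absorb_weights

    absorbed = absorb_weights(result.model, config.designated_mode)
    rows = fold_in_rows(X, absorbed, test_lab)
    scores = entity_scores(rows, result.supervision.theta)
    return auc(label_arr[test_lab], scores), result
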