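"""Penalty values, gradients, and projections for constrained CP fitting.

Four families are supported:

* **Angular diversity** — a squared hinge on the pairwise cosine similarity
  of a factor matrix's columns above a threshold ``theta``. Penalizing
  overlap pushes components apart without forcing orthogonality.
* **Simplex / l1-ball** — a hard constraint handled by Euclidean projection
  of factor columns onto ``{w >= 0, sum(w) <= s}`` after each gradient step;
  at s = 1 the columns live in the probability simplex.
* **l2 (ridge)** — penalty ``(beta2/2) * ||a_r||^2`` per column, whose
  gradient is simply ``beta2 * a_r``; combined with the simplex projection
  it acts like an elastic net, driving small entries to zero.
* **Logistic supervision** — the negative log-likelihood of binary labels
  under a logistic model on the rows of the first-mode factor matrix, so
  the decomposition is nudged toward discriminative components.

An l0 hard-thresholding operator (keep the top-k entries of a column) is
also provided; it is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = [
    "RegularizerConfig",
    "angular_value",
    "angular_grad",
    "project_l1_ball",
    "l2_value",
    "l2_grad",
    "hard_threshold",
    "logistic_term",
    "logistic_values",
    "logistic_grad_rows",
]


@dataclass(frozen=True)
class RegularizerConfig:
    """Weights and parameters of the regularizer menu.

    Defaults follow the settings used for the supervised phenotyping
    experiments: angular weight 0.02 with threshold 0.9, no ridge, logistic
    weight 0.06. ``simplex_modes`` lists the modes whose columns are
    projected onto the l1-ball of radius ``simplex_radius`` after each
    update (empty by default). ``hard_threshold_k`` caps the number of
    nonzeros per column when set (off by default).
    """

    beta_angular: float = 0.02
    beta_l2: float = 0.0
    beta_supervision: float = 0.06
    angular_threshold: float = 0.9
    simplex_radius: float = 1.0
    simplex_modes: tuple[int, ...] = ()
    hard_threshold_k: int | None = None

    def __post_init__(self) -> None:
        if min(self.beta_angular, self.beta_l2, self.beta_supervision) < 0:
            raise ValueError("regularizer weights must be nonnegative")
        if not 0.0 <= self.angular_threshold < 1.0:
            raise ValueError("angular_threshold must lie in [0, 1)")
        if self.simplex_radius <= 0:
            raise ValueError("simplex_radius must be positive")
        if self.hard_threshold_k is not None and self.hard_threshold_k < 1:
            raise ValueError("hard_threshold_k must be >= 1 when set")
        object.__setattr__(self, "simplex_modes", tuple(self.simplex_modes))


def _column_cosines(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise column cosine matrix; zero-norm columns get cosine 0."""
    norms = np.linalg.norm(A, axis=0)
    safe = np.where(norms > 0, norms, 1.0)
    U = A / safe
    C = U.T @ U
    zero = norms <= 0
    C[zero, :] = 0.0
    C[:, zero] = 0.0
    return C, norms


def angular_value(A: np.ndarray, threshold: float) -> float:
    """Sum over unordered column pairs of ``max(0, cos(a_p, a_r) - theta)^2``."""
    A = np.asarray(A, dtype=np.float64)
    C, _ = _column_cosines(A)
    H = np.maximum(0.0, C - threshold)
    np.fill_diagonal(H, 0.0)
    return float(np.triu(H**2, k=1).sum())


def angular_grad(A: np.ndarray, threshold: float, r: int | None = None) -> np.ndarray:
    """Exact gradient of :func:`angular_value` with respect to the columns.

    For column r the derivative is
    ``sum_{p != r} 2 h_pr [ u_p - cos_pr u_r ] / ||a_r||`` with unit columns
    ``u`` and hinge ``h_pr = max(0, cos_pr - theta)``. Zero-norm columns get
    a zero gradient. Returns the full I x R gradient matrix when ``r`` is
    None, else the length-I column-r gradient.
    """
    A = np.asarray(A, dtype=np.float64)
    C, norms = _column_cosines(A)
    H = np.maximum(0.0, C - threshold)
    np.fill_diagonal(H, 0.0)
    safe = np.where(norms > 0, norms, 1.0)
    U = A / safe
    # column r of the gradient: (2/||a_r||) * (U @ H[:, r] - (H[:, r] . C[:, r]) u_r)
    G = 2.0 * (U @ H - U * (H * C).sum(axis=0)) / safe
    G[:, norms <= 0] = 0.0
    if r is None:
        return G
    return G[:, r]


def project_l1_ball(v: np.ndarray, s: float) -> np.ndarray:
    """Euclidean projection of ``v`` onto ``{w : w >= 0, sum(w) <= s}``.

    If clipping negatives already satisfies the l1 bound the clipped vector
    is returned unchanged (so existing zeros are preserved); otherwise the
    usual sorted soft-threshold solution with ``sum(w) = s`` is used.
    """
    if s <= 0:
        raise ValueError("radius s must be positive")
    v = np.asarray(v, dtype=np.float64)
    w = np.maximum(v, 0.0)
    total = w.sum()
    if total <= s:
        return w
    # water-filling: find tau with sum(max(v - tau, 0)) = s over positive part
    u = np.sort(w)[::-1]
    css = np.cumsum(u)
    j = np.arange(1, u.size + 1)
    rho = np.max(np.flatnonzero(u - (css - s) / j > 0)) + 1
    tau = (css[rho - 1] - s) / rho
    return np.maximum(w - tau, 0.0)


def l2_value(a: np.ndarray, beta2: float) -> float:
    """Ridge penalty ``(beta2 / 2) * ||a||^2``."""
    a = np.asarray(a, dtype=np.float64)
    return 0.5 * beta2 * float((a * a).sum())


def l2_grad(a: np.ndarray, beta2: float) -> np.ndarray:
    """Gradient ``beta2 * a`` of the ridge penalty."""
    return beta2 * np.asarray(a, dtype=np.float64)


def hard_threshold(v: np.ndarray, k0: int) -> np.ndarray:
    """Keep the k0 largest-magnitude entries of ``v``, zero the rest.

    Ties are broken toward the lower index (stable sort order).
    """
    if k0 < 1:
        raise ValueError("k0 must be >= 1")
    v = np.asarray(v, dtype=np.float64)
    if k0 >= v.size:
        return v.copy()
    order = np.argsort(-np.abs(v), kind="stable")
    out = np.zeros_like(v)
    keep = order[:k0]
    out[keep] = v[keep]
    return out


def _margins(a_rows: np.ndarray, y_signed: np.ndarray, theta: np.ndarray) -> np.ndarray:
    a_rows = np.atleast_2d(np.asarray(a_rows, dtype=np.float64))
    R = theta.shape[0] - 1
    z = a_rows @ theta[:R] + theta[R]
    return y_signed * z


def logistic_term(a_row, y_i: int, theta, beta3: float):
    """Supervision loss and factor-row gradient for one labeled entity.

    ``value = -beta3 * log sigma(y_i * (theta . [a_row; 1]))`` with the
    label ``y_i`` in {-1, +1}; the gradient is taken with respect to the
    factor row only (theta held fixed). Uses log1p/exp guards so saturated
    margins never overflow.
    """
    theta = np.asarray(theta, dtype=np.float64)
    y = float(y_i)
    if y not in (-1.0, 1.0):
        raise ValueError("label must be -1 or +1")
    m = _margins(a_row, np.array([y]), theta)[0]
    value = beta3 * float(np.logaddexp(0.0, -m))  # -log sigma(m)
    grad = -beta3 * y * float(expit(-m)) * theta[:-1]
    return value, grad


def logistic_values(a_rows: np.ndarray, y01: np.ndarray, theta: np.ndarray, beta3: float) -> float:
    """Total supervision penalty over labeled rows (labels given as {0,1})."""
    y_signed = 2.0 * np.asarray(y01, dtype=np.float64) - 1.0
    m = _margins(a_rows, y_signed, np.asarray(theta, dtype=np.float64))
    return beta3 * float(np.logaddexp(0.0, -m).sum())


def logistic_grad_rows(a_rows: np.ndarray, y01: np.ndarray, theta: np.ndarray, beta3: float) -> np.ndarray:
    """Per-row gradients of :func:`logistic_values` w.r.t. the factor rows."""
    theta = np.asarray(theta, dtype=np.float64)
    y_signed = 2.0 * np.asarray(y01, dtype=np.float64) - 1.0
    m = _margins(a_rows, y_signed, theta)
    coef = -beta3 * y_signed * expit(-m)
    return np.outer(coef, theta[:-1])
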