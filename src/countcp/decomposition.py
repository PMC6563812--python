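"""Scikit-learn-style estimator facade over the fitting engine.

``PoissonCP`` is a decomposition estimator: ``fit`` learns the factor
matrices from a sparse count tensor (optionally with binary labels on the
first mode), ``transform`` folds new first-mode entities into the learned
component space, and ``predict_proba`` scores them with the trained
supervision coefficients. Hyperparameters follow the sklearn constructor
convention and fitted state carries a trailing underscore, so the
estimator composes with sklearn model-selection utilities.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from . import engine
from .evaluate import entity_scores, fold_in_rows
from .optimize import FitConfig
from .regularizers import RegularizerConfig
from .tensor import KruskalModel, SparseCountTensor, absorb_weights, poisson_loss

__all__ = ["PoissonCP"]


def _as_tensor(X) -> SparseCountTensor:
    if isinstance(X, SparseCountTensor):
        return X
    if isinstance(X, tuple) and len(X) == 3:
        indices, values, shape = X
        return SparseCountTensor.from_entries(indices, values, shape=shape)
    raise TypeError(
        "X must be a SparseCountTensor or an (indices, values, shape) tuple"
    )


class PoissonCP(BaseEstimator):
    """Constrained nonnegative CP decomposition of a sparse count tensor.

    Minimizes the Poisson (generalized KL) loss plus an angular diversity
    penalty, an optional ridge, optional simplex projection, and — when
    labels are supplied to :meth:`fit` — a logistic supervision term, using
    block-partitioned stochastic gradient descent with Adam.

    Parameters
    ----------
    rank : int
        Number of rank-one components R.
    beta_angular, beta_l2, beta_supervision : float
        Regularizer weights (defaults 0.02, 0, 0.06).
    angular_threshold : float
        Cosine threshold of the diversity hinge (default 0.9).
    simplex_radius : float, simplex_modes : tuple of int
        l1-ball projection applied to the listed modes (none by default).
    hard_threshold_k : int or None
        Optional per-column cap on nonzeros (off by default).
    learning_rate, batch_size, inner_iters, max_epochs, n_workers, tol
        SGD schedule; with ``step_scaling="mode_mean"`` the learning rate
        is a relative per-iteration step.
    designated_mode : int
        Mode that absorbs the component weights during optimization.
    random_state : int
        Seed for initialization and minibatch sampling.

    Attributes
    ----------
    factors_ : list of ndarray
        Fitted factor matrices (non-designated columns l1-normalized).
    weights_ : ndarray
        Component weights.
    theta_ : ndarray or None
        Supervision coefficients [weights; intercept] when labels were given.
    history_ : pandas.DataFrame
        Per-epoch objective trace.
    n_iter_ : int
        Number of completed epochs.
    """

    def __init__(
        self,
        rank: int = 3,
        *,
        beta_angular: float = 0.02,
        beta_l2: float = 0.0,
        beta_supervision: float = 0.06,
        angular_threshold: float = 0.9,
        simplex_radius: float = 1.0,
        simplex_modes: tuple = (),
        hard_threshold_k=None,
        learning_rate: float = 1e-4,
        batch_size: int = 200,
        inner_iters: int = 10,
        max_epochs: int = 100,
        n_workers: int = 1,
        tol: float = 1e-4,
        designated_mode: int = 0,
        step_scaling: str = "mode_mean",
        shuffle_strata: bool = False,
        random_state: int = 0,
    ):
        self.rank = rank
        self.beta_angular = beta_angular
        self.beta_l2 = beta_l2
        self.beta_supervision = beta_supervision
        self.angular_threshold = angular_threshold
        self.simplex_radius = simplex_radius
        self.simplex_modes = simplex_modes
        self.hard_threshold_k = hard_threshold_k
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.inner_iters = inner_iters
        self.max_epochs = max_epochs
        self.n_workers = n_workers
        self.tol = tol
        self.designated_mode = designated_mode
        self.step_scaling = step_scaling
        self.shuffle_strata = shuffle_strata
        self.random_state = random_state

    def _config(self) -> FitConfig:
        reg = RegularizerConfig(
            beta_angular=self.beta_angular,
            beta_l2=self.beta_l2,
            beta_supervision=self.beta_supervision,
            angular_threshold=self.angular_threshold,
            simplex_radius=self.simplex_radius,
            simplex_modes=tuple(self.simplex_modes),
            hard_threshold_k=self.hard_threshold_k,
        )
        return FitConfig(
            rank=self.rank,
            regularizers=reg,
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            inner_iters=self.inner_iters,
            max_epochs=self.max_epochs,
            n_workers=self.n_workers,
            tol=self.tol,
            seed=self.random_state,
            designated_mode=self.designated_mode,
            step_scaling=self.step_scaling,
            shuffle_strata=self.shuffle_strata,
        )

    def fit(self, X, y=None):
        """Fit the decomposition; ``y`` are optional mode-0 binary labels."""
        X = _as_tensor(X)
        result = engine.fit(X, self._config(), labels=y)
        self.model_ = result.model
        self.factors_ = result.model.factors
        self.weights_ = result.model.weights
        self.theta_ = None if result.supervision is None else result.supervision.theta
        self.history_ = result.history.as_dataframe()
        self.n_iter_ = len(result.history)
        self.converged_ = result.converged
        self.shape_ = result.model.shape
        self.loss_ = poisson_loss(X, result.model) if X.shape == result.model.shape else None
        return self

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise AttributeError("this PoissonCP instance is not fitted yet")

    def transform(self, X, entities=None) -> np.ndarray:
        """Fold mode-0 entities of ``X`` into the learned component space.

        ``X`` must share the non-first-mode shape with the training tensor;
        ``entities`` defaults to all of ``X``'s mode-0 indices. Returns the
        estimated (weight-absorbed) factor rows, one per entity.
        """
        self._check_fitted()
        X = _as_tensor(X)
        if X.shape[1:] != self.shape_[1:]:
            raise ValueError(
                f"non-first-mode shape {X.shape[1:]} differs from fitted {self.shape_[1:]}"
            )
        if entities is None:
            entities = np.arange(X.shape[0])
        absorbed = absorb_weights(self.model_, self.designated_mode)
        return fold_in_rows(X, absorbed, np.asarray(entities, dtype=np.int64))

    def predict_proba(self, X, entities=None) -> np.ndarray:
        """Outcome probabilities for mode-0 entities via fold-in + logistic."""
        self._check_fitted()
        if self.theta_ is None:
            raise AttributeError("no supervision model: fit was called without labels")
        rows = self.transform(X, entities=entities)
        p = entity_scores(rows, self.theta_)
        return np.column_stack([1.0 - p, p])

    def score(self, X, y=None) -> float:
        """Negative Poisson loss of ``X`` under the fitted model."""
        self._check_fitted()
        X = _as_tensor(X)
        return -poisson_loss(X, self.model_)

    def reconstruct(self, indices) -> np.ndarray:
        """Model means at the given (B, N) cell coordinates."""
        self._check_fitted()
        from .tensor import reconstruct_entries

        return reconstruct_entries(self.model_, np.asarray(indices, dtype=np.int64))
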