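"""Closed-form ridge estimation of the motion-to-performance relevance map.

The relevance map ``W~`` minimizes

    E(W~) = 1/2 sum_k (d_k - sum_{i,j} W~_{i,j} x_{i,j,k})^2
            + sigma^2/2 sum_{i,j} W~_{i,j}^2

over the per-cell standardized motion ``x`` and standardized performance
``d``.  The unique minimizer is ``w = (x^T x + sigma^2 I)^{-1} x^T d``;
equivalently (and cheaper when the feature count IJ exceeds the trial
count K, the usual regime here: IJ = 240 vs K ~ 150) the dual form
``w = x^T (x x^T + sigma^2 I)^{-1} d``.

The regularizer sigma^2 is equivalent to assuming i.i.d. Gaussian
observation noise of variance sigma^2/K on each motion feature and
minimizing the noise-averaged fitting error, which is why ridge rather
than ordinary least squares is the right estimator for noisy, highly
collinear joint-angle trajectories.

Prediction quality is reported as a *normalized* prediction error,
``sum_k (d_k - y_k)^2 / sum_k d_k^2``: 1 means no predictive
relationship between motion and performance, 0 a perfect one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .datamodel import MotionDataset, PerformanceSeries
from .standardization import (
    JointStandardization,
    RidgeStandardization,
    map_coefficients,
    standardize_for_ridge,
    standardize_per_joint,
)

__all__ = [
    "DEFAULT_SIGMA2_GRID",
    "RidgeModel",
    "trial_matrix",
    "fit_ridge",
    "predict",
    "prediction_error",
    "kfold_indices",
    "cross_validate",
    "fit_relevance_map",
]

#: log-spaced default regularization grid searched by cross-validation
DEFAULT_SIGMA2_GRID = tuple(np.logspace(-3.0, 3.0, 13))


def trial_matrix(x: np.ndarray) -> np.ndarray:
    """Vectorize an (I, J, K) array into the (K, I*J) design matrix.

    Row k is ``vec(X_{:,:,k})`` in joint-major (row-major) order; every
    vectorized quantity in the package uses this same convention.
    """
    I, J, K = x.shape
    return x.reshape(I * J, K).T


def fit_ridge(x: np.ndarray, d: np.ndarray, sigma2: float) -> np.ndarray:
    """Solve the ridge problem in closed form.

    Parameters
    ----------
    x : (K, P) design matrix (trials by vectorized features).
    d : (K,) standardized performance.
    sigma2 : regularization parameter, >= 0.  At 0 the design must have
        full column rank (otherwise the minimizer is not unique and a
        hard error advises sigma2 > 0).

    Returns
    -------
    (P,) coefficient vector.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    d = np.asarray(d, dtype=float).ravel()
    K, P = x.shape
    if d.size != K:
        raise ValueError(f"design has {K} trials but d has {d.size}")
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    if sigma2 == 0.0:
        if np.linalg.matrix_rank(x) < P:
            raise ValueError(
                "design is rank-deficient at sigma2 = 0; the minimizer is not "
                "unique -- use sigma2 > 0"
            )
        G = x.T @ x
        return scipy.linalg.solve(G, x.T @ d, assume_a="pos")
    if P <= K:  # primal: P x P system
        G = x.T @ x
        G[np.diag_indices_from(G)] += sigma2
        return scipy.linalg.solve(G, x.T @ d, assume_a="pos")
    # dual: K x K system, exact for sigma2 > 0
    G = x @ x.T
    G[np.diag_indices_from(G)] += sigma2
    return x.T @ scipy.linalg.solve(G, d, assume_a="pos")


def predict(w: np.ndarray, x_new: np.ndarray) -> np.ndarray:
    """Predicted standardized performance ``y_k = sum_p x_{k,p} w_p``.

    ``w`` may be the flat coefficient vector or the (I, J) map; ``x_new``
    correspondingly a (K, P) matrix or an (I, J, K) standardized array.
    """
    w = np.asarray(w, dtype=float)
    x_new = np.asarray(x_new, dtype=float)
    if x_new.ndim == 3:
        x_new = trial_matrix(x_new)
    if w.ndim == 2:
        w = w.ravel()
    if x_new.shape[1] != w.size:
        raise ValueError(f"{x_new.shape[1]} features in x_new vs {w.size} coefficients")
    return x_new @ w


def prediction_error(y: np.ndarray, d: np.ndarray) -> float:
    """Normalized prediction error ``sum (d - y)^2 / sum d^2``.

    Equals the mean squared error when ``d`` is standardized to unit
    second moment; 1 corresponds to predicting the mean (no
    relationship), 0 to perfect prediction.
    """
    y = np.asarray(y, dtype=float).ravel()
    d = np.asarray(d, dtype=float).ravel()
    if y.size != d.size:
        raise ValueError(f"length mismatch: y has {y.size}, d has {d.size}")
    denom = float(np.sum(d * d))
    if denom == 0.0:
        raise ValueError("cannot normalize: sum of squared performance is zero")
    return float(np.sum((d - y) ** 2) / denom)


def kfold_indices(n: int, folds: int, seed: int) -> list[np.ndarray]:
    """Shuffled trial-level k-fold partition (list of held-out index arrays)."""
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if n < folds:
        raise ValueError(f"cannot split {n} trials into {folds} folds")
    perm = np.random.default_rng(seed).permutation(n)
    return [np.sort(part) for part in np.array_split(perm, folds)]


def cross_validate(
    dataset: MotionDataset,
    perf: PerformanceSeries,
    sigma2_grid=DEFAULT_SIGMA2_GRID,
    folds: int = 10,
    seed: int = 0,
) -> tuple[float, float, np.ndarray]:
    """Grid-search sigma^2 by shuffled trial-level k-fold cross-validation.

    Standardization statistics are refit on every training fold and the
    held-out trials are transformed with those training moments.  Returns
    ``(best_sigma2, cv_error, grid_errors)`` where ``cv_error`` is the
    mean across folds of the normalized prediction error at the best grid
    value and ``grid_errors`` the same mean for every grid value.
    """
    grid = np.asarray(list(sigma2_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("sigma2 grid is empty")
    splits = kfold_indices(dataset.n_trials, folds, seed)
    all_idx = np.arange(dataset.n_trials)
    errors = np.zeros((len(splits), grid.size))
    for f, test_idx in enumerate(splits):
        train_idx = np.setdiff1d(all_idx, test_idx)
        train_ds = dataset.select_trials(train_idx)
        std = standardize_for_ridge(train_ds, perf.select_trials(train_idx))
        x_tr = trial_matrix(std.x)
        test_ds = dataset.select_trials(test_idx)
        x_te = trial_matrix(std.transform(test_ds))
        d_te = std.transform_performance(perf.d_raw[test_idx])
        for g, s2 in enumerate(grid):
            w = fit_ridge(x_tr, std.d, s2)
            errors[f, g] = prediction_error(x_te @ w, d_te)
    grid_errors = errors.mean(axis=0)
    best = int(np.argmin(grid_errors))
    return float(grid[best]), float(grid_errors[best]), grid_errors


@dataclass
class RidgeModel:
    """A fitted relevance map in both coefficient spaces.

    ``W_tilde`` lives in the per-cell regression space, ``W``/``const``
    in the per-joint module-comparison space (via
    :func:`~taskmodules.standardization.map_coefficients`), and
    ``cv_error`` is the cross-validated normalized prediction error at
    the selected ``sigma2``.
    """

    W_tilde: np.ndarray
    sigma2: float
    W: np.ndarray
    const: float
    cv_error: float
    cv_folds: int
    seed: int
    ridge_std: RidgeStandardization = field(repr=False)
    joint_std: JointStandardization = field(repr=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.W_tilde.shape

    def predict_dataset(self, dataset: MotionDataset) -> np.ndarray:
        """Standardized predicted performance for (new) raw motion data."""
        return predict(self.W_tilde, self.ridge_std.transform(dataset))


def fit_relevance_map(
    dataset: MotionDataset,
    perf: PerformanceSeries,
    sigma2: float | None = None,
    sigma2_grid=DEFAULT_SIGMA2_GRID,
    folds: int = 10,
    seed: int = 0,
) -> RidgeModel:
    """Fit the relevance map on the full dataset.

    When ``sigma2`` is None it is selected by :func:`cross_validate` on
    ``sigma2_grid``; otherwise cross-validation only scores the given
    value.  The returned model carries the map in both coefficient
    spaces plus the stored standardizations.
    """
    if sigma2 is None:
        best_sigma2, cv_error, _ = cross_validate(
            dataset, perf, sigma2_grid, folds=folds, seed=seed
        )
    else:
        best_sigma2, cv_error, _ = cross_validate(
            dataset, perf, [sigma2], folds=folds, seed=seed
        )
    ridge_std = standardize_for_ridge(dataset, perf)
    joint_std = standardize_per_joint(dataset)
    w = fit_ridge(trial_matrix(ridge_std.x), ridge_std.d, best_sigma2)
    W_tilde = w.reshape(dataset.n_joints, dataset.n_frames)
    W, const = map_coefficients(W_tilde, ridge_std, joint_std)
    return RidgeModel(
        W_tilde=W_tilde,
        sigma2=best_sigma2,
        W=W,
        const=const,
        cv_error=cv_error,
        cv_folds=folds,
        seed=seed,
        ridge_std=ridge_std,
        joint_std=joint_std,
    )
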