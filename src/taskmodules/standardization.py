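"""Standardization schemes and the map between the two coefficient spaces.

Two different standardizations are needed.  For the ridge regression,
each ``(joint, frame)`` cell is standardized across trials so that every
motion feature competes on equal footing::

    x_{i,j,k} = (X~_{i,j,k} - m_{i,j}) / s_{i,j}

with population (divide-by-K) moments, and the performance series is
standardized the same way.  For module extraction and comparison, each
joint is standardized across all frames and trials::

    X_{i,j,k} = (X~_{i,j,k} - m_i) / s_i

so that within-trial temporal shape is preserved.  A relevance map
``W~`` estimated in the regression space converts to the module space
via ``W_{i,j} = (s_i / s_{i,j}) W~_{i,j}`` plus a constant offset, and
the two prediction expressions agree on every trial:

    sum_{i,j} x_{i,j,k} W~_{i,j}  ==  sum_{i,j} X_{i,j,k} W_{i,j} + const

Standardization statistics are computed on the fitting set and stored,
so held-out trials can be transformed with training-set moments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import MotionDataset, PerformanceSeries

__all__ = [
    "RidgeStandardization",
    "JointStandardization",
    "standardize_for_ridge",
    "standardize_per_joint",
    "map_coefficients",
]

# relative floor below which a standard deviation is treated as zero
_ZERO_SD_RTOL = 1e-12


@dataclass
class RidgeStandardization:
    """Per-(joint, frame) standardization used for the ridge regression.

    Attributes
    ----------
    x : (I, J, K) standardized motion; every cell has zero mean and unit
        second moment across trials (population moments).
    m, s : (I, J) cell means and standard deviations.
    d : (K,) standardized performance; d_mean, d_sd its raw moments.
    fingerprint : hash of the dataset the statistics were fitted on.
    """

    x: np.ndarray
    m: np.ndarray
    s: np.ndarray
    d: np.ndarray
    d_mean: float
    d_sd: float
    fingerprint: str

    def transform(self, dataset: MotionDataset) -> np.ndarray:
        """Standardize new motion data with the stored (training) moments."""
        if dataset.angles.shape[:2] != self.m.shape:
            raise ValueError(
                f"dataset (I, J) = {dataset.angles.shape[:2]} does not match fitted {self.m.shape}"
            )
        return (dataset.angles - self.m[:, :, None]) / self.s[:, :, None]

    def transform_performance(self, d_raw) -> np.ndarray:
        return (np.asarray(d_raw, dtype=float) - self.d_mean) / self.d_sd


@dataclass
class JointStandardization:
    """Per-joint standardization used for module extraction (one mean and
    sd per joint, taken over all frames and trials)."""

    X: np.ndarray
    m_i: np.ndarray
    s_i: np.ndarray
    fingerprint: str

    def transform(self, dataset: MotionDataset) -> np.ndarray:
        if dataset.n_joints != self.m_i.size:
            raise ValueError("joint count does not match fitted statistics")
        return (dataset.angles - self.m_i[:, None, None]) / self.s_i[:, None, None]


def standardize_for_ridge(
    dataset: MotionDataset, perf: PerformanceSeries
) -> RidgeStandardization:
    """Standardize every (joint, frame) cell and the performance across trials.

    Uses population (1/K) moments.  A cell or performance series with
    (numerically) zero variance across trials is a hard error: the
    regression-space map would be undefined there and silently dropping
    features would desynchronize the map's indices.
    """
    if perf.n_trials != dataset.n_trials:
        raise ValueError("performance series length does not match dataset trials")
    A = dataset.angles
    m = A.mean(axis=2)
    s = A.std(axis=2)  # ddof=0: population moments
    dead = s <= _ZERO_SD_RTOL * (1.0 + np.abs(m))
    if dead.any():
        i, j = np.argwhere(dead)[0]
        raise ValueError(
            f"zero variance across trials at joint {i} ({dataset.joint_labels[i]}), frame {j}"
        )
    d_mean = float(perf.d_raw.mean())
    d_sd = float(perf.d_raw.std())
    if d_sd <= _ZERO_SD_RTOL * (1.0 + abs(d_mean)):
        raise ValueError("performance has zero variance across trials")
    return RidgeStandardization(
        x=(A - m[:, :, None]) / s[:, :, None],
        m=m,
        s=s,
        d=(perf.d_raw - d_mean) / d_sd,
        d_mean=d_mean,
        d_sd=d_sd,
        fingerprint=dataset.fingerprint(),
    )


def standardize_per_joint(dataset: MotionDataset) -> JointStandardization:
    """Standardize each joint over all (frame, trial) samples (population moments)."""
    A = dataset.angles
    m_i = A.mean(axis=(1, 2))
    s_i = A.std(axis=(1, 2))
    dead = s_i <= _ZERO_SD_RTOL * (1.0 + np.abs(m_i))
    if dead.any():
        i = int(np.argwhere(dead)[0][0])
        raise ValueError(
            f"zero variance over (frame, trial) for joint {i} ({dataset.joint_labels[i]})"
        )
    return JointStandardization(
        X=(A - m_i[:, None, None]) / s_i[:, None, None],
        m_i=m_i,
        s_i=s_i,
        fingerprint=dataset.fingerprint(),
    )


def map_coefficients(
    W_tilde: np.ndarray,
    ridge_std: RidgeStandardization,
    joint_std: JointStandardization,
) -> tuple[np.ndarray, float]:
    """Convert a regression-space map to the module-comparison space.

    Returns ``(W, const)`` with ``W_{i,j} = (s_i / s_{i,j}) W~_{i,j}`` and
    ``const = sum_{i,j} W~_{i,j} (m_i - m_{i,j}) / s_{i,j}``, so that for
    every trial the regression-space and module-space predictions agree.
    Both standardizations must have been fitted on the same dataset.
    """
    W_tilde = np.asarray(W_tilde, dtype=float)
    if W_tilde.shape != ridge_std.m.shape:
        raise ValueError(
            f"W~ shape {W_tilde.shape} does not match standardization {ridge_std.m.shape}"
        )
    if ridge_std.fingerprint != joint_std.fingerprint:
        raise ValueError(
            "ridge and per-joint standardizations were fitted on different datasets"
        )
    W = (joint_std.s_i[:, None] / ridge_std.s) * W_tilde
    const = float(
        np.sum(W_tilde * (joint_std.m_i[:, None] - ridge_std.m) / ridge_std.s)
    )
    return W, const
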