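"""Conventional motion-relevant modules via reshaped SVDs.

Motion-relevant modules reconstruct the motion data itself (they are the
PCA/SVD synergies of the kinematics, blind to the task).  Trial-invariant
spatial modules come from the SVD of the I x (J*K) unfolding; trial-
invariant temporal modules from the J x (I*K) unfolding.  Each trial's
motion then projects onto the shared spatial modules to give per-trial
temporal coefficients

    c_{r,k}^T = b_r^T X_{:,:,k} / a_r ,

so that ``sum_r a_r b_r c_{r,k}^T`` reproduces the projection of trial k
onto the retained spatial subspace exactly.  The per-trial coefficients
of distinct modules are mutually orthogonal only when the data are an
exact planted module mixture; with noise the orthogonality is
approximate.

Two standardizations are supported before unfolding: ``"per_joint"``
(each joint centred/scaled over all frames and trials; the default) and
``"columnwise"`` (each column of the unfolded matrix centred/scaled
across its rows), plus ``"none"`` for already-standardized input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import MotionDataset
from .standardization import standardize_per_joint

__all__ = [
    "MotionModules",
    "spatial_modules",
    "temporal_modules",
    "per_trial_temporal_coefficients",
    "motion_variance_explained",
    "extract_motion_modules",
]

_ZERO_SD_RTOL = 1e-12


def _as_array(data) -> np.ndarray:
    if isinstance(data, MotionDataset):
        return data.angles
    arr = np.asarray(data, dtype=float)
    if arr.ndim != 3:
        raise ValueError(f"motion data must be (I, J, K), got shape {arr.shape}")
    return arr


def _standardized(data, std: str) -> np.ndarray:
    if std == "none":
        return _as_array(data)
    if std == "per_joint":
        ds = data if isinstance(data, MotionDataset) else MotionDataset(_as_array(data))
        return standardize_per_joint(ds).X
    if std == "columnwise":
        return _as_array(data)  # standardization happens on the unfolded matrix
    raise ValueError(f"unknown standardization {std!r}")


def _columnwise(mat: np.ndarray) -> np.ndarray:
    m = mat.mean(axis=0)
    s = mat.std(axis=0)
    dead = s <= _ZERO_SD_RTOL * (1.0 + np.abs(m))
    if dead.any():
        raise ValueError(
            f"column {int(np.argwhere(dead)[0][0])} of the unfolded matrix has zero variance"
        )
    return (mat - m) / s


def _unfold_svd(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if not np.any(mat):
        raise ValueError("motion data are identically zero")
    U, a, _ = np.linalg.svd(mat, full_matrices=False)
    for r in range(U.shape[1]):  # largest-magnitude element positive
        peak = np.argmax(np.abs(U[:, r]))
        if U[peak, r] < 0:
            U[:, r] = -U[:, r]
    return U, a


def spatial_modules(data, std: str = "per_joint") -> tuple[np.ndarray, np.ndarray]:
    """Trial-invariant spatial modules from the I x (J*K) unfolding.

    Returns ``(B, a)``: columns of B are the orthonormal spatial modules
    (the principal axes of the unfolded data), ``a`` the singular values.
    """
    X = _standardized(data, std)
    I, J, K = X.shape
    mat = X.reshape(I, J * K)
    if std == "columnwise":
        mat = _columnwise(mat)
    return _unfold_svd(mat)


def temporal_modules(data, std: str = "per_joint") -> tuple[np.ndarray, np.ndarray]:
    """Trial-invariant temporal modules from the J x (I*K) unfolding."""
    X = _standardized(data, std)
    I, J, K = X.shape
    mat = X.transpose(1, 0, 2).reshape(J, I * K)
    if std == "columnwise":
        mat = _columnwise(mat)
    return _unfold_svd(mat)


def per_trial_temporal_coefficients(
    B: np.ndarray, a: np.ndarray, X: np.ndarray, rank: int | None = None
) -> np.ndarray:
    """Per-trial temporal coefficients ``c_{r,k}^T = b_r^T X_{:,:,k} / a_r``.

    ``X`` must be the same (standardized) array the spatial modules were
    extracted from.  Returns an (R, K, J) array.  A retained module with
    zero singular value is an error (its coefficients are undefined).
    """
    X = np.asarray(X, dtype=float)
    B = np.asarray(B, dtype=float)
    a = np.asarray(a, dtype=float)
    R = B.shape[1] if rank is None else rank
    if not 1 <= R <= B.shape[1]:
        raise ValueError(f"rank must be in 1..{B.shape[1]}")
    if np.any(a[:R] == 0):
        raise ValueError("retained module has zero singular value")
    # (R, K, J): project each trial onto each spatial module
    C = np.einsum("ir,ijk->rkj", B[:, :R], X) / a[:R, None, None]
    return C


def motion_variance_explained(a: np.ndarray) -> np.ndarray:
    """Cumulative fraction ``sum_{r<=r-hat} a_r^2 / sum_r a_r^2``."""
    a = np.asarray(a, dtype=float)
    power = a * a
    total = float(power.sum())
    if total == 0.0:
        raise ValueError("all singular values are zero")
    return np.cumsum(power) / total


@dataclass
class MotionModules:
    """Bundle of the conventional module extraction for one dataset."""

    B: np.ndarray          # (I, I) spatial modules as columns
    a_spatial: np.ndarray  # singular values of the spatial unfolding
    Cbar: np.ndarray       # (J, J) trial-invariant temporal modules as columns
    a_temporal: np.ndarray
    C: np.ndarray          # (R, K, J) per-trial temporal coefficients
    std: str

    @property
    def rank(self) -> int:
        return self.C.shape[0]


def extract_motion_modules(
    data, std: str = "per_joint", rank: int | None = None
) -> MotionModules:
    """Run the full conventional extraction (spatial, temporal, coefficients)."""
    X = _standardized(data, std)
    B, a_s = spatial_modules(X, std="columnwise" if std == "columnwise" else "none")
    Cbar, a_t = temporal_modules(X, std="columnwise" if std == "columnwise" else "none")
    R = B.shape[1] if rank is None else rank
    keep = min(R, int(np.sum(a_s > 0)))
    C = per_trial_temporal_coefficients(B, a_s, X, rank=keep)
    return MotionModules(B=B, a_spatial=a_s, Cbar=Cbar, a_temporal=a_t, C=C, std=std)
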