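"""Task-relevant spatiotemporal modules: SVD of the relevance map.

Decomposing the I x J relevance map as ``W = sum_r lambda_r s_r t_r^T``
yields task-relevant *spatial* modules ``s_r`` (one weight per joint)
and *temporal* modules ``t_r`` (one weight per frame), both orthonormal
families, ranked by singular value.  In contrast to conventional modules
(which reconstruct the motion itself), these modules reconstruct the
motion-to-performance map, i.e. they carry the spatial and temporal
structure of *task relevance*.

Each module contributes a fragment of the predicted performance on
trial k,

    yhat_{k,r} = lambda_r s_r^T X_{:,:,k} t_r ,

with ``sum_r yhat_{k,r} + const = y_k`` exactly, where X is the
per-joint standardized motion.  Two contribution curves summarize the
decomposition: the cumulative fraction of *predicted-performance*
variance explained by the first modules, and the cumulative fraction of
*motion* variance captured when each module's map is treated as a
direction in the vectorized motion space (lambda-hat_r = w_r X X^T w_r^T
with w_r = vec(lambda_r s_r t_r^T)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TaskModules",
    "ModuleFragments",
    "decompose_relevance",
    "module_fragments",
    "performance_variance_explained",
    "motion_variance_explained_by_task_modules",
]


def _fix_signs(S: np.ndarray, T: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # Deterministic sign convention: the largest-magnitude element of each
    # spatial module is positive; the paired temporal module flips jointly.
    for r in range(S.shape[1]):
        peak = np.argmax(np.abs(S[:, r]))
        if S[peak, r] < 0:
            S[:, r] = -S[:, r]
            T[:, r] = -T[:, r]
    return S, T


@dataclass
class TaskModules:
    """Singular triples of the relevance map.

    ``lam`` are the singular values (non-increasing), ``S`` is I x R with
    spatial modules as columns, ``T`` is J x R with temporal modules as
    columns.
    """

    lam: np.ndarray
    S: np.ndarray
    T: np.ndarray

    @property
    def rank(self) -> int:
        return self.lam.size

    def reconstruct(self) -> np.ndarray:
        """``sum_r lambda_r s_r t_r^T`` (equals W when no truncation)."""
        return (self.S * self.lam) @ self.T.T

    def vectorized_maps(self) -> np.ndarray:
        """Rows ``w_r = vec(lambda_r s_r t_r^T)`` in joint-major order, (R, I*J)."""
        R = self.rank
        I, J = self.S.shape[0], self.T.shape[0]
        out = np.empty((R, I * J))
        for r in range(R):
            out[r] = (self.lam[r] * np.outer(self.S[:, r], self.T[:, r])).ravel()
        return out


@dataclass
class ModuleFragments:
    """Per-trial, per-module fragments of predicted performance.

    ``yhat[k, r]`` is module r's contribution on trial k; the fragments
    plus ``const`` sum to the full predicted performance.
    """

    yhat: np.ndarray
    const: float

    @property
    def n_trials(self) -> int:
        return self.yhat.shape[0]

    @property
    def n_modules(self) -> int:
        return self.yhat.shape[1]

    def total(self) -> np.ndarray:
        return self.yhat.sum(axis=1) + self.const


def decompose_relevance(W: np.ndarray, rank: int | None = None) -> TaskModules:
    """Thin SVD of the relevance map with a deterministic sign convention.

    ``rank`` truncates to the leading modules; default keeps all
    min(I, J) triples.
    """
    W = np.asarray(W, dtype=float)
    if W.ndim != 2:
        raise ValueError(f"W must be a 2-D (I, J) map, got shape {W.shape}")
    if not np.all(np.isfinite(W)):
        raise ValueError("W contains non-finite values")
    U, lam, Vt = np.linalg.svd(W, full_matrices=False)
    if rank is not None:
        if not 1 <= rank <= lam.size:
            raise ValueError(f"rank must be in 1..{lam.size}")
        U, lam, Vt = U[:, :rank], lam[:rank], Vt[:rank]
    S, T = _fix_signs(U, Vt.T)
    return TaskModules(lam=lam, S=S, T=T)


def module_fragments(
    modules: TaskModules, X: np.ndarray, const: float = 0.0
) -> ModuleFragments:
    """Fragments ``yhat_{k,r} = lambda_r s_r^T X_{:,:,k} t_r``.

    ``X`` is the per-joint standardized motion array (I, J, K); ``const``
    is the offset from the coefficient-space mapping so that
    ``sum_r yhat_{k,r} + const`` equals the predicted performance.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 3 or X.shape[0] != modules.S.shape[0] or X.shape[1] != modules.T.shape[0]:
        raise ValueError(
            f"X shape {X.shape} incompatible with modules "
            f"(I={modules.S.shape[0]}, J={modules.T.shape[0]})"
        )
    yhat = np.einsum("ir,ijk,jr->kr", modules.S, X, modules.T) * modules.lam
    return ModuleFragments(yhat=yhat, const=float(const))


def performance_variance_explained(fragments: ModuleFragments) -> np.ndarray:
    """Cumulative fraction of predicted-performance variance explained.

    Entry r-hat is ``Var_k(sum_{r<=r-hat} yhat_{k,r}) / Var_k(sum_r yhat_{k,r})``;
    the final entry is 1 by construction.
    """
    if fragments.n_trials < 2:
        raise ValueError("need at least 2 trials to compute a variance")
    partial = np.cumsum(fragments.yhat, axis=1)
    total_var = float(np.var(partial[:, -1]))
    if total_var == 0.0:
        raise ValueError("total predicted performance has zero variance")
    return np.var(partial, axis=0) / total_var


def motion_variance_explained_by_task_modules(
    modules: TaskModules, x: np.ndarray
) -> np.ndarray:
    """Cumulative motion-variance contributions of the task-relevant modules.

    ``x`` is the trial-vectorized motion (K, I*J).  Each module's map is
    vectorized as ``w_r = vec(lambda_r s_r t_r^T)`` (including lambda_r,
    i.e. not unit-normalized) and its contribution is the quadratic form
    ``lambda-hat_r = w_r x^T x w_r^T``; the returned curve is
    ``cumsum(lambda-hat) / sum(lambda-hat)``.  Note w_r is generally not
    an eigenvector of x^T x, so unlike a plain SVD spectrum the
    contributions are a diagnostic, not an exact variance partition.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    Wvecs = modules.vectorized_maps()
    if x.shape[1] != Wvecs.shape[1]:
        raise ValueError(
            f"x has {x.shape[1]} features but modules imply {Wvecs.shape[1]}"
        )
    lam_hat = np.einsum("kr,kr->r", x @ Wvecs.T, x @ Wvecs.T)
    total = float(lam_hat.sum())
    if total == 0.0:
        raise ValueError("all module contributions are zero (zero motion or zero map)")
    return np.cumsum(lam_hat) / total
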