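"""Synthetic trial-structured kinematics with planted structure.

The generator emulates the statistical regime the framework assumes:

* low-rank smooth joint-angle trajectories -- each trial is a mixture of
  ``rank_motion`` planted spatial modules driven by smooth temporal
  coefficients (random band-limited Fourier mixtures, orthonormalized
  per trial), plus band-limited measurement noise.  Joint angles derived
  from low-pass filtered marker data contain no energy above the filter
  cutoff, so both signal and noise live in the low-frequency subspace
  (the default 11 Fourier modes span a 10-Hz band over a 500 ms window);
  smoothness makes neighbouring frames strongly collinear, the regime
  that motivates ridge over ordinary least squares;
* a linear motion-to-performance map -- performance is the inner product
  of a planted relevance map with the per-joint standardized motion,
  plus additive noise;
* a gradual gain-perturbation schedule -- zeros during baseline, a
  linear ramp (default 0.005 per trial for 10 trials, reaching 0.05),
  then a constant hold, mirroring a gradually falsified feedback
  paradigm;
* error-driven adaptation -- a single-state learner tracks the
  perturbation and scales the first module's recruitment down by
  ``adaptation_gain`` times the learned estimate, so the first
  task-relevant fragment correlates negatively with the perturbation
  while other modules are untouched.

Also houses the ballistic-task utilities: the parabola baseline
``h = p + v^2 / (2 g)`` for jump height, release detection from the toe
trajectory (first frame above 10% of the trial maximum), and a planar
serial-chain forward kinematics helper.

All generators are bit-reproducible given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .datamodel import MotionDataset, PerformanceSeries
from .standardization import standardize_per_joint

__all__ = [
    "SyntheticConfig",
    "fourier_basis",
    "planted_relevance_map",
    "generate_motion",
    "generate_performance",
    "perturbation_schedule",
    "simulate_adaptation",
    "parabola_height",
    "detect_release",
    "chain_endpoint_height",
]

GRAVITY = 9.8  # m/s^2


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study.

    Defaults mirror the target experimental regime: 4 joints, 60 frames
    at 120 Hz (a 500 ms pre-release window), ~150 trials, motion rank
    equal to the joint count, motion and performance noise at one tenth
    of the signal scale (SNR 10), and the gradual perturbation schedule
    (10 baseline trials, 10 ramp trials of 0.005 per trial, then a 0.05
    hold).  ``n_temporal_basis = 11`` is the number of Fourier modes in
    a 10-Hz band over a 500 ms window (constant plus five harmonic
    pairs), the bandwidth left by typical marker low-pass filtering.
    """

    I: int = 4
    J: int = 60
    K: int = 150
    rank_motion: int = 4
    noise_sd_motion: float = 0.1
    noise_sd_perf: float = 0.1
    baseline_trials: int = 10
    ramp_trials: int = 10
    ramp_step: float = 0.005
    hold_value: float | None = None
    adaptation_gain: float = 10.0
    learning_rate: float = 0.2
    n_temporal_basis: int = 11
    coef_sd: float = 0.5
    amplitude_decay: float = 0.7
    sample_rate: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.I, self.J, self.K) < 1:
            raise ValueError("dimensions must be positive")
        if self.rank_motion < 0 or self.rank_motion > min(self.I, self.J):
            raise ValueError(
                f"rank_motion must be in 0..min(I, J) = {min(self.I, self.J)}"
            )
        if self.noise_sd_motion < 0 or self.noise_sd_perf < 0:
            raise ValueError("noise scales must be >= 0")
        if self.hold_value is None:
            self.hold_value = self.ramp_step * self.ramp_trials


def fourier_basis(J: int, n_basis: int) -> np.ndarray:
    """Band-limited real Fourier basis: constant plus sine/cosine pairs.

    Columns are unit-norm; complete harmonic pairs give a flat pointwise
    energy profile (sum of squares is exactly ``n_basis / J`` at every
    frame when ``n_basis`` is odd), so band-limited random mixtures have
    frame-uniform variance.  Shape (J, n_basis).
    """
    j = np.arange(J)
    cols = [np.ones(J)]
    h = 1
    while len(cols) < n_basis:
        cols.append(np.cos(2.0 * np.pi * h * j / J))
        if len(cols) < n_basis:
            cols.append(np.sin(2.0 * np.pi * h * j / J))
        h += 1
    basis = np.column_stack(cols)
    return basis / np.linalg.norm(basis, axis=0)


def _oriented_qr(M: np.ndarray) -> np.ndarray:
    """Thin QR orthonormalization with columns oriented along the input."""
    Q, R = np.linalg.qr(M)
    return Q * np.sign(np.diag(R))


def planted_relevance_map(
    I: int,
    J: int,
    rank: int,
    seed: int = 0,
    n_basis: int = 11,
    singular_values=None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Random rank-``rank`` relevance map with smooth temporal modules.

    Spatial modules are random orthonormal directions; temporal modules
    are orthonormalized band-limited Fourier mixtures (so the map lives
    in the same smooth subspace as the generated motion).  Returns
    ``(W, S, T, lam)`` with the planted singular triples.
    """
    if not 1 <= rank <= min(I, J):
        raise ValueError(f"rank must be in 1..{min(I, J)}")
    rng = np.random.default_rng(seed)
    S = _oriented_qr(rng.standard_normal((I, rank)))
    T = _oriented_qr(fourier_basis(J, n_basis) @ rng.standard_normal((n_basis, rank)))
    lam = (
        np.asarray(singular_values, dtype=float)
        if singular_values is not None
        else 0.5 ** np.arange(rank)
    )
    if lam.size != rank or np.any(lam < 0):
        raise ValueError("singular_values must be `rank` non-negative values")
    return (S * lam) @ T.T, S, T, lam


def _structured_motion(
    config: SyntheticConfig, rng: np.random.Generator, amplitude_shift=None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Planted-module motion; returns (angles, spatial modules b, mean curves)."""
    I, J, K, R = config.I, config.J, config.K, config.rank_motion
    basis = fourier_basis(J, config.n_temporal_basis)
    b = _oriented_qr(rng.standard_normal((I, R)))
    theta_bar = rng.standard_normal((R, config.n_temporal_basis))
    amplitudes = config.amplitude_decay ** np.arange(R)
    shift = (
        np.zeros(K) if amplitude_shift is None else np.asarray(amplitude_shift, float)
    )
    if shift.size != K:
        raise ValueError("amplitude_shift must have one value per trial")
    signal = np.empty((I, J, K))
    for k in range(K):
        theta = theta_bar + config.coef_sd * rng.standard_normal(theta_bar.shape)
        c = _oriented_qr(basis @ theta.T)  # (J, R), orthonormal per trial
        a_k = amplitudes.copy()
        a_k[0] *= 1.0 + shift[k]
        signal[:, :, k] = (b * a_k) @ c.T
    scale = signal.std()
    if scale > 0:
        signal /= scale  # unit element scale: noise_sd_motion is 1/SNR
    mean_curves = _oriented_qr(basis @ theta_bar.T)
    return signal, b, mean_curves


def _bandlimited_noise(
    config: SyntheticConfig, rng: np.random.Generator
) -> np.ndarray:
    """Measurement noise confined to the temporal Fourier band.

    Element sd equals ``noise_sd_motion`` exactly in expectation (the
    flat-energy basis makes the per-frame variance uniform).
    """
    basis = fourier_basis(config.J, config.n_temporal_basis)
    z = rng.standard_normal((config.I, config.n_temporal_basis, config.K))
    z *= np.sqrt(config.J / config.n_temporal_basis)
    return config.noise_sd_motion * np.einsum("jp,ipk->ijk", basis, z)


def generate_motion(
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
    amplitude_shift=None,
) -> MotionDataset:
    """Generate a trial-structured motion dataset.

    With ``rank_motion >= 1`` each trial is a planted-module mixture
    (see module docstring) plus band-limited Gaussian measurement noise
    of element sd ``noise_sd_motion`` relative to the unit-scaled signal
    (noise is drawn in the same Fourier band as the trajectories,
    matching angles computed from low-pass filtered markers).  With
    ``rank_motion = 0`` the smooth generator is off and the angles are
    pure i.i.d. standard normal noise (the null regime).
    ``amplitude_shift`` optionally scales the first module's amplitude
    per trial (used by :func:`simulate_adaptation`).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    I, J, K = config.I, config.J, config.K
    if config.rank_motion == 0:
        angles = rng.standard_normal((I, J, K))
    else:
        signal, _, _ = _structured_motion(config, rng, amplitude_shift)
        angles = signal
        if config.noise_sd_motion > 0:
            angles = angles + _bandlimited_noise(config, rng)
    labels = ["toe", "ankle", "knee", "hip"] if I == 4 else [f"joint{i+1}" for i in range(I)]
    return MotionDataset(
        angles=angles, joint_labels=labels, sample_rate=config.sample_rate
    )


def generate_performance(
    dataset: MotionDataset,
    planted_W: np.ndarray,
    noise_sd_perf: float,
    seed: int = 0,
    perturbation=None,
) -> tuple[PerformanceSeries, np.ndarray]:
    """Per-trial performance from a planted linear map.

    ``d_k = <planted_W, X_k> + eps_k`` with ``X`` the per-joint
    standardized motion and i.i.d. Gaussian noise of sd
    ``noise_sd_perf`` (absolute units).  Returns the performance series
    and the pre-noise signal (for recovery experiments).
    """
    W = np.asarray(planted_W, dtype=float)
    if W.shape != (dataset.n_joints, dataset.n_frames):
        raise ValueError(
            f"planted_W shape {W.shape} does not match dataset "
            f"({dataset.n_joints}, {dataset.n_frames})"
        )
    X = standardize_per_joint(dataset).X
    signal = np.einsum("ij,ijk->k", W, X)
    rng = np.random.default_rng(seed)
    d_raw = signal + noise_sd_perf * rng.standard_normal(signal.size)
    perf = PerformanceSeries(d_raw=d_raw, perturbation=perturbation)
    return perf, signal


def perturbation_schedule(config: SyntheticConfig, K: int | None = None) -> np.ndarray:
    """Piecewise perturbation series: baseline zeros, linear ramp, hold.

    Trial index is 0-based; the m-th ramp trial (m = 1..ramp_trials)
    carries ``m * ramp_step``, after which the series stays at
    ``hold_value``.  With the defaults (baseline 10, ramp 10, step
    0.005) the 20th trial (1-based) carries exactly 0.05.
    """
    K = config.K if K is None else K
    if config.baseline_trials + config.ramp_trials > K:
        raise ValueError("baseline + ramp exceeds the number of trials")
    p = np.full(K, float(config.hold_value))
    p[: config.baseline_trials] = 0.0
    ramp = np.arange(1, config.ramp_trials + 1) * config.ramp_step
    p[config.baseline_trials : config.baseline_trials + config.ramp_trials] = ramp
    return p


def simulate_adaptation(
    config: SyntheticConfig,
) -> tuple[MotionDataset, PerformanceSeries]:
    """Simulate one subject of a gain-adaptation session.

    A single-state error-driven learner tracks the perturbation
    (``est_{k+1} = est_k + lr (p_k - est_k)``) and the first planted
    module's amplitude on trial k is scaled by
    ``1 - adaptation_gain * est_k``, so its recruitment -- and hence the
    first task-relevant fragment -- correlates negatively with the
    applied perturbation.  The planted relevance map is built from the
    generator's own first two spatial modules and mean temporal shapes,
    so the fitted leading task-relevant module aligns with the perturbed
    direction.  Performance noise is ``noise_sd_perf`` relative to the
    pre-noise signal sd.
    """
    ss = np.random.SeedSequence(config.seed)
    child = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2)]
    p = perturbation_schedule(config)
    est = np.zeros(config.K)
    for k in range(1, config.K):
        est[k] = est[k - 1] + config.learning_rate * (p[k - 1] - est[k - 1])
    shift = -config.adaptation_gain * est

    rng = np.random.default_rng(child[0])
    signal, b, mean_curves = _structured_motion(config, rng, amplitude_shift=shift)
    angles = signal
    if config.noise_sd_motion > 0:
        angles = angles + _bandlimited_noise(config, rng)
    labels = (
        ["toe", "ankle", "knee", "hip"]
        if config.I == 4
        else [f"joint{i+1}" for i in range(config.I)]
    )
    dataset = MotionDataset(
        angles=angles, joint_labels=labels, sample_rate=config.sample_rate
    )

    rank_W = min(2, config.rank_motion)
    lam = 0.5 ** np.arange(rank_W)
    W = (b[:, :rank_W] * lam) @ mean_curves[:, :rank_W].T
    X = standardize_per_joint(dataset).X
    signal_d = np.einsum("ij,ijk->k", W, X)
    noise_abs = config.noise_sd_perf * signal_d.std()
    d_raw = signal_d + noise_abs * np.random.default_rng(child[1]).standard_normal(
        config.K
    )
    perf = PerformanceSeries(d_raw=d_raw, perturbation=p)
    return dataset, perf


def parabola_height(p, v) -> np.ndarray | float:
    """Ballistic jump height ``h = p + v^2 / (2 g)`` (release height p in m,
    release vertical velocity v in m/s, g = 9.8 m/s^2)."""
    return np.asarray(p, dtype=float) + np.square(np.asarray(v, dtype=float)) / (
        2.0 * GRAVITY
    )


def detect_release(toe_height: np.ndarray) -> int:
    """First frame at which the toe height exceeds 10% of the trial maximum."""
    h = np.asarray(toe_height, dtype=float).ravel()
    if h.size == 0 or np.any(h < 0):
        raise ValueError("toe height must be a nonnegative, nonempty series")
    peak = h.max()
    if peak <= 0:
        raise ValueError("toe never leaves the ground (max height is 0)")
    return int(np.argmax(h > 0.1 * peak))


def chain_endpoint_height(joint_angles: np.ndarray, segment_lengths) -> np.ndarray:
    """Vertical endpoint coordinate of a planar serial chain.

    ``joint_angles`` has the joint axis first (radians, absolute-sum
    convention: segment m is inclined by the cumulative sum of the first
    m angles); broadcasting applies over trailing axes.  Used only by
    the simulator to turn four joint angles into a marker height.
    """
    q = np.asarray(joint_angles, dtype=float)
    L = np.asarray(segment_lengths, dtype=float)
    if L.size != q.shape[0]:
        raise ValueError("need one segment length per joint")
    cum = np.cumsum(q, axis=0)
    return np.tensordot(L, np.sin(cum), axes=(0, 0))
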