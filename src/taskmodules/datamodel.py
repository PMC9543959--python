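"""Trial-structured kinematic data model and delimited-text I/O.

A recording session is a stack of ``K`` trials; each trial holds ``I``
joint-angle trajectories sampled at ``J`` time frames (e.g. toe, ankle,
knee and hip angles over the 500 ms before release of a vertical jump,
60 frames at 120 Hz).  Alongside the motion, every trial carries one
scalar performance value (e.g. jump height in % of each subject's
maximum), a target value, and an optional perturbation value used in
adaptation experiments.

The interchange format is tidy (long) delimited text:

* motion file — columns ``subject, trial, frame, joint, angle``
* trial file  — columns ``subject, trial, performance, target, perturbation``

The delimiter is inferred from the file extension (``.tsv``/``.tab`` is
tab-separated, anything else comma-separated) and floats are written with
9 significant digits.  Frames are 0-based; the frame index is written
explicitly so the convention is visible in the files themselves.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "MotionDataset",
    "PerformanceSeries",
    "read_trials",
    "write_trials",
    "extract_prerelease_window",
]

MOTION_COLUMNS = ("subject", "trial", "frame", "joint", "angle")
TRIAL_COLUMNS = ("subject", "trial", "performance", "target", "perturbation")
FLOAT_FORMAT = "%.9g"


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


@dataclass
class MotionDataset:
    """Joint-angle array indexed ``(joint i, frame j, trial k)``.

    Parameters
    ----------
    angles
        Real array of shape ``(I, J, K)`` with no missing values.
    joint_labels
        ``I`` joint names, in array order.
    sample_rate
        Sampling rate in Hz; together with ``J`` it fixes the analysis
        window duration (``window_ms``).
    units
        Angle units, ``"deg"`` or ``"rad"`` (declared, not converted).
    """

    angles: np.ndarray
    joint_labels: list[str] = field(default_factory=list)
    sample_rate: float = 120.0
    units: str = "deg"
    subject_id: str = "s01"
    experiment_id: str = "exp1"

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.ndim != 3:
            raise ValueError(f"angles must be (I, J, K), got shape {self.angles.shape}")
        I, J, K = self.angles.shape
        if I < 1 or J < 1 or K < 2:
            raise ValueError(f"need I >= 1, J >= 1, K >= 2, got (I, J, K) = {(I, J, K)}")
        if not np.all(np.isfinite(self.angles)):
            bad = np.argwhere(~np.isfinite(self.angles))[0]
            raise ValueError(
                f"non-finite angle at joint {bad[0]}, frame {bad[1]}, trial {bad[2]}"
            )
        if not self.joint_labels:
            self.joint_labels = [f"joint{i + 1}" for i in range(I)]
        if len(self.joint_labels) != I:
            raise ValueError(
                f"{len(self.joint_labels)} joint labels for {I} joints"
            )
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def n_joints(self) -> int:
        return self.angles.shape[0]

    @property
    def n_frames(self) -> int:
        return self.angles.shape[1]

    @property
    def n_trials(self) -> int:
        return self.angles.shape[2]

    @property
    def window_ms(self) -> float:
        """Duration represented by the J frames, in milliseconds."""
        return 1000.0 * self.n_frames / self.sample_rate

    def fingerprint(self) -> str:
        """Content hash used to verify that two objects derive from the same data."""
        h = hashlib.sha1()
        h.update(np.ascontiguousarray(self.angles).tobytes())
        h.update(repr(self.angles.shape).encode())
        return h.hexdigest()

    def select_trials(self, index) -> "MotionDataset":
        """Subset along the trial axis (used for cross-validation folds)."""
        return replace(self, angles=self.angles[:, :, np.asarray(index)])


@dataclass
class PerformanceSeries:
    """Per-trial scalars accompanying a :class:`MotionDataset`.

    ``d_raw`` is the raw (unstandardized) performance, ``target`` the
    instructed target, ``perturbation`` the feedback offset applied on
    that trial (0 when absent), and ``trial_index`` the original trial
    numbers (strictly increasing).
    """

    d_raw: np.ndarray
    target: np.ndarray | None = None
    perturbation: np.ndarray | None = None
    trial_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.d_raw = np.asarray(self.d_raw, dtype=float).ravel()
        K = self.d_raw.size
        if self.target is None:
            self.target = np.zeros(K)
        if self.perturbation is None:
            self.perturbation = np.zeros(K)
        if self.trial_index is None:
            self.trial_index = np.arange(K)
        self.target = np.asarray(self.target, dtype=float).ravel()
        self.perturbation = np.asarray(self.perturbation, dtype=float).ravel()
        self.trial_index = np.asarray(self.trial_index).ravel()
        for name in ("target", "perturbation", "trial_index"):
            if getattr(self, name).size != K:
                raise ValueError(f"{name} length does not match d_raw ({K})")
        if K > 1 and not np.all(np.diff(self.trial_index) > 0):
            raise ValueError("trial_index must be strictly increasing")
        if not np.all(np.isfinite(self.d_raw)):
            raise ValueError("non-finite performance value")

    @property
    def n_trials(self) -> int:
        return self.d_raw.size

    def select_trials(self, index) -> "PerformanceSeries":
        idx = np.asarray(index)
        return PerformanceSeries(
            d_raw=self.d_raw[idx],
            target=self.target[idx],
            perturbation=self.perturbation[idx],
            trial_index=self.trial_index[idx],
        )


def _apply_schema(df: pd.DataFrame, schema: dict | None, required) -> pd.DataFrame:
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s) {missing}; found {list(df.columns)}")
    return df


def read_trials(
    motion_path,
    trials_path,
    schema: dict | None = None,
    sample_rate: float = 120.0,
    units: str = "deg",
) -> tuple[MotionDataset, PerformanceSeries]:
    """Read a motion file and a trial file into the in-memory data model.

    Trials are matched between the two files by trial index; only trials
    present in both are kept.  ``schema`` maps canonical column names to
    the names actually used in the files, e.g. ``{"angle": "theta"}``.

    Raises
    ------
    ValueError
        If a (trial, frame, joint) cell is absent or duplicated, if
        trials have unequal frame counts (ragged), or if no trial is
        common to both files.
    """
    motion = _apply_schema(
        pd.read_csv(motion_path, sep=_sep_for(motion_path)), schema, MOTION_COLUMNS
    )
    trials = _apply_schema(
        pd.read_csv(trials_path, sep=_sep_for(trials_path)), schema, TRIAL_COLUMNS
    )

    common = np.intersect1d(motion["trial"].unique(), trials["trial"].unique())
    if common.size == 0:
        raise ValueError("no trial index is present in both files")
    motion = motion[motion["trial"].isin(common)]
    trials = trials[trials["trial"].isin(common)].sort_values("trial")
    if trials["trial"].duplicated().any():
        dup = trials.loc[trials["trial"].duplicated(), "trial"].iloc[0]
        raise ValueError(f"duplicated trial {dup} in trial file")

    joints = list(dict.fromkeys(motion["joint"]))  # preserve file order
    frames = np.sort(motion["frame"].unique())
    trial_ids = np.sort(common)

    counts = motion.groupby("trial")["frame"].nunique()
    if counts.nunique() > 1:
        raise ValueError(
            f"ragged trials: frame counts per trial vary ({counts.min()}..{counts.max()})"
        )

    cells = motion.set_index(["joint", "frame", "trial"])["angle"]
    if cells.index.duplicated().any():
        j, f, t = cells.index[cells.index.duplicated()][0]
        raise ValueError(f"duplicate motion cell (trial {t}, frame {f}, joint {j})")
    full = pd.MultiIndex.from_product(
        [joints, frames, trial_ids], names=["joint", "frame", "trial"]
    )
    cells = cells.reindex(full)
    if cells.isna().any():
        j, f, t = cells.index[cells.isna()][0]
        raise ValueError(f"missing motion cell (trial {t}, frame {f}, joint {j})")

    I, J, K = len(joints), len(frames), len(trial_ids)
    angles = cells.to_numpy().reshape(I, J, K)
    subject = str(motion["subject"].iloc[0])
    dataset = MotionDataset(
        angles=angles,
        joint_labels=[str(j) for j in joints],
        sample_rate=sample_rate,
        units=units,
        subject_id=subject,
    )
    perf = PerformanceSeries(
        d_raw=trials["performance"].to_numpy(),
        target=trials["target"].to_numpy(),
        perturbation=trials["perturbation"].to_numpy(),
        trial_index=trials["trial"].to_numpy(),
    )
    return dataset, perf


def write_trials(dataset: MotionDataset, perf: PerformanceSeries, motion_path, trials_path) -> None:
    """Write the long-format motion and trial files read by :func:`read_trials`."""
    if perf.n_trials != dataset.n_trials:
        raise ValueError(
            f"performance series has {perf.n_trials} trials, dataset has {dataset.n_trials}"
        )
    I, J, K = dataset.angles.shape
    joints = np.repeat(dataset.joint_labels, J * K)
    frames = np.tile(np.repeat(np.arange(J), K), I)
    trial_ids = np.tile(perf.trial_index, I * J)
    motion = pd.DataFrame(
        {
            "subject": dataset.subject_id,
            "trial": trial_ids,
            "frame": frames,
            "joint": joints,
            "angle": dataset.angles.ravel(),
        }
    )
    trials = pd.DataFrame(
        {
            "subject": dataset.subject_id,
            "trial": perf.trial_index,
            "performance": perf.d_raw,
            "target": perf.target,
            "perturbation": perf.perturbation,
        }
    )
    motion.to_csv(motion_path, sep=_sep_for(motion_path), index=False, float_format=FLOAT_FORMAT)
    trials.to_csv(trials_path, sep=_sep_for(trials_path), index=False, float_format=FLOAT_FORMAT)


def extract_prerelease_window(
    dataset: MotionDataset, release_frame, n_frames: int
) -> MotionDataset:
    """Cut the ``n_frames`` frames strictly before release from each trial.

    ``release_frame`` gives, per trial, the (0-based) frame at which
    release was detected; the returned window covers frames
    ``release_frame - n_frames .. release_frame - 1``, i.e. it ends at
    the frame immediately preceding release.
    """
    release = np.broadcast_to(
        np.asarray(release_frame, dtype=int), (dataset.n_trials,)
    )
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    short = np.nonzero(release < n_frames)[0]
    if short.size:
        k = short[0]
        raise ValueError(
            f"trial {k}: release frame {release[k]} leaves fewer than {n_frames} frames before release"
        )
    out = np.empty((dataset.n_joints, n_frames, dataset.n_trials))
    for k in range(dataset.n_trials):
        out[:, :, k] = dataset.angles[:, release[k] - n_frames : release[k], k]
    return replace(dataset, angles=out)
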