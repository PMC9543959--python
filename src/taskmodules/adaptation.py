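"""Adaptation statistics: perturbation-fragment correlations and module comparisons.

In a gain-adaptation experiment the displayed outcome is offset from the
actual outcome by a per-trial perturbation.  If a task-relevant module
carries the trial-to-trial update of planned output, the fragment of
predicted performance it contributes should *compensate* the
perturbation, i.e. correlate negatively with it.  The group-level
question -- is the correlation consistently non-zero across subjects? --
is answered by a two-sided one-sample t-test on the per-subject Pearson
correlations, corrected for the number of modules tested (Bonferroni by
default; Holm and no correction are available and the method is always
recorded in the output).

For comparing module shapes across experiments, temporal modules are
averaged within contiguous phases (default: three roughly equal thirds
of the movement) and each feature (spatial: per joint; temporal: per
phase) is submitted to a one-way ANOVA across experiments followed by
Tukey's HSD on all experiment pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "AdaptationStats",
    "ModuleComparison",
    "perturbation_correlation",
    "group_correlation_test",
    "phase_average",
    "compare_across_experiments",
]


def perturbation_correlation(
    fragments, perturbation: np.ndarray, trial_subset=None
) -> np.ndarray:
    """Pearson correlation between the perturbation and each module's fragment.

    ``fragments`` is a :class:`~taskmodules.task_modules.ModuleFragments`
    or a (K, R) array.  ``trial_subset`` optionally restricts to a set
    of trial indices (default: all trials).  At least 3 trials are
    required and neither series may be constant on the subset.
    """
    yhat = np.asarray(getattr(fragments, "yhat", fragments), dtype=float)
    p = np.asarray(perturbation, dtype=float).ravel()
    if yhat.shape[0] != p.size:
        raise ValueError(f"{yhat.shape[0]} fragment trials vs {p.size} perturbations")
    if trial_subset is not None:
        idx = np.asarray(trial_subset)
        yhat, p = yhat[idx], p[idx]
    if p.size < 3:
        raise ValueError("need at least 3 trials for a correlation")
    if np.ptp(p) == 0:
        raise ValueError("perturbation is constant on the selected trials")
    rho = np.empty(yhat.shape[1])
    for r in range(yhat.shape[1]):
        if np.ptp(yhat[:, r]) == 0:
            raise ValueError(f"fragment of module {r + 1} is constant; correlation undefined")
        rho[r] = scipy.stats.pearsonr(p, yhat[:, r]).statistic
    return rho


def _correct(p_raw: np.ndarray, method: str) -> np.ndarray:
    m = p_raw.size
    if method == "none":
        return p_raw.copy()
    if method == "bonferroni":
        return np.minimum(p_raw * m, 1.0)
    if method == "holm":
        order = np.argsort(p_raw)
        stepped = p_raw[order] * (m - np.arange(m))
        stepped = np.minimum(np.maximum.accumulate(stepped), 1.0)
        out = np.empty(m)
        out[order] = stepped
        return out
    raise ValueError(f"unknown correction method {method!r}")


@dataclass
class AdaptationStats:
    """Group-level test of perturbation-fragment correlations.

    ``rho`` is the (subjects x modules) matrix of per-subject Pearson
    correlations; ``t_stats``/``p_raw``/``p_corrected`` are per-module
    results of the two-sided one-sample t-test of the mean correlation
    against zero.
    """

    rho: np.ndarray
    t_stats: np.ndarray
    p_raw: np.ndarray
    p_corrected: np.ndarray
    correction_method: str

    def significant(self, alpha: float = 0.05) -> np.ndarray:
        return self.p_corrected < alpha


def group_correlation_test(
    rho_by_subject: np.ndarray, correction: str = "bonferroni"
) -> AdaptationStats:
    """Two-sided one-sample t-test of per-subject correlations against 0.

    ``rho_by_subject`` has shape (n_subjects, n_modules); the correction
    spans the modules tested.  All-identical correlations within a
    module make the t statistic undefined and raise.
    """
    rho = np.atleast_2d(np.asarray(rho_by_subject, dtype=float))
    if rho.shape[0] < 2:
        raise ValueError("need at least 2 subjects for a group test")
    if np.any(np.ptp(rho, axis=0) == 0):
        r = int(np.argwhere(np.ptp(rho, axis=0) == 0)[0][0])
        raise ValueError(f"module {r + 1}: all subjects have identical correlations")
    res = scipy.stats.ttest_1samp(rho, popmean=0.0, axis=0)
    p_raw = np.atleast_1d(res.pvalue)
    return AdaptationStats(
        rho=rho,
        t_stats=np.atleast_1d(res.statistic),
        p_raw=p_raw,
        p_corrected=_correct(p_raw, correction),
        correction_method=correction,
    )


def phase_average(t_module: np.ndarray, n_phases: int = 3) -> np.ndarray:
    """Mean of a length-J temporal module within contiguous phases.

    The J frames are split into ``n_phases`` contiguous blocks; when J
    is not divisible the earliest blocks are one frame larger.
    """
    t = np.asarray(t_module, dtype=float).ravel()
    if n_phases < 1:
        raise ValueError("n_phases must be >= 1")
    if n_phases > t.size:
        raise ValueError(f"cannot split {t.size} frames into {n_phases} phases")
    return np.array([block.mean() for block in np.array_split(t, n_phases)])


@dataclass
class ModuleComparison:
    """Across-experiment comparison of module features.

    One row of ``table`` per feature, with the one-way ANOVA F and p;
    ``tukey`` maps feature name -> DataFrame of pairwise Tukey HSD
    p-values between experiments.
    """

    table: pd.DataFrame
    tukey: dict[str, pd.DataFrame]
    experiments: list[str]


def compare_across_experiments(features: pd.DataFrame) -> ModuleComparison:
    """One-way ANOVA + Tukey HSD per feature across experiments.

    ``features`` is tidy with columns ``subject, experiment, feature,
    value`` (one value per subject x experiment x feature).  Requires at
    least 2 experiments with at least 2 subjects each.
    """
    required = {"subject", "experiment", "feature", "value"}
    if not required.issubset(features.columns):
        raise ValueError(f"features table needs columns {sorted(required)}")
    experiments = sorted(features["experiment"].unique())
    if len(experiments) < 2:
        raise ValueError("need at least 2 experiments")
    rows, tukey = [], {}
    for feat, sub in features.groupby("feature", sort=True):
        groups = [
            sub.loc[sub["experiment"] == e, "value"].to_numpy() for e in experiments
        ]
        if any(g.size < 2 for g in groups):
            raise ValueError(f"feature {feat!r}: every experiment needs >= 2 subjects")
        F, p = scipy.stats.f_oneway(*groups)
        hsd = scipy.stats.tukey_hsd(*groups)
        pair = pd.DataFrame(
            hsd.pvalue, index=experiments, columns=experiments
        )
        rows.append({"feature": feat, "anova_F": float(F), "anova_p": float(p)})
        tukey[feat] = pair
    return ModuleComparison(
        table=pd.DataFrame(rows), tukey=tukey, experiments=list(experiments)
    )
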