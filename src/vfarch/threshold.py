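"""Calibration of the minimum meaningful archetype weight / weight change.

Healthy eyes tested repeatedly show small fluctuations in decomposed AT
weights that carry no clinical signal.  The meaningful-weight threshold is
derived from two floors: (1) the upper 95% confidence limit of the mean
absolute between-visit weight change of any abnormal AT among control eyes,
and (2) the uniform-mixture floor 100/k (the weight every AT would carry if
all were equally present).  The threshold is the smallest integer percent
strictly greater than both, a deliberately conservative rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ChangeStats",
    "ThresholdResult",
    "control_change_stats",
    "meaningful_threshold",
    "threshold_from_limits",
]


@dataclass
class ChangeStats:
    """Per-AT summary of absolute weight changes among control eyes (%)."""

    mean_change: np.ndarray  # (k,)
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    n_changes: np.ndarray  # (k,) int
    degenerate: np.ndarray  # (k,) bool; True when CI is based on < 2 changes
    normal_at: Optional[int]  # 0-based index of the designated normal AT

    @property
    def abnormal_ats(self) -> np.ndarray:
        k = len(self.mean_change)
        return np.array([j for j in range(k) if j != self.normal_at])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "at": np.arange(1, len(self.mean_change) + 1),
                "mean_abs_change": self.mean_change,
                "ci_lo": self.ci_lo,
                "ci_hi": self.ci_hi,
                "n_changes": self.n_changes,
                "degenerate": self.degenerate,
                "is_normal_at": [
                    j == self.normal_at for j in range(len(self.mean_change))
                ],
            }
        )


@dataclass
class ThresholdResult:
    """The calibrated meaningful-weight threshold and its two floors (%)."""

    ci_upper_max: float
    floor_1_over_k: float
    threshold: int


def control_change_stats(
    trajectories: Sequence[np.ndarray],
    normal_at: Optional[int] = 0,
    mode: str = "consecutive",
) -> ChangeStats:
    """Absolute between-visit weight changes pooled across control eyes.

    Parameters
    ----------
    trajectories
        One (n_visits, k) percent-weight array per eye, visits time-ordered.
        Eyes with a single visit contribute nothing.
    normal_at
        0-based index of the normal-field AT, excluded from the abnormal set
        used by :func:`meaningful_threshold` (``None`` marks all abnormal).
    mode
        ``"consecutive"`` (default) pools |w(t+1) - w(t)| over successive
        visit pairs; ``"baseline"`` pools |w(t) - w(0)| for t > 0.

    The 95% CI of the mean uses the t-distribution on the pooled changes;
    ATs with fewer than two pooled changes are flagged degenerate.
    """
    if mode not in ("consecutive", "baseline"):
        raise ValueError("mode must be 'consecutive' or 'baseline'")
    diffs = []
    for W in trajectories:
        W = np.atleast_2d(np.asarray(W, dtype=float))
        if W.shape[0] < 2:
            continue
        if mode == "consecutive":
            diffs.append(np.abs(np.diff(W, axis=0)))
        else:
            diffs.append(np.abs(W[1:] - W[0]))
    if not diffs:
        raise ValueError("no eye contributed >= 2 visits")
    D = np.vstack(diffs)  # (total changes, k)
    n = D.shape[0]
    mean = D.mean(axis=0)
    degenerate = np.full(D.shape[1], n < 2)
    if n >= 2:
        sem = D.std(axis=0, ddof=1) / np.sqrt(n)
        tcrit = stats.t.ppf(0.975, df=n - 1)
        lo, hi = mean - tcrit * sem, mean + tcrit * sem
        lo = np.maximum(lo, 0.0)
    else:
        lo = hi = mean.copy()
    return ChangeStats(
        mean_change=mean,
        ci_lo=lo,
        ci_hi=hi,
        n_changes=np.full(D.shape[1], n, dtype=int),
        degenerate=degenerate,
        normal_at=normal_at,
    )


def meaningful_threshold(stats_: ChangeStats, k: int) -> ThresholdResult:
    """Smallest integer percent strictly above both calibration floors.

    With the control-eye CI upper limit at 4.1% and a 16-AT model
    (uniform-mixture floor 100/16 = 6.25%), the rule yields 7%.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(stats_.mean_change) == 0:
        raise ValueError("empty change statistics")
    abnormal = stats_.abnormal_ats
    if abnormal.size == 0:
        raise ValueError("no abnormal ATs to calibrate against")
    ci_upper_max = float(np.max(stats_.ci_hi[abnormal]))
    return threshold_from_limits(ci_upper_max, k)


def threshold_from_limits(ci_upper_max: float, k: int) -> ThresholdResult:
    """Apply the integer-threshold rule to a CI upper limit and model order."""
    if k < 2:
        raise ValueError("k must be >= 2")
    floor = 100.0 / k
    base = max(float(ci_upper_max), floor)
    threshold = int(np.floor(base)) + 1
    return ThresholdResult(
        ci_upper_max=float(ci_upper_max), floor_1_over_k=floor, threshold=threshold
    )
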