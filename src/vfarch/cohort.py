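"""Baseline and longitudinal cohort summaries of archetype decompositions.

Operations here consume percent weight vectors (summing to 100) produced by
the archetype engine: counting meaningful ATs, finding dominant ATs,
grouped cumulative weights, Spearman correlations of AT weights with global
indices (Bonferroni-corrected), and treatment-arm difference tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EyeSeries",
    "meaningful_at_count",
    "dominant_at",
    "grouped_cumulative_weight",
    "regional_weight_mean",
    "spearman_with_bonferroni",
    "group_difference_tests",
    "identify_global_ats",
]


def identify_global_ats(model, normal_cutoff_db: float = -5.0):
    """Locate the globally normal and globally abnormal archetypes of a model.

    The normal archetype is the highest-RW archetype whose average TD is
    above ``normal_cutoff_db`` (models of recovering cohorts place a
    near-zero pattern first by frequency; a low-RW near-normal duplicate
    should not be mistaken for it).  The diffuse-loss archetype is the one
    with the most negative average TD.  Returns ``(normal_idx, diffuse_idx)``
    as 0-based indices; ``normal_idx`` is None if no archetype is near
    normal.
    """
    near = np.flatnonzero(model.avg_td > normal_cutoff_db)
    normal_idx = int(near[np.argmax(model.rw_percent[near])]) if near.size else None
    diffuse_idx = int(np.argmin(model.avg_td))
    return normal_idx, diffuse_idx


@dataclass
class EyeSeries:
    """Ordered visits of one eye: weights plus per-visit indices."""

    eye_id: str
    visit_days: np.ndarray  # (v,)
    weights: np.ndarray  # (v, k) percent
    md: Optional[np.ndarray] = None
    psd: Optional[np.ndarray] = None
    va_logmar: Optional[np.ndarray] = None
    cs_letters: Optional[np.ndarray] = None

    def __post_init__(self):
        days = np.asarray(self.visit_days)
        if np.any(np.diff(days) < 0):
            raise ValueError(f"eye {self.eye_id}: visit days must be nondecreasing")

    @property
    def duplicated_days(self) -> np.ndarray:
        """Days appearing more than once (duplicated baseline/outcome tests)."""
        days, counts = np.unique(self.visit_days, return_counts=True)
        return days[counts > 1]


def meaningful_at_count(w: np.ndarray, threshold: float) -> int:
    """Number of ATs whose weight is at or above the threshold (boundary inclusive)."""
    if not (0.0 < threshold < 100.0):
        raise ValueError("threshold must be in (0, 100)")
    w = np.asarray(w, dtype=float)
    return int(np.sum(w >= threshold))


def dominant_at(w: np.ndarray) -> Optional[int]:
    """0-based index of the AT carrying >= 50% weight, if any.

    At most one AT can strictly exceed 50%; an exact 50/50 tie has no unique
    dominant pattern and returns ``None``.
    """
    w = np.asarray(w, dtype=float)
    qualifying = np.flatnonzero(w >= 50.0)
    if qualifying.size != 1:
        return None
    return int(qualifying[0])


def grouped_cumulative_weight(w: np.ndarray, at_subset: Iterable[int]) -> float:
    """Summed weight (%) over a subset of AT indices (0-based)."""
    w = np.asarray(w, dtype=float)
    idx = sorted(set(int(i) for i in at_subset))
    if any(i < 0 or i >= w.size for i in idx):
        raise ValueError("at_subset contains out-of-range indices")
    return float(w[idx].sum()) if idx else 0.0


def regional_weight_mean(w: np.ndarray, excluded: Iterable[int]) -> float:
    """Mean weight (%) over ATs outside ``excluded`` (0-based indices).

    Used to relate PSD to the overall load of regional-defect patterns,
    excluding the globally normal and globally abnormal ATs.
    """
    w = np.asarray(w, dtype=float)
    excl = set(int(i) for i in excluded)
    keep = [i for i in range(w.size) if i not in excl]
    if not keep:
        raise ValueError("cannot exclude every AT")
    return float(w[keep].mean())


def spearman_with_bonferroni(
    pairs: Sequence[Tuple[str, np.ndarray, np.ndarray]],
    m: Optional[int] = None,
) -> pd.DataFrame:
    """Spearman rank correlations with Bonferroni-adjusted p-values.

    ``pairs`` holds (name, x, y) triples; ``m`` is the number of comparisons
    used for the correction (defaults to ``len(pairs)``, recorded in the
    output).  Zero-variance inputs yield an undefined (NaN) correlation.
    Ties are handled by midranks; two-sided p-values use the t
    approximation.
    """
    if m is None:
        m = len(pairs)
    rows = []
    for name, x, y in pairs:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError(f"pair {name!r}: x and y must be 1-d and equal length")
        if x.size < 3:
            raise ValueError(f"pair {name!r}: need n >= 3")
        if np.all(x == x[0]) or np.all(y == y[0]):
            r, p = np.nan, np.nan
        else:
            res = stats.spearmanr(x, y)
            r, p = float(res.statistic), float(res.pvalue)
        rows.append(
            {
                "pair": name,
                "r": r,
                "p_raw": p,
                "p_adj": min(1.0, p * m) if np.isfinite(p) else np.nan,
                "n": x.size,
                "m": m,
            }
        )
    return pd.DataFrame(rows)


def group_difference_tests(
    weights_by_arm: Dict[str, np.ndarray],
    threshold: float,
) -> pd.DataFrame:
    """Per-AT treatment-arm comparisons at baseline.

    For each AT: a chi-squared test (no continuity correction) on the
    arm x (weight >= threshold) contingency table, and a Kruskal-Wallis test
    on the raw weight values across arms.  Arms with no eyes are dropped
    with a warning.
    """
    import warnings

    arms = {}
    for arm, W in weights_by_arm.items():
        W = np.atleast_2d(np.asarray(W, dtype=float))
        if W.shape[0] == 0:
            warnings.warn(f"arm {arm!r} is empty and was excluded", stacklevel=2)
            continue
        arms[arm] = W
    if len(arms) < 2:
        raise ValueError("need at least 2 nonempty arms")
    sizes = [W.shape[0] for W in arms.values()]
    if min(sizes) < 2:
        raise ValueError("each arm needs at least 2 eyes")
    k = next(iter(arms.values())).shape[1]
    rows = []
    for j in range(k):
        table = np.array(
            [
                [int(np.sum(W[:, j] >= threshold)), int(np.sum(W[:, j] < threshold))]
                for W in arms.values()
            ]
        )
        if np.all(table[:, 0] == 0) or np.all(table[:, 1] == 0):
            chi2, chi2_p = 0.0, 1.0  # all arms identical w.r.t. the cutoff
        else:
            chi2, chi2_p, _, _ = stats.chi2_contingency(table, correction=False)
        groups = [W[:, j] for W in arms.values()]
        if all(np.all(g == groups[0][0]) for g in groups):
            kw_stat, kw_p = 0.0, 1.0
        else:
            kw_stat, kw_p = stats.kruskal(*groups)
        rows.append(
            {
                "at": j + 1,
                "chi2": float(chi2),
                "chi2_p": float(chi2_p),
                "kruskal": float(kw_stat),
                "kruskal_p": float(kw_p),
                "n_meaningful": [int(t) for t in table[:, 0]],
                "arms": list(arms.keys()),
            }
        )
    return pd.DataFrame(rows)
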