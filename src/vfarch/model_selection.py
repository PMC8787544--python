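"""Model-order selection by cross-validated, sample-size-normalized RSS.

The number of archetypes is chosen by 10-fold cross-validation: the rows of
the data matrix are partitioned into folds by a seeded shuffle, a model is
fitted on each training set for every candidate k, each held-out field is
decomposed onto the fitted archetypes, and the held-out residual sum of
squares is normalized by the number of held-out cells (rows x locations) so
curves are comparable across fold sizes.  The final k is the start of the
flattened region of the curve (automated elbow rule), mirroring the visual
selection practice this pipeline replaces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .archetypes import FitOptions, decompose_matrix, fit_archetypes

__all__ = ["RSSCurve", "cv_rss_curve", "select_num_archetypes"]


@dataclass
class RSSCurve:
    """Cross-validated RSS per candidate k (normalized per held-out cell)."""

    k_values: List[int]
    cv_rss: List[float]
    fold_rss: List[List[float]]
    folds: int
    seed: int
    errors: Dict[int, str] = field(default_factory=dict)
    models: Dict[int, list] = field(default_factory=dict)  # per-k fold models

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "k": self.k_values,
                "cv_rss": self.cv_rss,
                **{
                    f"fold_{i}": [row[i] for row in self.fold_rss]
                    for i in range(self.folds)
                },
            }
        )


def _fold_assignment(n: int, folds: int, seed: int) -> List[np.ndarray]:
    """Disjoint fold index sets; depends only on (n, folds, seed)."""
    perm = np.random.default_rng(seed).permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(perm, folds)]


def cv_rss_curve(
    X: np.ndarray,
    k_range: Sequence[int],
    folds: int = 10,
    seed: int = 0,
    opts: Optional[FitOptions] = None,
    keep_models: bool = False,
) -> RSSCurve:
    """Mean held-out RSS per cell for each candidate number of archetypes.

    Each fold serves as the test set once; held-out fields are decomposed by
    fresh simplex projection onto the archetypes fitted on the training
    folds.  Candidate k values exceeding a training-set size are recorded in
    ``errors`` and omitted from the curve.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if n < folds:
        raise ValueError(f"need at least {folds} rows for {folds}-fold CV")
    opts = opts or FitOptions()
    assignment = _fold_assignment(n, folds, seed)
    k_values, cv_rss, fold_rss = [], [], []
    errors: Dict[int, str] = {}
    models: Dict[int, list] = {}
    for k in k_range:
        per_fold = []
        kept = []
        try:
            for f, test_idx in enumerate(assignment):
                mask = np.ones(n, dtype=bool)
                mask[test_idx] = False
                X_train, X_test = X[mask], X[test_idx]
                if X_train.shape[0] < k:
                    raise ValueError(
                        f"k={k} exceeds training size {X_train.shape[0]}"
                    )
                fold_opts = FitOptions(
                    n_restarts=opts.n_restarts,
                    max_iter=opts.max_iter,
                    rel_tol=opts.rel_tol,
                    seed=opts.seed + 1000003 * f + 101 * k,
                    inner_iter=opts.inner_iter,
                )
                model = fit_archetypes(X_train, k, fold_opts)
                W = decompose_matrix(X_test, model) / 100.0
                resid = X_test - W @ model.archetype_td
                per_fold.append(float(np.einsum("ij,ij->", resid, resid)) / resid.size)
                if keep_models:
                    kept.append(model)
        except ValueError as exc:
            errors[k] = str(exc)
            continue
        k_values.append(int(k))
        fold_rss.append(per_fold)
        cv_rss.append(float(np.mean(per_fold)))
        if keep_models:
            models[int(k)] = kept
    return RSSCurve(
        k_values=k_values,
        cv_rss=cv_rss,
        fold_rss=fold_rss,
        folds=folds,
        seed=seed,
        errors=errors,
        models=models,
    )


def select_num_archetypes(curve: RSSCurve, epsilon: float = 0.05) -> int:
    """First k after which every relative CV-RSS improvement is below epsilon.

    Returns the smallest k such that for every subsequent consecutive pair
    (k_i, k_{i+1}) in the curve, (rss_i - rss_{i+1}) / rss_i < epsilon.  If
    the curve never flattens, returns the largest k with a warning.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if len(curve.k_values) < 3:
        raise ValueError("curve must contain at least 3 entries")
    rss = curve.cv_rss
    ks = curve.k_values
    m = len(ks)
    flat_after = m - 1
    for i in range(m - 2, -1, -1):
        improvement = (rss[i] - rss[i + 1]) / rss[i] if rss[i] > 0 else 0.0
        if improvement < epsilon:
            flat_after = i
        else:
            break
    if flat_after == m - 1:
        warnings.warn(
            "CV-RSS curve never flattens below epsilon; returning the largest k",
            stacklevel=2,
        )
        return ks[-1]
    return ks[flat_after]
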