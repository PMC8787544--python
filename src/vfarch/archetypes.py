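"""Archetypal analysis of total-deviation matrices.

The model approximates an n x p data matrix X (n visual fields, p analysis
locations) as X ~ A Z with Z = B X, where the rows of A live on the
k-simplex (each field is a convex combination of k archetypes) and the rows
of B live on the n-simplex (each archetype is a convex combination of
observed fields).  Fitting alternates two convex subproblems:

* coefficient step - for fixed archetypes Z, solve the simplex-constrained
  least-squares problem for every row of A simultaneously with an accelerated
  projected-gradient (FISTA) iteration;
* archetype step - for fixed A, compute the unconstrained least-squares
  archetypes and project each one back onto the convex hull of the data with
  an exact penalized non-negative least-squares solve.

The archetype projection may transiently raise the residual sum of squares,
so the fit keeps the incumbent best (A, B, Z) triple; the recorded RSS trace
is the incumbent's and is therefore non-increasing by construction.

Single-field decomposition (:func:`simplex_ls`, :func:`decompose`) always
uses the exact penalized-NNLS solve (Lawson-Hanson with a sum-to-one penalty
row of weight M = 200, then renormalization), so decomposing the same field
against the same model is deterministic to the bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from scipy.optimize import nnls

from .grids import VFDataError

__all__ = [
    "FitOptions",
    "ArchetypeModel",
    "simplex_ls",
    "decompose",
    "decompose_matrix",
    "fit_archetypes",
    "relative_weights",
    "avg_td",
]

#: Penalty weight enforcing the sum-to-one constraint in the NNLS realization.
SUM_PENALTY = 200.0


@dataclass(frozen=True)
class FitOptions:
    """Tunable fitting parameters (all positive)."""

    n_restarts: int = 5
    max_iter: int = 200
    rel_tol: float = 1e-6
    seed: int = 0
    inner_iter: int = 80  # FISTA iterations per coefficient step

    def __post_init__(self):
        if min(self.n_restarts, self.max_iter, self.inner_iter) < 1 or self.rel_tol <= 0:
            raise ValueError("FitOptions fields must be positive")


@dataclass
class ArchetypeModel:
    """A fitted k-archetype model, ordered by relative weight.

    Archetype number j (1-based ATj) is row ``j-1`` of ``archetype_td``;
    ``order`` records, for each AT number, the internal index the archetype
    had at fit time.  ``rw_percent`` sums to 100 and is non-increasing.
    """

    k: int
    archetype_td: np.ndarray  # (k, p)
    rw_percent: np.ndarray  # (k,)
    avg_td: np.ndarray  # (k,)
    order: np.ndarray  # (k,) AT number -> fit-time index
    fit_rss: float
    rss_trace: List[float] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    @property
    def p(self) -> int:
        return self.archetype_td.shape[1]

    def to_json(self, path) -> None:
        payload = {
            "k": self.k,
            "archetype_td": self.archetype_td.tolist(),
            "rw_percent": self.rw_percent.tolist(),
            "avg_td": self.avg_td.tolist(),
            "order": self.order.tolist(),
            "fit_rss": self.fit_rss,
            "rss_trace": list(self.rss_trace),
            "provenance": self.provenance,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ArchetypeModel":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(
            k=d["k"],
            archetype_td=np.asarray(d["archetype_td"], dtype=float),
            rw_percent=np.asarray(d["rw_percent"], dtype=float),
            avg_td=np.asarray(d["avg_td"], dtype=float),
            order=np.asarray(d["order"], dtype=int),
            fit_rss=d["fit_rss"],
            rss_trace=list(d["rss_trace"]),
            provenance=d.get("provenance", {}),
        )


def avg_td(archetype_td: np.ndarray) -> float:
    """Mean TD of one archetype pattern (dB); its severity index."""
    v = np.asarray(archetype_td, dtype=float)
    if v.size == 0:
        raise ValueError("empty archetype pattern")
    return float(v.mean())


def simplex_ls(target: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """Least-squares weights of ``target`` over ``basis`` rows on the simplex.

    Minimizes ``||target - w @ basis||`` subject to ``w >= 0`` and
    ``sum(w) = 1``, via NNLS on the system augmented with a sum-to-one
    penalty row, followed by exact renormalization.  Deterministic.
    """
    basis = np.atleast_2d(np.asarray(basis, dtype=float))
    target = np.asarray(target, dtype=float)
    k = basis.shape[0]
    if k == 0:
        raise ValueError("basis must contain at least one row")
    if not (np.all(np.isfinite(basis)) and np.all(np.isfinite(target))):
        raise VFDataError("non-finite values in simplex_ls input")
    A = np.vstack([basis.T, np.full((1, k), SUM_PENALTY)])
    b = np.concatenate([target, [SUM_PENALTY]])
    w, _ = nnls(A, b)
    s = w.sum()
    if s <= 0:  # pragma: no cover - cannot happen with the penalty row
        return np.full(k, 1.0 / k)
    return w / s


def decompose(td: np.ndarray, model: ArchetypeModel) -> np.ndarray:
    """Decompose one TD vector into AT weights in percent (sum = 100)."""
    td = np.asarray(td, dtype=float)
    if td.shape != (model.p,):
        raise ValueError(f"td has shape {td.shape}; model expects ({model.p},)")
    w = simplex_ls(td, model.archetype_td)
    return 100.0 * w


def decompose_matrix(X: np.ndarray, model: ArchetypeModel) -> np.ndarray:
    """Decompose each row of ``X``; returns an (n, k) percent matrix."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return np.vstack([decompose(row, model) for row in X])


# ---------------------------------------------------------------------------
# fitting internals
# ---------------------------------------------------------------------------


def _project_rows_to_simplex(V: np.ndarray) -> np.ndarray:
    """Euclidean projection of each row of V onto the probability simplex."""
    n, k = V.shape
    U = np.sort(V, axis=1)[:, ::-1]
    css = np.cumsum(U, axis=1) - 1.0
    idx = np.arange(1, k + 1)
    cond = U - css / idx > 0
    rho = k - 1 - np.argmax(cond[:, ::-1], axis=1)
    theta = css[np.arange(n), rho] / (rho + 1)
    return np.maximum(V - theta[:, None], 0.0)


def _fista_coefficients(
    G: np.ndarray, H: np.ndarray, W0: np.ndarray, n_iter: int, tol: float = 1e-7
) -> np.ndarray:
    """Minimize 0.5||T - W Z||^2 over simplex rows of W; G = T Z', H = Z Z'."""
    L = np.linalg.norm(H, 2) + 1e-12
    W = W0
    Y = W0.copy()
    t = 1.0
    for _ in range(n_iter):
        W_new = _project_rows_to_simplex(Y - (Y @ H - G) / L)
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        Y = W_new + ((t - 1.0) / t_new) * (W_new - W)
        step = np.abs(W_new - W).max()
        W, t = W_new, t_new
        if step < tol:
            break
    return W


def _rss(X: np.ndarray, A: np.ndarray, Z: np.ndarray) -> float:
    R = X - A @ Z
    return float(np.einsum("ij,ij->", R, R))


def _furthest_sum(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Greedy furthest-sum selection of k mutually distant rows.

    Starts from a random row, repeatedly adds the row maximizing the summed
    distance to the current selection, then discards the random starting row
    — a standard initialization for archetypal analysis that lands near the
    extreme points of the data cloud.
    """
    n = X.shape[0]
    sq = np.einsum("ij,ij->i", X, X)
    idx = [int(rng.integers(n))]
    sumd = np.zeros(n)
    for _ in range(k):
        last = idx[-1]
        d = np.sqrt(np.maximum(sq + sq[last] - 2.0 * (X @ X[last]), 0.0))
        sumd += d
        cand = sumd.copy()
        cand[idx] = -np.inf
        idx.append(int(np.argmax(cand)))
    return np.asarray(idx[1:], dtype=int)


def _fit_single(
    X: np.ndarray,
    k: int,
    rng: np.random.Generator,
    opts: FitOptions,
    init: str = "random",
):
    n, p = X.shape
    if init == "furthest-sum":
        idx = _furthest_sum(X, k, rng)
    else:
        idx = rng.choice(n, size=k, replace=False)
    B = np.zeros((k, n))
    B[np.arange(k), idx] = 1.0
    Z = B @ X
    A = _fista_coefficients(X @ Z.T, Z @ Z.T, np.full((n, k), 1.0 / k), opts.inner_iter)
    best = (_rss(X, A, Z), A, B, Z)
    trace = [best[0]]
    stall = 0
    for _ in range(opts.max_iter):
        Zhat, *_ = np.linalg.lstsq(A, X, rcond=None)
        B = np.vstack([simplex_ls(Zhat[j], X) for j in range(k)])
        Z = B @ X
        A = _fista_coefficients(X @ Z.T, Z @ Z.T, A, opts.inner_iter)
        r = _rss(X, A, Z)
        if r < best[0]:
            stall = stall + 1 if (best[0] - r) <= opts.rel_tol * best[0] else 0
            best = (r, A, B, Z)
        else:
            stall += 1
            _, A, B, Z = best
        trace.append(best[0])
        if stall >= 2:
            break
    return best, trace


def fit_archetypes(
    X: np.ndarray, k: int, opts: Optional[FitOptions] = None
) -> ArchetypeModel:
    """Fit a k-archetype model to the rows of X by alternating minimization.

    The best of ``opts.n_restarts`` random initializations (k distinct data
    rows each) is kept by final RSS.  The returned model is ordered by
    descending relative weight over X (see :func:`relative_weights`).
    """
    opts = opts or FitOptions()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if not np.all(np.isfinite(X)):
        raise VFDataError("data matrix contains non-finite values")
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < k:
        raise ValueError(f"need at least k={k} rows, got {n}")

    degenerate = bool(np.allclose(X, X[0]))
    seeds = np.random.SeedSequence(opts.seed).spawn(opts.n_restarts)
    best = None
    best_trace = None
    # first restart starts from mutually distant rows; the rest are random
    for i, ss in enumerate(seeds):
        init = "furthest-sum" if i == 0 else "random"
        (r, A, B, Z), trace = _fit_single(
            X, k, np.random.default_rng(ss), opts, init=init
        )
        if best is None or r < best[0]:
            best = (r, A, B, Z)
            best_trace = trace
    r, A, B, Z = best
    model = ArchetypeModel(
        k=k,
        archetype_td=Z,
        rw_percent=np.full(k, 100.0 / k),
        avg_td=Z.mean(axis=1),
        order=np.arange(k),
        fit_rss=r,
        rss_trace=best_trace,
        provenance={
            "n": int(n),
            "p": int(p),
            "n_restarts": opts.n_restarts,
            "max_iter": opts.max_iter,
            "rel_tol": opts.rel_tol,
            "inner_iter": opts.inner_iter,
            "seed": opts.seed,
            "degenerate": degenerate,
        },
    )
    return relative_weights(model, X, coefficients=A)


def relative_weights(
    model: ArchetypeModel,
    X: np.ndarray,
    coefficients: Optional[np.ndarray] = None,
) -> ArchetypeModel:
    """Compute relative weights of each archetype over X and renumber ATs.

    RW_j is the mean decomposition weight of archetype j across the rows of
    X, rescaled so the RWs sum to 100%.  ATs are renumbered in descending RW
    order (ties broken by ascending average TD, then fit-time index); AT1 is
    the most frequent pattern.  ``coefficients`` may supply precomputed
    decomposition weights (fractions, one row per row of X).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 0:
        raise ValueError("relative_weights requires a nonempty data matrix")
    if coefficients is None:
        coefficients = decompose_matrix(X, model) / 100.0
    mean_w = coefficients.mean(axis=0)
    rw = 100.0 * mean_w / mean_w.sum()
    av = model.archetype_td.mean(axis=1)
    # lexsort: last key is primary
    order = np.lexsort((np.arange(model.k), av, -rw))
    return ArchetypeModel(
        k=model.k,
        archetype_td=model.archetype_td[order],
        rw_percent=rw[order],
        avg_td=av[order],
        order=model.order[order],
        fit_rss=model.fit_rss,
        rss_trace=list(model.rss_trace),
        provenance=dict(model.provenance),
    )
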