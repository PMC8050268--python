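"""Nonnegative CP (CANDECOMP/PARAFAC) decomposition of EMG tensors.

The model approximates a nonnegative 3-way array ``X`` (muscles x
frames x trials) by a sum of R rank-1 components,

    X[i, j, k] ~ sum_r lambda_r * s[i, r] * t[j, r] * u[k, r],

with all factor entries nonnegative, each factor column unit Euclidean
norm and all scale absorbed into lambda_r. Fitting minimizes the halved
squared reconstruction error E by alternating multiplicative updates
(the Lee-Seung rule applied mode-wise to the matricized tensor), which
keeps factors nonnegative and never increases E. The number of
components is selected as the smallest rank whose best-restart
uncentered coefficient of determination,

    R^2 = 1 - sum((X - Xhat)^2) / sum(X^2),

reaches a threshold (0.80 by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import EMGTensor
from .exceptions import ConstraintError, DegenerateInputError

__all__ = [
    "CPModel",
    "RankScan",
    "fit_ntf",
    "reconstruct",
    "uncentered_r2",
    "select_rank",
    "parameter_count",
]

_EPS = 1e-12


@dataclass
class FitDiagnostics:
    objective: float
    n_iter: int
    restart_seed: int
    r2: float
    objective_history: np.ndarray
    converged: bool


@dataclass
class CPModel:
    """Fitted nonnegative CP model with unit-norm factor columns.

    Components are sorted by lambda descending; ties break on the lower
    argmax index of the spatial column. Degenerate (lambda = 0)
    components are dropped unless the whole model is degenerate.
    """

    spatial: np.ndarray   # (S, R)
    temporal: np.ndarray  # (T, R)
    trial: np.ndarray     # (K, R)
    lambdas: np.ndarray   # (R,)
    diagnostics: FitDiagnostics | None = field(default=None, compare=False)

    @property
    def rank(self) -> int:
        return self.lambdas.size

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.spatial.shape[0], self.temporal.shape[0],
                self.trial.shape[0])


def _as_array(X: EMGTensor | np.ndarray) -> np.ndarray:
    arr = X.X if isinstance(X, EMGTensor) else np.asarray(X, dtype=float)
    if arr.ndim != 3:
        raise ValueError("expected a 3-way array (muscles, frames, trials)")
    if np.any(arr < 0):
        raise ConstraintError("tensor must be nonnegative")
    return arr


def _mttkrp(X: np.ndarray, A: np.ndarray, B: np.ndarray, C: np.ndarray,
            mode: int) -> np.ndarray:
    if mode == 0:
        return np.einsum("ijk,jr,kr->ir", X, B, C, optimize=True)
    if mode == 1:
        return np.einsum("ijk,ir,kr->jr", X, A, C, optimize=True)
    return np.einsum("ijk,ir,jr->kr", X, A, B, optimize=True)


def _objective(norm_x2: float, X: np.ndarray, A: np.ndarray, B: np.ndarray,
               C: np.ndarray) -> float:
    gram = (A.T @ A) * (B.T @ B) * (C.T @ C)
    inner = float(np.sum(_mttkrp(X, A, B, C, 0) * A))
    return 0.5 * max(norm_x2 - 2.0 * inner + float(gram.sum()), 0.0)


def _mu_run(
    X: np.ndarray,
    init: tuple[np.ndarray, np.ndarray, np.ndarray],
    tol: float,
    max_iter: int,
) -> tuple[list[np.ndarray], np.ndarray, bool]:
    """One multiplicative-update run; returns factors, objective history
    and a convergence flag."""
    factors = [f.copy() for f in init]
    norm_x2 = float(np.sum(X * X))
    history = [_objective(norm_x2, X, *factors)]
    converged = False
    for _ in range(max_iter):
        for mode in range(3):
            A = factors[mode]
            others = [factors[m] for m in range(3) if m != mode]
            gram = (others[0].T @ others[0]) * (others[1].T @ others[1])
            num = _mttkrp(X, *factors, mode)
            den = A @ gram
            factors[mode] = A * num / np.maximum(den, _EPS)
        e = _objective(norm_x2, X, *factors)
        history.append(e)
        prev = history[-2]
        if prev - e < tol * max(prev, _EPS):
            converged = True
            break
    return factors, np.asarray(history), converged


def _normalize_and_sort(
    factors: list[np.ndarray],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Absorb column norms into lambdas, drop dead components, sort."""
    norms = [np.linalg.norm(f, axis=0) for f in factors]
    lam = norms[0] * norms[1] * norms[2]
    unit = [f / np.where(n > 0, n, 1.0) for f, n in zip(factors, norms)]
    alive = lam > 0
    if not alive.all():
        if alive.any():
            warnings.warn(
                f"dropping {int((~alive).sum())} degenerate component(s) "
                "with zero scale", stacklevel=3)
            unit = [f[:, alive] for f in unit]
            lam = lam[alive]
        else:  # fully degenerate model (e.g. all-zero tensor): keep as-is
            pass
    tie = np.argmax(unit[0], axis=0)
    order = sorted(range(lam.size), key=lambda r: (-lam[r], tie[r]))
    return (unit[0][:, order], unit[1][:, order], unit[2][:, order],
            lam[order])


def fit_ntf(
    X: EMGTensor | np.ndarray,
    rank: int,
    restarts: int = 10,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 2000,
    extra_inits: list[tuple[np.ndarray, np.ndarray, np.ndarray]] | None = None,
) -> CPModel:
    """Fit a rank-``R`` nonnegative CP model by multiplicative updates.

    The best of ``restarts`` seeded uniform(0, 1] initializations (plus
    any ``extra_inits``, e.g. warm starts from a lower-rank fit) is kept;
    factors are then column-normalized with scale absorbed into lambda
    and components sorted by lambda descending.
    """
    arr = _as_array(X)
    S, T, K = arr.shape
    if rank < 1:
        raise ValueError(f"rank must be >= 1, got {rank}")
    if rank > min(S * T, S * K, T * K):
        raise ValueError(f"rank {rank} exceeds the maximal CP rank bound")

    root = np.random.default_rng(seed)
    best: tuple[float, list[np.ndarray], np.ndarray, bool, int] | None = None
    runs: list[tuple[int, tuple[np.ndarray, np.ndarray, np.ndarray]]] = []
    for i in range(restarts):
        rng = np.random.default_rng(root.integers(2 ** 31))
        init = tuple(
            1.0 - rng.random((dim, rank)) for dim in (S, T, K))  # uniform (0, 1]
        runs.append((i, init))
    for j, init in enumerate(extra_inits or []):
        runs.append((restarts + j, tuple(np.asarray(f, dtype=float) for f in init)))

    for run_id, init in runs:
        factors, history, converged = _mu_run(arr, init, tol, max_iter)
        e = history[-1]
        if best is None or e < best[0]:
            best = (float(e), factors, history, converged, run_id)

    e, factors, history, converged, run_id = best
    s, t, u, lam = _normalize_and_sort(factors)
    norm_x2 = float(np.sum(arr * arr))
    r2 = 1.0 - 2.0 * e / norm_x2 if norm_x2 > 0 else 1.0
    diag = FitDiagnostics(
        objective=e, n_iter=len(history) - 1, restart_seed=run_id,
        r2=max(min(r2, 1.0), 0.0), objective_history=history,
        converged=converged)
    return CPModel(spatial=s, temporal=t, trial=u, lambdas=lam,
                   diagnostics=diag)


def reconstruct(model: CPModel) -> np.ndarray:
    """Exact multilinear expansion sum_r lambda_r s_r o t_r o u_r."""
    return np.einsum("r,ir,jr,kr->ijk", model.lambdas, model.spatial,
                     model.temporal, model.trial)


def uncentered_r2(X: EMGTensor | np.ndarray, Xhat: np.ndarray) -> float:
    """Uncentered coefficient of determination, clipped below at 0."""
    arr = X.X if isinstance(X, EMGTensor) else np.asarray(X, dtype=float)
    denom = float(np.sum(arr * arr))
    if denom == 0.0:
        raise DegenerateInputError("uncentered R^2 undefined for all-zero data")
    resid = float(np.sum((arr - Xhat) ** 2))
    return max(1.0 - resid / denom, 0.0)


@dataclass
class RankScan:
    """Variance-explained curve over candidate ranks and the selected rank."""

    ranks: np.ndarray
    r2: np.ndarray
    selected_rank: int
    threshold: float
    reached: bool
    models: list[CPModel] = field(default=None, compare=False, repr=False)

    def model(self, rank: int | None = None) -> CPModel:
        """Best fitted model at ``rank`` (default: the selected rank)."""
        rank = self.selected_rank if rank is None else rank
        return self.models[int(np.flatnonzero(self.ranks == rank)[0])]

    def select(self, threshold: float) -> tuple[int, bool]:
        """Smallest scanned rank whose R^2 reaches ``threshold``."""
        hit = np.flatnonzero(self.r2 >= threshold)
        if hit.size:
            return int(self.ranks[hit[0]]), True
        return int(self.ranks[-1]), False


def select_rank(
    X: EMGTensor | np.ndarray,
    threshold: float = 0.80,
    r_max: int = 20,
    restarts: int = 10,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 2000,
    nested_init: bool = True,
    full_scan: bool = False,
) -> RankScan:
    """Scan ranks 1..r_max and select the smallest reaching ``threshold``.

    With ``nested_init`` each rank adds one warm-start candidate built
    from the previous rank's best factors plus a small random column,
    which makes the best-restart R^2 curve nondecreasing in rank.
    If no rank reaches the threshold, the scan returns ``r_max`` with
    ``reached=False``. The scan stops at the first rank reaching the
    threshold unless ``full_scan`` forces the whole curve.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    arr = _as_array(X)
    ranks = np.arange(1, r_max + 1)
    r2s, models = [], []
    prev: CPModel | None = None
    rng = np.random.default_rng(np.random.default_rng(seed).integers(2 ** 31))
    for rank in ranks:
        extra = None
        if nested_init and prev is not None and prev.rank == rank - 1:
            # previous best fit plus one small random column: the warm
            # start begins within a whisker of the lower rank's optimum
            scale = 1e-3 * max(float(prev.lambdas.min(initial=1.0)), _EPS)
            S_, T_, K_ = arr.shape
            extra = [(
                np.hstack([prev.spatial * prev.lambdas,
                           scale * rng.random((S_, 1))]),
                np.hstack([prev.temporal, rng.random((T_, 1))]),
                np.hstack([prev.trial, rng.random((K_, 1))]),
            )]
        model = fit_ntf(arr, int(rank), restarts=restarts, seed=seed + int(rank),
                        tol=tol, max_iter=max_iter, extra_inits=extra)
        r2s.append(model.diagnostics.r2)
        models.append(model)
        prev = model
        if model.diagnostics.r2 >= threshold and not full_scan:
            break
    scanned = ranks[: len(r2s)]
    r2s = np.asarray(r2s)
    hit = np.flatnonzero(r2s >= threshold)
    if hit.size:
        selected, reached = int(scanned[hit[0]]), True
    else:
        selected, reached = int(scanned[-1]), False
    return RankScan(ranks=scanned, r2=r2s, selected_rank=selected,
                    threshold=threshold, reached=reached, models=models)


_LAYOUTS = {
    "cp": lambda s, t, k, r: r * (s + t + k),
    "nnmf_shared_spatial": lambda s, t, k, r: r * s + r * t * k,
    "nnmf_per_trial": lambda s, t, k, r: (r * s + r * t) * k,
}


def parameter_count(S: int, T: int, K: int, R: int, layout: str = "cp") -> int:
    """Free-parameter count of a factorization layout.

    ``cp`` shares one spatial, temporal and trial factor across the whole
    tensor (R(S+T+K)); ``nnmf_shared_spatial`` shares spatial modules but
    fits each trial's time courses (RS + RTK); ``nnmf_per_trial`` fits
    spatial and temporal modules per trial ((RS + RT)K).
    """
    if min(S, T, K, R) < 1:
        raise ValueError("S, T, K, R must be positive integers")
    try:
        return int(_LAYOUTS[layout](S, T, K, R))
    except KeyError:
        raise ValueError(
            f"unknown layout {layout!r}; expected one of {sorted(_LAYOUTS)}"
        ) from None
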