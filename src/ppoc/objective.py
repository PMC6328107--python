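"""Prior-probability-oriented clustering (PPOC).

Standard codebook clusterings (k-means, GMM) minimize a quantization or
likelihood criterion and leave the cluster prior probabilities w_k — the
fraction of samples each codeword absorbs — to fall where they may.  For
feature encoding, strongly unequal priors are a liability: components with
near-zero prior contribute nothing (or constant blocks) to the encoded
signatures, shrinking the effective codebook.  PPOC instead minimizes

    J = sum_k |w_k - 1/K|  +  lambda * (1/T) * sum_t d(x_t; Theta)^2

over the K*d mean coordinates, where the first ("main") term is an L1
surrogate for the variance of the priors — zero exactly when every cluster
holds the same fraction of samples — and d(x_t; Theta) is a quantization
regularizer that smooths the otherwise piecewise-constant landscape.  With
the default lambda = 1e-9 the regularizer only breaks ties.

Two variants mirror the two baseline clusterings:

* hard mode — d is the Euclidean distance to the nearest mean; the result
  is a ``HardCodebook``, a drop-in for k-means;
* soft mode — samples are hard-assigned (a peaky-posterior approximation),
  per-cluster weights and diagonal variances are estimated from the
  assignment, and d is the Mahalanobis distance under those variances; the
  result is a ``GaussianCodebook``, a drop-in for the GMM.

Because J is non-differentiable (the priors are counts), minimization uses
derivative-free search with a fixed evaluation budget and best-ever-seen
tracking.  The workhorse backend is a Subplex-style method: cyclic
Nelder-Mead over small subspaces of coordinates, re-partitioned by recent
progress — far more effective than one full-dimensional simplex when K*d
is large.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .clustering import VARIANCE_FLOOR, hard_assign, kmeans_fit
from .data import GaussianCodebook, HardCodebook, SampleSet

__all__ = [
    "ObjectiveConfig",
    "OptimizerResult",
    "main_objective_term",
    "priors_from_hard_assignment",
    "hard_regularizer",
    "estimate_soft_params",
    "soft_regularizer",
    "objective",
    "objective_components",
    "minimize_derivative_free",
    "fit_ppoc",
    "OPTIMIZERS",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ObjectiveConfig:
    """Settings of the composite objective.

    mode
        "hard" (k-means alternative, Euclidean regularizer) or "soft"
        (GMM alternative, Mahalanobis regularizer).
    lam
        Weight of the regularization term; small by design so the prior
        balance dominates.
    K
        Number of clusters; the target prior is 1/K for every cluster.
    floor
        Lower bound applied to every estimated variance (soft mode).
    square_regularizer
        The composite objective squares d(x_t); in soft mode d is itself
        already a squared Mahalanobis form, and this switch controls
        whether that outer squaring is applied literally (default) or not.
    variance_about_centroid
        Soft-mode variances are second moments about the candidate mean
        being evaluated (default) or, alternatively, about the centroid of
        the assigned samples.
    """

    mode: str
    K: int
    lam: float = 1e-9
    floor: float = VARIANCE_FLOOR
    square_regularizer: bool = True
    variance_about_centroid: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("hard", "soft"):
            raise ValueError(f"mode must be 'hard' or 'soft', got {self.mode!r}")
        if self.lam < 0:
            raise ValueError("lambda must be nonnegative")
        if self.K < 1:
            raise ValueError("K must be at least 1")

    @property
    def w_bar(self) -> float:
        """Mean prior under the probabilistic constraint: always 1/K."""
        return 1.0 / self.K


@dataclass
class OptimizerResult:
    """Outcome of a budgeted derivative-free minimization."""

    best_flat_means: np.ndarray
    best_objective: float
    n_evals: int
    trace: list  # (eval index, objective) at every improvement
    trial_seed: Optional[int] = None


def main_objective_term(priors: np.ndarray) -> float:
    """L1 spread of the priors around their target 1/K.

    Zero iff the priors are uniform; at most 2(K-1)/K (all mass on one
    cluster).  Raises if the priors are not a normalized distribution.
    """
    priors = np.asarray(priors, dtype=float).ravel()
    if (priors < -1e-12).any():
        raise ValueError("priors must be nonnegative")
    if abs(priors.sum() - 1.0) > 1e-6:
        raise ValueError(f"priors must sum to 1, got {priors.sum()!r}")
    K = priors.shape[0]
    return float(np.abs(priors - 1.0 / K).sum())


def priors_from_hard_assignment(assignment: np.ndarray, K: int) -> np.ndarray:
    """Occupancy fractions w_k = (#assigned to k) / T; empty cluster -> 0."""
    assignment = np.asarray(assignment, dtype=int).ravel()
    counts = np.bincount(assignment, minlength=K)
    return counts / assignment.shape[0]


def hard_regularizer(samples: SampleSet, means: np.ndarray) -> float:
    """Mean squared Euclidean distance to the nearest mean, (1/T) sum_t d_t^2."""
    means = np.atleast_2d(np.asarray(means, dtype=float))
    if means.shape[1] != samples.d:
        raise ValueError("dimension mismatch between samples and means")
    diff2 = _nearest_sq_dists(samples.points, means)
    return float(diff2.mean())


def _nearest_sq_dists(points: np.ndarray, means: np.ndarray) -> np.ndarray:
    from scipy.spatial.distance import cdist

    return cdist(points, means, metric="sqeuclidean").min(axis=1)


def estimate_soft_params(
    samples: SampleSet, means: np.ndarray, floor: float = VARIANCE_FLOOR
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cluster weights and diagonal variances under hard assignment.

    Samples are assigned to their nearest candidate mean; w_k is the
    occupancy fraction and the variance of cluster k is the per-dimension
    second moment of its samples about the candidate mean, floored at
    ``floor``.  An empty cluster gets w_k = 0 and floor variances.
    """
    means = np.atleast_2d(np.asarray(means, dtype=float))
    assign = hard_assign(samples, means)
    K, d = means.shape
    pts = samples.points
    priors = priors_from_hard_assignment(assign, K)
    variances = np.full((K, d), floor)
    for k in range(K):
        mask = assign == k
        if mask.any():
            second_moment = ((pts[mask] - means[k]) ** 2).mean(axis=0)
            variances[k] = np.maximum(second_moment, floor)
    return priors, variances


def soft_regularizer(
    samples: SampleSet,
    means: np.ndarray,
    variances: np.ndarray,
    square: bool = True,
) -> float:
    """Mean (squared) Mahalanobis quantization error under hard assignment.

    d_t is the squared Mahalanobis distance from x_t to its assigned mean
    under that component's diagonal variances; the composite objective then
    squares d_t again (``square=True``, the literal form) or uses it as is.
    """
    means = np.atleast_2d(np.asarray(means, dtype=float))
    variances = np.atleast_2d(np.asarray(variances, dtype=float))
    if means.shape[1] != samples.d:
        raise ValueError("dimension mismatch between samples and means")
    if (variances <= 0).any():
        raise ValueError("variances must be strictly positive")
    assign = hard_assign(samples, means)
    diff = samples.points - means[assign]
    d_t = np.sum(diff**2 / variances[assign], axis=1)
    if square:
        d_t = d_t**2
    return float(d_t.mean())


def objective_components(
    samples: SampleSet, flat_means: np.ndarray, config: ObjectiveConfig
) -> tuple[float, float, float]:
    """Evaluate the composite objective; returns (J, main term, regularizer).

    Non-finite candidate means yield J = +inf (an optimizer-safe sentinel).
    """
    flat_means = np.asarray(flat_means, dtype=float).ravel()
    if flat_means.shape[0] % config.K != 0:
        raise ValueError(
            f"flat means length {flat_means.shape[0]} is not a multiple of K={config.K}"
        )
    if not np.isfinite(flat_means).all():
        logger.debug("objective: non-finite candidate means")
        return float("inf"), float("inf"), float("inf")
    d = flat_means.shape[0] // config.K
    means = flat_means.reshape(config.K, d)
    if config.mode == "hard":
        assign = hard_assign(samples, means)
        priors = priors_from_hard_assignment(assign, config.K)
        reg = hard_regularizer(samples, means)
    else:
        if config.variance_about_centroid:
            assign = hard_assign(samples, means)
            priors = priors_from_hard_assignment(assign, config.K)
            variances = np.full((config.K, d), config.floor)
            for k in range(config.K):
                mask = assign == k
                if mask.any():
                    centroid = samples.points[mask].mean(axis=0)
                    variances[k] = np.maximum(
                        ((samples.points[mask] - centroid) ** 2).mean(axis=0), config.floor
                    )
        else:
            priors, variances = estimate_soft_params(samples, means, config.floor)
        reg = soft_regularizer(samples, means, variances, square=config.square_regularizer)
    main = main_objective_term(priors)
    return main + config.lam * reg, main, reg


def objective(samples: SampleSet, flat_means: np.ndarray, config: ObjectiveConfig) -> float:
    """Composite objective J = main term + lambda * regularizer."""
    return objective_components(samples, flat_means, config)[0]


# ---------------------------------------------------------------------------
# Budgeted derivative-free minimization


class _BudgetExhausted(Exception):
    pass


class _Tracker:
    """Counts evaluations, enforces the budget, and keeps the best point seen."""

    def __init__(self, f: Callable[[np.ndarray], float], budget: int):
        self.f = f
        self.budget = budget
        self.n_evals = 0
        self.best_x: Optional[np.ndarray] = None
        self.best_f = float("inf")
        self.trace: list[tuple[int, float]] = []

    def __call__(self, x: np.ndarray) -> float:
        if self.n_evals >= self.budget:
            raise _BudgetExhausted
        x = np.asarray(x, dtype=float)
        fx = self.f(x)
        if not np.isfinite(fx):
            fx = float("inf")
        self.n_evals += 1
        if fx < self.best_f:
            self.best_f = float(fx)
            self.best_x = x.copy()
            self.trace.append((self.n_evals, self.best_f))
        return fx


def _run_neldermead(tracker: _Tracker, x0: np.ndarray) -> None:
    try:
        _scipy_minimize(
            tracker,
            x0,
            method="Nelder-Mead",
            options={
                "maxfev": tracker.budget,
                "xatol": 1e-12,
                "fatol": 1e-14,
                "adaptive": x0.shape[0] > 8,
            },
        )
    except _BudgetExhausted:
        pass


def _run_cobyla(tracker: _Tracker, x0: np.ndarray) -> None:
    try:
        _scipy_minimize(
            tracker,
            x0,
            method="COBYLA",
            options={"maxiter": tracker.budget, "rhobeg": 0.1, "tol": 1e-12},
        )
    except _BudgetExhausted:
        pass


def _run_powell(tracker: _Tracker, x0: np.ndarray) -> None:
    try:
        _scipy_minimize(
            tracker,
            x0,
            method="Powell",
            options={"maxfev": tracker.budget, "xtol": 1e-10, "ftol": 1e-12},
        )
    except _BudgetExhausted:
        pass


def _nm_subspace(
    tracker: _Tracker,
    x: np.ndarray,
    coords: np.ndarray,
    step: np.ndarray,
    maxfev: int,
) -> np.ndarray:
    """One Nelder-Mead pass restricted to ``coords``; returns the updated x."""
    base = x.copy()

    def f_sub(y: np.ndarray) -> float:
        z = base.copy()
        z[coords] = y
        return tracker(z)

    y0 = base[coords]
    ns = coords.shape[0]
    simplex = np.tile(y0, (ns + 1, 1))
    for i in range(ns):
        simplex[i + 1, i] += step[coords[i]]
    try:
        _scipy_minimize(
            f_sub,
            y0,
            method="Nelder-Mead",
            options={
                "initial_simplex": simplex,
                "maxfev": maxfev,
                "xatol": 1e-10,
                "fatol": 1e-12,
            },
        )
    except _BudgetExhausted:
        pass
    if tracker.best_x is not None and tracker.best_f < np.inf:
        return tracker.best_x.copy()
    return base


def _run_subplex(tracker: _Tracker, x0: np.ndarray, seed: Optional[int] = None) -> None:
    """Subspace-searching simplex: cyclic Nelder-Mead over small coordinate blocks.

    The coordinates are partitioned into blocks of at most ``nsmax``; each
    block is minimized by a short Nelder-Mead run while the others are held
    fixed.  After a full cycle the blocks are re-ordered by the magnitude of
    the progress each coordinate made, and the per-coordinate step sizes are
    rescaled toward that progress (shrinking when a cycle stalls).
    """
    n = x0.shape[0]
    nsmax = min(5, n)
    x = x0.copy()
    step = np.full(n, 0.1)
    progress = np.ones(n)
    psi = 0.5  # shrink factor on a stalled cycle
    inner_fev = max(10 * (nsmax + 1), 20)
    while tracker.n_evals < tracker.budget:
        order = np.argsort(-np.abs(progress), kind="stable")
        blocks = [order[i : i + nsmax] for i in range(0, n, nsmax)]
        x_before = x.copy()
        f_before = tracker.best_f
        for coords in blocks:
            if tracker.n_evals >= tracker.budget:
                return
            remaining = tracker.budget - tracker.n_evals
            x = _nm_subspace(tracker, x, coords, step, min(inner_fev, remaining))
        dx = x - x_before
        progress = dx if np.any(dx != 0) else progress
        if tracker.best_f >= f_before:  # stalled cycle
            step *= psi
            if np.max(step) < 1e-12:
                step = np.full(n, 0.1)
        else:
            step = np.clip(np.maximum(np.abs(dx), psi * step), 1e-10, 1.0)


OPTIMIZERS: dict[str, Callable] = {
    "neldermead": _run_neldermead,
    "subplex": _run_subplex,
    "cobyla": _run_cobyla,
    "powell": _run_powell,
}


def minimize_derivative_free(
    f: Callable[[np.ndarray], float],
    x0: np.ndarray,
    budget: int,
    algorithm: str = "subplex",
    seed: Optional[int] = None,
) -> OptimizerResult:
    """Minimize ``f`` with at most ``budget`` evaluations; returns the best seen.

    The starting point is always evaluated first, so the reported optimum is
    never worse than f(x0).  With ``budget=1`` the result is exactly x0.
    """
    if budget < 1:
        raise ValueError("budget must be at least 1")
    algorithm = algorithm.lower()
    if algorithm not in OPTIMIZERS:
        raise ValueError(
            f"unknown algorithm {algorithm!r}; available: {sorted(OPTIMIZERS)}"
        )
    x0 = np.asarray(x0, dtype=float).ravel()
    tracker = _Tracker(f, budget)
    tracker(x0)
    if tracker.n_evals < budget:
        if algorithm == "subplex":
            _run_subplex(tracker, x0, seed=seed)
        else:
            OPTIMIZERS[algorithm](tracker, x0)
    return OptimizerResult(
        best_flat_means=tracker.best_x,
        best_objective=tracker.best_f,
        n_evals=tracker.n_evals,
        trace=tracker.trace,
        trial_seed=seed,
    )


# ---------------------------------------------------------------------------
# Full fitting protocol


def fit_ppoc(
    samples: SampleSet,
    K: int,
    config: Optional[ObjectiveConfig] = None,
    optimizer: str = "subplex",
    budget: int = 2000,
    warmstart_iters: int = 10,
    trials: int = 5,
    seeds: Optional[Sequence[int]] = None,
    mode: str = "hard",
    lam: float = 1e-9,
):
    """Fit a balanced-prior codebook: warm start + budgeted black-box search.

    Per trial: k-means++ seeding, ``warmstart_iters`` Lloyd iterations, then
    ``budget`` objective evaluations of the selected derivative-free
    algorithm from the flattened warm-start means.  The best trial by
    objective wins.  Hard mode returns a :class:`HardCodebook`; soft mode a
    :class:`GaussianCodebook` with the estimated weights and floored
    diagonal variances.  Returns ``(codebook, OptimizerResult)``.
    """
    if config is None:
        config = ObjectiveConfig(mode=mode, K=K, lam=lam)
    if config.K != K:
        config = replace(config, K=K)
    if seeds is None:
        seeds = list(range(trials))
    best: Optional[OptimizerResult] = None
    for seed in seeds:
        warm, _ = kmeans_fit(samples, K, max_iter=warmstart_iters, seed=seed)
        x0 = warm.means.ravel()
        result = minimize_derivative_free(
            lambda v: objective(samples, v, config),
            x0,
            budget=budget,
            algorithm=optimizer,
            seed=seed,
        )
        j, j_main, j_reg = objective_components(samples, result.best_flat_means, config)
        logger.info(
            "fit_ppoc trial seed=%d J=%.6g J_main=%.6g J_reg=%.6g evals=%d",
            seed, j, j_main, j_reg, result.n_evals,
        )
        if best is None or result.best_objective < best.best_objective:
            best = result
    assert best is not None
    means = best.best_flat_means.reshape(K, samples.d)
    j, j_main, j_reg = objective_components(samples, best.best_flat_means, config)
    meta = {
        "method": f"ppoc-{config.mode}",
        "optimizer": optimizer,
        "lambda": config.lam,
        "seed": best.trial_seed,
        "objective_value": j,
        "J_main": j_main,
        "J_reg": j_reg,
        "n_evals": best.n_evals,
    }
    if config.mode == "hard":
        assign = hard_assign(samples, means)
        priors = priors_from_hard_assignment(assign, K)
        codebook = HardCodebook(means=means, priors=priors, meta=meta)
    else:
        priors, variances = estimate_soft_params(samples, means, config.floor)
        weights = priors.copy()
        if weights.sum() <= 0:
            weights = np.full(K, 1.0 / K)
        elif abs(weights.sum() - 1.0) > 1e-12:
            weights = weights / weights.sum()
        codebook = GaussianCodebook(means=means, variances=variances, weights=weights, meta=meta)
    return codebook, best
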