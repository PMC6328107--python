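"""Baseline clusterings: k-means (Lloyd) and diagonal-covariance GMM (EM).

These serve both as reference methods and as building blocks for the
balanced-prior objective: k-means++ seeding and a short Lloyd warm start
initialize the derivative-free search, and the hard nearest-cluster
assignment is reused by the objective and by the encoders.

All randomness flows through explicit integer seeds; identical inputs and
seed give bitwise-identical results.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist
from scipy.special import logsumexp

from .data import GaussianCodebook, HardCodebook, SampleSet

__all__ = [
    "kmeanspp_init",
    "hard_assign",
    "kmeans_quantization_error",
    "kmeans_fit",
    "gaussian_logpdf",
    "gmm_posteriors",
    "gmm_fit",
    "count_distinct_components",
    "VARIANCE_FLOOR",
]

logger = logging.getLogger(__name__)

#: Default floor applied to every diagonal variance entry.
VARIANCE_FLOOR = 1e-6


def kmeanspp_init(samples: SampleSet, K: int, seed: int) -> np.ndarray:
    """Choose K starting means from the samples by k-means++ D² weighting.

    The first center is drawn uniformly; each subsequent one is drawn with
    probability proportional to its squared distance to the nearest center
    already chosen.  Returns a K x d matrix of (distinct) sample rows.
    """
    pts = samples.points
    T = pts.shape[0]
    if K > T:
        raise ValueError(f"K={K} exceeds the number of samples T={T}")
    rng = np.random.default_rng(seed)
    centers = np.empty((K, pts.shape[1]), dtype=float)
    idx = int(rng.integers(T))
    centers[0] = pts[idx]
    taken = {idx}
    d2 = np.sum((pts - centers[0]) ** 2, axis=1)
    for k in range(1, K):
        d2[list(taken)] = 0.0
        total = d2.sum()
        if total > 0:
            probs = d2 / total
            idx = int(rng.choice(T, p=probs))
        else:
            # all remaining mass at distance zero (duplicate points):
            # fall back to a uniform draw over untaken rows
            free = np.setdiff1d(np.arange(T), sorted(taken))
            idx = int(rng.choice(free))
        centers[k] = pts[idx]
        taken.add(idx)
        d2 = np.minimum(d2, np.sum((pts - centers[k]) ** 2, axis=1))
    return centers


def hard_assign(samples: SampleSet, means: np.ndarray) -> np.ndarray:
    """Map every sample to its Euclidean-nearest mean (ties -> lowest index)."""
    means = np.atleast_2d(np.asarray(means, dtype=float))
    if means.shape[1] != samples.d:
        raise ValueError(
            f"dimension mismatch: samples have d={samples.d}, means d={means.shape[1]}"
        )
    d2 = cdist(samples.points, means, metric="sqeuclidean")
    return np.argmin(d2, axis=1)


def kmeans_quantization_error(samples: SampleSet, means: np.ndarray) -> float:
    """Sum over samples of the squared distance to the assigned (nearest) mean."""
    means = np.atleast_2d(np.asarray(means, dtype=float))
    if means.shape[1] != samples.d:
        raise ValueError("dimension mismatch between samples and means")
    d2 = cdist(samples.points, means, metric="sqeuclidean")
    return float(d2.min(axis=1).sum())


def kmeans_fit(
    samples: SampleSet,
    K: int,
    max_iter: int = 100,
    seed: int = 0,
) -> tuple[HardCodebook, dict]:
    """Lloyd's algorithm from a k-means++ start.

    Returns the fitted codebook (means plus occupancy priors) and an info
    dict with the per-iteration quantization-error trace, the final
    assignment, and the iteration count.  An empty cluster is repaired by
    relocating its mean to the sample farthest from its current center.
    """
    pts = samples.points
    T = pts.shape[0]
    means = kmeanspp_init(samples, K, seed)
    errors: list[float] = []
    assign = hard_assign(samples, means)
    for it in range(max_iter):
        errors.append(kmeans_quantization_error(samples, means))
        new_means = means.copy()
        for k in range(K):
            mask = assign == k
            if mask.any():
                new_means[k] = pts[mask].mean(axis=0)
            else:
                d2 = cdist(pts, new_means, metric="sqeuclidean").min(axis=1)
                far = int(np.argmax(d2))
                new_means[k] = pts[far]
                logger.debug("kmeans_fit: empty cluster %d re-seeded at sample %d", k, far)
        new_assign = hard_assign(samples, new_means)
        means = new_means
        if np.array_equal(new_assign, assign):
            assign = new_assign
            break
        assign = new_assign
    errors.append(kmeans_quantization_error(samples, means))
    counts = np.bincount(assign, minlength=K)
    priors = counts / T
    codebook = HardCodebook(means=means, priors=priors, meta={"seed": seed})
    info = {"errors": errors, "assignment": assign, "n_iter": len(errors) - 1}
    return codebook, info


def gaussian_logpdf(x: np.ndarray, mean: np.ndarray, variances: np.ndarray) -> float:
    """Log density of a diagonal-covariance multivariate normal at ``x``."""
    x = np.asarray(x, dtype=float).ravel()
    mean = np.asarray(mean, dtype=float).ravel()
    variances = np.asarray(variances, dtype=float).ravel()
    if (variances <= 0).any():
        raise ValueError("variances must be strictly positive")
    z2 = ((x - mean) ** 2) / variances
    return float(-0.5 * (np.sum(np.log(2.0 * np.pi * variances)) + z2.sum()))


def _component_logpdfs(points: np.ndarray, codebook: GaussianCodebook) -> np.ndarray:
    """T x K matrix of per-component diagonal-normal log densities."""
    var = codebook.variances  # K x d
    diff = points[:, None, :] - codebook.means[None, :, :]  # T x K x d
    z2 = np.sum(diff**2 / var[None, :, :], axis=2)
    const = np.sum(np.log(2.0 * np.pi * var), axis=1)  # K
    return -0.5 * (const[None, :] + z2)


def gmm_posteriors(samples: SampleSet, codebook: GaussianCodebook) -> np.ndarray:
    """Responsibilities q_{t,k} = w_k p_k(x_t) / sum_j w_j p_j(x_t).

    Computed with log-sum-exp, so rows never underflow to zero.
    """
    if samples.d != codebook.d:
        raise ValueError("dimension mismatch between samples and codebook")
    log_p = _component_logpdfs(samples.points, codebook)
    log_w = np.log(codebook.weights)
    log_joint = log_p + log_w[None, :]
    return np.exp(log_joint - logsumexp(log_joint, axis=1, keepdims=True))


def gmm_fit(
    samples: SampleSet,
    K: int,
    max_iter: int = 100,
    seed: int = 0,
    floor: float = VARIANCE_FLOOR,
) -> tuple[GaussianCodebook, dict]:
    """EM for a diagonal-covariance GMM, initialized from a k-means fit.

    Variances are floored at ``floor`` after every M step.  Returns the
    codebook and an info dict with the per-iteration mean log-likelihood
    trace (non-decreasing except where the floor fires).
    """
    pts = samples.points
    T, d = pts.shape
    km, km_info = kmeans_fit(samples, K, max_iter=10, seed=seed)
    assign = km_info["assignment"]
    means = km.means.copy()
    variances = np.empty((K, d))
    weights = np.empty(K)
    for k in range(K):
        mask = assign == k
        weights[k] = max(mask.mean(), 1.0 / T)
        if mask.any():
            variances[k] = np.maximum(pts[mask].var(axis=0), floor)
        else:
            variances[k] = np.maximum(pts.var(axis=0), floor)
    weights = weights / weights.sum()

    loglik: list[float] = []
    cb = GaussianCodebook(means=means, variances=variances, weights=weights)
    for _ in range(max_iter):
        log_p = _component_logpdfs(pts, cb)
        log_joint = log_p + np.log(cb.weights)[None, :]
        lse = logsumexp(log_joint, axis=1)
        loglik.append(float(lse.mean()))
        gamma = np.exp(log_joint - lse[:, None])  # T x K
        nk = gamma.sum(axis=0)  # K
        new_weights = nk / T
        degenerate = new_weights < 1e-12
        safe_nk = np.where(nk > 0, nk, 1.0)
        new_means = (gamma.T @ pts) / safe_nk[:, None]
        new_vars = np.empty_like(cb.variances)
        for k in range(K):
            diff = pts - new_means[k]
            new_vars[k] = (gamma[:, k] @ (diff**2)) / safe_nk[k]
        if degenerate.any():
            for k in np.nonzero(degenerate)[0]:
                logger.warning("gmm_fit: degenerate component %d, variance reset to floor", k)
                new_vars[k] = floor
        new_vars = np.maximum(new_vars, floor)
        new_weights = np.maximum(new_weights, 0.0)
        new_weights = new_weights / new_weights.sum()
        converged = (
            np.allclose(new_means, cb.means, atol=1e-10)
            and np.allclose(new_vars, cb.variances, atol=1e-10)
            and np.allclose(new_weights, cb.weights, atol=1e-12)
        )
        cb = GaussianCodebook(means=new_means, variances=new_vars, weights=new_weights)
        if converged:
            break
    cb.meta.update({"seed": seed})
    return cb, {"loglik": loglik, "n_iter": len(loglik)}


def count_distinct_components(means: np.ndarray, tol: float) -> int:
    """Number of groups of means under single-linkage merging at distance tol.

    Two means closer than ``tol`` belong to the same group; groups are the
    connected components of the resulting proximity graph.  Used to count
    how many effectively distinct codewords a fitted mixture retains.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    means = np.atleast_2d(np.asarray(means, dtype=float))
    dist = cdist(means, means)
    adjacency = (dist < tol).astype(int)
    n, _ = connected_components(adjacency, directed=False)
    return int(n)
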