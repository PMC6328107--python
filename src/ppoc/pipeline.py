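"""End-to-end harness: PCA reduction, codebook building, encoding, evaluation.

The image-recognition pipeline mirrors the standard local-feature workflow:
pool the training descriptors, reduce them with PCA (default 8 dimensions,
no whitening), build a codebook of size K with one of four methods
(k-means, diagonal GMM, or the balanced-prior objective in hard/soft
mode), encode every image's descriptor set into a fixed-length signature,
and score a linear classifier over seeded stratified splits.

Descriptor extraction from actual images is out of scope here: the
pipeline ingests descriptor matrices (one text file per image plus a
manifest), whatever backend produced them.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.decomposition import PCA
from sklearn.svm import LinearSVC

from .clustering import gmm_fit, kmeans_fit
from .data import DescriptorSet, SampleSet
from .encoders import encode_bovw, encode_fv, encode_vlad
from .objective import ObjectiveConfig, fit_ppoc, main_objective_term

__all__ = [
    "PipelineConfig",
    "PCAProjection",
    "pca_fit",
    "pca_project",
    "build_codebook",
    "encode_dataset",
    "evaluate_recognition",
]

logger = logging.getLogger(__name__)

_HARD_METHODS = {"kmeans", "ppoc-hard"}
_GAUSSIAN_METHODS = {"gmm", "ppoc-soft"}
_METHODS = _HARD_METHODS | _GAUSSIAN_METHODS
_ENCODERS = {"bovw", "vlad", "fv"}


@dataclass
class PipelineConfig:
    """Configuration of a full codebook-and-encoding run."""

    K_grid: Sequence[int] = (16, 32, 64, 128, 256)
    d_out: int = 8
    method: str = "ppoc-soft"
    encoder: str = "fv"
    lam: float = 1e-9
    budget: int = 2000
    em_iters: int = 30
    warmstart_iters: int = 10
    optimizer: str = "subplex"
    trials: int = 5
    seeds: Sequence[int] = (0, 1, 2, 3, 4)
    floor: float = 1e-6

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {sorted(_METHODS)}")
        if self.encoder not in _ENCODERS:
            raise ValueError(f"unknown encoder {self.encoder!r}; choose from {sorted(_ENCODERS)}")
        if self.encoder == "vlad" and self.method in _GAUSSIAN_METHODS:
            raise ValueError("VLAD requires a hard-type codebook (kmeans or ppoc-hard)")
        if self.encoder == "fv" and self.method in _HARD_METHODS:
            raise ValueError("the Fisher Vector requires a Gaussian-type codebook (gmm or ppoc-soft)")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class PCAProjection:
    """Mean vector plus orthonormal basis of the top principal directions."""

    mean: np.ndarray
    components: np.ndarray  # d_out x D
    explained_variance: np.ndarray

    @property
    def d_out(self) -> int:
        return self.components.shape[0]


def pca_fit(descriptors: np.ndarray, d_out: int) -> PCAProjection:
    """Fit a mean-centered PCA (no whitening) on the pooled descriptor matrix."""
    descriptors = np.asarray(descriptors, dtype=float)
    D = descriptors.shape[1]
    if d_out > D:
        raise ValueError(f"d_out={d_out} exceeds descriptor dimension D={D}")
    if descriptors.shape[0] <= d_out:
        raise ValueError("need more pooled descriptors than output dimensions")
    model = PCA(n_components=d_out, svd_solver="full")
    model.fit(descriptors)
    return PCAProjection(
        mean=model.mean_.copy(),
        components=model.components_.copy(),
        explained_variance=model.explained_variance_.copy(),
    )


def pca_project(image: DescriptorSet, projection: PCAProjection) -> DescriptorSet:
    """Project one image's descriptors onto the fitted basis (labels preserved)."""
    if image.d != projection.mean.shape[0]:
        raise ValueError(
            f"dimension mismatch: descriptors d={image.d}, projection expects {projection.mean.shape[0]}"
        )
    projected = (image.descriptors - projection.mean) @ projection.components.T
    return DescriptorSet(projected, label=image.label, image_id=image.image_id)


def build_codebook(config: PipelineConfig, samples: SampleSet, K: Optional[int] = None):
    """Dispatch codebook construction for one K; records J and J_main in meta.

    ``K`` defaults to the first entry of the config's K grid.  The codebook's
    ``meta`` carries method, K, lambda, seeds and both objective conventions
    (the full J and the main term alone), so baselines and the balanced-prior
    fits can be compared either way.
    """
    if K is None:
        K = int(config.K_grid[0])
    if K > samples.T:
        raise ValueError(f"K={K} exceeds the number of clustering samples T={samples.T}")
    if config.method == "kmeans":
        codebook, info = kmeans_fit(samples, K, max_iter=config.em_iters, seed=config.seeds[0])
        codebook.meta["J_main"] = main_objective_term(codebook.priors)
    elif config.method == "gmm":
        codebook, info = gmm_fit(
            samples, K, max_iter=config.em_iters, seed=config.seeds[0], floor=config.floor
        )
        codebook.meta["J_main"] = main_objective_term(codebook.weights)
    else:
        mode = "hard" if config.method == "ppoc-hard" else "soft"
        obj = ObjectiveConfig(mode=mode, K=K, lam=config.lam, floor=config.floor)
        codebook, _ = fit_ppoc(
            samples,
            K,
            config=obj,
            optimizer=config.optimizer,
            budget=config.budget,
            warmstart_iters=config.warmstart_iters,
            seeds=list(config.seeds)[: config.trials],
        )
    codebook.meta.update({"method": config.method, "K": K, "lambda": config.lam,
                          "seeds": list(config.seeds)})
    return codebook


def encode_dataset(
    collection: Sequence[DescriptorSet], codebook, encoder: str
) -> tuple[np.ndarray, np.ndarray]:
    """Encode every image; returns (signature matrix, label vector) in manifest order."""
    if encoder not in _ENCODERS:
        raise ValueError(f"unknown encoder {encoder!r}")
    rows, labels = [], []
    for image in collection:
        if encoder == "bovw":
            fv = encode_bovw(image, codebook)
        elif encoder == "vlad":
            fv = encode_vlad(image, codebook)
        else:
            fv = encode_fv(image, codebook)
        rows.append(fv.values)
        labels.append(-1 if image.label is None else image.label)
    return np.vstack(rows), np.asarray(labels, dtype=int)


def evaluate_recognition(
    signatures: np.ndarray,
    labels: np.ndarray,
    train_per_category: int,
    trials: int = 5,
    seeds: Optional[Sequence[int]] = None,
    classifier_factory=None,
) -> dict:
    """Seeded stratified splits + a linear classifier; mean accuracy over trials.

    Per trial, ``train_per_category`` images of every category are drawn for
    training and the rest are tested; accuracy is correct/test.  The
    classifier is pluggable (default: LinearSVC with library defaults).
    Returns mean, sd, the per-trial accuracies, and the classifier name.
    """
    signatures = np.asarray(signatures, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if seeds is None:
        seeds = list(range(trials))
    cats = np.unique(labels)
    for c in cats:
        if (labels == c).sum() <= train_per_category:
            raise ValueError(
                f"category {c} has only {(labels == c).sum()} images; "
                f"needs more than train_per_category={train_per_category}"
            )
    if classifier_factory is None:
        classifier_factory = lambda: LinearSVC()  # noqa: E731
    accuracies = []
    for seed in list(seeds)[:trials]:
        rng = np.random.default_rng(seed)
        train_idx = []
        for c in cats:
            members = np.nonzero(labels == c)[0]
            train_idx.extend(rng.choice(members, size=train_per_category, replace=False))
        train_mask = np.zeros(labels.shape[0], dtype=bool)
        train_mask[train_idx] = True
        clf = classifier_factory()
        clf.fit(signatures[train_mask], labels[train_mask])
        pred = clf.predict(signatures[~train_mask])
        accuracies.append(float(np.mean(pred == labels[~train_mask])))
    accuracies = np.asarray(accuracies)
    return {
        "mean_accuracy": float(accuracies.mean()),
        "sd_accuracy": float(accuracies.std(ddof=1)) if len(accuracies) > 1 else 0.0,
        "accuracies": accuracies.tolist(),
        "classifier": type(classifier_factory()).__name__,
    }
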