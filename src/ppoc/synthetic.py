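"""Synthetic benchmarks: 2-D Gaussian mixtures and descriptor collections.

Two families of clustering fixtures emulate the structure of the public
A-sets and S-sets benchmarks:

* A-like — many moderately separated clusters on a jittered grid
  (K = 20/35/50 at 150 points per cluster, totals 3000/5250/7500), for the
  hard (k-means-alternative) objective;
* S-like — K = 15 clusters and 5000 points with overlap growing with the
  level: the cluster layout is held fixed and the spread is inflated, so
  the spacing/sigma ratio strictly decreases from level 1 to 3.  At level 3
  the overlap is strong enough that a short-run GMM habitually collapses
  component pairs onto each other — the failure mode the balanced-prior
  objective is designed to avoid.

These are emulators: they match the published benchmarks' sample counts,
cluster counts, dimensionality and qualitative overlap ordering, not their
exact coordinates.  Real benchmark files in the same plain-text format load
through :func:`ppoc.data.load_points_file`.

A labeled multi-category descriptor-set generator stands in for local
descriptors extracted from real photographs, so the full encode-and-classify
pipeline can be exercised without image data.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .data import DescriptorSet, SampleSet, load_points_file, min_max_normalize, save_points_file

__all__ = [
    "MixtureSpec",
    "generate_mixture",
    "make_a_like",
    "make_s_like",
    "make_degenerate_fixture",
    "make_descriptor_dataset",
    "write_descriptor_collection",
    "read_descriptor_collection",
    "load_points_file",
    "save_points_file",
]


@dataclass
class MixtureSpec:
    """Ground truth of a Gaussian-mixture clustering fixture.

    ``overlap`` is the ratio sigma / (nearest-neighbour mean spacing); means
    and variances may be supplied explicitly or are generated from it.
    """

    K: int
    n_per_cluster: Union[int, Sequence[int]] = 150
    d: int = 2
    true_means: Optional[np.ndarray] = None
    true_variances: Optional[np.ndarray] = None
    overlap: float = 0.1
    seed: int = 0

    def counts(self) -> np.ndarray:
        if np.isscalar(self.n_per_cluster):
            return np.full(self.K, int(self.n_per_cluster))
        counts = np.asarray(self.n_per_cluster, dtype=int)
        if counts.shape != (self.K,):
            raise ValueError("n_per_cluster must be scalar or length K")
        return counts

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be at least 1")
        if (self.counts() < 1).any():
            raise ValueError("every cluster needs at least one point")
        if self.overlap <= 0:
            raise ValueError("overlap must be positive")


def _random_means(K: int, d: int, rng: np.random.Generator, min_sep: float) -> np.ndarray:
    """Uniform means on [0, 10]^d with rejection to keep a minimum spacing."""
    means = np.empty((K, d))
    placed = 0
    while placed < K:
        cand = rng.uniform(0.0, 10.0, size=d)
        if placed == 0 or np.min(np.linalg.norm(means[:placed] - cand, axis=1)) >= min_sep:
            means[placed] = cand
            placed += 1
    return means


def generate_mixture(spec: MixtureSpec) -> tuple[SampleSet, MixtureSpec]:
    """Draw the mixture, attach labels, min-max normalize to [0, 1]^d.

    Returns the normalized sample set and the spec with any generated
    ground-truth means/variances filled in (in pre-normalization units).
    """
    rng = np.random.default_rng(spec.seed)
    if spec.true_means is None:
        min_sep = 1.5
        means = _random_means(spec.K, spec.d, rng, min_sep)
    else:
        means = np.asarray(spec.true_means, dtype=float)
    if spec.true_variances is None:
        if spec.K > 1:
            from scipy.spatial.distance import pdist, squareform

            dist = squareform(pdist(means))
            np.fill_diagonal(dist, np.inf)
            spacing = dist.min(axis=1)
        else:
            spacing = np.asarray([1.0])
        sigma = spec.overlap * spacing
        variances = np.tile((sigma**2)[:, None], (1, spec.d))
    else:
        variances = np.asarray(spec.true_variances, dtype=float)
    counts = spec.counts()
    chunks, labels = [], []
    for k in range(spec.K):
        pts = rng.normal(means[k], np.sqrt(variances[k]), size=(counts[k], spec.d))
        chunks.append(pts)
        labels.append(np.full(counts[k], k))
    raw = SampleSet(np.vstack(chunks), labels=np.concatenate(labels))
    normalized, _ = min_max_normalize(raw)
    filled = MixtureSpec(
        K=spec.K,
        n_per_cluster=spec.n_per_cluster,
        d=spec.d,
        true_means=means,
        true_variances=variances,
        overlap=spec.overlap,
        seed=spec.seed,
    )
    return normalized, filled


_A_GRID = {1: (20, 5, 4), 2: (35, 7, 5), 3: (50, 10, 5)}


def make_a_like(level: int, seed: int = 0) -> tuple[SampleSet, MixtureSpec]:
    """A-sets emulator: K in {20, 35, 50} clusters of 150 points on a jittered grid."""
    if level not in _A_GRID:
        raise ValueError("A-like level must be 1, 2 or 3")
    K, nx, ny = _A_GRID[level]
    rng = np.random.default_rng(seed)
    gx, gy = np.meshgrid(np.arange(nx, dtype=float), np.arange(ny, dtype=float))
    means = np.column_stack([gx.ravel(), gy.ravel()])[:K]
    means = means + rng.uniform(-0.18, 0.18, size=means.shape)
    sigma = 0.11  # grid spacing 1.0: moderate separation with thin boundary overlap
    spec = MixtureSpec(
        K=K,
        n_per_cluster=150,
        d=2,
        true_means=means,
        true_variances=np.full((K, 2), sigma**2),
        overlap=sigma,
        seed=seed,
    )
    return generate_mixture(spec)


# level -> sigma in a fixed K=15 layout on [0, 10]^2 with min spacing 1.8
_S_SIGMA = {1: 0.30, 2: 0.55, 3: 0.90}
_S_TOTAL = 5000
_S_K = 15


def make_s_like(level: int, seed: int = 0) -> tuple[SampleSet, MixtureSpec]:
    """S-sets emulator: 15 clusters, ~5000 points, overlap rising with the level.

    The mean layout depends only on the seed, so levels 1-3 of the same seed
    differ purely in cluster spread; the spacing/sigma ratio strictly
    decreases with the level.
    """
    if level not in _S_SIGMA:
        raise ValueError("S-like level must be 1, 2 or 3")
    layout_rng = np.random.default_rng(seed)
    means = _random_means(_S_K, 2, layout_rng, min_sep=1.8)
    sigma = _S_SIGMA[level]
    base, extra = divmod(_S_TOTAL, _S_K)
    counts = np.full(_S_K, base)
    counts[:extra] += 1
    spec = MixtureSpec(
        K=_S_K,
        n_per_cluster=counts,
        d=2,
        true_means=means,
        true_variances=np.full((_S_K, 2), sigma**2),
        overlap=sigma,
        seed=seed,
    )
    return generate_mixture(spec)


def make_degenerate_fixture(seed: int = 0) -> tuple[SampleSet, MixtureSpec]:
    """A mixture engineered to make maximum-likelihood GMM fitting collapse.

    15 equal-mass clusters (5000 points total): 11 wide isotropic clusters
    (sigma 0.75, minimum spacing 1.8 on [0, 10]^2) and 4 tight dense cores
    (sigma 0.12) placed just off-center (0.25 sigma_wide) inside 4 of the
    wide clusters.  A likelihood fit rewards a concentric pair — two
    components at nearly the same mean with very different variances — so
    long-run EM ends with fewer than 15 distinct mean positions, while the
    balanced-prior objective, whose hard assignment cannot let coincident
    means share samples, keeps the means apart.
    """
    n_core = 4
    sigma_wide, sigma_core, core_off = 0.75, 0.12, 0.25
    rng = np.random.default_rng(seed)
    sites = _random_means(_S_K - n_core, 2, rng, min_sep=1.8)
    means = [s for s in sites]
    sigmas = [sigma_wide] * (_S_K - n_core)
    for i in range(n_core):
        direction = rng.normal(size=2)
        direction /= np.linalg.norm(direction)
        means.append(sites[i] + core_off * sigma_wide * direction)
        sigmas.append(sigma_core)
    means = np.asarray(means)
    sigmas = np.asarray(sigmas)
    base, extra = divmod(_S_TOTAL, _S_K)
    counts = np.full(_S_K, base)
    counts[:extra] += 1
    spec = MixtureSpec(
        K=_S_K,
        n_per_cluster=counts,
        d=2,
        true_means=means,
        true_variances=np.tile((sigmas**2)[:, None], (1, 2)),
        overlap=1.0,
        seed=seed,
    )
    return generate_mixture(spec)


# ---------------------------------------------------------------------------
# Descriptor collections


def make_descriptor_dataset(
    categories: int,
    images_per_category: int,
    descriptors_per_image: int,
    d: int = 8,
    category_signal: float = 1.0,
    seed: int = 0,
    n_category_components: int = 3,
    n_background_components: int = 2,
) -> list[DescriptorSet]:
    """Labeled descriptor sets: each category owns a shifted descriptor mixture.

    Every category's mixture shares ``n_background_components`` background
    components with all others; its ``n_category_components`` own components
    sit at the shared base positions displaced by ``category_signal`` times a
    category-specific offset.  With ``category_signal = 0`` all categories
    draw from the identical distribution (the null case); large signals make
    encoded signatures linearly separable.
    """
    if min(categories, images_per_category, descriptors_per_image) < 1:
        raise ValueError("all counts must be at least 1")
    rng = np.random.default_rng(seed)
    background = rng.uniform(-1.0, 1.0, size=(n_background_components, d))
    base = rng.uniform(-1.0, 1.0, size=(n_category_components, d))
    offsets = rng.normal(0.0, 1.0, size=(categories, n_category_components, d))
    sigma = 0.35
    collection: list[DescriptorSet] = []
    for c in range(categories):
        cat_means = base + category_signal * offsets[c]
        comp_means = np.vstack([background, cat_means])
        n_comp = comp_means.shape[0]
        for i in range(images_per_category):
            which = rng.integers(n_comp, size=descriptors_per_image)
            descs = comp_means[which] + rng.normal(0.0, sigma, size=(descriptors_per_image, d))
            collection.append(
                DescriptorSet(descs, label=c, image_id=f"cat{c:02d}_img{i:03d}")
            )
    return collection


def write_descriptor_collection(directory, collection: Sequence[DescriptorSet]) -> Path:
    """One delimited matrix file per image plus a manifest (id, label, path)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest_path = directory / "manifest.tsv"
    with open(manifest_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["image_id", "label", "path"])
        for i, image in enumerate(collection):
            image_id = image.image_id or f"img{i:05d}"
            rel = f"{image_id}.txt"
            save_points_file(directory / rel, image.descriptors)
            writer.writerow([image_id, image.label, rel])
    return manifest_path


def read_descriptor_collection(manifest_path) -> list[DescriptorSet]:
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    collection = []
    with open(manifest_path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            path = root / row["path"]
            if not path.exists():
                raise FileNotFoundError(f"descriptor file missing for image {row['image_id']}")
            pts = load_points_file(path)
            label = int(row["label"]) if row["label"] not in ("", "None") else None
            collection.append(
                DescriptorSet(pts.points, label=label, image_id=row["image_id"])
            )
    return collection
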