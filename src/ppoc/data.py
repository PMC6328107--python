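"""Core containers and plain-text / JSON serialization.

The package works on three kinds of data:

* clustering samples (``SampleSet``) — the ``T x d`` point cloud a codebook
  is learned from;
* codebooks — either a ``HardCodebook`` (mean vectors plus occupancy priors,
  the k-means family) or a ``GaussianCodebook`` (means, diagonal variances
  and mixing weights, the GMM family);
* per-image descriptor sets (``DescriptorSet``) — the local features that
  the encoders turn into fixed-length signatures.

Point and descriptor files are plain whitespace-delimited text, one point
per row (the distribution format of the public A-sets/S-sets clustering
benchmarks).  Codebooks round-trip through a small JSON schema; floats are
serialized with Python's shortest round-trip repr, so a load after a save
reproduces every number bit-exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

__all__ = [
    "SampleSet",
    "DescriptorSet",
    "HardCodebook",
    "GaussianCodebook",
    "FeatureVector",
    "MinMaxParams",
    "min_max_normalize",
    "load_points_file",
    "save_points_file",
    "load_codebook",
    "save_codebook",
]


def _as_2d_float(points, name: str = "points") -> np.ndarray:
    arr = np.asarray(points, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.ndim != 2:
        raise ValueError(f"{name} must be a 2-D matrix, got ndim={arr.ndim}")
    return arr


def _check_finite(arr: np.ndarray, name: str) -> None:
    bad = ~np.isfinite(arr)
    if bad.any():
        row = int(np.nonzero(bad.any(axis=1))[0][0])
        raise ValueError(f"non-finite value in {name} at row {row}")


@dataclass
class SampleSet:
    """T points in d dimensions, optionally with ground-truth labels."""

    points: np.ndarray
    labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.points = _as_2d_float(self.points)
        if self.points.shape[0] < 1:
            raise ValueError("SampleSet needs at least one point")
        _check_finite(self.points, "points")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (self.points.shape[0],):
                raise ValueError("labels must have one entry per point")

    @property
    def T(self) -> int:
        return self.points.shape[0]

    @property
    def d(self) -> int:
        return self.points.shape[1]


@dataclass
class DescriptorSet:
    """N local descriptors of a single image, with an optional category label."""

    descriptors: np.ndarray
    label: Optional[int] = None
    image_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.descriptors = _as_2d_float(self.descriptors, "descriptors")
        _check_finite(self.descriptors, "descriptors")

    @property
    def N(self) -> int:
        return self.descriptors.shape[0]

    @property
    def d(self) -> int:
        return self.descriptors.shape[1]


_PRIOR_TOL = 1e-8


@dataclass
class HardCodebook:
    """K mean vectors plus the occupancy fractions they absorb."""

    means: np.ndarray
    priors: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.means = _as_2d_float(self.means, "means")
        self.priors = np.asarray(self.priors, dtype=float)
        if self.means.shape[0] < 1:
            raise ValueError("codebook needs K >= 1")
        if self.priors.shape != (self.means.shape[0],):
            raise ValueError("priors must have one entry per mean")
        if (self.priors < -_PRIOR_TOL).any():
            raise ValueError("priors must be nonnegative")
        if abs(self.priors.sum() - 1.0) > _PRIOR_TOL:
            raise ValueError("priors must sum to 1")

    @property
    def K(self) -> int:
        return self.means.shape[0]

    @property
    def d(self) -> int:
        return self.means.shape[1]


@dataclass
class GaussianCodebook:
    """Diagonal-covariance Gaussian mixture: means, variances, mixing weights."""

    means: np.ndarray
    variances: np.ndarray
    weights: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.means = _as_2d_float(self.means, "means")
        self.variances = _as_2d_float(self.variances, "variances")
        self.weights = np.asarray(self.weights, dtype=float)
        if self.variances.shape != self.means.shape:
            raise ValueError("variances must match means in shape")
        if (self.variances <= 0).any():
            raise ValueError("variances must be strictly positive")
        if self.weights.shape != (self.means.shape[0],):
            raise ValueError("weights must have one entry per component")
        if abs(self.weights.sum() - 1.0) > _PRIOR_TOL:
            raise ValueError("weights must sum to 1")

    @property
    def K(self) -> int:
        return self.means.shape[0]

    @property
    def d(self) -> int:
        return self.means.shape[1]


@dataclass
class FeatureVector:
    """A fixed-length image signature with its encoder provenance."""

    values: np.ndarray
    encoder: str
    K: int
    d: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()

    def __len__(self) -> int:
        return self.values.shape[0]


# ---------------------------------------------------------------------------
# Min-max normalization


@dataclass
class MinMaxParams:
    """Per-dimension affine transform fitted by :func:`min_max_normalize`."""

    mins: np.ndarray
    ranges: np.ndarray  # max - min; 0 marks a constant dimension

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = _as_2d_float(points)
        safe = np.where(self.ranges > 0, self.ranges, 1.0)
        out = (points - self.mins) / safe
        out[:, self.ranges == 0] = 0.0
        return out


def min_max_normalize(samples: SampleSet) -> tuple[SampleSet, MinMaxParams]:
    """Linearly rescale each dimension to span [0, 1].

    A constant dimension maps to all zeros.  Returns the rescaled samples
    together with the fitted transform so it can be reused on held-out data.
    """
    pts = samples.points
    mins = pts.min(axis=0)
    ranges = pts.max(axis=0) - mins
    params = MinMaxParams(mins=mins, ranges=ranges)
    return SampleSet(params.apply(pts), labels=samples.labels), params


# ---------------------------------------------------------------------------
# Plain-text point files (A-sets/S-sets distribution format)


def load_points_file(path) -> SampleSet:
    """Read a whitespace-delimited point file, one point per row.

    Blank lines are ignored.  Ragged rows or non-numeric tokens raise a
    ``ValueError`` naming the offending line (1-based).
    """
    rows: list[list[float]] = []
    ncols: Optional[int] = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            try:
                row = [float(tok) for tok in tokens]
            except ValueError:
                raise ValueError(f"{path}: non-numeric token on line {lineno}") from None
            if ncols is None:
                ncols = len(row)
            elif len(row) != ncols:
                raise ValueError(
                    f"{path}: line {lineno} has {len(row)} columns, expected {ncols}"
                )
            rows.append(row)
    if not rows:
        raise ValueError(f"{path}: no data rows")
    return SampleSet(np.asarray(rows, dtype=float))


def save_points_file(path, points: np.ndarray) -> None:
    points = _as_2d_float(points)
    with open(path, "w") as fh:
        for row in points:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# Codebook JSON


def save_codebook(path, codebook) -> None:
    """Write a codebook to the shared JSON schema (bit-exact round trip)."""
    if isinstance(codebook, HardCodebook):
        obj = {
            "kind": "hard",
            "K": codebook.K,
            "d": codebook.d,
            "means": codebook.means.tolist(),
            "priors": codebook.priors.tolist(),
            "meta": codebook.meta,
        }
    elif isinstance(codebook, GaussianCodebook):
        obj = {
            "kind": "gaussian",
            "K": codebook.K,
            "d": codebook.d,
            "means": codebook.means.tolist(),
            "priors": codebook.weights.tolist(),
            "variances": codebook.variances.tolist(),
            "meta": codebook.meta,
        }
    else:
        raise TypeError(f"not a codebook: {type(codebook)!r}")
    Path(path).write_text(json.dumps(obj, indent=1))


def load_codebook(path):
    obj = json.loads(Path(path).read_text())
    kind = obj.get("kind")
    if kind == "hard":
        return HardCodebook(
            means=np.asarray(obj["means"], dtype=float),
            priors=np.asarray(obj["priors"], dtype=float),
            meta=obj.get("meta", {}),
        )
    if kind == "gaussian":
        return GaussianCodebook(
            means=np.asarray(obj["means"], dtype=float),
            variances=np.asarray(obj["variances"], dtype=float),
            weights=np.asarray(obj["priors"], dtype=float),
            meta=obj.get("meta", {}),
        )
    raise ValueError(f"unknown codebook kind: {kind!r}")
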