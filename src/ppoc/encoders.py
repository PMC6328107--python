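"""Feature encoders: BoVW, VLAD, and the Fisher Vector.

Each encoder turns the N local descriptors of one image into a single
fixed-length signature under a codebook:

* BoVW — histogram of nearest-codeword counts; length K.
* VLAD — per-codeword sums of residuals x_i - mu_k over the descriptors
  hard-assigned to codeword k; length K*d.
* Fisher Vector — per-component gradient statistics of a diagonal GMM:
  a frequency block F(w)_k = (1/(N sqrt(w_k))) sum_i (q_ik - w_k), a mean
  block F(mu)_k = (1/(N sqrt(w_k))) sum_i q_ik (x_i - mu_k)/sigma_k and a
  variance block F(sigma)_k = (1/(N sqrt(2 w_k))) sum_i q_ik
  [((x_i - mu_k)/sigma_k)^2 - 1], concatenated as
  [F(w)_1..K, F(mu)_1..K, F(sigma)_1..K]; length K(2d+1).

FV posteriors q_ik are soft GMM responsibilities by default; a hard
nearest-mean one-hot approximation is available.  Signatures are raw by
default; optional power (signed square-root) and l2 post-normalizations
can be switched on.
"""

from __future__ import annotations

import logging

import numpy as np

from .clustering import gmm_posteriors, hard_assign
from .data import DescriptorSet, FeatureVector, GaussianCodebook, HardCodebook, SampleSet

__all__ = ["encode_bovw", "encode_vlad", "encode_fv", "save_signature", "load_signature"]

logger = logging.getLogger(__name__)


def _check_nonempty(image: DescriptorSet) -> None:
    if image.N < 1:
        raise ValueError("cannot encode an empty descriptor set")


def _postnormalize(values: np.ndarray, power: bool, l2: bool) -> np.ndarray:
    if power:
        values = np.sign(values) * np.sqrt(np.abs(values))
    if l2:
        norm = np.linalg.norm(values)
        if norm > 0:
            values = values / norm
    return values


def encode_bovw(
    image: DescriptorSet,
    codebook: HardCodebook,
    power: bool = False,
    l2: bool = False,
) -> FeatureVector:
    """Bag-of-visual-words histogram: f_k counts descriptors nearest to mu_k."""
    _check_nonempty(image)
    assign = hard_assign(SampleSet(image.descriptors), codebook.means)
    counts = np.bincount(assign, minlength=codebook.K).astype(float)
    return FeatureVector(
        _postnormalize(counts, power, l2), encoder="bovw", K=codebook.K, d=codebook.d
    )


def encode_vlad(
    image: DescriptorSet,
    codebook: HardCodebook,
    power: bool = False,
    l2: bool = False,
) -> FeatureVector:
    """VLAD: block k is the sum of residuals x_i - mu_k over descriptors in k."""
    _check_nonempty(image)
    assign = hard_assign(SampleSet(image.descriptors), codebook.means)
    K, d = codebook.K, codebook.d
    blocks = np.zeros((K, d))
    residuals = image.descriptors - codebook.means[assign]
    np.add.at(blocks, assign, residuals)
    return FeatureVector(
        _postnormalize(blocks.ravel(), power, l2), encoder="vlad", K=K, d=d
    )


def encode_fv(
    image: DescriptorSet,
    codebook: GaussianCodebook,
    assignment: str = "soft",
    power: bool = False,
    l2: bool = False,
) -> FeatureVector:
    """Fisher Vector of a descriptor set under a diagonal-GMM codebook.

    ``assignment="soft"`` (default) uses the GMM responsibilities;
    ``"hard"`` uses the one-hot nearest-mean approximation.  A component
    with zero weight contributes zero blocks (logged as a warning).
    """
    _check_nonempty(image)
    if assignment not in ("soft", "hard"):
        raise ValueError("assignment must be 'soft' or 'hard'")
    K, d = codebook.K, codebook.d
    N = image.N
    X = image.descriptors
    sample_view = SampleSet(X)
    if assignment == "soft":
        q = gmm_posteriors(sample_view, codebook)  # N x K
    else:
        idx = hard_assign(sample_view, codebook.means)
        q = np.zeros((N, K))
        q[np.arange(N), idx] = 1.0
    w = codebook.weights
    sigma = np.sqrt(codebook.variances)  # K x d

    fw = np.zeros(K)
    fmu = np.zeros((K, d))
    fsig = np.zeros((K, d))
    for k in range(K):
        if w[k] <= 0:
            logger.warning("encode_fv: component %d has zero weight; blocks zeroed", k)
            continue
        qk = q[:, k]
        z = (X - codebook.means[k]) / sigma[k]  # N x d
        fw[k] = (qk - w[k]).sum() / (N * np.sqrt(w[k]))
        fmu[k] = (qk[:, None] * z).sum(axis=0) / (N * np.sqrt(w[k]))
        fsig[k] = (qk[:, None] * (z**2 - 1.0)).sum(axis=0) / (N * np.sqrt(2.0 * w[k]))
    values = np.concatenate([fw, fmu.ravel(), fsig.ravel()])
    return FeatureVector(_postnormalize(values, power, l2), encoder="fv", K=K, d=d)


def save_signature(path, fv: FeatureVector) -> None:
    """One value per line, with a header naming encoder/K/d."""
    with open(path, "w") as fh:
        fh.write(f"# encoder={fv.encoder} K={fv.K} d={fv.d}\n")
        for v in fv.values:
            fh.write(repr(float(v)) + "\n")


def load_signature(path) -> FeatureVector:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing signature header")
        fields = dict(tok.split("=") for tok in header[1:].split())
        values = [float(line) for line in fh if line.strip()]
    return FeatureVector(
        np.asarray(values), encoder=fields["encoder"], K=int(fields["K"]), d=int(fields["d"])
    )
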