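# Methods

## The model

Given clustering samples X = {x_t ∈ R^d}, t = 1..T, and a codebook size K,
the package fits K mean vectors Θ = {μ_k} by minimizing

    J(Θ) = Σ_k |w_k − w̄|  +  λ · (1/T) Σ_t d(x_t; Θ)²

where w_k is the prior probability of cluster k and w̄ = 1/K exactly (the
priors obey the probabilistic constraint Σ w_k = 1, so their mean is always
1/K; it is not re-estimated empirically).  The main term is an L1 surrogate
for the variance of the priors: it is 0 iff the priors are uniform and at
most 2(K−1)/K.  The regularizer stops the search from wandering: with only
the main term the landscape is piecewise constant (priors are counts), and
small mean moves would not change J at all.

Two modes mirror the two standard codebook clusterings:

* **hard** (k-means alternative).  Samples are assigned to the nearest mean
  (ties to the lowest index), w_k is the occupancy fraction
  (count assigned to k)/T, and d(x_t; Θ) is the Euclidean distance to the
  assigned mean, so the regularizer is the mean squared quantization error.
  The result is a hard codebook (means + priors) usable by BoVW and VLAD.
* **soft** (GMM alternative).  Posteriors are approximated by the same
  one-hot nearest-mean assignment (the peaky-posterior approximation), the
  weights w_k and diagonal variances Σ_k are estimated from that
  assignment, and d(x_t; Θ) is the Mahalanobis form
  (x_t − μ_k)ᵀ Σ_k⁻¹ (x_t − μ_k) at the assigned component.  The result is
  a Gaussian codebook (means, diagonal variances, weights) usable by the
  Fisher Vector.

Two readings of the soft regularizer are deliberately exposed:

* the Mahalanobis form above is already a squared distance, and the
  composite objective squares d again.  The default squares it literally;
  `square_regularizer=False` uses the form once.  At the default
  λ = 10⁻⁹ the two are numerically indistinguishable in J.
* during optimization a candidate mean is not the centroid of the samples
  assigned to it, so "the variance of cluster k" is ambiguous.  The default
  takes the second moment of the assigned samples about the *candidate*
  mean (the estimator formula evaluated at the available μ);
  `variance_about_centroid=True` uses the moment about the assigned-sample
  centroid instead.

Empty clusters contribute |0 − 1/K| to the main term and nothing to the
regularizer; they are not repaired during objective evaluation, because the
objective itself is the repair mechanism — emptiness is exactly what the
optimizer is paid to remove.

## Optimization

J is non-differentiable, so minimization is derivative-free with a hard
budget of objective evaluations (default 2000) and best-ever-seen tracking:
the reported solution is the best point evaluated, never worse than the
starting point, even when a backend terminates early or wanders.

The full protocol per trial: k-means++ seeding → 10 Lloyd iterations (a
cheap warm start that puts the means on the data) → flatten the K×d means
into one vector → budgeted search.  Five seeded trials (seeds 0..4 by
default) are run and the best objective wins.

Backends: scipy's Nelder–Mead, COBYLA and Powell, plus a Subplex-style
optimizer implemented here (cyclic Nelder–Mead over blocks of ≤ 5
coordinates, re-partitioned each cycle by per-coordinate progress, with
step sizes rescaled toward the progress vector and halved on stalled
cycles; inner simplex runs are capped at 10·(ns+1) evaluations).  Full
Nelder–Mead degrades quickly as K·d grows (a 2-D K = 20 problem is already
40-dimensional); the subspace scheme keeps simplices small and is the
workhorse, consistently the strongest backend on the benchmark emulators.
Initial step size is 0.1 — samples are min-max normalized to [0, 1] per
dimension before clustering, so 0.1 is a tenth of the data range.

Numerical choices: non-finite candidate means evaluate to +∞ (optimizer-
safe sentinel); variances are floored at ε = 10⁻⁶ everywhere (guarantees
valid log-densities and caps Mahalanobis terms); GMM responsibilities are
computed with log-sum-exp so no row underflows to zero; nearest-mean ties
break to the lowest cluster index for determinism; k-means repairs an empty
cluster by relocating its mean to the sample farthest from its current
center (the fit keeps K live clusters; only the balanced objective leaves
emptiness visible on purpose).

## Baselines

`kmeans_fit` is Lloyd's algorithm from a k-means++ start; its quantization
error is non-increasing by construction.  `gmm_fit` is EM for a diagonal-
covariance mixture initialized from a short k-means fit, with the variance
floor applied after every M step; its log-likelihood trace is
non-decreasing except where the floor fires.  EM termination is exposed as
`max_iter` with no single privileged default: numerical comparisons here
run it long (it is cheap in 2-D), while the image-pipeline default is 30
iterations, the conventional short-run setting for codebook construction
(`PipelineConfig.em_iters`).

## Encoders

BoVW: f_k counts descriptors whose nearest codeword is k; length K.
VLAD: block k sums residuals x_i − μ_k over descriptors assigned to k;
length K·d.  Fisher Vector: per component, the frequency block
(1/(N√w_k)) Σ_i (q_ik − w_k), the mean block
(1/(N√w_k)) Σ_i q_ik (x_i − μ_k)/σ_k, and the variance block
(1/(N√(2 w_k))) Σ_i q_ik [((x_i − μ_k)/σ_k)² − 1], concatenated w-blocks
first, then μ-blocks, then σ-blocks; length K(2d+1).  σ_k is the
per-dimension standard deviation; divisions are element-wise.  Posteriors
q are soft GMM responsibilities by default, with the one-hot hard
approximation behind a flag.  A zero-weight component contributes zero
blocks and a warning.  No power or ℓ2 post-normalization is applied by
default; both exist as flags.

At K = 256, d = 8 the VLAD and FV lengths are 2048 and 4352 — the
dimensionality laws K·d and K(2d+1) are asserted across the whole grid
K ∈ {16, 32, 64, 128, 256}.

## Synthetic benchmarks

`make_a_like(level)` emulates the A-sets: K ∈ {20, 35, 50} equal clusters
of 150 points (totals 3000/5250/7500) on a jittered unit grid with
σ = 0.11 — moderate separation with thin boundary overlap, so converged
k-means usually, but not always, finds the balanced solution.
`make_s_like(level)` emulates the S-sets: 15 equal clusters, 5000 points,
a layout with minimum spacing 1.8 on [0, 10]², and spread σ ∈
{0.30, 0.55, 0.90} for levels 1–3, so the spacing/σ ratio strictly
decreases with the level.  Both are *emulators*: they match the published
benchmarks' sample counts, cluster counts, dimensionality and overlap
ordering, not their coordinates; the plain-text loader accepts the real
files when a user supplies them.

`make_degenerate_fixture(seed)` is the dedicated demonstration of the
failure mode that motivates the balanced objective: 15 equal-mass clusters
where 4 are tight dense cores (σ = 0.12) sitting just off-center
(0.25 σ_wide) inside wide clusters (σ = 0.75).  Maximum-likelihood fitting
rewards placing two components at nearly the same mean with very different
variances — a concentric pair — so a long EM run ends with fewer than 15
distinct mean positions (distinctness measured by single-linkage grouping
at tol = 0.02 of the normalized data range).  The balance objective cannot
do this: under hard assignment, coincident means cannot both absorb their
share of samples, so the fitted means stay distinct.  Equal-spread
isotropic mixtures — including the S-like emulators at every level — do
not reproduce mean-coincidence within practical EM budgets; density
heterogeneity is what drives it, which is why this fixture exists
separately from the S-like family.

The descriptor-collection generator gives each category a mixture over
descriptor space: shared background components plus category components
displaced by `category_signal` times a category-specific offset.  Signal 0
makes all categories identically distributed (a null for the recognition
harness); large signal makes encoded signatures linearly separable.  What
these fixtures do *not* emulate: real local-descriptor statistics (heavy
tails, manifold structure, spatial correlation within an image), class
imbalance, or label noise — so passing tests demonstrate the machinery and
the direction of the codebook-balance effect, not image-recognition
accuracy on real data.

## Pipeline

PCA (no whitening; the variance-ordered orthonormal basis) is fitted on
the pooled codebook-training descriptors only and applied everywhere,
default output dimension 8.  The recognition harness draws a seeded
stratified split (`train_per_category` images per category), fits a linear
classifier (default: scikit-learn's LinearSVC with its default
regularization, recorded in the output), and reports mean ± sd accuracy
over five trials.  Problem sizes in the test suite are kept desk-scale
(thousands of points, tens of images); they are the package's default
study conditions, chosen to exercise every code path with stable
statistics.

## Known limitations

* The balance objective controls prior spread, not inter-mean distance:
  under heavy overlap two means may legitimately sit close together while
  splitting a merged blob evenly.  Distinctness of the balanced solution
  is an empirical tendency (demonstrated on the degenerate fixture), not
  an invariant.
* The Subplex-style backend is a faithful-in-spirit reimplementation of
  the subspace-simplex idea, not a port of any particular library's code;
  evaluation-by-evaluation traces will differ from other implementations.
* Hard mode scales as O(T·K) per evaluation; the 2000-evaluation budget on
  T ≈ 5000, K·d ≈ 40 problems runs in seconds, but very large T or K·d
  calls for subsampling the clustering pool (standard practice for
  codebook construction).
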