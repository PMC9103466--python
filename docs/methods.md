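# Methods

This note records the models behind each stage, the defaults that matter,
what the synthetic generators do and do not emulate, and the places where the
design was genuinely open and a choice had to be made.

## Data model

Epochs are fixed-length windows (default 30 s at 100 Hz) cut half-open and
non-overlapping from a multichannel recording; a trailing partial window is
dropped. A raw epoch row concatenates all channels, so two 100 Hz channels
give 6000 features per 30 s epoch. Six-stage labels follow the classical
scoring order AWA=0, REM=1, S1=2, S2=3, S3=4, S4=5; merged schemes are total
surjective maps (5-class merges S3+S4; 4-class also S1+S2; 3-class all NREM;
2-class wake vs sleep), and merging conserves totals by construction.
Movement/unscored hypnogram entries are removed before anything else touches
the data.

Raw sample geometry carries almost no stage information: band-limited noise
epochs of equal power are nearly equidistant in Euclidean distance regardless
of their spectra. The pipeline therefore inserts a featurization stage —
per-channel relative band powers (Welch periodogram; delta 0.5–4, theta 4–8,
alpha 8–13, sigma 12–16, beta 16–30 Hz; log-transformed) — before clustering.
These are the conventional EEG bands; the featurization can be disabled for
inputs that are already feature matrices.

ICA cleanup uses the fixed-point deflation scheme (FastICA, logcosh
contrast) with whitening; by default all components are retained, making the
step a lossless reconstruction unless components are explicitly dropped.
Non-convergence degrades to returning whitened data with a warning.

## Clustering

* Linkage clustering uses Euclidean single/complete linkage
  (min/max cross-pair distance) with agglomeration until K clusters remain.
* Spectral clustering forms Gaussian weights, the symmetric normalized
  Laplacian, and estimates K by the largest gap among the first
  min(n−1, 50) eigenvalue differences; the embedding rows are normalized to
  unit length (zero-norm rows are zeroed and logged) and clustered by
  K-means with 10 restarts under a fixed seed.
* Kernel scale: the default `auto` scale is the median distance to the 7th
  nearest neighbor. A global median-pairwise scale (available as
  `sigma="median"`) grows linearly with between-cluster separation, which
  drives all cross-cluster weights toward a constant and makes the eigengap
  land at K = 1 no matter how separated the clusters are; the local scale
  does not have this defect. This was verified numerically on two-blob
  configurations at 20–40 blob widths of separation.
* PCA subspace clustering samples anchors uniformly, takes each anchor's
  (dmax+1)-nearest-neighbor subcluster, fits a local PCA basis (smallest
  rank reaching 90% variance, capped at dmax), and scores anchor pairs by
  the mean squared cosine of the principal angles between their bases —
  a standard subspace affinity in [0, 1]. Rows keep their dmax largest
  entries, the matrix is symmetrized (D + Dᵀ), anchors are spectrally
  clustered, and out-of-sample points take their nearest anchor's label.
  Near the intersection of subspaces the nearest-anchor rule is inherently
  ambiguous; exact recovery holds when anchors cover all points and the data
  avoid the intersection. dmax also sets the neighborhood width: once noise
  rivals the nearest-neighbor spacing, small neighborhoods (4 points) no
  longer pin down the local subspace and dmax ≈ 10 is appropriate.
  The algorithm's nominal inputs λ1, λ2, m, t_max play no role in the
  procedure and are accepted with a warning.
* Representative selection allocates per-cluster quotas proportionally
  (largest remainder, minimum one per cluster) and keeps the rows closest to
  each cluster centroid; output size is exact.

## SVD ranking and synchronization

Measurements R_ij ≈ r_i − r_j live on an undirected graph; H is skew-symmetric
with H_ij = R_ij on edges. In the noise-free complete case
H = re⊤ − er⊤ has rank 2 with left singular vectors spanning {e, r − r̄e} and
equal singular values ‖r − r̄e‖√n. The estimator takes the top-2 left singular
subspace, projects e/√n onto it, uses the in-span orthogonal unit vector as
the score direction, chooses the global sign minimizing upsets (edges whose
measured sign contradicts the recovered order; ties excluded), recovers the
scale τ by least squares of the observed entries of H against τ(ue⊤ − eu⊤),
and centers. The published recursion for the last step is garbled in its
source; scale-then-center is the unique reading that reproduces centered r
exactly in the noise-free complete case, which the rank-2 analysis demands,
and the tests verify that exactness for all n ≤ 8.

Epochs do not come with pairwise measurements. For the pipeline, an epoch's
score is its projection on the leading principal component and
R_ij = s_i − s_j on a symmetrized 10-NN graph — a documented, configurable
interpretation. The pipeline applies the keep-top-⌈n/factor⌉ reduction
*within each cluster*: the leading-PC score separates clusters, so a global
cut can annihilate entire clusters (observed on 5-class synthetic runs),
whereas the per-cluster cut preserves composition. The library operation
itself stays global.

## VBMF

Fully factorized Gaussian posteriors over every entry of U (K×P) and V (K×Q),
conjugate zero-mean Gaussian priors with per-component (ARD) variances,
Gaussian noise on the observed entries. Coordinate ascent updates each factor
row in closed form, then the ARD variances and the noise variance, so the
evidence lower bound is non-decreasing (asserted to 1e−8 relative tolerance
in tests). Initialization is the truncated SVD of the zero-filled matrix plus
seeded jitter — random small initialization can converge to the all-zero
fixed point of the updates even on noiseless rank-1 data. ARD prunes
components the data cannot support (warning emitted); with pruning active the
reconstruction error saturates in K rather than strictly decreasing, so the
rank-monotonicity check runs with fixed priors.

## Sparse group lasso with dual-level screening

Objective: ½‖y − Xβ‖² + αλ Σ_g √n_g ‖β_g‖₂ + λ‖β‖₁ (the printed composite
penalty in the source is typographically damaged; this is the standard form
consistent with its own dual thresholds). Solver: block proximal descent
with per-block Lipschitz steps and the soft-threshold-then-group-shrink
proximal map; convergence is declared by duality gap, with the dual point
obtained by ray-rescaling the residual into feasibility. λ_max per group
solves ‖S₁(X_g⊤y/λ)‖ = α√n_g by bisection.

Screening: the optimal dual point lies in a sphere of radius √(2·gap)/λ
around any feasible dual point (the dual is λ²-strongly concave). The group
statistic sup‖S₁(X_g⊤θ)‖ and the feature statistic sup|x_gk⊤θ| over the
sphere are bounded by Lipschitz closed forms
(‖S₁(X_g⊤θ_c)‖ + ‖X_g‖₂ρ and |x_gk⊤θ_c| + ‖x_gk‖ρ); upper-bounding the
suprema keeps the test safe — a screened coefficient is exactly zero at the
optimum, verified against unscreened solves on 50 random designs. The
pathwise driver uses 30 log-spaced λ from λ_max down to 1% of λ_max with
warm starts, screens sequentially, and returns the solution closest to the
feature budget without exceeding it. Default α = 0.5; groups default to
per-channel contiguous blocks. Multiclass selection aggregates |β| across
one-vs-rest responses.

## Distributed ridge (one-shot, limiting weights)

Sites fit β̂_i = (X_i⊤X_i + n_iλI)⁻¹X_i⊤Y_i. Variance components are
estimated per site by maximizing the marginal likelihood of
Y ~ N(0, α²XX⊤ + σ²I) over the eigenbasis of XX⊤ (Nelder–Mead in log-space
from three starts), then pooled by averaging. The grid is
λ₀·{0.1, 0.25, 0.5, 1, 2, 4, 10} around λ₀ = qp/(nα̂²), scored by held-out
error on a 20% split. The published weight formula contains undefined
symbols; since the protocol assumes i.i.d. equal-sized sites, the optimal
weights are symmetric, and the implementation uses w_i = w(λ)/q with the
scalar w(λ) calibrated in closed form on the validation split (`equal` mode
fixes w_i = 1/q). The identity β̂_dist = Σ w_i β̂_i holds exactly by
construction.

## Multiclass GP classification

Per-class latent GPs with squared-exponential kernels (per-dimension length
scales as printed, i.e. divisors on squared differences; an indicator noise
term σ₀² on the diagonal). The ε-corrupted argmax likelihood takes exactly
two values on strict-argmax latents, 1−ε and ε/(C−1), so the expected
log-likelihood under the variational posterior is
Q_i log(1−ε) + (1−Q_i) log(ε/(C−1)) with Q_i the posterior probability that
the target latent wins. Inference: factorized Gaussian q over per-class
latent vectors; Q_i is estimated by Rao-Blackwellized Monte Carlo — the
target latent is sampled by reparameterization (64 fixed draws), the other
classes are integrated analytically through normal CDFs — giving smooth
analytic gradients despite the step-function likelihood. Adam maximizes the
bound; kernel hyperparameters start from a dimension-variance heuristic and a
shared scale/amplitude pair is refined by coordinate search on the bound
every 50 steps. Ties count as losses (Θ(0) = 0): a tied maximum carries no
argmax evidence. ε defaults to 0.05; ε = 0 is accepted and floored at 1e−6
inside the bound only. The variational covariance is diagonal; a full
covariance was considered and dropped — the diagonal family already passes
the interpolation, symmetry and oracle-agreement checks, and keeps the cost
linear in n per step. Prediction propagates q through the GP conditionals
and Monte Carlo samples the argmax.

## RACC ensemble

B1 weak learners; each draws B2 subspaces from the hierarchical-uniform
distribution (size uniform on {1..D}, then features without replacement),
keeps the candidate minimizing out-of-bag misclassification of the base
learner (SVM by default) on a 63.2% bootstrap portion, and trains on that
portion restricted to the chosen subspace. The published selection criterion
and threshold rule are unspecified; out-of-bag error uses only training data,
and the vote threshold α defaults to 0.5 with an optional grid search on
{0.30..0.70} by training error. Binary labels use the thresholded vote
fraction; multiclass is one-vs-rest by argmax of vote fractions. The
per-feature chosen proportion η is reported and, on planted designs,
concentrates on informative features.

## LSTM with focal loss

The cell is nonstandard: all gates read [a_{t−1}, x_t, c_{t−1}]
(peephole-style, as the gate equations print). The published cell update is
self-referential as printed; c_t = f_t⊙c_{t−1} + i_t⊙c_in is the only reading
consistent with the surrounding description, and the implementation verifies
its memory property (f ≡ 1, i ≡ 0 conserves c over any horizon). The
architecture is input → one recurrent layer → two fully connected layers →
softmax ("four layers" counted with the input layer). Focal loss
−(1−ŷ)^γ log ŷ with γ = 2, dropout 0.1, batch 128, hidden size 64, Adam —
the reference hyperparameters; tests use smaller widths for speed. The whole
network is numpy with hand-derived backpropagation through time (checked
against finite differences to ~1e−10) — no deep-learning framework is
involved, which also keeps the nonstandard gate wiring exact. 3000-sample
epochs reshape to 60 steps × 50 features by default (config-exposed; the
input shaping is not dictated by the architecture).

## Pipeline and evaluation

Stage chain: featurize → cluster → representative selection (default ratio
90000/127658 ≈ 0.705 of the input, the proportional analogue of the
full-scale protocol) → ranking reduction (factor 3) or VBMF row embedding →
SGL-DLI or RR-LWS feature budget → classifier under stratified 10-fold CV.
The deep (LSTM) route bypasses reduction and selection and consumes the
clustered epochs directly. Reports carry per-fold predictions, the pooled
confusion matrix, accuracy, Cohen's κ (marginal-product chance correction;
degenerate single-class input defined as 0 with a warning), and rank-based
significance tests (Friedman across ≥3 classifiers, paired two-sided
Wilcoxon). Everything is deterministic given the seed. CV stratifies by
merged class at epoch level; subject-level grouping is a caller
responsibility when subject provenance is present.

## Synthetic data

* `gen_sleep_epochs`: epochs are sums of band-limited Gaussian noise
  weighted by per-class band-power profiles plus broadband noise. This
  captures the spectral signature of stages (delta-dominant deep sleep,
  alpha/beta-rich wake) and nothing else — no spindles, K-complexes,
  artifacts, inter-subject variability, or stage transitions. Pipeline
  accuracies on these data demonstrate implementation correctness of the
  chain, not clinical performance on real polysomnography.
* `gen_subspace_points`, `gen_pairwise_comparisons` (score differences
  corrupted to U[−M, M] with probability 1−η), `gen_lowrank_matrix`, and
  `gen_group_sparse_regression` provide ground-truthed fixtures for each
  stage; all are pure functions of (parameters, seed).

## Problem sizes

The test suite and the acceptance script run at desk scale by choice: 600
epochs for the end-to-end chain (reduced 600 → 424 → ~144), 30×20 designs
for screening safety, n ≤ 8 complete graphs for exact rank recovery, 20×15
matrices for VBMF, four sites × 250 samples for the distributed ridge. The
stage ratios — not the absolute counts — are what the full-scale protocol
fixes, and they are preserved.

## Known limitations

* Real-data accuracy claims are out of scope; the package supports sleep-EDF
  style inputs but ships no recordings.
* The GP classifier is dense (O(n³) kernel factorizations) and intended for
  n up to a few thousand.
* The EDF writer is a minimal 16-bit single-record implementation for
  round-tripping synthetic signals, not a general EDF+ producer; EDF+
  annotation grammars are not parsed.
* Epoch-level CV can leak subject identity across folds when multiple
  epochs per subject are present.
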