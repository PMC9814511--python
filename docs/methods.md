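# Methods

`gradientspace` re-implements, as a tested pipeline, the cortical-gradient
analysis used to characterize depressed and altered states of
consciousness: parcellated fMRI time series are cleaned, converted to
functional-connectivity (FC) matrices, embedded with a diffusion map,
summarized by gradient-space geometry statistics and co-activation
pattern (CAP) dynamics, and compared across conditions with classical and
JZS Bayes-factor statistics.  A synthetic-cohort generator with a known
latent gradient geometry serves as ground truth for every downstream
stage.  This note documents the models, the parameters that matter, the
numerical choices, and what the validation studies do and do not show.

## Preprocessing model

Frame-wise displacement (FD) is the Euclidean norm of the six
motion-parameter first differences (`fd[0] = 0`); a frame with
FD > 0.4 mm is censored together with its preceding frame.  On the
retained frames a single OLS projection removes: intercept, polynomial
drift (default order 2), the six motion parameters and their first
differences, optional white-matter/CSF averages, optionally the global
mean signal (GSR, default on), and sine/cosine pairs at every DFT
frequency outside the 0.01–0.1 Hz passband.  Band-passing by regression
(rather than an IIR filter) is well defined across censored gaps and
makes censor-then-filter exactly equal to row deletion followed by
regression; the projection is idempotent.  Each parcel is finally
standardized to zero mean, unit variance over retained frames.

Degrees-of-freedom guard: the band-stop columns occupy a fixed fraction
of the spectrum by construction, so the guard is on the residual dof
after the whole design — it must be at least half the count of
non-spectral nuisance regressors and at least 5.  Rotational motion
inputs are taken as mm-equivalent; a CLI flag converts degrees via an
arc-length factor.

## Connectivity and affinity

Pearson correlation over retained frames, Fisher z-transform with the
diagonal set to 0 (a self-connection carries no profile information and
+inf would always survive thresholding), perfect correlations clipped at
`atanh(1 - 1e-7)`.  Row sparsification keeps the top
`ceil((1 - s) P)` entries per row by signed value (s = 0.9 by default,
i.e. top 10%; ranking by magnitude available via a flag), ties broken by
(value desc, column asc).  The affinity between two parcels is the
normalized cosine angle between their sparsified row profiles,
`a = 1 - arccos(cos) / pi`, which is symmetric by construction even
though sparsification is row-wise.

## Diffusion-map embedding

With degrees `d_i = sum_j a_ij`, the kernel is density-normalized,
`w_ij = a_ij / (d_i^alpha d_j^alpha)` (alpha = 0.5 by default), and
row-normalized into a Markov operator whose eigenvectors are computed
through the symmetric conjugate for numerical stability.  The trivial
constant eigenvector is dropped; component m is scaled by
`lambda_m / (1 - lambda_m)` at diffusion time t = 0 (damped
regularization) or by `lambda^t` for t > 0.  Variance explained is each
retained eigenvalue's share of the retained non-trivial spectrum
(10 components by default) — the denominator matters and is stated here
because different conventions circulate.

Alignment is orthogonal Procrustes (rotation/reflection only): scaling
is excluded because gradient range is a downstream outcome and must not
be absorbed by alignment.  Every individual embedding is aligned to the
same external reference.  The choice of reference is load-bearing:

* a reference built from the baseline condition's own scans biases
  baseline-vs-condition contrasts (we measured null-cohort type-I error
  rising to ~0.12 before fixing this);
* a pooled all-condition reference lets a strong condition effect
  reorder the gradient labels;
* the default is therefore a reference from an *independent* healthy
  cohort (for synthetic studies, simulated from the same population
  template; for real data, supply a reference gradient file), mirroring
  the common practice of aligning to an external healthy-population
  gradient set.

## Gradient-space geometry

On the first three aligned gradients: per-gradient range (max − min
loading), global dispersion (sum of squared distances of all parcels to
the global centroid), per-network eccentricity and pairwise network
centroid distances (squared Euclidean by default, unsquared via a flag —
both conventions appear in the field, so every reported number should
state which it used).  Dispersion satisfies the law-of-total-variance
decomposition over networks exactly.

## CAP dynamics

Eight pattern centroids (one signed indicator per network plus global
activation/deactivation GN+/GN−) or k-means-derived centroids (z-scored
volumes, Euclidean distance, best of n restarts, seeded).  Each retained
volume is assigned to its most spatially similar centroid (Pearson
correlation across parcels; ties to the lowest index; zero-variance
volumes fall back to dot products with a warning).  Occurrence rates are
fractions of retained volumes — censored frames leave both numerator and
denominator.  Kendall tau-b links per-scan network distances to
occurrence rates, FDR-corrected within the family of tested pairs.

## Statistics

Paired comparisons use a one-sample t on differences, independent ones a
pooled-variance Student t (Welch available).  The JZS Bayes factor puts
a Cauchy(0, 0.707) prior on the standardized effect; the marginal
likelihood is a trapezoid quadrature of the noncentral-t likelihood
against the prior on an adaptively expanded grid (expansion stops when
the outermost contribution is < 1e-8 of the integral), and the same
normalized integrand yields the posterior median and equal-tail 95%
interval.  The quadrature reproduces published JASP-style BF10 values to
< 0.1% and agrees with a 10^6-draw Monte-Carlo marginal-likelihood
estimate to < 1%.  Evidence labels follow the Jeffreys-style bins with a
`BF10 > 10` pass flag.  BH-FDR is applied within each dataset's family
of classical p values.  Rank tests (Wilcoxon signed-rank W+ with exact
small-sample null, Mann–Whitney U) are cross-checked against exhaustive
enumeration.

## Synthetic cohort generator

Signal model per scan:
`x(t) = g0 f0(t) + U f(t) + A c_{s(t)} + eps(t)`, with unit-variance
latent series band-limited to the preprocessing passband (so filtering
cannot leak condition effects), a common-mode loading g0 = 2.0, CAP
amplitude A = 5.0 on a sticky 8-state Markov chain, and i.i.d. Gaussian
noise (sd 2.0).  Defaults: 120 volumes at TR 2 s (4-minute scans),
subject-level network jitter at 10% of the between-network spread,
0.6 mm motion spikes at 0.5/min so scrubbing is exercised.

The latent geometry is the part that required genuine design work:

* **Ellipsoid-surface layout.**  Parcels tile an ellipsoid
  (semi-extents 1.0 / 0.95 / 0.9) quasi-uniformly via a jittered
  spherical Fibonacci lattice; networks are contiguous regions sized to
  the parcellation (balanced nearest-anchor assignment).  Functional
  networks tile real gradient space the same way.  On a closed,
  quasi-uniformly sampled surface the three coordinate functions are the
  leading smooth modes of any local similarity graph, so the pipeline's
  embedding is essentially linear in the planted coordinates (measured
  Procrustes disparity 0.002–0.003).  Cluster-concentrated layouts
  (each network a Gaussian blob) distort kNN-graph spectral embeddings
  badly (disparity 0.15–0.35) and are kept only as an explicit
  `layout="cluster"` option.  The distinct semi-extents give the three
  gradients distinct eigenvalues, mirroring the declining variance
  shares of empirical gradients, and keep all linear modes above the
  first quadratic harmonic.
* **Common mode.**  Correlations normalize per-parcel scale twice in
  this pipeline (Pearson, then cosine of profiles); without a shared
  global component only the *directions* of latent vectors would be
  identifiable.  The common-mode loading anchors the scale so positions
  are encoded.  Note that GSR removes most of the common mode, so
  preprocessing with GSR pushes the pipeline toward direction-only
  geometry; the validation studies run on clean generated data without
  nuisance projection, and preprocessing is validated separately.
* **Saturating compression.**  Gradient degradation is modeled as a
  monotone warp that squashes the *extremes* of a latent axis
  (`f(x) = x (1 - (1-c)|x/a|^p)`, `p = c/(1-c)`, rescaled so the
  planted range scales exactly by c).  An affine squash would shrink the
  manifold area and thereby shift the other gradients' eigenvalues (the
  kNN sparsification adapts its bandwidth to density), producing
  spurious cross-axis effects; saturating only the sparsely populated
  tails leaves cross-axis drift at ~1% while the compressed axis
  responds strongly.  This also matches the substantive interpretation
  of degradation as loss of differentiation at the gradient extremes.
* **Geometry-coupled CAP occupancy.**  A condition's VAN–DMN
  contraction multiplies the VAN+ stationary rate by `exp(+beta dd)` and
  the DMN+/DAN+ rates by `exp(-beta dd)` (dd = latent distance change),
  renormalized; scan transition matrices are rebuilt around the coupled
  stationary law.

Because the embedding is eigenvector-normalized (scale-free), a planted
compression maps to a *smaller but not proportional* embedded range
reduction (c = 0.6 yields an embedded gradient-1 range ratio ≈ 0.73–0.87
depending on noise regime); detection operates at the level of paired
contrasts, not absolute ratios.

## What the validation studies show — and what they do not

The studies (in `gradientspace.studies`, exercised by the test suite and
`scripts/acceptance.py`) demonstrate: exact spectral agreement with a
dense oracle; recovery of planted geometry through the full default
pipeline; 50/50 detection of a planted gradient-1 compression at n = 26
with ≤ 5% false positives on the other gradients; per-metric type-I
error within [0.02, 0.08] on 200 null cohorts; the expected sign
structure of the geometry–dynamics coupling (tau ≈ −0.4 for VAN+,
+0.6 for DMN+); and < 1% agreement of the Bayes factor with its
Monte-Carlo oracle.

The generator emulates multi-subject band-limited signals with latent
low-rank correlation structure, motion spikes, and Markov CAP dynamics.
It does not emulate hemodynamic convolution, spatially autocorrelated
or physiological (respiratory/cardiac) noise, scanner drifts beyond
polynomials, site effects, or real atlas geometry — so passing these
studies shows the *pipeline* is correct and well calibrated under the
stated model, not that effect sizes on real recordings will match.

## Problem sizes

Power, recovery, and coupling studies run the full 400-parcel scheme
(26 paired subjects, 120-volume scans; 50 replicate cohorts for power).
The null-calibration study uses a proportionally reduced 300-parcel
scheme with 16 subjects per cohort so 200 replicate cohorts fit in a
routine validation run; geometry metrics are parcel-count-normalized in
nothing — rates, not magnitudes, are compared there.

## Known limitations

* The bundled 400-parcel scheme is a synthetic stand-in reproducing the
  canonical network sizes and naming convention, not the real atlas
  lookup table (substitute via `ParcellationScheme.from_tsv`).
* With GSR enabled the synthetic common mode is removed and latent
  radius information degrades; condition contrasts remain valid but
  absolute geometry values shift.
* Bayesian rank tests, Bayesian Kendall correlations, assumption checks
  (Shapiro–Wilk, Levene), and power analysis are out of scope; classical
  rank tests and Kendall p values are provided.
* CAP dwell-time and transition-probability analyses beyond occurrence
  rates are not implemented.
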