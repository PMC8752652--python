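# Methods

This note documents the models, the numerical choices, and what the
synthetic benchmark does and does not demonstrate.

## Lesion model and phantom generator

Each phantom patch holds one mass on a low-frequency tissue background.
The outline is a radial curve about the patch center,

    r(θ) = R · (1 + a · s(θ)),

where `R` is `base_radius` (px), `a` is `spiculation_amplitude` ∈ [0, 1),
and `s(θ)` is a zero-mean periodic perturbation with max |s| = 1: a cosine
carrying `spiculation_count` lobes plus Gaussian harmonic jitter, low-pass
filtered at the `boundary_smoothness` harmonic. Because r(θ) is
single-valued in θ, the boundary polygon is always simple and closed. The
polygon is sampled at 180 angles, so its area differs from the ideal
πR²(1 + a²/2) only by discretization.

The interior is filled with fractional-Brownian-motion-like texture from
spectral synthesis: white complex Gaussian Fourier coefficients shaped by
an isotropic amplitude spectrum f^−(H+1) — i.e. power ∝ 1/f^(2H+2), the
spectral density of a 2-D fBm surface. That exponent is deliberate: it
makes the pairwise increment scaling E|I(p) − I(q)| ∝ d^H hold with the
target `texture_hurst`, so the fractal feature estimator has a recoverable
ground truth (the 1-D convention 2H+1 would bias it). The field is scaled
to `texture_contrast` gray levels of standard deviation and added to a
mass plateau 45 gray levels above `background_level`; output is 8-bit,
matching the quantization assumptions of the co-occurrence features.

Class presets encode the clinical contrast: benign masses are near-round
(a = 0.10, 6 lobes, smoothness cutoff 8) with smooth homogeneous interiors
(H = 0.60, contrast 14); malignant masses are spiculated (a = 0.30, 11
lobes, cutoff 18) with rough heterogeneous interiors (H = 0.40, contrast
24). Per-sample jitter (radius ±20%, amplitude ×U(0.5, 1.5), H ±0.15,
contrast ×U(0.7, 1.3), lobe count ±2) is wide enough that the
class-conditional distributions overlap at the margins — cohorts contain
borderline lesions, and a benchmark should too. No public quantitative
parameters exist for these presets; they are calibration choices, fixed
once. Per-sample seeds are hashed from (master seed, sample index), so
regeneration is order-independent and bit-exact.

**What the phantom does not emulate:** full-breast anatomy, pectoral
muscle, calcifications, overlapping tissue, acquisition noise, scanner
variation, or annotation error. The phantom classes remain more separable
than real benign/malignant cohorts, so benchmark accuracies (high 90s)
exceed what the same pipeline achieves on clinical data; passing tests
demonstrate the *machinery* (feature correctness, selection behavior,
evaluation protocol), not clinical performance.

## Feature battery — numerical choices

Texture operators consume the full rectangular ROI (convolutions and
co-occurrence counting need a dense grid), geometry operators the binary
mask only. Choices the feature definitions leave open:

* **Quantization** (SGLCM/GLDS/SFM): gray values are shifted to zero
  minimum and requantized to G = 32 bins only when more than G distinct
  values remain; small-range inputs keep their exact differences.
* **SGLCM**: displacement 1, four directions (0°, 45°, 90°, 135°),
  symmetric accumulation, the 14 Haralick statistics averaged over
  directions. Natural logarithms. Degenerate (flat) patches: correlation
  and the maximal correlation coefficient fall back to 0 rather than NaN;
  the information-measure denominators guard against zero marginal
  entropy.
* **GLDS**: displacement set {(0,1), (1,0), (1,1), (1,−1)}, features of
  each difference density averaged; 0·log 0 := 0.
* **FOS**: population moments; non-excess kurtosis; zero-variance patches
  report skewness = kurtosis = 0.
* **SFM**: displacement lattice 0..4 × 0..4. Coarseness = n/ΣDSS over the
  non-zero displacements (0 for flat patches); contrast =
  √((CON(0,1)+CON(1,0))/2); periodicity = relative depth of the deepest
  dissimilarity valley; roughness = mean of the two axis-wise fractal
  dimensions 3 − H fitted to log DSS vs log distance.
* **LTEM**: 5×5 masks from L5/E5/S5/W5/R5 outer products; energy = mean
  absolute response over fully-overlapping positions; mixed pairs (XY, YX)
  averaged into one of the 14 named features; no L5L5 normalization.
* **Fractal**: H1 = least-squares slope of log mean-absolute-difference
  vs log distance over rounded pixel distances 1–8 (all displacement
  vectors pooled per distance); H2 = the same over 1–4 after 2×2 block
  averaging; estimates clipped to [0, 1]; flat patches report (0, 0).
* **FPS**: power fractions of the non-DC spectrum — an annulus from a
  quarter to a half of the Nyquist frequency (S_r) and a ±22.5° wedge
  about the horizontal-variation axis (S_θ).
* **Shape**: equivalent-ellipse axis statistics; orientation in degrees in
  (−90, 90] from the row axis; convex area counts pixel centers covered by
  the hull of the foreground pixel centers; Euler number uses 8-connected
  foreground; perimeter is the half-level contour length of the
  zero-padded mask (sub-pixel marching squares), so the circularity ratio
  of a digital disk lands near 1 within discretization tolerance.
* **Zernike**: computed on the binary mask (the descriptor group is
  geometric), pixel centers mapped to the closed unit disk by centroid
  centering and division by the maximum centroid distance; magnitudes
  reported, which are rotation-invariant and exactly equal for conjugate
  orders (n, ±m).
* **GFD**: polar frequency grid R = 4 radial × T = 13 angular = 52
  descriptors, each mask pixel contributing
  exp(−j(2π·r·ρ + θ·φ)) with r the normalized centroid distance; the DC
  coefficient is normalized by area (FD1 ≡ 1, scale invariance), the rest
  by |PF(0,0)|. Centroid centering gives exact translation invariance;
  magnitudes give rotation invariance up to rasterization.

## Selection and evaluation

All selectors see z-scored features (configurable) with classes coded
benign = 0 / malignant = 1. Relief-F uses k = 10 nearest hits and misses,
every sample as a target (m = n — weight estimates stabilize as m grows),
Euclidean neighbor distances, range-normalized value differences, and
distance ties broken by sample index; weights are bounded in [−1, 1] and a
constant feature scores exactly 0. The diagonal NCA ascends the expected
leave-one-out soft-neighbor assignment probability with kernel exp(−d_w),
d_w = Σ w_f²Δ_f², from w = 1 for 200 iterations at learning rate 0.1 with
an L2 penalty λ = 1/n; the penalty uses an implicit (proximal) update so
arbitrarily strong regularization shrinks weights stably instead of
diverging. A caveat found while validating: cohorts containing exact
duplicate rows saturate the soft-neighbor kernel (every point gains a
zero-distance same-class neighbor) and slow the ascent, so duplicated data
needs more iterations to reach the same ranking.

Relief-F's ability to recover injected signal depends on cohort size: with
a pooled Bayes accuracy of 0.9 spread over 6 of 125 features, recovery of
all six into the top twelve is near-certain at a few hundred samples but
becomes unreliable at cohorts of ~100 — a genuine small-sample limitation
of nearest-neighbor-based filters in noise-dominated feature spaces. The
recovery check is therefore run at 100 samples per class, the scale at
which a correct implementation is expected to succeed reliably.

k-NN uses explicit distance matrices (Euclidean, cosine with zero-norm
vectors at distance 1, Minkowski order 3), equidistant neighbors admitted
by ascending training index, vote ties resolved by the nearest neighbor,
and squared-inverse weights 1/(d² + 1e−12) so coincident neighbors
dominate. Cross-validation is stratified 10-fold, repeated 10 times with
fold seeds = master seed + repeat index; features are standardized with
training-fold statistics only; each repeat's metrics are computed on the
pooled fold predictions (more stable than per-fold averaging at ~115
samples) and repeats are averaged. The compact subset comes from greedy
sequential forward selection over the top-20 candidates (a deterministic
replacement for manual subset picking): additions must strictly improve
mean accuracy, ties break by sensitivity then lower feature index, the
search stops at 9 features, and the full candidate set is also evaluated
so the returned subset is never worse than using all candidates on the
same seeds.

## Known limitations

* Phantom separability exceeds clinical reality (above); absolute
  accuracies on the benchmark should not be quoted as diagnostic
  performance.
* The SFM scalar definitions follow the dissimilarity-matrix family but
  fix their own valley/decay readings of periodicity and roughness; other
  implementations differ in detail.
* The fractal estimator is biased toward 0.5 at extreme Hurst values
  (finite patches, rounded distances); orderings are reliable, absolute
  values near the ends of (0, 1) are not.
* Zernike moments are truncated at order 4 (15 magnitudes); fine boundary
  detail beyond that order is carried only by the Fourier descriptors.
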