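# Methods

`epifly` detects epileptic-seizure activity in single-channel EEG records.
A record is decomposed by a tunable Q-factor wavelet transform (TQWT), a
fused feature vector is extracted (time-domain statistics, power-spectrum
descriptors, chaotic/fractal measures per subband, plus gray-level
co-occurrence textures of the whole record viewed as an image), a firefly
metaheuristic with simulated-annealing refinement selects a compact feature
subset by wrapper fitness, and a random forest classifies seizure vs
seizure-free with repeated stratified cross-validation.

## Tunable Q-factor wavelet transform

The TQWT is an oversampled two-channel filter bank iterated J times on its
low-pass branch. Its three user parameters are the Q-factor Q ≥ 1 (number
of oscillations of the wavelet), the redundancy r > 1, and the stage count
J. They map to the per-stage scaling factors

    β = 2/(Q+1),   α = 1 − β/r,

so a length-N band splits into a low-pass band of length ≈ αN and a
high-pass band of length ≈ βN. The low-pass response is 1 below
(1−β)π, 0 above απ, and follows the transition prototype
θ(ω) = ½(1+cos ω)√(2−cos ω) in between; the high-pass response is its
power complement (θ(ω)² + θ(π−ω)² ≡ 1), which is what makes the bank
perfectly invertible.

Because α and β are in general irrational, the bank is realised in the
frequency domain. Numerical choices:

* Each band is transformed with a **unitary DFT**, multiplied by the
  responses sampled on that band's grid, and resampled by spectral
  truncation (low-pass keeps the low bins, high-pass the high bins).
  Unitary scaling makes the subband energies sum exactly to the signal
  energy.
* Band lengths are rounded to even integers, N0 = 2·round(αN/2),
  N1 = 2·round(βN/2), so the recursion never meets an odd length.
* The transition band is sampled on **integer breakpoints**: pass band
  P = (N−N1)/2 bins, T = (N0+N1−N)/2 − 1 interior θ samples, stop band
  from bin N0/2. Ending the transition exactly on the low-pass subband's
  Nyquist bin keeps the two responses power complementary *on the sampled
  grid*, so reconstruction is exact to rounding (measured ≲ 1e−14,
  asserted < 1e−8).
* Real inputs stay real: positive and negative frequency bins are mirrored
  explicitly and the imaginary residual is asserted < 1e−10 before it is
  discarded.
* Odd-length records (Bonn records have 4097 samples) are zero-padded by
  one trailing sample, recorded in the decomposition metadata and stripped
  on synthesis.
* J is capped at the largest value keeping the final low-pass band ≥ 8
  samples; shorter bands cannot sample the transition band.

## Feature sets

Thirteen features per subband, four textures per record; with the default
J = 3 that is 13·4 + 4 = 56 named columns (`sb1_mean` … `glcm_homogeneity`).

Time domain: mean; sample standard deviation and variance (N−1 divisor);
Shannon entropy of a 16-bin equal-width amplitude histogram, in bits
(16 bins is fixed for determinism; entropy implemented as −Σp·log₂p so it
is non-negative); approximate entropy ApEn(m=2, r=0.2·STD) — the Pincus
regularity statistic φᵐ(r) − φᵐ⁺¹(r) with self-matches and Chebyshev
distance, the universal defaults. The production ApEn counts template
neighbours with a k-d tree; the O(N²) double loop exists only as a test
oracle.

Spectrum (one-sided magnitude spectrum, DC included): centroid and spread
in bin-index units (the spread is the magnitude-weighted second moment
around the centroid); flatness = geometric/arithmetic mean ratio over the
nonzero bins (1 for a flat spectrum); slope = ordinary least-squares slope
of |Y| against physical frequency in Hz; spectral entropy in nats of the
magnitude-normalised spectrum. An all-zero band reports all five as 0 and
is flagged degenerate rather than raising.

Chaotic: Higuchi fractal dimension (kmax = 10, the common default; exactly
1 for a line, →2 for white noise); rescaled-range Hurst exponent on dyadic
windows 8…N/2 (≈0.5 for i.i.d. noise, →1 for integrated noise; the fitted
scaling constant is returned but is not a feature; the plain R/S estimator
carries the usual small-sample upward bias at 0.5, within the tolerances
used); Katz fractal dimension with Euclidean polyline length and extent,
which makes a straight line of any slope exactly 1 and bounds the value
below by 1.

Textures: the record is min–max quantised to 8 gray levels and reshaped
row-major to the most-square w×h grid (w = floor(√N); 4096 retained
samples → 64×64), then a symmetric, normalised co-occurrence matrix at
displacement (0, 1) yields energy, contrast, correlation and homogeneity.
The smallest standard Haralick setup is fixed for determinism; textures are
computed on the whole record, not per subband. A single-level image has
zero marginal variance; its correlation is defined as 1.

## Firefly wrapper selection

Candidate subsets live as points in [0,1]^D; thresholding at 0.5 gives the
mask. Fitness is f = w1·acc + w2·(1 − |S|/D) with w1 = 0.9, w2 = 0.1: the
second term *rewards* parsimony, which matches the selector's purpose of
shrinking the feature set (an empty mask scores −∞). Accuracy comes from
stratified inner cross-validation of a reduced random forest on the masked
table, seeded for determinism and memoised by mask.

Search mechanics per iteration: rank the swarm; identify the leader g_best
and a second leader S_best — the fittest firefly farther from g_best than
the median pairwise distance (runner-up as fallback), so two distinct
regions guide the swarm; refine the leaders' midpoint by simulated
annealing into the guide g_best′; move every dimmer firefly by

    x ← x + β0·C_k·(x_j′ − x) + C_k·ε·(g_best′ − x) + α′·sign(rand − ½)

where x_j′ is the nearest brighter neighbour plus Gaussian jitter
(σ = 0.1), C_k is a chaotic logistic-map factor, ε ~ U[−0.5, 0.5], and the
random-walk step α′ decays linearly 0.5 → 0.05 over the run; apply per-bit
mask mutation (p = 0.01) by reflecting the coordinate across the
threshold; contract the worst firefly toward the leaders' midpoint with a
Gaussian factor. Positions are clipped to [0,1]^D. The swarm itself is
initialised from a single logistic-map stream (x₀ drawn away from the
map's fixed points, 100-step burn-in).

The SA refinement starts at the midpoint of the two leaders and iterates
single-coordinate Gaussian perturbations (σ = 0.6), i.e. local moves that
toggle roughly one mask bit at a time; worse candidates are accepted with
p = exp(Δf/T) under a linear cooling schedule from T = 1 to 0.01, and the
best position ever visited is kept. Single-coordinate moves were chosen
over full-vector jitter because the selection landscape is a noisy
pseudo-Boolean function: one-bit neighbourhood search around the leaders is
what reliably discovers "add the one missing informative feature / drop one
redundant feature" moves.

Cost defaults: the inner wrapper uses a 10-tree forest with 2-fold
stratified CV and an 8-step SA budget. A 30-iteration, 20-firefly run makes
roughly 900 distinct mask evaluations; these defaults keep a 20-seed
recovery experiment within minutes on one CPU while still recovering all
planted features in ≥ 90% of seeds. All three knobs are `SelectionConfig`
fields; heavier settings (e.g. 25 trees, 3 folds) only sharpen the fitness
estimate. The result reports the best mask ever evaluated, so the fitness
history is non-decreasing and the final best never falls below the initial
best.

## Classification and evaluation

The classifier is a bagged ensemble of unpruned CART trees: each tree grows
on a bootstrap resample to maximal depth with √D candidate features per
split, and prediction is the majority vote (scikit-learn's
`RandomForestClassifier` stands behind this surface; 100 trees by default,
the community default since the ensemble size is not otherwise
constrained). Vote ties break toward the seizure-free class, the
deterministic conservative choice. Labels are 0 = seizure-free,
1 = seizure; the positive class is the seizure.

Evaluation is repeated stratified k-fold cross-validation (10 folds × 10
repeats by default). Confusion counts are pooled over the folds of each
repeat, the five metrics — sensitivity, specificity, accuracy, F-measure,
Matthews correlation — are computed per repeat from the pooled counts and
averaged over repeats; pooling was chosen over macro-averaging across folds
because fold-level counts are small and pooled ratios are unbiased by fold
imbalance. All metrics are percentages; an undefined sensitivity or
specificity (empty class) is reported as missing, and a zero MCC
denominator yields 0, flagged degenerate.

## Synthetic data

The generator emulates the layout of the public Bonn benchmark: 4097
samples per record at 173.61 Hz (~23.6 s), single channel, three classes.
Healthy records are band-limited (0.5–30 Hz) Gaussian noise with a 1/f^0.7
amplitude rolloff (the mild colouring gives the Hurst and fractal features
non-trivial values), unit standard deviation. Seizure-free (interictal)
records add 4–8 sparse Gaussian-shaped transients of 2–3.5× the background
scale. Ictal records are a dominant rhythmic oscillation at 3–7 Hz with
second and third harmonics over 0.35× background noise, normalised to ten
times the healthy standard deviation — the order-of-magnitude subband
amplitude contrast seizure recordings show against background EEG, which
also places the ictal spectral centroid below the healthy one. Per-record
seeds spawn from a master seed, so datasets are reproducible and records
pairwise distinct.

The planted-feature tables used to exercise the selector hold two balanced
Gaussian classes: the informative columns are shifted by a standardised
effect size (default 3) in class 1; all other columns are N(0,1) noise in
both classes.

What the generator does **not** emulate: physiological EEG morphology
(neural mass dynamics, spike-wave complexes), recording artifacts (EMG,
eye blinks, electrode drift), inter-subject variability, or
non-stationarity within a record. Passing the end-to-end check therefore
demonstrates that the pipeline's mechanics — decomposition, feature
fusion, selection, classification, and their seeding — are correct and
that the advertised amplitude/rhythmicity contrast is exploited; it does
not certify clinical performance on real recordings, where class contrasts
are far subtler.

## Problem sizes used in the checks

The shipped checks run the filter-bank exactness grid on ~100 random
signals over (Q, J) ∈ {1,2,3}², the feature oracles on 50 random
length-256 signals and 50 random 8×8 images, the selector recovery on
twenty 200×50 planted tables (20 fireflies, 30 iterations), and the
end-to-end experiment on 100 seizure-free + 100 ictal synthetic records
with the default configuration plus a 3-permutation label-shuffle null.
These sizes were chosen as the smallest at which each property is stable
across seeds.

## Known limitations

* The TQWT here targets analysis/synthesis correctness, not speed; there is
  no radix-2 fast variant, and no wavelet-domain denoising.
* Hurst and Higuchi estimators need reasonably long bands (≥ 64 samples for
  R/S); deep decompositions of short records will refuse to featurise the
  final low-pass band.
* The wrapper fitness is a noisy estimate; with very small tables the
  parsimony term (w2/D per feature) can be smaller than the accuracy noise,
  and redundant noise features survive in the selected mask even when all
  informative ones are found.
* Only the two-class task (seizure-free vs ictal) is wired end to end; the
  three-class healthy/interictal/ictal problem is supported by the
  generator but not by the binary confusion metrics.
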