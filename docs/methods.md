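# Methods

This note documents the models, estimator choices, defaults and known
limitations of `qusradiomics`, in the package's own terms. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Acquisition model and geometry

Frames are 2-D grids of digitized backscatter voltage (axial sample × scan
line). Defaults follow a linear-array acquisition: 8 MHz nominal center
frequency, 40 MHz sampling, 256 scan lines over a 3.8 cm lateral field of
view (0.1484 mm/line), assumed sound speed c = 1540 m/s (the soft-tissue
standard; the acquisition description leaves it unstated). The axial sample
pitch is c/2fs = 19.25 µm. Depths are measured to the sample itself with
0-based indices; gate-center depths are derived downstream. Volumetric
sweeps are out of scope — multi-plane data are treated as independent 2-D
frames whose features can be averaged.

## Spectral chain

* **Gating.** 2 × 2 mm windows, 94% overlap by default (step 0.12 mm), with
  the *center-in* convention: a window contributes wherever its center
  pixel lies inside the ROI, maximizing node coverage. Each scan line in
  the gate is Hann-tapered and zero-padded to 4× the gate length; the
  window spectrum is the mean per-line periodogram. Taper and FFT length
  are our choices (the protocol leaves them open) and are configurable.
* **Reference normalization.** The phantom spectrum used for a gate comes
  from the *same axial gate position*, averaged over all phantom frames and
  a spread of lateral positions, so the depth-dependent system response
  cancels. The −6 dB analysis band (maximal contiguous interval with power
  ≥ peak/4) is detected once per dataset from the reference spectrum, not
  per window, so features are comparable across subjects; plateau ties
  break toward lower frequency.
* **Attenuation.** Spectral log difference: per in-band frequency, the
  normalized dB power is regressed on gate depth; those depth slopes are
  regressed on frequency, whose slope is −4·Δα. The estimate is a single
  linear-in-frequency coefficient (dB·cm⁻¹·MHz⁻¹), clamped at zero with a
  warning. Correction is point compensation at the gate-center depth:
  +4·Δα·f·z dB. ROIs spanning < 0.5 cm of depth fall back to the phantom's
  α with a warning.
* **Line fit.** Ordinary least squares of in-band dB power on frequency;
  SS = slope, SI = intercept at 0 MHz, MBF = fitted value at the band
  center, so MBF ≡ SI + SS·f_mid to machine precision.

## Scatterer properties

* **BSC inversion.** `BSC(f) = BSC_ref(f)·10^{S̃/10}` is fitted in log10
  space against `C·f⁴·FF(f;a)`. For each candidate radius the optimal
  log-concentration is closed-form; the radius is scanned on a 1–150 µm
  grid (0.1 µm step, cached form-factor tables) and refined by the
  parabolic vertex of the three bracketing SSE values. Grid-edge solutions
  carry a boundary flag. ASD = 2a (µm); AAC = 10·log₁₀C (dB) on the
  generator's arbitrary concentration scale.
* **Form factors.** Gaussian: exp(−0.827·k²a²). Anderson fluid sphere: the
  partial-wave series with fixed weak contrast (density ratio 1.02,
  sound-speed ratio 1.05, sphere/medium — the model's classic constants are
  not stated in the protocol, so these are package defaults), truncated at
  l_max = ka + 4·ka^{1/3} + 8 and normalized by its Rayleigh limit
  (the backscatter sum scales as (ka)⁶) so FF(0) = 1. The two models agree
  within 5% for ka ≤ 0.3, which the tests assert.
* **SAS.** Burg AR(10) spectra (order configurable; the protocol does not
  state it, and the ambiguous phrase "AR model on the power spectrum" is
  resolved as AR on the gated RF, yielding an AR power spectrum) are
  averaged over lines — and over gates when several are supplied —
  normalized by the planar-reflector spectrum and autocorrelated over the
  in-band frequency axis. The first peak at lag ≥ 0.4 MHz whose prominence
  is ≥ 3× the RMS of the autocorrelation over the searched lags defines the
  comb period Δf, and SAS = c/2Δf. The RMS scale replaces a median-based
  scale deliberately: the median of a decaying autocorrelation is dominated
  by near-zero large-lag values and lets white-noise ripple pass the gate.
  Windows without a significant peak are *undefined* (NaN in the map), not
  errors — diffuse random media genuinely have no spacing. A 5%-jittered
  lattice keeps its comb only in expectation (in-band comb orders n = 2–4
  decay like exp(−(2πnσ/s)²)), so accurate spacing recovery requires
  averaging the spectra of many gates; single 2 mm gates lose it.

## Texture radiomics

Maps are min–max quantized per subject to Ng = 16 tones (global
quantization would couple subjects; the min–max choice also makes textures
exactly invariant to affine rescaling of a map). GLCMs are symmetric,
accumulated at distances {1,2,3,4} lattice steps (values unstated in the
protocol) × directions {0°,45°,90°,135°}, with NaN pixels excluded
pairwise. Contrast, correlation, energy and homogeneity follow the standard
definitions with marginal moments; correlation is missing when a marginal
SD vanishes, and per-feature averages over the 16 GLCMs skip missing
entries. Constant maps flag their textures missing. The feature vector is
8 map means + 32 textures = 40 named features; the source study counts 41
but its text does not decompose that number, and 40 is the closest
self-consistent reading (a lymph-node-size clinical feature would be a
natural 41st but is not part of the pipeline).

## Statistics and classification

Per feature, both groups are Shapiro–Wilk tested at α = 0.05; only if both
pass is the two-sided Welch t-test used (Welch rather than pooled variance:
robust to the visibly unequal group SDs), otherwise the two-sided
Mann–Whitney U. No multiple-testing correction by default, mirroring the
per-feature p < 0.05 convention; Benjamini–Hochberg is available. Features
with fewer than three finite values in a group (e.g. SAS textures in
diffuse media) are reported as "insufficient" rather than tested.

LOOCV is at subject level. Per fold: z-scoring, greedy wrapper SFS
(utility = inner leave-one-out accuracy on the training subjects; ties
break toward the lower feature index; stops when no candidate improves),
and training all use the n−1 training subjects only. The feature budget is
min(3, ⌊n_train/10⌋) per the one-in-ten rule. Classifiers: ridge-stabilized
maximum-likelihood logistic (λ = 1e-6, so separable folds converge),
Gaussian naive Bayes with a 1e-6 pooled-variance floor and empirical
priors, and 1-NN whose score blends inverse distances to the nearest
neighbor of each class — raw 1-NN votes are 0/1 and would give degenerate
ROCs. Naive-Bayes and 1-NN inner loops use closed-form leave-one-out
updates that are algebraically identical to refitting (NB posteriors are
invariant to the per-fold affine standardization). The positive class is
complete response (configurable); pooled metrics use threshold 0.5 and the
AUC is pairwise concordance with ties counted ½; its 95% CI is DeLong's.
The inner CV protocol is leave-one-out (the fold count is not stated in
the protocol). Fixed-feature models (no selection) are provided alongside
SFS models, since the published univariate/bivariate tables may have used
either route.

Two pooling caveats the tests quantify rather than hide: pooled LOOCV
scores are pessimistically biased for weak effects (fold-specific models
shift score scales; the univariate simulation lands below the closed-form
Gaussian AUC of the generating distributions), and with wrapper selection
the permuted-label null AUC scatters widely around ~0.45 across seeds, so
null calibration is asserted on the across-seed mean.

## Synthetic data: what it emulates, and what it does not

`simulate_rf_frame` is an echo-summation model: each point scatterer
contributes a Gaussian-enveloped cosine pulse (60% fractional −6 dB
bandwidth, chosen to put the band near 5–11 MHz) at its round-trip delay,
with amplitude ∝ diameter³ (Rayleigh/volume proxy), an amplitude form
factor √FF_gaussian(f; d/2) for its finite size, and round-trip
frequency-proportional attenuation applied per depth bin. Diameters are
gamma-distributed (exact mean and CV, strictly positive); positions are
uniform (density in scatterers/mm², Poisson count) or a quasi-periodic
axial lattice with fractional jitter. White noise is set relative to mean
echo power (default −40 dB). The matched phantom (40 µm monodisperse beads,
α = 0.5 dB·cm⁻¹·MHz⁻¹, ≥ 6 frames) tabulates its BSC from the same Gaussian
form-factor model, so the reference-phantom method is self-consistent by
construction; the planar spectrum is the pulse power spectrum.

This reproduces exactly the statistics the estimators assume — fully
developed speckle, size-dependent spectral shape, comb lines, linear
attenuation — and nothing else: no wave propagation, beamforming,
diffraction, nonlinearity or elevational effects. Passing recovery tests
therefore validates the *estimators*, not the fidelity of any tissue model;
true nodal-tissue scatterer statistics are unknown.

`simulate_feature_cohort` draws multivariate-normal two-class cohorts
(default 13 CR / 19 PR). The nine reported per-class feature statistics are
used as-is **with the printed dispersions read as standard deviations**:
although the source table's footnote says "mean ± one standard error", the
printed group p-values are arithmetically consistent only with the SD
reading (e.g. SI-contrast 1.86±0.36 vs 1.57±0.36 at n = 13/19 gives
Welch p ≈ 0.03, matching the printed 0.022; the SEM reading would give
p ≪ 0.001). The remaining 31 features get class-neutral means at realistic
scales (textures: contrast ≈ 1.7, correlation ≈ 0.82, energy ≈ 0.05,
homogeneity ≈ 0.70; map means at plausible magnitudes), so they act as
honest noise features for the selection machinery. Features within one
map family (mean + its 4 textures) share exchangeable correlation ρ = 0.3
(no covariance is published); families are independent.

## Problem sizes used in tests and the acceptance script

Simulated frames are 1024–2048 axial samples × 96–128 lines, ROIs
~1–1.9 cm, and map-building demos use 50–75% window overlap; these sizes
are the package's chosen demonstration scale and recover the ground truth
well within the stated tolerances. Recovery experiments average spectra
over 2 frames × 7 depths × ~20 lateral positions (scatterer size), ~90
gates (spacing), and 10 depths (attenuation). Cohort simulations use 200
draws for the group-statistics consistency checks and 10 draws for null
calibration. The end-to-end run uses 16 subjects (8 per class, 30 vs 60 µm
scatterers, 1 cm ROIs).

## Known limitations

* AAC is on the generator's arbitrary concentration scale; absolute values
  are not comparable to literature dB/cm³ figures, only contrasts are.
* The Anderson fit applied to Gaussian-generated media recovers a slightly
  different size scale — expected, since the models' roll-offs differ
  beyond the Rayleigh regime.
* Spectral-log-difference attenuation assumes a homogeneous medium; axial
  size gradients alias into α (the tests demonstrate this by splitting
  two-region media laterally instead).
* SAS is undefined over diffuse media by design; cohorts without
  quasi-periodicity carry missing SAS features, which selection skips.
* GLCM displacement convention: 45° means (−1, +1) in (row, col); a
  90°-rotated grid exactly swaps the 0/90 and 45/135 feature pairs, and the
  16-GLCM average is rotation invariant.
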