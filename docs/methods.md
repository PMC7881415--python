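# Methods

`neoresp` reimplements, as a tested pipeline, the quantitative analyses
used to characterize a mouse model of congenital central hypoventilation
syndrome (CCHS): newborn plethysmography breath scoring and apnea
detection, PCA-based quantification of chemogenetic (DREADD/CNO)
effects on breathing, burst-irregularity analysis of integrated
preBötzinger-complex rhythms, and dual thymidine-analog (CldU/EdU)
image quantification with S-phase estimation and classifier-based
object discrimination. Because no recordings or images are deposited
with the source study, every stage is exercised against synthetic data
whose statistical structure matches the described inputs; this note
records the models, the defaults, and what the synthetic tests do and
do not establish.

## Synthetic data model

**Plethysmography.** A recording is a concatenation of breaths, each an
inspiratory half-sine lobe followed by an expiratory half-sine lobe of
equal duration. Per-breath period and amplitude are drawn lognormally
(lognormal guarantees positivity; the arithmetic mean and CV are matched
exactly, and CV = 0 reproduces the nominal value bit-exactly). Defaults
emulate a 10-minute newborn (P0) recording: 180 breaths/min base rate
(newborn mice breathe roughly 100–300/min), 10% period and amplitude
CV, peak flow 1 mL/s, additive Gaussian sensor noise with SD 2% of the
peak flow, 1 kHz sampling (instrument rates are vendor-specific; 1 kHz
comfortably oversamples a <5 Hz rhythm). Inspiration is negative flow
(head-out convention), configurable.

The half-sine waveform was chosen because every derived parameter has a
closed form: V_T = A·Ti·2/π, PIF = PEF = A, EF50 = A (half the expired
volume is reached at mid-lobe where |flow| peaks), and the relaxation
time satisfies cos(πRT/Te) = −0.3, giving PAU = (Te − RT)/RT ≈ 0.675
for symmetric lobes. These closed forms are the oracles for the breath
metric tests.

Apneas are inserted as silent gaps of exactly the requested duration,
starting at the first breath boundary at or after the requested start
(rather than zeroing flow mid-breath). A mid-breath cut would leave a
truncated sub-threshold lobe whose near-zero tail extends the measured
silent interval unpredictably; boundary-aligned insertion keeps the
ground-truth gap duration exact, which the apnea-rule fidelity tests
rely on. Noise is present inside gaps.

**Burst trains.** Integrated population rhythms are sums of Gaussian
bursts (amplitude 1, σ = 0.2 s by default) at a lognormally jittered
period (3 s default, emulating slice rhythms in the 0.1–0.5 Hz range),
riding on half-normal baseline noise (the emulated signal is rectified
and therefore nonnegative). The Gaussian shape gives the closed-form
FWHM = 2√(2 ln 2)·σ used as the half-width oracle. The spec constraint
`mean_period > 4·burst_sigma` keeps bursts separable.

**Cell-cycle populations.** Cycling cells occupy a uniform random
position in a cycle of length T_c with S-phase an interval of length
T_S. The pulse schedule is CldU at t = 0, EdU 2 h later, collection
0.5 h after that (the assay's schedule). Both analogs are treated as
bioavailable from injection to collection — the standard dual-pulse
assumption — so label fractions have closed forms: EdU+ =
(T_S + 0.5)/T_c, CldU+EdU− = 2/T_c, and EdU+ ⊂ CldU+. The estimator's
model matches the simulator's by construction; passing the recovery
test shows internal consistency of estimator and availability model,
not that real tissue obeys them (analog clearance, injection-timing
jitter and antibody sensitivity are not modeled).

**Images.** Multichannel fields of non-overlapping rotated ellipses
(axis ranges configurable; defaults give ~10–14 px major axes,
comparable to E10.5 neuroepithelial nuclei at typical magnification),
with per-channel intensity rules keyed to cell state (e.g. the "BrdU"
channel bright iff the cell is CldU+; the channel keeps the BrdU name
because CldU is detected with an anti-BrdU antibody). Nuclei are
rendered as uniform-intensity ellipses with a 1 px Gaussian edge blur
(a `profile="gaussian"` option renders elliptical Gaussian profiles
instead). The flat profile is the default because it gives a
well-defined ground-truth mean intensity and makes the rendered shape
match the nominal axes, so segmentation and eccentricity can be scored
against ground truth. Optics (PSF, depth, shading) are not modeled;
segmentation performance on these images is an upper bound for real
micrographs.

## Breath analysis

Breaths are segmented at signed zero crossings of the (lightly
smoothed, σ = 5 ms) flow: lobes whose peak |flow| falls below the
silence band or that are shorter than `min_cycle_s/8` are treated as
noise ripples and merged. A breath requires an inspiratory lobe
followed by an expiratory lobe; end-inspiratory/expiratory pauses (EIP,
EEP) are the sub-band intervals at the phase transitions. The silence
band defaults to 5% of the robust flow amplitude (95th percentile of
|flow|).

Per-breath quantities are stored in raw flow units; mass normalization
to mL/kg happens when `breath_metrics` aggregates (keeping segmentation
a pure signal operation). f_R = 60·n/Σ(breath durations), V_T is the
trapezoidal inspiratory flow integral, and V_E = f_R·V_T exactly by
construction. EF50 is |flow| at the sample where cumulative expired
volume first reaches 50%; RT is the time to expire 65% of the breath's
volume (the Buxco convention — the source describes no threshold);
PAU = (Te − RT)/RT and Penh = PAU·PEF/PIF. Vendor definitions of
EF50/PAU/Penh vary; these are documented defaults, not claims about any
instrument.

**Apnea rule.** An apnea is a maximal interval with smoothed |flow|
below the silence band whose duration strictly exceeds two expected
respiratory cycles — a gap of exactly two cycles is not scored ("more
than two"). The study scored apneas manually by a blind observer; a
reproducible proxy for the "expected cycle" is required, and the
trailing median duration of the preceding 10 breaths (global median
when fewer precede) was chosen for robustness to the occasional
irregular breath; the window is configurable.

## Variability descriptor, PCA and effect distance

Each animal/condition recording becomes a 48-dimensional descriptor:
12 base per-breath metrics (f_R, V_T, V_E, Ti, Te, PIF, PEF, EF50, EIP,
EEP, PAU, Penh) × {mean, CV, Poincaré SD1, Poincaré SD2}. The source
states only the count (48); this mean/CV/SD1/SD2 composition is a
reconstruction, and the schema is parameterizable. SD1/SD2 are the
population standard deviations of (x_{n+1} ∓ x_n)/√2 — the dispersions
across and along the identity line of the Poincaré plot. A constant
series is assigned CV = 0 even at mean 0 (no variability), which keeps
pause-free synthetic recordings (EIP ≡ 0) finite.

Features are z-scored before PCA because they carry heterogeneous units
(whether the source standardized is unstated; the default is
documented and switchable). Constant columns are dropped with a
warning. All components with nonzero variance are retained — at most
min(n − 1, 48); the source's 30 components reflect its sample size
(n = 15 animals × 2 conditions), not a methodological constant. The
per-animal treatment effect is the Euclidean distance between the pre-
and post-treatment projections; with all components retained this
equals the l2 distance in standardized feature space (orthogonal
projection restricted to the data span is an isometry), which is the
identity the tests check to 1e−9. Binned-frequency dot-plot exports
exist but are not part of the default 48-feature schema.

## Rhythm analysis

Raw extracellular traces are full-wave rectified and integrated with a
first-order exponential moving average (discrete leaky integrator); the
step response converges to the rectified input level.

Burst detection thresholds at baseline + 30% of (robust max −
baseline), with hysteresis: an event is a contiguous run above half the
threshold offset that reaches the full threshold, which prevents noise
from chattering across a single crossing. One candidate peak is taken
per run; peaks closer than half the estimated period merge, keeping the
higher. Each burst's local baseline is the 5th-percentile value of its
surrounding inter-peak window (≈5 estimated periods). A rolling median
was considered and rejected: when bursts occupy a large fraction of the
cycle (σ = 0.5 s at a 4 s period) the median sits on the burst flanks
and biases the half-maximum level enough to violate the one-sample
half-width accuracy requirement; a low quantile stays on the true
baseline. Half-width is the full width at baseline + amplitude/2,
located by linear interpolation between samples. Period is defined
peak-to-peak (robust to slow burst onsets).

The irregularity score of a metric series is
IrS_n = 100·|X_n − X_{n−1}|/X_{n−1} — the predecessor is the
denominator, the convention of the score's source method (the study
cites it without a formula). IrS is scale-invariant and zero for
constant series. The IrS–period relationship is OLS of period IrS on
period, either one point per animal (default, matching the per-animal
plots) or pooled per-burst pairs.

## Image quantification

Segmentation: Gaussian smoothing (σ = 2 px) → Otsu global threshold →
hole filling → distance-transform watershed (seeds are maxima of the
smoothed distance map, minimum separation = the median component
equivalent radius — smoothing leaves one maximum per convex blob and
keeps the split deterministic) → size filter (min 30 px²) → contiguous
relabeling. An empty image yields an empty label map, not an error.

Features are measured strictly under each object's mask, so pixels
outside an object can never influence its features (a tested
invariant): per-channel mean intensity; Haralick texture (contrast,
correlation, energy, homogeneity) from a gray-level co-occurrence
matrix quantized per object to 32 levels (min–max within the mask),
offsets of 1 px in 4 directions averaged, out-of-mask pairs excluded by
reserving level 0 and trimming it from the matrix; shape (area,
eccentricity, orientation) from the mask's second moments. The source
names "Haralick texture" without parameters; 32 levels/4 directions is
the recorded default.

The domain of interest (e.g. the pMNv progenitor domain) is isolated by
K-means on object centroids (what exactly the source clustered is
unstated; pixel-space clustering is available as a variant through the
feature-column parameter), selecting the cluster whose centroid is
extreme along the configured anatomical axis. Selection by position
makes the result invariant to cluster label permutation.

Marker positivity thresholds per-object mean intensities by Otsu
(unstated in the source; a fixed threshold mode is provided).
Proliferation fractions are marker+/DAPI counts, with z-scored versions
across regions for KDE comparison. The S-phase estimate is

    T_S = interval · EdU+ / (CldU+EdU−) − edu_window,

where `interval` = 2 h between injections and `edu_window` = 0.5 h from
EdU to collection. The subtraction corrects the EdU+ cohort's occupancy
— cells in S at any time in the final window have steady-state share
(T_S + window)/T_c, not T_S/T_c. `edu_window_h` defaults to 0 (the
plain ratio estimator); passing 0.5 applies the correction matching the
simulator's availability model, and the recovery tests use it.

Maximum-intensity projection, Laplacian-of-Gaussian puncta counting
(threshold relative to the image maximum, so uniform intensity
rescaling cannot change counts) and polygon/mask ROI mean gray value
complete the module.

## Classification

Random forest (100 trees), AdaBoost (100 rounds), RBF-kernel SVM (with
feature standardization) and LDA are trained on a stratified 70% split
(stratification protects small classes; the source says only "randomly
sampled", and a plain random mode exists) and evaluated on the held-out
30%: confusion matrix, accuracy, and impurity-based feature importance
for the tree ensembles (importances sum to 1; ranking ties break by
feature name). Hyperparameters are fixed defaults recorded in the
report. Feature-distribution comparisons use Gaussian KDEs (Silverman
bandwidth) on a shared grid plus a two-sample t-test; zero-variance
input degenerates the KDE to a spike and is flagged rather than
estimated.

## Statistics layer

Fisher's exact 2×2 test (two-sided p sums all tables with probability
not exceeding the observed one's; validated against direct
hypergeometric enumeration over every table with total ≤ 40); a
two-sided variance-ratio F-test, F = s_a²/s_b², p = 2·min(cdf, sf)
(written in-house: the installed SciPy offers no two-sided
variance-ratio test); Welch's t-test by default (robustness to unequal
variances; pooled available) and one-way ANOVA with Tukey HSD; OLS with
R-style formulas including factor interactions, rejecting
rank-deficient designs with the aliased columns named; and
comparative-Ct relative expression 2^(−ΔΔCt).

## Problem sizes and determinism

All randomness flows from explicit integer seeds; generators are pure
functions of their specs, pipelines write a resolved config plus
provenance headers, and reruns are bit-identical. The default test and
acceptance workloads use: 100 ten-minute 1 kHz traces for the apnea
rule; 10⁴-cell populations × 120 condition/seed combinations for
S-phase recovery; one 1200×1200 px, 500-nucleus field for segmentation;
10⁴ replicates for test-calibration rates and 1000 replicates for CI
coverage (Monte-Carlo SE ≈ 0.7% against a ±2% acceptance band).

## Known limitations

- The study's animal-derived numbers (Fisher p = 0.0005, the −109 and
  −35 BPM/s Te slopes, F = 6.538, PC1/PC2 = 50.5%/20.1%, the metabolic
  interaction effects) depend on recordings that were not deposited and
  are not reproducible here; the pipeline reproduces the *procedures*
  and validates them on synthetic data.
- Apnea scoring replaces a human observer with the trailing-median
  rule; agreement with manual scoring on real traces is untested.
- 2-D analysis only (with a max-projection front-end); no PSF or 3-D
  segmentation.
- The breath segmenter assumes a bipolar flow signal around zero;
  drifting baselines must be detrended upstream.
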