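# Methods

`sahq` reimplements the quantitative analysis stack of a longitudinal rat
study of subarachnoid hemorrhage (SAH): continuous epidural EEG with
spectral band statistics, MRI-volume-based in vivo SAH classification,
brain-wide microglial (Iba-1) image quantification, and the behavioral /
survival / phagocytosis outcome statistics.  Because no raw data from such
studies are publicly deposited, every pipeline stage is driven by a
synthetic-cohort generator with known ground truth; the package's tests
quantify how faithfully each stage recovers what the generator put in.

## Quantitative EEG

Recordings come from six epidural electrodes (L1-L3 left, R1-R3 right;
R2/R3/L3 overlie the usual territory of the hemorrhage after right-sided
endovascular perforation), nominally sampled at 1000 Hz.  Analysis:

1. **Epoching.** Non-overlapping 5-min epochs, half-open `[t, t+300)` s,
   zero-based from record start; a trailing partial epoch is dropped.
2. **Artifact rejection.** An epoch is discarded when any sample exceeds
   1000 µV in magnitude, its variance falls below 1e-6 µV² (flatline), or
   any single-sample step exceeds the amplitude threshold.  These criteria
   are this package's own, deliberately simple and configurable; they are
   tuned to catch the generator's injected ±2000 µV square-pulse artifacts
   unambiguously.
3. **Spectral estimation.** Welch/short-time-Fourier PSD per epoch:
   2-s Hamming windows, 50% overlap, mean detrending, one-sided density
   scaling so that the integral of the PSD over frequency equals the
   epoch variance (verified to 5% across sine, noise, and mixed inputs).
   The 2-s window gives 0.5 Hz resolution, enough to resolve the 1 Hz
   lower band edge; window length and overlap are package choices.
4. **Band powers.** Rectangle-rule integration over half-open bands
   delta 1-4, theta 4-8, alpha 8-12, beta 12-30 Hz and a broadband range
   of 1-20 Hz, so shared edges are counted exactly once.  Derived
   statistics: relative band power (band / broadband; "relative alpha
   variability", RAV, for alpha), alpha-delta ratio ADR = α/δ, and the
   fast-slow spectral power ratio SPR = (α+β)/(δ+θ).  Because broadband
   stops at 20 Hz while beta runs to 30 Hz, `rel_beta` may exceed 1;
   δ/θ/α relative powers lie in [0, 1].  A ratio whose denominator is
   below 1e-12 µV² is reported as NaN rather than clamped, and NaN epochs
   are excluded from means (no denominator-floor bias).
5. **Aggregation.** Per (subject, electrode, day, metric) means over
   retained epochs, with the retained-epoch count carried alongside;
   empty cells are omitted with a warning.

Useful flat-spectrum constants (exact on an ideal flat PSD, and the
reference points for generator fidelity tests): SPR = 22/7 ≈ 3.143,
ADR = 4/3, rel_alpha = 4/19.

A caveat that matters when validating the generator through the analyzer:
a Welch estimate smears the true spectrum by the window's bandwidth
(≈0.68 Hz for a 2-s Hamming window).  At the 1 Hz lower edge of a
spectrum with no sub-delta content, this biases delta power low by ~10%
at 2-s windows.  Fidelity tests therefore measure with 8-s windows
(0.125 Hz bins), where the edge bias is ~1-2%; the 2-s analysis default
is unchanged, since real EEG has continuous spectra without brick edges.

## Synthetic EEG generator

Each channel is

    x(t) = Σ_b g_b · BP_b(w_b(t)) + g_pink · pink(t),   w_b ~ N(0,1) white,

where `BP_b` is an ideal frequency-domain band-pass (Fourier mask over
the half-open band), so in-band density is exactly flat and band power
expectations are exactly `g_b² · bandwidth / Nyquist · amplitude²`.
Ideal masking was chosen over low-order IIR band-passes because the
latter lose ~8% of in-band power to filter skirts — with the loss at the
1 Hz delta edge uncompensated by any neighbouring band — which breaks the
10% analytic-fidelity contract the tests enforce.

The gain schedule encodes the study's qualitative spatiotemporal
physiology (no quantitative spectral profile is published, so the
calibration is qualitative and fixed once):

* sham: all band gains 1 (flat spectrum) plus a 1/f component
  (`pink_gain`, default 0.3 amplitude);
* SAH / SAH+fingolimod: delta gain ×3 at the electrodes over the bleed
  (R2, R3, L3), ×2 elsewhere; alpha gain ×0.5 globally;
* exponential recovery toward sham with time constant
  `recovery_tau_days = 7`:  g(day) = g_sham·(1 + (f−1)·e^(−day/τ)), which
  is monotone non-increasing in day for elevated bands.

Amplitude scale is 100 µV (broadband RMS ≈ 25 µV, typical of rodent
epidural EEG).  Artifacts are injected as 1-s ±2000 µV square pulses with
probability `artifact_rate` per 5-min block, on one random channel, and
their positions are recorded in the recording's metadata so rejection can
be validated against ground truth.  Default recording length is 30 min
(configurable; a full 24 h × 6 ch × 1000 Hz record is ~0.5 G samples, so
analyses stream epoch-by-epoch).  Tests and the bundled pipeline default
use 10-min recordings at 200 Hz — two epochs per recording — which keeps
the full suite desk-scale while leaving every spectral property intact
(Nyquist 100 Hz is far above the 30 Hz top band edge).

What the generator does **not** emulate: dipole/volume-conduction
physics, inter-channel correlation, circadian or state (sleep/wake)
structure, seizures and interictal spikes, and realistic artifact
morphology beyond the square pulse.  Passing tests therefore demonstrate
correctness of the analysis arithmetic and its directional sensitivity to
group contrasts, not performance on real recordings.

## MRI volumes and SAH classification

The hypointense skull-base volume V_hypo (mm³) is modeled per group as a
Gaussian truncated at zero (by resampling): SAH 7.45 ± 3.86, sham
1.56 ± 1.40, with whole-brain and ventricular volumes drawn from the
published summaries likewise.  Two simulated blinded observers measure
each latent volume with 3% proportional noise and are averaged — the
proportional form keeps volumes nonnegative and the observer-averaged
mean unbiased relative to the truncated normal (whose analytic mean, not
the untruncated one, is the oracle in tests: 7.70 mm³ for SAH, 1.90 mm³
for sham at these parameters).

ROC analysis uses the convention *positive iff value > threshold*, with
candidate thresholds at midpoints between adjacent sorted unique values
plus ∓∞ endpoints (the published analysis does not state its threshold
convention; midpoints are reproducible and data-independent).  AUC is
computed by the midrank pairwise estimator (ties count ½), which equals
the trapezoidal area under the midpoint ROC and U/(n₁n₂) of the rank-sum
statistic — both identities are asserted in tests.  The reported cutoff
is the threshold with 100% specificity that maximises sensitivity
(smallest such threshold on ties).

`simulate_operating_point` draws replicate cohorts from the group
summaries, classifies at a fixed cutoff, and reports median per-cohort
sensitivity/specificity.  At the published cutoff of 4.63 mm³ with 10 SAH
and 8 sham per cohort, the per-animal positive probabilities under the
zero-truncated Gaussians are ≈0.79 (SAH) and ≈0.016 (sham), whose
binomial medians give exactly 80% sensitivity and 100% specificity —
the published operating point.

## Histology quantification

Simulated Iba-1 fields are Boolean disc models: a Poisson number of cells
(field area × density, cells/mm²) at uniform positions with Gaussian
radii (4.0 ± 0.4 µm, giving mean cell area ≈ 51 µm², near the published
object sizes), rendered dark (level 70) on a light background (200) with
Gaussian noise (SD 8) at 0.5 µm/px — a DAB-like 20× scan.  The exact
binary mask is returned as ground truth.  Default ipsilateral densities
(cells/mm²): sham 160→152, SAH 410→386, SAH+FTY 390→160 across days 2→7;
contralateral fields are scaled ×0.6 for hemorrhage groups.  These values
put percent-positive areas near the published group summaries (~0.8%
sham, ~2% SAH ipsilateral) and make the day-2→day-7 decreases ≈0.04%,
0.12% and 1.17% for sham, SAH and SAH+FTY — the published fold-reduction
arithmetic (1.15/0.12 ≈ 9.58) at the level of expectations.

Quantification: binarization by a fixed threshold or Otsu (polarity flag,
dark-positive by default), 8-connected components, speckle filter
removing components under 3 px, percent-positive area and per-image mean
object size (µm²), then animal-level means over ROIs within a hemisphere
and group mean ± SD across animals.  Two robustness choices: Otsu falls
back to an empty mask when its class means are separated by less than 20
intensity levels (on a stain-free field Otsu would otherwise split the
background noise and report several percent positive area); "average
object size" is computed per image then averaged, since the published
pooling order is unstated.  ROI identity (1-32 ipsilateral, 33-64
contralateral, spanning 7 rostro-caudal blocks) comes from the input
manifest; no atlas registration is attempted.

A known small-sample instability: the fold-reduction ratio divides by the
untreated group's day-2→day-7 decrease, which is configured (and
published) near zero.  At desk-scale cohorts (4-6 animals, a handful of
ROIs) the denominator's sampling noise exceeds its expectation and the
ratio can be large or sign-flipped; the statistic is only stable at the
level of group expectations or large cohorts.

## Outcomes

* **Garcia score** (21-point composite neuroscore, floor taken as 3 since
  the modified scale's minimum is unstated):
  `score = round(clip(a + b·SPR + ε, 3, 21))` with a = 9, b = 3.5.  The
  noise SD can be given directly or derived from a target Spearman
  correlation via the Gaussian-copula inversion
  ρ_pearson = 2·sin(π·ρ_spearman/6) applied to the observed SPR spread
  (default target 0.48, the published SPR-score correlation).  Rounding
  and clipping attenuate the realised rank correlation slightly; recovery
  tests allow ±0.1-0.2 accordingly.
* **Open field:** ambulatory distance as summed Euclidean steps; center
  time as percent of samples inside the concentric square with half the
  arena side (25% of area — "center" is never defined in the source
  literature, so this is a configurable package convention); rotations by
  integrating signed step-heading change with a counter incremented per
  completed ±360°, and the CCW:CW ratio undefined when no clockwise
  rotation occurred.
* **Survival:** per-day death hazards over days 1-7 with censoring at
  day 7.  Defaults concentrate hazard in the first 48 h and integrate to
  ≈56% (SAH), ≈7% (sham) and ≈17% (SAH+FTY) cumulative mortality,
  matching the published proportions.  (The published treated-group
  16.7% is not an integer fraction of its stated n; the generator targets
  the percentage, and no exact assertion is made on it.)
* **Perfusion:** percent rCBF drop = 100·(baseline − value)/baseline,
  negative drops (hyperemia) allowed; group means 84.8% (SAH) / 11.6%
  (sham) at occlusion.
* **Phagocytosis:** beads-per-cell as negative binomial with mean m and
  dispersion k (variance m + m²/k): hemin 6.55 with k = 4.9 — which
  reproduces the published 3.91 SD exactly — and vehicle 1.12 with
  k = 50 (near-Poisson).  The published vehicle SD of 0.30 implies
  variance below the mean, which no overdispersed count distribution can
  produce; it is likely an image-level summary, and only the mean is
  matched.
* **Dose conversion:** human equivalent dose = animal dose / 6.2 (the
  standard rat→human body-surface-area factor), rounded to 2 decimals.

## Statistics

All test statistics are computed from first principles — midrank
assignment, exact Mann-Whitney U-distribution counting (tie-free, both
samples small), balanced sums-of-squares decomposition by successive
cell-mean differencing, product-limit survival estimation, and log-rank
O/E/V accumulation with the discrete hypergeometric variance at tied
event days (animal deaths are recorded in whole days) — with SciPy used
only for the reference distributions (t, F, normal, χ²) that convert
statistics into p-values.  Spearman p-values use the t approximation at
all n, with exact permutation available for n ≤ 8.  The factorial ANOVA
requires a complete balanced design (1-3 fixed factors, optional additive
subject block) and refuses unbalanced data, directing users to mixed
models; full repeated-measures covariance modelling is out of scope.
Independent implementations (scipy.stats, statsmodels OLS ANOVA,
lifelines) serve as oracles in the test suite, never as the
implementation.

## I/O and reproducibility

EEG interchange uses a minimal continuous EDF (16-bit samples, 1-s
records, per-channel symmetric physical range in µV; round-trip error is
bounded by range/2¹⁶ and the writer is cross-validated against MNE's EDF
reader) or a lossless CSV with `#` metadata headers.  All tabular
outputs are tidy one-row-per-observation CSVs; scalar results go to a
JSON summary embedding the seed and a SHA-256 hash of the full
configuration.  Every generator is a pure function of (parameters, seed)
via hierarchical seed sequences keyed by subject/day/stage, so a pipeline
run is byte-reproducible and individual stages can be re-run from cached
inputs.  YAML configuration rejects unknown keys.

## Numerical notes and limitations

* Ratio denominators below 1e-12 µV² mark the ratio undefined (NaN).
* Šidák adjustment uses `-expm1(m·log1p(-p))` for numerical accuracy at
  tiny p.
* The t-test with zero pooled variance returns t = 0 (equal means) or a
  flagged infinite statistic (unequal means).
* The degenerate all-identical-values ROC has only the ∓∞ endpoints.
* Problem sizes in the tests (200 Hz, 10-min recordings, 2-6 animals per
  group, 256-px fields, 1000 classification replicates) were chosen as
  the smallest at which every assertion's tolerance is comfortably met;
  all scale up through configuration.
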