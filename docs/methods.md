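# Methods

This note documents the models, numerical choices and limitations of
`msipix`, in the order of the pipeline.

## Synthetic data generator

The generator (`msipix.synth`) emulates a tissue-microarray MSI study of
seven thyroid tissue classes with a patient → core → pixel hierarchy.
Defaults are desk-scale (2 patients/class × 3 cores × 50 pixels = 2100
spectra on 4000 channels over 700–3700 Da with 200 Gaussian peptide peaks);
a study-scale configuration (hundreds of patients, ~360 pixels/core, ~1500
peaks) is the same code with larger counts.

**Signal model.**  The noiseless abundance (peak area) of peak *k* for a
pixel of class *r*, patient *q* is

```
A = M[r,k] · P[q,k] · E[pixel,k]
```

with `P` and `E` independent log-normal factors *centered to mean one*:
`P = exp(N(-σp²/2, σp))` shared across all of a patient's cores and pixels
(per peak), and `E = exp(N(-σx²/2, σx))` per pixel, `σx = pixel_cv · h_r`.
The per-class heterogeneity multipliers `h_r` default to NT 0.7, FA 0.8,
PTC-CV/FV 1.0, FTC 1.1, MTC 1.2, ATC 1.5 — normal tissue most homogeneous,
anaplastic carcinoma least, medullary in between.  Mean-one centering makes
heterogeneity differences variance-only: classes with different `h` have
identical mean abundances on non-signature peaks, so the null
configuration has exactly zero planted effect everywhere.

The patient effect is drawn per (patient, peak) rather than as a single
per-patient scalar: a global scalar would be a pure TIC change, removed by
normalization, whereas per-peak patient effects create the dominant
inter-individual variance component that survives normalization (the
leading principal axis in real cohorts).

**Planted effect sizes.**  Each class owns a signature block of
`n_discriminative` peaks (default 10) whose mean area is elevated by a
factor `1 + δ`, so every class pair differs on `2·n_discriminative` peaks.
Because all multiplicative noise is mean-one log-normal, the pixel-level
abundance of peak *k* in class *r* has mean `M[r,k]` and SD
`M[r,k]·c_r`, `c_r = sqrt(expm1(σp² + σx²))`, and the elevation achieving a
target Cohen's d has the closed form

```
δ = (a + sqrt(2a − a²)) / (1 − a),   a = (d · c)² / 2
```

(calibrated at the mean heterogeneity; the exact analytic d of every peak ×
pair, using each class's own `c_r`, is recorded in the ground truth).
Base areas are log-normal (`exp(N(ln 300, 1))`), spanning several decades
as tryptic-peptide MSI intensities do, which is what makes a multi-modal
intensity-class structure recoverable.

**Artifacts.**  On top of the signal: a smooth per-core baseline (slow
exponential plus two 300–800 Da-wide Gaussian bumps, amplitude
`baseline_amp` = 30 a.u.), additive Gaussian channel noise (SD 2 a.u.,
spectrum clipped at zero), a per-pixel log-normal TIC factor (CV 0.15) with
an `outlier_fraction` = 1% of pixels multiplied by a 6–12× aberrant factor,
and a per-core uniform integer channel shift within ±`shift_channels_max`.
Peak widths scale linearly with m/z (`σ = peak_sigma_da · m/z / 1000`),
the time-of-flight resolution behavior.

**What it does not emulate:** isotope envelopes, detector saturation,
matrix clusters, spatial autocorrelation within a core, or chemical noise
correlated across pixels.  Passing recovery tests therefore demonstrates
correctness of the algorithms under the stated generative model, not
performance on real tissue.

## Preprocessing

Fixed order: unification → baseline → TIC outliers → alignment →
normalization.

* **Baseline**: smoothed rolling minimum (minimum filter then moving
  average, window 50 Da, clipped at zero).  Window chosen as several times
  the widest peak (~4 Da at m/z 3700) yet far below baseline curvature
  scales (hundreds of Da).
* **TIC outliers**: medcouple-adjusted boxplot fences,
  `[Q1 − 1.5·e^(−4·MC)·IQR, Q3 + 1.5·e^(3·MC)·IQR]` for medcouple MC ≥ 0
  (−3/+4 exponents for MC < 0).  The medcouple is estimated on a 5000-pixel
  subsample beyond that size (it is O(n²)).  Flagged pixels are retained
  but excluded from every downstream fit.
* **Alignment**: integer channel shift maximizing FFT cross-correlation
  with the average of non-outlier spectra, within ±`shift_max` (default
  10), per spectrum or per core.  Two passes are used: the first reference
  is blurred by the very shifts being estimated, so the reference is
  re-averaged from the aligned spectra and the originals re-aligned to the
  sharpened consensus.  *Identifiability*: aligning to an internal
  reference determines shifts only up to one global grid offset (the
  consensus grid of the cohort); recovery tests assert exactness modulo
  that single constant.
* **Normalization**: every spectrum scaled to the mean pre-normalization
  TIC of non-outlier pixels.  Any positive target constant is equivalent
  downstream because classification Z-scores features and effect sizes are
  scale-free.

Preprocessing is idempotent in practice (second pass: all shifts 0,
~1% residual intensity change from re-estimated baseline).

## Gaussian-mixture spectral components

The average spectrum is treated as an unnormalized density over m/z.  It is
split at near-zero valleys (below 10⁻³ of the global maximum), and any
segment wider than 40 Da is split recursively at its lowest internal
valley, bounding the per-segment model size.  Within a segment, a 1-D
Gaussian mixture is fitted by intensity-weighted EM (responsibilities
weighted by channel intensity; log-space E-step; σ floored at half the
channel spacing; means initialized at evenly spaced weighted quantiles).
Model size minimizes a weighted BIC with the Kish effective sample size
`N_eff = (Σw)²/Σw²` — invariant to the arbitrary intensity units — and is
escalated while the segment's L1 reconstruction residual exceeds 5%.

Pruning removes components below the 5% amplitude quantile or broader than
5× the median σ (background humps).  Merging groups components whose means
are closer than 1.0 × max(σᵢ, σⱼ), transitively (union-find); the group is
represented at the dominant (highest-amplitude) member's location.

**Abundances** are plain convolutions: `a(p,k) = Σₘ sₚ(m)·gₖ(m)·Δm` with
`gₖ` the sum of component *k*'s unit-area member Gaussians.  Consequences
to be aware of: (i) the scale is area-like but includes a 1/(2σ√π) kernel
factor; (ii) merged components sum member integrals, so their raw scale
grows with member count; (iii) peaks closer than a few σ share intensity
through kernel tails (cross-talk).  None of this affects classification
(Z-scoring) or effect screening (within-component comparisons), but raw
abundance values are only quantitative for resolved peaks — the recovery
test checks area correlation on artifact-free spectra restricted to peaks
more than 6σ from their neighbors (r > 0.95 there, r ≈ 0.998 observed).

**Intensity classes**: a 5-component 1-D Gaussian mixture
(scikit-learn EM, k-means init, 5 restarts, seeded) on log₁₀ mean
abundances; thresholds at the grid points where the posterior-most-probable
class switches between abundance-ordered components; degenerate fits reduce
the class count with a warning.  The top class plays the "most abundant
components" role in feature-set ablations.

## Similarity

Normalized dot product on component abundances (all components or an
intensity-class subset).  Group CDFs use all unordered pairs up to
`max_pairs` (default 10⁵), beyond which pairs are drawn uniformly with
replacement (seeded) — an unbiased estimator of the same CDF; at
study scale the full intra-cohort pair set (~10¹⁰) is never materialized.
The spectral contrast angle is the arccosine of this index; being a
monotone transform, it induces identical orderings and is not separately
implemented.

## Classification

* **Patient classes and folds**: each patient carries the majority class
  of its cores (ties: canonical order NT, FA, PTC-CV, PTC-FV, FTC, ATC,
  MTC).  Patients are shuffled within class (seeded) and dealt round-robin
  into k=5 folds, so classes with ≥ 2 patients never concentrate in one
  fold; all of a patient's cores and pixels inherit its fold.  Every fold
  plan is audited for patient disjointness between training and
  validation.
* **Ensemble**: Z-score standardization from training pixels only
  (zero-variance features dropped with record); 21 linear soft-margin SVMs
  (liblinear primal, balanced class weights).  Default C = 0.1: with few
  patients per class, per-patient abundance offsets are themselves
  linearly separable directions, and weaker regularization (C = 1) lets
  binaries encode the training patients instead of the class signal — the
  effect is strongest for the most homogeneous class, whose within-class
  noise is smallest relative to the patient effect.  C = 0.1 improved
  cross-patient accuracy on every synthetic configuration examined and is
  exposed in the API.
* **Univocal rule**: class C is assigned iff all six binaries featuring C
  vote C.  Viewing the 21 votes as an orientation of the complete graph
  K₇, C must have out-degree 6; two such vertices cannot coexist, which
  the implementation asserts and the test suite verifies by exhaustive
  enumeration of all 2²¹ orientations (7·2¹⁵ = 229 376 patterns are
  univocal, 10.9%).
* **Core aggregation**: modal class over the core's non-outlier pixel
  outcomes (8 classes: 7 ROIs + NOT_CLASSIFIED); ties prefer any ROI over
  NOT_CLASSIFIED, then canonical order; a NOT_CLASSIFIED mode yields
  NOT_DIAGNOSTIC.
* **Strategies**: single-pixel (above); mean-spectrum (ensemble trained
  and evaluated on per-core mean abundance vectors, same patient-level
  folds); hybrid (pixel-trained ensemble applied to core means).
  Validation decisions are pooled across folds into one core decision
  table; quality indices are one-vs-rest sensitivity/precision/accuracy
  plus overall correct and not-diagnostic fractions.

## Effect sizes and PCA

Cohen's d with the pooled-variance denominator; pixels pooled per class
(super-groups such as WDTC = FTC ∪ PTC-CV ∪ PTC-FV pool pixels before
computing d).  Categories use |d| with *closed* lower boundaries
(|d| = 0.8 is "large"); the sign is retained in records.  No
multiple-testing machinery: effect size is used precisely because it is
independent of the enormous pixel counts.  The exploratory embedding is
log₁₀(x+1) scaling, per-feature centering and SVD, with optional seeded
per-core pixel thinning for plots.

## Annotation

A component at m/z *m* matches every peptide whose listed measured mass
lies within ±0.05% of *m* (relative tolerance, configurable).  All matches
are retained, sorted by |relative error| — annotation via MALDI-TOF mass
alone is deliberately non-unique.  Whether the peptide list carries neutral
or [M+H]⁺ masses is the list's declaration; the matcher compares numbers
as given.

## Problem sizes and determinism

The bundled studies run at 2100 pixels × 4000 channels (~200 true peaks,
~600 fitted components), which exercises every code path of the
study-scale configuration at interactive cost: the full pipeline completes
in well under a minute, the complete test suite in about two minutes.  All
stochastic steps (generation, fold shuffling, pair subsampling, mixture
initialization) consume explicit integer seeds; identical seeds reproduce
byte-identical datasets and decisions.

## Known limitations

* Raw abundance scales are kernel- and multiplicity-dependent (see above);
  compare abundances only within a component.
* Alignment resolves integer channel shifts only, and only up to a global
  cohort-wide offset.
* The univocal rule's rejection rate grows with the number of classes
  (only 10.9% of random vote patterns are univocal); with many classes
  and weak signal most pixels are rejected, and the core-level
  NOT_DIAGNOSTIC rate rises accordingly.
* The mean-spectrum strategy trains on as many observations as there are
  cores; with few patients per class it is additionally confounded by
  patient effects, which is exactly the regime where the single-pixel
  strategy dominates in the bundled studies.
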