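# msipix — single-pixel MALDI-MSI tissue classification

`msipix` implements an end-to-end analysis pipeline for multi-class tissue
classification from MALDI-TOF mass spectrometry imaging (MSI) data at the
level of *individual spectra* ("pixels").  It targets the tissue-microarray
setting in thyroid pathology — seven tissue classes: normal thyroid (NT),
follicular adenoma (FA), classical and follicular-variant papillary
carcinoma (PTC-CV, PTC-FV), follicular carcinoma (FTC), anaplastic
carcinoma (ATC) and medullary carcinoma (MTC) — where each ~1 mm tissue
core yields hundreds of spectra of tryptic peptides and the diagnostic
question is the class of the *core*, decided from its pixels.

The package is for computational proteomics / MSI researchers who want a
tested, self-contained implementation of this workflow, including a
synthetic-data generator that emulates the patient → core → pixel hierarchy
with planted effect sizes for parameter-recovery studies.

## The pipeline

1. **Preprocessing** (`msipix.preprocess`): mass-channel unification,
   smoothed rolling-minimum baseline subtraction, outlier flagging of
   pixels whose total ion current (TIC) falls outside medcouple-adjusted
   boxplot fences (a criterion for skewed, heavy-tailed distributions),
   FFT cross-correlation alignment to the (iteratively refined) average
   spectrum, and TIC normalization.
2. **Spectral components** (`msipix.gmm`): the average spectrum is modeled
   as a Gaussian mixture fitted segment-wise by intensity-weighted EM with
   a BIC sweep; low-amplitude/overly-broad components are pruned and
   components modeling the same peak merged.  Each pixel's abundance of
   component *k* is the convolution ∑ₘ sₚ(m)·gₖ(m)·Δm with gₖ the unit-area
   Gaussian profile — a peak-area scale feature matrix (pixels ×
   components), plus a five-class intensity stratification of components
   from a 1-D Gaussian mixture on log₁₀ mean abundances.
3. **Similarity** (`msipix.similarity`): the pairwise similarity index of
   two abundance vectors is their normalized dot product
   ⟨a,b⟩/(‖a‖‖b‖); intra- and inter-class populations of pairwise
   similarities are summarized as CDFs with medians.
4. **Classification** (`msipix.classify`): features are Z-scored; all
   C(7,2)=21 one-vs-one linear SVMs are trained; a pixel is classified as
   class C only if the decision is *univocal* — all six binaries featuring
   C vote C — otherwise NOT_CLASSIFIED.  A core's label is the modal class
   of its pixels over the 8 outcomes (NOT_CLASSIFIED mode ⇒
   NOT_DIAGNOSTIC).  Validation is patient-stratified 5-fold CV (a patient
   is never split between training and validation).  Three strategies:
   *single-pixel* (majority over pixel calls), *mean-spectrum* (train and
   classify on core means), *hybrid* (pixel-trained models applied to core
   means).
5. **Effect sizes** (`msipix.effects`): per component and ROI pair,
   Cohen's d = (mean₁−mean₂)/pooled SD, categorized |d| ≥ 0.5 / 0.8 / 1.2
   as medium / large / very large (no p-values by design — d is
   sample-size free), plus pseudo-log (log₁₀(x+1)) PCA.
6. **Annotation** (`msipix.annotate`): components matched to LC-MS/MS
   peptide identifications within ±0.05% relative mass tolerance.

## Worked example

```python
import warnings; warnings.simplefilter("ignore")
from msipix import run_study

study = run_study(seed=1)          # 7 ROIs x 2 patients x 3 cores x 50 pixels
print(study.gmm_results.summary())
print(study.classification["single-pixel"].summary())
```

prints

```
Average-spectrum Gaussian mixture
========================================
raw components:      815
retained components: 627
m/z range:           700.3 - 3699.7
explained intensity: 0.962

Core classification (single-pixel, features=all)
========================================================
cores evaluated:        42
correct fraction:       0.905
not diagnostic:         0.000
mean binary accuracy:   0.889
pixels not classified:  0.066

One-vs-rest quality indices:
        sensitivity  precision  accuracy
NT            1.000      1.000     1.000
FA            1.000      1.000     1.000
PTC-CV        0.833      0.833     0.952
PTC-FV        1.000      1.000     1.000
FTC           1.000      1.000     1.000
ATC           0.833      0.625     0.905
MTC           0.667      1.000     0.952
...
```

The generator planted per-class signatures at Cohen's d = 1.5; 627 spectral
components were detected from 4000 mass channels (96% of intensity
explained), 6.6% of pixels were rejected by the univocal rule, and 90.5% of
the 42 cores were classified correctly — versus 14.3% expected from random
indexing of seven classes, and 66.7% for the mean-spectrum strategy on the
same data (the single-pixel approach is robust to within-core heterogeneity
that core means average into patient idiosyncrasy).

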