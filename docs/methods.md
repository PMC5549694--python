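# Methods

## Scope

`lymphospec` implements a complete in-vitro ¹H-NMR tissue-classification
analysis: spectral standardization, a from-scratch single-response O-PLS
(discriminant and regression modes), blinded evaluation, and a synthetic
cohort generator that stands in for tissue data which cannot be
redistributed. Everything upstream of the exported spectrum — pulse
sequences, Fourier transformation, phasing — is out of scope; spectra enter
the pipeline as (ppm, intensity) traces in delimited text.

## Chemical-shift axis

An acquisition of `n_points` real points with spectral width `sw` (Hz) on a
spectrometer of frequency `f` (MHz) spans `sw/f` ppm. The axis is uniform,
descending (standard NMR display), and centred on the water-presaturation
carrier (default 4.7 ppm). The default acquisition (32768 points, 6200 Hz,
400 MHz) therefore spans 15.5 ppm, from 12.45 to −3.05 ppm. "32K" is read as
2¹⁵ points, the NMR convention for power-of-two sizes. Methanol-based
calibration of the real instrument is not reproducible from exported traces
and is ignored; the carrier anchors the axis instead.

## Standardization pipeline

Order is fixed and logged: **align → bin → normalize**.

**Alignment (RSPA).** Each spectrum is aligned to a reference (element-wise
median of the training cohort by default). A segment is shifted by the
integer offset within ±`rspa_max_shift` (default 10 points) that maximizes
Pearson correlation with the reference on that segment; vacated edge points
repeat the boundary value. A shift is accepted when the correlation gain
exceeds `rspa_corr_gain_min` (default 0.01) *of the remaining decorrelation*
(1 − r_before). The relative form matters: a whole-spectrum displacement of
a few points changes raw correlation only in the 4th decimal because peaks
are much wider than the shift, yet it is exactly the defect alignment
exists to remove; measuring gain against 1 − r makes such shifts decisive
while leaving identical spectra untouched (gain 0) and far-displaced peaks
unshifted (absolute correlation stays near zero, relative gain below
threshold). After an accepted shift the segment is split at the
minimum-intensity interior point of the middle third — of the *reference*,
so every sample shares one segmentation — and both halves are aligned
recursively; recursion stops below `rspa_min_segment` (50 points) or when
the gain test fails. All shifts, correlations and intensity changes are
recorded in an audit table.

**Binning.** Buckets of `bin_width` (default 0.04 ppm) are laid from the
high edge of the analysis window downward; each bucket sums the intensities
of points in [centre − w/2, centre + w/2) (closed toward lower ppm; the
window's own high edge is kept); a trailing partial bucket is dropped, so a
15.5-ppm window yields ⌊15.5/0.04⌋ = 387 buckets. Mean-bucketing is
available as an option; summing is canonical. Exclusion regions (e.g.
residual water) are applied after binning and are off by default. The study
pipeline uses an explicit analysis window of 0.5–9.5 ppm (225 buckets): the
region outside carries no resonances, and every uninformative bucket a PLS
model sees adds sampling noise to its weight vector, degrading blinded-test
scores for no benefit. Anchoring the grid at 9.5 ppm also places one bucket
symmetrically on the 3.8-ppm marker rather than splitting it across an edge.

**Normalization (PQN).** Negative intensities are clipped at zero (counts
logged; quotients are undefined for mixed signs). Each spectrum is scaled to
a common total area (100), the reference is the element-wise median spectrum
of the *training* cohort, per-bucket quotients x_j/ref_j are formed over
buckets with ref_j > 0, and the sample is divided by the median quotient.
The function returns the total divisor applied to the raw row (area factor ×
quotient median) so injected dilutions can be checked against estimates. Test
samples are always normalized against the training reference — the
conservative, leakage-safe choice.

**Baseline.** A modified-polyfit operator (iteratively clipping the trace to
the current polynomial fit, degree ≤ 5) is provided as optional plumbing,
off by default; it stands in for interactive baseline correction and makes
no fidelity claim.

## O-PLS model

Single-response O-PLS with the NIPALS deflation scheme (see README for the
update equations). Design choices:

- **Scaling**: columns of X and y centred; unit-variance (SD, ddof = 1) by
  default, Pareto (√SD) as an option; zero-variance columns keep scale 1 and
  are flagged. The mode is stored in the serialized model.
- **Sign convention**: the fit is oriented so q₁ ≥ 0 — higher t₁ means
  higher response, i.e. malignant for 0/1 coding.
- **Classification**: ŷ ≥ 0.5 calls malignant; an exact tie calls malignant
  (sensitivity-favouring) and is logged.
- **Cross-validation**: 7 venetian-blind folds by row order (row i → fold
  i mod 7), deterministic, no RNG; centring, scaling and all orthogonal
  components refit per fold; PRESS accumulated in response units against the
  full-data mean. Q²Y ≤ R²Y + ε is asserted as an invariant.
- **Component count**: the study default is 1 predictive + 3 orthogonal
  components. An `autofit` rule (add orthogonal components while Q²Y improves
  by > 0.01) is provided as an alternative.
- **Diagnostics**: DModX_i = s_i/s₀ with s_i² = Σ_j e_ij²/(m − A),
  s₀² = ΣΣe²/((n − A − 1)(m − A)), A = 1 + k; Hotelling's
  T²_i = Σ_a t_ia²/var(t_a) with limit A(n−1)/(n−A)·F_{1−α}(A, n−A) at
  α = 0.05. Sample variance (ddof = 1) throughout.
- **Interpretation**: per-bucket Pearson correlation and covariance between
  the scaled column and t₁ (the S-plot pair); an orientation flag flips signs
  so benign-predictive buckets plot positive.
- **Tolerances**: orthogonality and reconstruction identities are asserted
  at 1e-8 absolute — comfortable IEEE-double headroom for problems of this
  size.

Where a model in the 0-orthogonal-component limit coincides with 1-LV PLS1,
scikit-learn's `PLSRegression` serves as an independent oracle in the test
suite; it plays no role in the implementation.

## Study workflow

`run_train` fits preprocessing constants (alignment reference, bucket grid,
PQN reference) and the model on the training cohort only; `run_blinded_test`
processes test spectra with those constants, renders the prediction table,
records its SHA-256 hash in the run log, and only then reads the label
table — the hash pins down what was predicted before unsealing. Sensitivity
and specificity are reported as raw counts and percentages (10/11 = 90.9%,
reported alongside its rounded form). `run_age_control` refits the identical
pipeline as a regression with y = months since tissue extraction (continuous
response, not discriminant coding, since months is a continuous quantity)
and reports training Q²Y plus the predicted-vs-true correlation on the test
cohort.

## Synthetic cohorts

Each spectrum is a sum of Lorentzian/Gaussian resonances with per-sample
log-normal amplitude jitter, one shared class-independent latent factor
multiplying a designated peak subset (N-acetyl, choline, aromatic filler),
per-peak chemical-shift wobble on the pH-sensitive resonances (lactate,
creatine, the 3.8-ppm marker), a whole-spectrum integer shift (±3 points), a
log-normal dilution factor (σ = 0.3), and additive Gaussian noise (σ = 5% of
the median library amplitude). Benign samples multiply the 3.8-ppm marker
amplitude by `class_effect` (default 2.0). Cohort sizes default to the study
design: 20 + 25 training, 11 + 13 test. Ages are uniform integers on
[1, 80] months, independent of everything unless the age-effect positive
control injects an age-proportional resonance at 2.7 ppm. Each sample draws
from an RNG stream keyed by (seed, sample index), so resizing a cohort never
re-randomizes existing samples.

Peak amplitudes and widths are invented for plausibility; the only fidelity
claims are structural — the 1–1.5 ppm lipid/lactate envelope dominates every
spectrum, and the benign-elevated 3.8-ppm marker carries the class
contrast. Effect sizes are deliberately calibrated (and frozen) so the
default benchmark separates classes decisively, reproducing the study
design's headline blinded counts; that calibration is a declared property of
the benchmark, not a discovery. Two calibration mechanisms are worth
recording: the marker's biological CV (0.02) is kept well below the class
effect so the 2× contrast dominates within-class spread, and the sub-bucket
chemical-shift wobble concentrates stable class correlation in the bucket
*containing* the marker (edge buckets acquire first-order position variance,
the centred bucket only second-order).

What the generator does **not** emulate: J-coupling multiplets, realistic
lineshape distortions, baseline roll, water-suppression artifacts,
metabolite-level biochemical differences spread across many correlated
regions. Passing the benchmark therefore demonstrates that the pipeline
recovers a class signal of the assumed structure under dilution, shift and
nuisance variation — not that real lymph-node cohorts would separate with
these exact metrics.

## Problem sizes and runtime

The frozen benchmark runs at full resolution (32768 points, 69 spectra) —
about 15 s end to end. Multi-seed null controls (permuted labels, a null
class effect, independent-age models) use 4096-point axes, which preserve
every pipeline property at ~10 points per bucket while keeping 20-cohort
sweeps to a few seconds. The permutation null uses 50 label permutations on
the benchmark training matrix.

## Known limitations

- RSPA internals (Pearson objective, reference-side segmentation,
  relative-gain acceptance, boundary-value edge fill) are one concrete,
  brute-force-checkable variant of recursive segment alignment; published
  variants differ in objective and segmentation rule.
- DModX and T² use the standard chemometric forms; commercial software
  applies additional proprietary normalizations, so absolute values are not
  comparable across tools.
- The 0.5 classification threshold with unbalanced training classes (25/20)
  shifts the decision boundary toward the minority class; with shrinkage on
  blinded data this asymmetry favours false positives over false negatives.
- PQN assumes the majority of buckets are uninformative for dilution; with
  only ~16 resonances the quotient median is coarser than in real tissue
  spectra with hundreds of signals.
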