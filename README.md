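# lymphospec

Chemometric classification of lymph-node tissue from 1D ¹H-NMR spectra.

Distinguishing benign from malignant lymphadenopathy is hard with
morphology-based imaging; high-resolution NMR spectra of intact tissue carry
metabolic information that a whole-spectrum pattern-recognition model can
exploit. `lymphospec` implements that analysis as a tested, reusable
pipeline for spectroscopists and chemometricians:

- **spectral standardization** — recursive segment-wise peak alignment
  (RSPA), fixed-width 0.04-ppm bucketing, and probabilistic quotient
  normalization (PQN) for dilution correction;
- **OPLS-DA** written from scratch — orthogonal projections to latent
  structures with one predictive and *k* orthogonal components, venetian-blind
  cross-validation (Q²Y), DModX and Hotelling's T² outlier diagnostics,
  blinded prediction, and S-plot-style loading-correlation interpretation;
- **a synthetic cohort generator** that emulates a two-phase tissue study
  (45 training samples: 20 benign / 25 malignant; 24 blinded test samples:
  11 benign / 13 malignant) with a dominant lipid/lactate envelope at
  1–1.5 ppm, a benign-elevated marker resonance at 3.8 ppm, dilution,
  chemical-shift jitter, class-independent nuisance variation and noise, so
  that the whole pipeline runs and is benchmarked without any external data.

## Model

With X the n × m matrix of bucketed intensities (columns centred and
unit-variance scaled) and y the class response (0 = benign, 1 = malignant),
O-PLS decomposes

    X = t₁ p₁′ + Tₒ Pₒ′ + E
    y = t₁ q₁  + F

where t₁ holds all class-predictive variation and the k orthogonal
score/loading pairs (Tₒ, Pₒ) absorb systematic variation uncorrelated with
y. Fitting is NIPALS-style: per orthogonal round, w = X′y/(y′y) (normalized),
t = Xw, p = X′t/(t′t), wₒ ∝ p − (w′p)w, tₒ = Xwₒ, pₒ = X′tₒ/(tₒ′tₒ), and X is
deflated by tₒpₒ′. Fit quality is R²Y = 1 − ‖F‖²/‖y_c‖²; generalization is
Q²Y = 1 − PRESS/SS with 7-fold venetian-blind cross-validation and the full
pipeline refit per fold. New samples are projected with training constants
only and called malignant when ŷ ≥ 0.5.

## Worked example

The numbered scripts under `analysis/` run the complete study on the frozen
synthetic benchmark and write their tables under `results/`:

```
$ python analysis/01_simulate_cohort.py
wrote cohort to results/benchmark
  45 training samples (20 benign, 25 malignant)
  24 blinded test samples (11 benign, 13 malignant)
  axis: 32768 points, 12.45 to -3.05 ppm

$ python analysis/02_preprocess.py
aligned 45 training spectra: 44 segment shifts applied (max |shift| = 9 points)
binned to 225 buckets of 0.04 ppm on the (0.5, 9.5) ppm window
PQN dilution factors span 892.50 - 3872.49
wrote matrix (45 x 225) to results/preprocess/train_matrix.csv

$ python analysis/03_train_and_blind_test.py
training fit: R2Y = 0.996, Q2Y = 0.858 (7-fold)
Hotelling T2 outliers beyond the 95% limit: 0
blinded test: 13/13 malignant and 10/11 benign correct -> sensitivity 100.0%, specificity 90.9%
strongest predictor: bin at 3.80 ppm (benign-oriented correlation +0.99)

$ python analysis/04_age_control.py
age model on independent ages (20 seeds): mean Q2Y = -0.442, mean |r(pred, true)| on test = 0.170
  -> no predictive ability: storage age cannot explain the benign/malignant separation
positive control (age-linked 2.7 ppm resonance): Q2Y = 0.739, test r = 0.875
```

Reading the output: R²Y ≈ 1 says the 4-component model explains nearly all
class variance on the training cohort; Q²Y = 0.86 says that skill survives
cross-validation (permuted labels give Q²Y ≈ −0.5, so this is not
over-fitting). The blinded confusion table (13 TP, 0 FN, 10 TN, 1 FP) yields
the sensitivity/specificity line, and the loading-correlation table
identifies the 3.8-ppm bucket — the generator's benign-elevated marker — as
the strongest predictor, oriented positive, i.e. benign-predictive. The age
control shows storage time is unpredictable when it is truly independent of
the spectra, while an injected age effect is readily detected.

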