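# Methods

## The measurement being modelled

Each acquisition is a non-contact autofluorescence spectrum: tissue excited
at 405 nm, emission recorded by a CCD spectrometer as wavelength–intensity
pairs in arbitrary units. The diagnostically relevant emitters and their
emission properties at this excitation are

| fluorophore          | peak (nm) | FWHM (nm) |
|----------------------|-----------|-----------|
| free NADH            | 487       | 84        |
| protein-bound NADH   | 501       | 64        |
| free FAD             | 544       | 75        |
| basic porphyrins     | 590       | 25        |
| neutral porphyrins   | 630       | 25        |
| "unexplained 671"    | 671       | 25        |

The last row is an optional emitter for the recurring differential-
fluorescence peak near 671 nm whose molecular origin is unsettled; it is
given a porphyrin-like width.

## Synthetic-data generator

Since only peak and FWHM are known for each band, the minimal shape
consistent with both is a Gaussian,
`v(λ) = A·exp(−(λ−peak)²/(2σ²))`, `σ = FWHM / (2√(2 ln 2))`.
One simulated acquisition is

```
I(λ) = attenuation · Σ_f  A_f·J_f · g_f(λ)  +  baseline·J_b  +  rolloff(λ)  +  ε(λ)
```

clipped at zero, where `J_f`, `J_b` are unit-mean lognormal jitters and
`ε` is white Gaussian noise. Defaults, chosen once to emulate the study
conditions:

* **Grid**: 400–800 nm, 1736 points (≈0.23 nm spacing); the 445–750 nm trim
  then retains exactly 1323 samples, the input width of the network
  comparator.
* **Counts**: 393 sarcoma + 118 healthy usable acquisitions (the study's
  3:1 imbalance), assigned round-robin to 6 mice per class. A mouse-level
  random effect knob exists but defaults to 0 (no mouse effect is modelled
  in the analysis being emulated).
* **Class contrast** (Warburg structure): sarcoma = healthy ×
  {free NADH ×1.6, free FAD ×1.4, porphyrins ×0.5}, with whole-emission
  attenuation 0.65 modelling the extra scattering that mutes raw sarcoma
  intensity. Healthy amplitudes (a.u.): free NADH 1.0, bound NADH 0.8,
  FAD 0.5, porphyrins 0.25 each, 671-emitter 0.16 (sarcoma 0.24, ×1.5, so
  the raw sarcoma curve stays below healthy through 660 nm while the
  pin-normalized differential at 671 nm stays positive).
* **Jitter**: per-acquisition lognormal abundance CV of 0.25 for the broad
  NADH/FAD bands, 0.45 for the narrow porphyrin bands and 0.5 for the
  671-emitter; baseline CV 0.5. These per-band CVs spread the preprocessed
  data's variance over ~5 principal directions, matching the five-component
  regime the analysis operates in; a single shared CV concentrates it into
  three.
* **Background**: ambient-light baseline 0.05 a.u.; excitation-line rolloff
  `0.8·exp(−(λ−405)/8 nm)` (negligible past the 445 nm trim); noise sd
  0.02 a.u.
* **Failures**: with probability `p_failed` an acquisition is rescaled so
  its trimmed mean falls to 0.003 a.u., below the quality threshold —
  emulating poor sample positioning. Default 0, so the default dataset is
  exactly the 511 usable spectra; QC bookkeeping is exercised by explicitly
  constructed fixtures.

Everything is driven by `numpy.random.default_rng(seed)`; identical
configs give bit-identical datasets.

What the generator does **not** emulate: instrument line-shape asymmetry,
wavelength-dependent detector response, cosmic-ray spikes, autofluorescence
photobleaching over the 0.5 s integration, blood/hemoglobin absorption
features, and genuine biological covariance between fluorophores (jitters
are independent). Passing tests therefore demonstrate that the pipeline's
logic is correct and that it recovers structure *of this kind*; they are
not evidence about any particular real tissue dataset.

## Preprocessing

Fixed order: trim → QC → smooth → pin-normalize.

* Trim keeps the closed interval [445, 750] nm (the lower edge matching
  the dichroic mirror's 90 % attenuation wavelength; the upper edge past
  any expected metabolite emission).
* QC rejects spectra whose mean trimmed intensity is **strictly below**
  0.005 a.u.; exactly 0.005 is kept, with a 1e−12 guard absorbing float
  round-off. The mean is taken on trimmed, unsmoothed, unnormalized
  intensities (the stated pipeline order implies post-trim; mean rather
  than median is the plain reading of "average").
* The moving average has an even window of 10 samples; the convention is a
  centred window covering samples [i−5, i+4], truncated at the edges, which
  makes the impulse response deterministic (ten consecutive outputs of
  0.1). Smoothing is linear and bounded by the input extremes.
* Pin-normalization divides by the intensity at the grid sample nearest
  500 nm (ties toward the lower wavelength); the pin sample becomes exactly
  1.0, making spectra shape-comparable and scale-invariant. Intensity at
  the pin below 1e−9 is a degenerate-pin error rather than a silent
  division.

Class-average/differential curves average each class (raw, or after
per-spectrum pin-normalization), divide both mean curves by the single
maximum across the two, and difference sarcoma − healthy; the +1.2 offset
is applied only when plotting. Standard errors use ddof = 1.

## Band statistics

The integration window for each fluorophore is peak ± FWHM/2 — e.g. free
NADH (445, 529), free FAD (506.5, 581.5); edges are kept exact, never
rounded. Per-spectrum abundance is the composite trapezoid integral over
grid samples inside the closed window; edges falling between samples are
not interpolated (determinism; error at most one grid step per edge, and
the tests hold the result to 0.5 % of a 10×-finer Riemann sum).

Band scores are compared with a two-sided Mann–Whitney U test implemented
in-repo: U from midranks (equivalently pair counting with half credit for
ties), the reported U being the sarcoma sample's. The p-value is exact
(integer-arithmetic enumeration of the null distribution via the Gaussian
binomial recurrence) for tie-free samples with n₁·n₂ ≤ 400, otherwise the
normal approximation with tie correction and continuity correction. A
Shapiro–Wilk check per class at α = 0.05 is recorded alongside (scipy's
implementation; its coefficient tables are standard), but the
nonparametric comparison is always the one reported. No multiple-testing
correction is applied across the six bands, matching the analysis being
reproduced. Band AUCs are computed on whatever spectra are passed in —
preprocessed by default in the pipeline; passing trimmed/smoothed but
unnormalized spectra is the "raw mode" used when a shift should stay
attributed to its own band.

## PCA

Mean-centred only: wavelengths share one unit, and per-wavelength
standardization would inflate noise-only regions. The retained count is
the smallest k whose cumulative explained-variance ratio reaches 0.95.
Loadings carry a deterministic sign (largest-magnitude element positive).
The benchmark fits PCA inside the model pipeline, i.e. on training folds
only (leakage-safe); fitting once on everything is available as an
interpretation mode for loading-spectrum plots, where the first three
components are flagged "major" when they jointly explain ≥ 90 % of
variance.

## Classifier benchmark

80:20 stratified split with per-class round-half-up test counts
(393/118 → 79 + 24 test spectra), then per family a nested grid search:
5 outer stratified folds; within each outer-fold training portion an
exhaustive search over the stock grids

* SVM (RBF): C ∈ {0.5, 1, 5, 10, 30, 40}; γ ∈ {0.001, 0.005, 0.01,
  1/n_features, 1/(n_features·Var X)};
* logistic regression: C ∈ {0.001, 0.01, 0.1, 1}; solver ∈ {newton-cg,
  lbfgs, sag, saga}; penalty ∈ {L1, L2, none};
* KNN: k ∈ {5, 7, 10, 15, 20}; metric ∈ {Manhattan, Euclidean,
  Minkowski}; weights ∈ {distance, uniform};

scored by 5 inner stratified folds on plain accuracy. Each outer fold's
winner is scored on that fold's held-out portion; the best outer score
wins and is refit on the full training set (ties: higher score, then lower
complexity — smaller C, stronger penalty, larger k — then grid order).
Combinations a fitter rejects (e.g. newton-cg with L1) are skipped and
recorded, not fatal. Splits are by acquisition, matching the emulated
protocol; a group-aware (by-mouse) split mode exists for honest
generalization estimates. Test metrics all derive from one confusion
matrix with sarcoma positive; specificity is the healthy true-negative
rate; macro values are unweighted two-class means; AUC comes from a
threshold sweep (and equals U/(n₁·n₂) — a cross-module identity the tests
enforce against the in-repo Mann–Whitney).

Learning curves run 5-fold CV over a 90 % stratified subset at training
fractions 0.1–0.9. The sample-size extrapolation fits
`acc(n) = a − b·n^(−c)` (a ∈ (0,1], b, c > 0) by least squares and inverts
to the smallest n with `acc(n) ≥ target`, flagging targets above the
fitted asymptote as non-attainable.

## Network comparator

Input 1323 preprocessed intensities ("raw" in the sense of not
PCA-reduced — the trimmed input width is fixed by the architecture), then
Dense(128, ReLU) → Dense(64, ReLU) → linear 2-node output with softmax
folded into the categorical cross-entropy loss; Adam (lr 0.001,
β = 0.9/0.999), batch size 4, Glorot-uniform initialization. The
implementation is a compact numpy network whose parameter count is exactly
`(F·128 + 128) + (128·64 + 64) + (64·2 + 2)`.

Training runs five times from independently derived seeds
(`SeedSequence.spawn`); curves and validation metrics are averaged across
repeats and the ensemble averages softmax outputs. The validation split is
a seeded 20 % stratified holdout. There is no early stopping: the optimal
epoch is the post-hoc argmin of the averaged validation loss (earliest on
ties), which lands in the few-tens-of-epochs regime on the default data.
Activation-map introspection is deliberately not provided — ReLU
nonlinearities make such maps unreliable as evidence of feature
preference.

## Problem sizes used in the test suite

Deterministic unit tests run on hand-built fixtures. Stochastic checks use
scaled simulations chosen to keep the suite fast while leaving comfortable
statistical margins: null calibration of the band test uses 1000 replicates
of 36 + 12 spectra on a coarse (1 nm) grid; the label-permutation check
uses 100 permutations of a 90 + 30 spectrum set; the classification-regime
checks run the full 393 + 118 default study through the complete nested
grid search and the 35-epoch, 5-repeat network training.

## Known limitations

* Gaussian bands and independent lognormal jitters are a deliberate
  simplification; real spectra have asymmetric bands and correlated
  biology.
* The exact Mann–Whitney p is only used for small tie-free samples; large
  or tied samples use the (tie-corrected) normal approximation, as is
  standard.
* Band windows at non-grid edges under-cover by up to one grid step; at
  the default 0.23 nm spacing this is negligible against the 25–84 nm
  windows.
* The benchmark's single 80:20 test split reports point metrics, not
  fold-averaged ones; fold records are kept so a fold-averaged view can be
  derived if wanted.
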