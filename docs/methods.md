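# Methods

## The diagnostic problem and the data model

The pipeline classifies serum Raman spectra into three diagnostic groups:
healthy controls (HC), breast cancer (BC) and ductal carcinoma in situ
(DCIS). A spectrum is an intensity vector on a fixed wavenumber axis
(default 1698 evenly spaced points on 400–4000 cm⁻¹, matching a bench
spectrometer with ~4.5 cm⁻¹ resolution). Raw spectra are modelled as

    y(ν) = b(ν) + Σ_k A_k · m_k(c) · j_k · L(ν; ν_k, w_k) + ε(ν)

where `b` is a smooth fluorescence background, `L` a unit-height Lorentzian
(the natural Raman line shape) at position ν_k with FWHM w_k, `A_k` the base
band amplitude, `m_k(c)` a class-dependent multiplier, `j_k` a per-sample
lognormal amplitude jitter, and `ε` i.i.d. Gaussian detector noise. Each
sample is acquired `R` times (default 5) and the acquisitions are averaged,
which shrinks the effective noise sd by 1/√R (a tested invariant).

### Generator defaults and what they emulate

* **Cohort**: 241 HC / 463 BC / 100 DCIS = 804 samples — the class imbalance
  a hospital serum bank actually produces (BC-dominated, DCIS scarce).
* **Bands**: the 11 canonical serum positions (593, 810, 950, 1004, 1154,
  1280, 1445, 1514, 1576, 2517, 2662 cm⁻¹), FWHM 16 cm⁻¹ (well above
  instrument resolution, ~7.5 axis bins). The β-carotene bands 1154 and
  1514 cm⁻¹ carry the largest amplitudes (1.0 and 0.95), as in real serum.
* **Class signal**: β-carotene multipliers 1.0 (HC) / 0.78 (DCIS) / 0.60
  (BC) — carotenoid depletion increasing with disease severity, DCIS
  intermediate — and a mild protein/lipid elevation (1.08 / 1.15) on the
  950–2662 cm⁻¹ protein bands. Published evidence for these differences is
  graphical, not numeric, so the magnitudes are a modelling choice fixed
  once here; they live entirely in `PeakSpec.class_multipliers` and every
  consumer treats them as free parameters.
* **Background**: cubic polynomial in the normalised axis coordinate,
  coefficients (1.2, −1.5, 0.9, −0.2): strictly positive, monotonically
  decaying from 1.2 to 0.4, range ≈ 0.8 — comparable to the strongest peak,
  which is what makes baseline removal a real task rather than a formality.
* **Noise / jitter**: acquisition noise sd 0.01 (≈ 1% of the strongest
  band), per-peak lognormal jitter σ = 0.08. With replicate averaging the
  residual noise is ≈ 0.45% of signal — a clean bench measurement.
* **Reproducibility**: each sample's RNG stream is derived from
  (seed, sample counter), so generation is order-independent: adding a class
  or drawing samples in a different order never changes earlier spectra.

What the generator does **not** emulate: cosmic-ray spikes, detector
etaloning, wavenumber miscalibration or drift, inter-batch effects,
within-class biological covariance structure (age, medication), or any
SERS-specific physics. Passing tests on this synthetic cohort therefore
demonstrate that the pipeline machinery is correct and that the protocol can
recover class structure of the assumed form — not that the reported
real-cohort accuracies transfer to new patients.

## Preprocessing

Per spectrum, in fixed order (a regression test pins the order):

1. **Savitzky–Golay** (window 11, order 3). The window/order are not
   standardised for this instrument class; 11 points ≈ 23 cm⁻¹ at the default
   axis spacing, below the 16 cm⁻¹ FWHM bands' distortion threshold. Both are
   configurable. Smoothing is applied to the replicate-averaged spectrum.
2. **airPLS** (λ = 10⁵, ratio = 10⁻³, maxiter = 30). λ controls baseline
   stiffness: 10⁵ on a ~1700-point axis yields a curve that follows broad
   fluorescence but cannot bend into 7-bin peaks. The weighted Whittaker
   system (W + λDᵀD)z = Wy is pentadiagonal symmetric positive definite and
   is solved exactly with a banded Cholesky factorization (O(L) time and
   memory). Numerical notes:
   * a signal with zero second difference (constant, straight line) is its
     own baseline — the corrected signal is ~0 to machine precision;
   * an all-zero signal converges at iteration 1 (the stop test uses ≤ so
     the degenerate 0 < 0 comparison cannot spin);
   * each solve is shift-equivariant (constants lie in the penalty's null
     space), but the stop rule normalises by ‖y‖₁, which a constant shift
     changes — so baseline(y + c) = baseline(y) + c holds exactly at a fixed
     iteration count, and only approximately across different stop points.
3. **Min–max scaling** to [0, 1]. Per spectrum, so the models see relative
   intensity only; a constant spectrum is a hard error, never silently
   passed through.

## Classifiers

**CNN.** conv(8, k=3, valid) → tanh → batch-norm → conv(16, k=3, valid) →
tanh → max-pool(width 3, stride 3, floor) → flatten → dense → softmax.
Unpadded convolutions with floor pooling are the only geometry whose flatten
width on a 1698-point input is (((1698−2)−2)÷3)·16 = 9024 ("same" padding
would give 9056); the acceptance script verifies the arithmetic against a
real forward pass. One batch-norm layer sits between the two convolution
blocks (Keras momentum/eps conventions: 0.99, 10⁻³). Training: categorical
cross-entropy, Adam (β₁ 0.9, β₂ 0.999, ε 10⁻⁷), batch 16, 100 epochs,
learning rate 10⁻³, samples reshuffled each epoch from the run seed. A
stratified 20% of the training data is held out for the per-epoch validation
curves (the network never trains on it); the fraction is a package choice —
the protocol being emulated plots validation curves without stating one.
The implementation is plain numpy (im2col + BLAS matmuls, float32): the
network has ~30k parameters, so a 562-sample, 100-epoch run trains in about
a minute on one CPU and is bit-reproducible from the seed. Epoch metrics are
minibatch averages (train) and a full held-out pass (validation). A NaN loss
aborts with a diagnostic rather than training on.

**Baselines.** KNN (Euclidean), random forest, RBF-kernel SVM — scikit-learn
estimators behind the package's fitting surface. Labels are integer-encoded
in the fixed (HC, BC, DCIS) order before fitting, so score ties resolve to
the smallest class index. Hyperparameters are selected by stratified 5-fold
cross-validated grid search (accuracy, argmax of the fold mean, first
maximum on ties). Default grids — none are standardised for this protocol,
all configurable: k ∈ {1, 3, …, 15} (capped at the fold size during CV);
trees ∈ {100, 200, 500} × depth ∈ {5, 10, ∞}; C ∈ {0.1, 1, 10, 100} ×
γ ∈ {10⁻⁴…1} log-spaced. The SVM uses one-vs-rest decomposition (it makes
the per-class ROC scores direct); its probability scores come from sigmoid
(Platt) calibration of the decision values, KNN/RF scores are vote
fractions, and the CNN's are its softmax outputs — the scheme is recorded in
the report metadata.

## Evaluation protocol

* **Split**: stratified 7:3; per class exactly ⌊0.7·n_c⌋ training samples,
  chosen uniformly from the seed. This floor rule is the one that reproduces
  the emulated design's cell counts exactly: (241, 463, 100) →
  train (168, 324, 70) / test (73, 139, 30).
* **Three-class run**: confusion matrix (rows = truth), accuracy,
  misdiagnosis count, macro-averaged one-vs-rest AUC with trapezoidal
  integration, per-class ROC curves.
* **Binary runs**: the three pairs (HC, BC), (HC, DCIS), (BC, DCIS), each
  restricted to the *same* train/test partition as the three-class run, each
  family refit from scratch. The positive class is the second-listed
  (disease over healthy, DCIS over BC); sensitivity is its recall,
  specificity the other class's recall. An empty truth row yields NaN with
  the affected rate named — never a silent zero.
* **Display rounding** is half-up at 2 dp in the CSV tables; `report.json`
  keeps full precision. Reports are byte-identical across reruns of the same
  config: all randomness (generator, split, fold shuffling, weight init,
  epoch shuffling, forest bootstrap) descends from the single config seed.

## Problem sizes used by the shipped checks

The full-cohort experiments in the acceptance tests run the default
804-sample generator at three seeds with the SVM grid search and the
100-epoch CNN; the report-determinism check and the CLI tests use scaled
cohorts (tens of samples, short CNN schedules, small grids) — determinism
and plumbing are structural properties that do not depend on cohort size.
The known-truth airPLS oracle runs at the full 1698-point axis.

## Known limitations

* The class-effect magnitudes are assumptions; real between-class
  differences may be weaker, correlated across bands, or confounded with
  age/batch — none of which the generator models. Headline accuracies on
  synthetic data characterise the pipeline, not clinical performance.
* The CNN trains with a fixed schedule (no early stopping or weight decay);
  on data with no class signal it memorises noise and its test predictions
  follow the class priors rather than collapsing to the majority class —
  the relevant null behaviour to expect when auditing for leakage.
* airPLS convergence is assessed by the ‖y‖₁-normalised residual rule; for
  signals whose baseline-to-signal ratio is extreme the fixed default λ may
  need retuning (it is a config field).
* Binary tasks reuse the three-class split rather than re-stratifying,
  by design (comparability across tasks), so pair-level class balance is
  inherited, not controlled.
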