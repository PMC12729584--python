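# Methods

This note documents the models, numerical choices and limitations of the
`gefc` pipeline in enough detail to reproduce or audit any stage.

## Signal representation and windowing

All features are computed on the per-sample magnitude
`d = sqrt(x² + y² + z²)` of each tri-axial sensor, never per axis. The
magnitude is rotation-invariant, which removes sensor-orientation nuisance
at the cost of discarding directional information. Windows are 100 samples
(1 s at 100 Hz) with a 50-sample step (50% overlap); trailing samples that
do not fill a window are discarded, and windows are never padded. Window
counts therefore follow `floor((N − L)/step) + 1` for signals of length
`N ≥ L`.

## The 29-feature bank

Twelve statistical features (mean, median, std, variance, min, max, range,
IQR, quartile deviation `=(Q3−Q1)/2`, skewness, excess kurtosis,
coefficient of variation), four energy features (SMA `= mean(|v|)`, RMS,
total energy `= Σv²`, log energy `= Σ log(v² + 10⁻¹²)`), eight spectral
features, and five nonlinear features, per sensor (× 3 = 87 columns).
Choices worth recording:

* **Moments.** Skewness and kurtosis use population (biased) moments;
  kurtosis is excess kurtosis. A constant window returns 0 for both by
  sentinel. The coefficient of variation is `std/|mean|` with sentinel 0
  when `|mean| < 10⁻¹²`.
* **Spectrum.** Mean-removed, rectangular window (no taper), one-sided
  periodogram — the simplest dialect, chosen once and fixed for
  reproducibility. The DC bin is excluded from every spectral statistic.
  Spectral entropy is Shannon entropy of the normalised power, divided by
  `log(n_bins)` so it lies in [0, 1]. Roll-off is the lowest frequency
  below which ≥ 85% of the power lies. Spectral flux is the Euclidean
  distance between consecutive windows' power spectra of the same sensor
  stream; the first window's flux is 0. Spectral variability is the
  standard deviation of the power-spectrum bins.
* **Sample entropy.** `m = 2`, tolerance `r = 0.2·std(window)`, Chebyshev
  distance, self-matches excluded; sentinel 0 when either template count is
  zero (guards the log).
* **Higuchi fractal dimension.** `k_max = 10` (capped at half the window),
  least-squares slope of `log L(k)` against `log(1/k)`; straight-line input
  gives FD ≈ 1.
* **Lyapunov exponent.** Rosenstein's method with embedding dimension 2,
  delay 1, a one-sample temporal exclusion zone for the nearest-neighbour
  search, and a least-squares fit of the mean log-divergence over the first
  10 steps. 100-sample windows preclude heavier estimators; windows too
  short to supply neighbours return sentinel 0.

All features are finite on any finite window after sentinel handling; the
matrix assembler additionally replaces (and logs) any residual non-finite
value with 0 as a last-resort guard.

## Composite feature scoring

Three scores per feature:

* **t-test**: `−log₁₀(p + ε)` with `ε = 10⁻¹⁰` *inside* the logarithm —
  this realises the guard against `p = 0` (capping the score at exactly 10)
  which the alternative reading `−log₁₀(p) + ε` cannot. The test is paired
  at the patient level: window values are aggregated to per-patient means
  per state before a paired t-test, because windows are not one-to-one
  across states. Without patient identifiers the code falls back to
  Welch's unpaired test and logs it. Degenerate inputs are mapped
  explicitly: a zero-variance paired difference yields `p = 0` if the means
  differ (perfectly consistent shift) and `p = 1` otherwise.
* **Random forest**: mean decrease in Gini impurity over 200 trees
  (unlimited depth, √-features per split, seeded). The per-tree impurity
  decreases are used unnormalised and averaged — an average, not a
  probability vector — since min-max normalisation downstream absorbs
  scale anyway.
* **PCA**: columns standardised, eigendecomposition of the correlation
  matrix, loadings = eigenvector × √eigenvalue (correlation loadings), and
  the score is the sum of absolute loadings over *all* components with
  eigenvalue > 10⁻¹². Zero-variance columns score 0 (logged).

Each raw score vector is min-max normalised independently (a constant
vector maps to all-zeros rather than NaN), fused with weights 0.4/0.3/0.3,
and ranked by descending composite with ties broken by feature name. The
top `max(1, floor(0.8·n))` features are retained.

## Grammatical evolution

The grammar derives arithmetic expressions over `x1..xd`:
`expr → (expr op expr) | func(expr) | terminal` (3 rules),
`op → + | − | * | /` (4), `func → sin | cos | exp | log` (4),
`terminal → xlist | const` (2), `xlist → x1 | … | xd` (d), and `const` a
decimal literal built from two digit nonterminals. The constant branch can
be disabled by a flag for tracing derivations that never take it.

Mapping is the classic leftmost derivation: each nonterminal consumes one
codon and selects rule `codon mod NR`. When the codon stream is exhausted
it wraps to the start, at most twice; a derivation still containing
nonterminals after the wrap budget is invalid. The wrap counter increments
lazily — consuming exactly the whole chromosome counts as zero wraps. A
depth/step cap guards pathological recursion. Expressions serialise to
fully parenthesised infix and parse back to structurally equal trees.

Evaluation is guarded rather than grammar-restricted: division by
`|b| < 10⁻¹⁰⁰`, `log` of a non-positive argument, `exp` overflow, or any
intermediate magnitude above `10¹⁰⁰` clears a finite-flag instead of
raising. Invalid evaluations are penalised downstream.

## Feature-construction GA

`Nf` expressions are mapped from **one** codon stream by sequential
consumption (expression *i+1* resumes where *i* stopped). The alternative —
splitting the chromosome into equal segments — was rejected because it caps
expression size asymmetrically.

Defaults: 500 generations × 500 chromosomes of 100 codons in [0, 255],
selection rate `ps = 0.10`, mutation rate `pm = 0.05`, tournament size 4.
Per generation the best `(1 − ps)·Nc` survive intact; `ps·Nc` offspring are
bred by tournament selection from the whole population, one-point crossover
(cut uniform in `[1, L−1]`) and per-codon uniform-reset mutation, and
replace the worst individuals. Only offspring are (re-)evaluated, so a run
costs `Nc + (Ng−1)·ps·Nc` fitness evaluations. Elitism makes the
best-fitness trace monotone non-increasing, which the tests assert on every
run.

Fitness is the training SSE of a Gaussian RBF network on the transformed
patterns: 10 nodes (mirroring the 10 processing nodes used by the
evaluation networks; the fitness model's node count is otherwise a free
choice), centers by seeded k-means, width of node *j* = mean distance of
its cluster members to the center (floored at 10⁻⁶), output weights by
ridge-stabilised least squares (ridge 10⁻⁸). Unmappable chromosomes or
non-finite transformed values earn a finite penalty fitness of 10¹⁰⁰ so the
population ordering stays total.

At transform time (applying a final expression set to a dataset) guarded
cells are clipped to ±10¹⁰⁰ and counted in the log, because every row must
survive.

## Evaluation protocol

Stratified k-fold cross-validation (default 10 folds) repeated (default 30
times) with repeat-indexed seeds. Error is `100·(FP+FN)/total`; precision
and recall are macro-averaged over both classes (the choice is documented
and could be made per-class), with zero-denominator classes contributing 0.
For the FC method the entire scoring + retention + evolution pipeline is
re-fit inside each training fold and the held-out fold is only transformed,
so no label information leaks. An optional patient-grouped mode keeps all
windows of a patient in one fold, avoiding the window-level optimism of
plain stratification; both modes exist because recording protocols differ
in whether they allow a subject's windows to span folds.

The FC method's final classifier is the RBF network on the constructed
features — the same model family as the fitness function and as the
raw-feature baseline, making the FC-vs-RBF comparison a pure test of the
representation. A GA-trained MLP final stage is available as an option.
Baselines: `rbf` (RBF on raw features, 10 nodes), `gen_mlp` (one sigmoid
hidden layer, 10 nodes, weights in [−10, 10] evolved by a real-coded
elitist GA on training SSE), `pca_mlp` (2 principal components, then the
MLP trained by BFGS from a seeded random initialisation). ROC and PR curves
sweep the unique decision scores; areas use the trapezoid rule.

## Synthetic cohort generator

The generator emulates the study conditions the pipeline assumes — 14
patients, both medication states, four exercises, 100 Hz, 10 s per session
(19 windows per session, ~266 windows per class per exercise):

* **Tremor**: a sinusoid at a per-patient frequency drawn uniformly from
  4–6 Hz, with phase-random-walk and smooth amplitude jitter scaled by the
  state (OFF 0.3, ON 0.1) — OFF tremor is both larger (amplitude 1.0 vs
  0.4) and more irregular.
* **Medication-response heterogeneity**: per-patient lognormal severity
  (σ = 0.4) and *state-specific* response multipliers (σ = 0.6), so a
  minority of synthetic patients barely respond in amplitude. Amplitude is
  therefore confounded with patient identity while the regularity contrast
  stays consistent — the structure under which nonlinear/regularity
  descriptors, not raw energy, are the reliable state markers.
* **Exercises**: rest (tremor only), postural (0.3 Hz drift + tremor),
  tapping and open–close (Gaussian pulse trains at 1.5 Hz OFF vs 2.5 Hz ON,
  scaled per patient — the bradykinesia axis).
* **Sensors**: the accelerometer rides on a 9.81-unit gravity offset
  (keeping the magnitude in its linear regime so the tremor fundamental,
  not a rectification harmonic, dominates the spectrum); the gyroscope
  carries the oscillation's rate with a small bias; the magnetometer is
  drift-dominated with attenuated tremor, deliberately the least
  informative channel. A random per-session rotation couples the axes.
* White sensor noise (sd 0.05) on every axis; all randomness derives from
  `(seed, patient, exercise, state)` tuples, so sessions are bit-identical
  per seed.

What the generator does **not** model: biomechanically realistic hand
kinematics, sensor calibration error and drift, movement artifacts,
non-stationary disease progression within a session, or the correlation
structure of real multi-joint movement. Passing tests on this cohort
demonstrate that the pipeline recovers planted OFF/ON structure under
realistic nuisance (patient confounding, noise, weak responders); they do
not certify performance on real patients.

## Problem sizes used in the shipped checks

The test suite evaluates the evolutionary search at reduced scale chosen to
exercise every mechanism while keeping runs short: the elitism property
over 30 runs at 30 generations × 50 chromosomes; the end-to-end synthetic
comparison at 50 generations × 100 chromosomes with `Nf = 3` and a single
10-fold pass; reproducibility on a 4-patient cohort. The published-scale
defaults (500 × 500, 30 repeats) remain the config defaults.

## Known limitations

* The RBF fitness retrains k-means per candidate, which dominates run time;
  caching or mini-batch centers would speed large runs.
* The paired t-test aggregates windows to patient means; with very few
  patients its power is limited, and no multiple-testing correction is
  applied (by design — scores are ranks, not inference).
* PCA loading scores retain all components, so pure-noise variance
  contributes; truncating to components above the mean eigenvalue would be
  a reasonable variant.
* Window-level stratified CV lets windows of one session span folds;
  patient-grouped CV is provided and reports noticeably higher error, as
  expected.
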