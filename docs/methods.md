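# Methods

## Scoring model

The scorer assumes the five ordinal severity levels are separated by four
*parallel* hyperplanes in gait-feature space — one direction `w` encodes
"worse gait", and only the offsets differ between levels. The signed
distance `xhp = wᵀx + c` is pushed through a fixed sigmoid centred at
`(b_u + b_l)/2 = 2` with range `(b_l, b_u) = (−0.5, 4.5)`, then through a
continuous piecewise-linear map whose knots `p₁..p₄` (the bounded-distance
values at the hyperplanes) are mapped to 0.5, 1.5, 2.5, 3.5. The
composition is strictly increasing, so rounding the score at half-integers
is equivalent to locating `xhp` between hyperplanes; the continuous value
additionally grades severity within a level. The parameterisation `(w, c,
p)` is the one actually trained; the redundant unnormalised form (direction
plus per-hyperplane constants) is never materialised.

Assumptions worth stating: levels are ordered along a single direction
(no level-specific feature interactions); the sigmoid centre and bounds are
fixed, not trained; scores of different subjects are comparable only after
the features are on a common scale (see standardisation below).

## Loss and optimisation

`L = (Σ_j E_j)/N + λ R1 + β R2` with `λ = 0.1`, `β = 0.005`.

* `E_j` averages `|y − Y|` (continuous score vs integer clinician level)
  within level `j`; dividing by the number of levels present, `N`, weights
  levels equally regardless of group sizes.
* `R1 = Σ_k (w_k std(x_k))²` uses the per-feature sample standard
  deviation (n−1) of the raw training matrix, making the ridge invariant
  to feature units.
* `R2 = Σ 1/gap` over the five segment gaps (equal to 5.0 at the default
  evenly spaced knots) repels degenerate, collapsing segments.

Optimisation is SLSQP from the deterministic initialisation `w = 0, c = 0,
p = (0.5, 1.5, 2.5, 3.5)` under `p₁ ≥ b_l`, `p_{i+1} − p_i ≥ ε_gap`
(default 1e−3; optimisers need a closed feasible set in place of strict
inequalities) and `p₄ ≤ b_u`. The absolute error is kept non-smooth; the
implementation supplies the analytic (sub)gradient of the loss
(`jac="analytic"`, verified against finite differences to ~1e−6), which
both converges to lower loss values and halves runtime relative to
finite-difference gradients (`jac="fd"` remains available). An optional
Huber smoothing of the absolute error (`huber_delta`) exists behind a
flag and is off by default. Multi-start is deliberately absent from the
default path: the fit is bit-reproducible given the data. Spot checks with
random multi-restarts on several datasets reached numerically identical
minima, so the single deterministic start is not a practical limitation.

Fitted models always satisfy the constraint set (`check_constraints`);
the fit falls back to the initial point if the optimiser cannot improve
on it, so the returned loss never exceeds the initial loss.

## Evaluation protocol

Leave-one-subject-out: for each subject the scaler and the model are
re-fitted on the remaining subjects only. Standardisation inside a fold
uses the fold's *healthy* rows (z-score by healthy mean and n−1 std) when
at least two exist, otherwise all training rows; constant columns are
centred but left unscaled. Errors follow one recipe everywhere: rounded
score (half-points round up, toward higher severity — ties must resolve
deterministically and the clinical convention is to not understate
severity), `e = |rounded − clinician level|`, cumulative shares
`c_i = 100 · #{e ≤ i}/N`. Baselines (linear one-vs-rest SVM with C = 1,
Gaussian naive Bayes, least-squares regression clamped to [−0.5, 4.5]
before rounding) consume identical fold splits, so comparisons are paired.
The SVM kernel and C, and the NB variance floor, are exposed but default
to the simplest choices sensible for ~50 subjects and ≤ 12 features.

Feature selection: one-way fixed-effects ANOVA per feature across levels
(healthy subjects count as level 0) removes features with p ≥ 0.01; a
feature constant everywhere is assigned F = 0, p = 1. The wrapper search
is *forward* greedy on LOSO mean estimation error — despite the field
often labelling this "RFE", adding the single best feature per step is
what the error-curve construction requires; a backward-elimination mode
exists for comparison. Ties break toward the smaller set, then canonical
feature order, so the search is deterministic.

## Signal pipeline

* **Frame correction.** The quasi-static standing period (gyro magnitude
  < 5 °/s for ≥ 1 s) gives the gravity direction; the minimal rotation
  mapping it onto −X aligns the sensor X axis with the shank long axis.
  Residual roll about the shank axis is unobservable from gravity and is
  harmless: the progression axis is later defined from data. An explicit
  override rotation is accepted for rigs without a standing period.
* **Event detection.** Gyro Z is low-pass filtered (zero-phase, 4th-order
  Butterworth, 10 Hz). Mid-swing produces a positive peak (prominence
  ≥ 50 °/s, separation ≥ 0.4 s); toe-off is the prominent trough
  immediately before a peak, heel-strike the trough immediately after.
  Trough prominence is thresholded relative to the median swing-peak
  prominence (15%) so filter ripple is never mistaken for an event. If the
  dominant peaks are negative (mirrored mounting on the other shank), the
  working copy of the signal is flipped first. Cycles run HS→HS with the
  interior TO splitting stance from swing; implausible durations (outside
  0.4–4 s) are dropped. The first four cycles per leg are treated as
  gait initiation and discarded; up to ten steady cycles are kept.
* **Trajectory.** Zero-velocity instants are the minima of the 0.1
  s-smoothed gyro magnitude within each stance (rejected above 40 °/s —
  no foot-flat means no ZUPT). The attitude is anchored to gravity at the
  zero-velocity instant and propagated across the cycle by strapdown
  integration of the body rates; gravity-compensated acceleration is
  integrated twice (trapezoid), velocity is pinned to zero at the anchor,
  and the residual velocity at the *next* cycle's anchor is removed
  linearly in time (`drift_model="linear"`; `"none"` disables). The
  progression axis is the horizontal vector joining the ankle positions at
  the two bounding heel strikes; vertical is up; lateral completes the
  right-handed frame. The sensor sits at the ankle; no lever-arm
  correction is applied.
* **Features.** Twelve per cycle; SL, MH, RL, MPV, MVV, MHD are divided
  by subject height. The height datum and the landing points are the
  cycle-start heel strike ("two adjacent landing points" is read as the
  stride of one leg, since each IMU is processed independently). A
  subject's row is the flat mean over all steady cycles of both legs and
  all trials — not a mean of trial means; with balanced trials the
  difference is second order.

## Synthetic data

The feature-tier generator draws each subject's position `t` in
signed-distance space inside its level's band (bands are the sigmoid
pre-images of `[p_{l−1}, p_l)`), then sets
`x = μ_healthy + σ_healthy ⊙ (t·ŵ* + ε)`. Within-band positions follow a
Beta(2, 2) scaled to the band: clinically, presentations cluster centrally
within a level and borderline cases are rarer, and the resulting
within-level score distributions are unimodal like those of real cohorts.
Outer bands (levels 0 and 4 have no far boundary) are truncated at 1.5×
the adjacent inner band width. Noise `ε` is isotropic Gaussian in
standardised feature units; the `noise_band_frac` convenience sets one
homoskedastic σ as a fraction of the *mean inner band width* — noise is a
property of the measurement, not of the subject's severity. The default
severity direction lowers SL, MH, RSZ, MPV, MSV and MHD (slower, shorter,
flatter strides), leaving the other six features uninformative.

The signal-tier generator builds an analytic ankle path per cycle — still
during stance, a quintic arc in swing with zero velocity and acceleration
at the stance boundaries, peak height and its timing prescribed — and a
sagittal shank-rotation profile: negative dips at each heel strike and
toe-off and a raised-cosine-squared mid-swing pulse whose peak equals the
MSV target, balanced so net rotation per trial is zero. Acceleration is
the exact second derivative of the path plus gravity, rotated into the
sensor frame (the left sensor is mirrored; the right leg leads by half a
cycle); trials start and end with quiet standing for the static
calibration. Because only mediolateral-axis rotation is synthesised,
RSX/RSY ground truth is zero and MPV, MVV and RSZ follow from the arc
shape rather than being free targets. Default per-level presets
(SL 1.20/0.88/0.56 m, GD 1.05/1.20/1.40 s, PSP 40/38/35%, MH
0.16/0.12/0.08 m, MSV 400/300/200 °/s for levels 0/1/2) encode the
qualitative slower-shorter-flatter trend; they are package defaults, not
clinical reference values.

What passing tests on this generator do **not** show about real data:
real gait has stance-phase ankle motion, turning, asymmetry,
stride-to-stride variability, soft-tissue artefact and sensor bias, none
of which are emulated; the feature-tier generator realises the scoring
model's own geometry, so recovery tests validate the estimation machinery,
not the clinical adequacy of the parallel-hyperplane assumption.

## Numerical choices and degenerate inputs

100 Hz trapezoid integration leaves ~3 mm of quadrature error per cycle in
the re-integrated swing arc; pipeline tolerances (e.g. ±0.05 m on a 1.2 m
stride) absorb it. Readers reject rather than clip out-of-range samples
(beyond a 1% glitch allowance), non-monotonic time, and >1% deviation from
the nominal rate. Scoring at extreme distances clamps the bounded distance
into the open interval by 1e−12 to protect the piecewise map from float
saturation. Zero-variance reference columns raise by default and are
unit-scaled only inside the LOSO harness. Degenerate cycles (TO at HS),
empty aggregations, single-level training sets, gravity-free calibration
windows and empty error vectors all raise typed errors.

## Problem sizes

Test and demonstration runs use desk-scale cohorts chosen to exercise the
statistics without waste: 30 subjects (10/level) for exactness checks,
150 (50/level) × 10 seeds for noisy-recovery rates, 60 (20/level) × 10
seeds for the baseline comparison, and 8–16-cycle trials for the signal
pipeline. These sizes are the package's test conditions, comparable to a
single clinical cohort of the kind the method targets.

## Known limitations

Heading is unobservable (no magnetometer): trajectories are per-cycle and
cannot be stitched into a global path. The event detector expects the
classic shank-gyro pattern of level walking; festination, shuffling or
freezing episodes may defeat the prominence logic. The per-level MAE loss
can, on unfavourable draws, narrow the score segment of a level squeezed
between much wider neighbours, costing exact-accuracy there — a property
of the objective, not of the optimiser (restarts reach the same minima).
Levels 3–4 are never exercised with gait data since such patients cannot
perform the walking task; the model accepts them formally.
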