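# Methods

`cardiowalk` analyzes instrumented six-minute walk tests (6MWT) in cardiac
rehabilitation: a chest-worn device records a lead-II ECG (reduced here to
R-peak timestamps) and triaxial acceleration at 32 Hz over a 5-min rest /
6-min walk / 5-min recovery protocol, repeated over five serial tests per
patient across the rehabilitation program. The package covers four stages —
synthetic data generation, biomarker extraction, distance prediction, and
progression mapping — each documented below.

## Heart-rate biomarkers

**Artifact rejection.** Beat detection errors and ectopic beats distort
rate statistics. Since interactive beat-editing is not reproducible, we use
a deterministic rule: each RR interval is compared against the median of an
11-interval window centred on it; intervals deviating by more than 30%
(relative) are flagged, and the beats *interior to runs of two or more
consecutive flagged intervals* are removed. A premature beat produces the
classic short/long interval pair and is excised exactly; an isolated long
interval (a missed detection) has no interior beat, so nothing is removed —
deleting a neighbouring genuine beat would only widen the gap. The rule is
idempotent on clean input. Residual effect of 2% ectopy after cleaning is a
small negative bias on resting HR (each excised beat leaves one interval at
half rate), measured at about 1–2 bpm.

**Local HR.** The instantaneous rate 60/RR is treated as a step function
over beat intervals and averaged inside contiguous 150 ms bins — the width
of the widest plausible QRS complex, so no bin can contain more than one
beat onset. The bin value is computed *exactly* as the difference of the
cumulative step-function integral at the bin edges (no grid discretization);
the test suite checks it against dense numerical integration to < 0.1 bpm.
Bins before the first or after the last beat inherit the nearest interval's
rate.

**Scalar parameters.** From the binned series with phase boundaries at
300/660/960 s:

| parameter | definition | unit |
|---|---|---|
| `hr_rest` | mean over bins in [0, 300) | bpm |
| `hr_max` | max over bins in [540, 660), i.e. the last 2 min of the walk | bpm |
| `hr_avg` | mean over all bins in [0, 960) | bpm |
| `chronotropic_response` | `hr_max − hr_rest` (identity, asserted) | bpm |
| `time_to_hr_max` | start of the earliest maximizing bin − 300 s | s |
| `time_to_recuperation` | see below | s |

The `hr_max` search window is deliberately the final 2 min *of the walk*:
in the final 2 min of the whole recording HR is already decaying, so a
maximum there would not measure exercise capacity.

**Recuperation time.** The recovery clock starts 5 s after walk end (the
first bin whose start is ≥ 665 s); recuperation is the elapsed time until
the first bin at or below `hr_max − 0.666·(hr_max − hr_rest)`. For a
mono-exponential recovery with time constant τ the true crossing lies at
`τ·ln(1/0.334)` after walk end, so the extracted value should be
`τ·ln(1/0.334) − 5` s; tests verify this within max(1 s, 2 bins) for
τ ∈ {30, 60, 120} s. A recovery that never crosses the threshold before
record end is flagged (`recuperation_reached = False`, value NaN) and such
rows are excluded from model fitting rather than imputed. A negative
chronotropic response is permitted (flagged, not an error): the threshold
then sits above `hr_max` and is met immediately.

**Effort.** Physical effort over a window is the summed squared triaxial
acceleration `Σ_k (x_k² + y_k² + z_k²)` (g²·samples), computed over the
three consecutive 2-min walk windows and the full walk. By default each
axis is de-meaned with means computed *once over the walk phase*: without
this, the static 1 g gravity projection dominates the sum and the statistic
is insensitive to activity. The shared means make the three window efforts
sum to the walk total exactly. `demean=False` gives the literal raw-sample
definition; both modes are tested. Effort is reported in the stream's native
units (g² here); no unit conversion is applied.

## Distance models

**Stepwise linear regression.** Forward entry at p < 0.05 on the partial
t-test (equivalent to the partial F-test for a single column), backward
removal at p > 0.10 — the conventional thresholds of the procedure. The
candidate pool is age, height, weight, sex (binary indicator), `hr_max`,
`hr_rest`, `hr_avg`, chronotropic response, recuperation time, time to
HR_max, and total walk effort. Candidates numerically collinear with the
current design (residual variance fraction < 1e-10 after projection) are
skipped with a warning, so a duplicated predictor can enter only once.
Reported: R² and RMSE of the final fit on all complete rows. Note the
usual caveat: with several pure-noise candidates each tested at 5%, the
familywise chance of at least one entering is roughly `1 − 0.95^k`, only
partly recovered by backward removal.

**SVM regression.** Epsilon-insensitive SVR compared over five kernels
(RBF, linear, polynomial degree 2/3/4) and six feature combinations
({effort, CR}, {effort, height}, {effort}, {effort, CR, height}, {CR},
{CR, height}, with CR = chronotropic response and effort = walk total).
Features are standardized with train-set statistics only. Defaults:
ε = 0.1 × train outcome SD; C = max|mean(y) ± 3·sd(y)| (a standard
output-range heuristic); polynomial kernels use scale 1, offset 1. The RBF
scale starts from the median pairwise distance of a ≤256-row train
subsample (γ = 1/(2d²)) and is refined over γ·{¼, ½, 1, 2, 4} on a
train-internal by-subject split before refitting on the full train set.

**Validation** is Monte-Carlo cross-validation: 20 repeats (5 in the
reduced end-to-end run) of a fresh random 80/20 split *at the patient
level* — all sessions of a patient stay on one side, since sessions of one
patient are strongly dependent. The train count rounds to the nearest
patient with ties toward test (89 patients → 71 train / 18 test). Reported
MAE ± SD pools absolute errors over all test sessions of all repeats;
per-repeat means are also exported. A failed fit is recorded as a flagged
grid cell, never silently dropped.

## Progression mapping

Each session's composite is (chronotropic response, effort over the last
2 min of the walk, session number), z-scored per column — the inputs differ
by orders of magnitude (bpm vs summed g²), so unscaled Euclidean distances
would be degenerate. The walking distance never enters the matrix (a test
asserts bitwise-identical coordinates with the outcome column deleted); it
is used only to color points. The 3-column matrix is embedded into 3-D with
exact-gradient t-SNE (perplexity 30, shrunk with a warning below 3×perplexity
rows; PCA initialization; 1000 iterations; fixed seed ⇒ bitwise-reproducible
output, with seed, perplexity and an input-matrix hash stored for
provenance). 2-D output is supported for flat reporting. Embedding quality
is checked as 10-nearest-neighbour overlap between input and embedded
space against the k/(N−1) random baseline.

Per-patient trajectories order a patient's embedded sessions and report
first-to-last deltas of distance, chronotropic response and effort — exact
table differences, independent of the embedding. A gain ≥ 50 m (the
conventional clinically significant 6MWD change) tags the patient
`responder`, otherwise `limited-response`.

## Synthetic cohort generator

The generator is the package's test bed and defines the conditions under
which every claim here is verified.

**HR dynamics.** Rest is constant `hr_rest`; the walk rises toward
`hr_plateau` as `hr_plateau − (hr_plateau − hr_rest)·e^{−(t−300)/rise_tau}`;
recovery decays from the walk-end rate back to rest with time constant
`recovery_tau`. Both transitions are single exponentials — the simplest
dynamic with an analytically checkable recuperation time. Beats are placed
sequentially with interval 60/HR evaluated at the interval midpoint (one
fixed-point refinement, keeping the integrated rate within 0.5 bpm of the
profile), plus Gaussian RR jitter. The jitter SD is `hrv_sd` (default
15 ms) *scaled by RR/RR_rest*, shrinking variability as HR rises, as vagal
withdrawal does physiologically; a constant rest-level jitter would inflate
the max-over-bins `hr_max` estimator by several bpm at plateau. Ectopy
(default 1% per beat) replaces a beat with an early beat at 0.6× the local
interval plus a compensatory pause restoring phase; dropout (default 0.2%)
deletes a beat.

**Accelerometer.** The gravity axis carries a constant 1 g; during the walk
the two lateral axes carry sinusoids at the step frequency and the gravity
axis at the step frequency and its double (impact harmonic), scaled by
`step_amplitude` with random phases; white noise (default 0.02 g) is added
throughout. Raw ECG waveforms and biomechanically realistic gait are
deliberately out of scope: all downstream computation consumes R-peaks and
acceleration summaries, so waveform synthesis would add no testable content.

**Cohort structure.** Defaults: 89 patients × 5 sessions. Each patient has
a latent fitness `f` (baseline ~ N(0.5, 0.15)); responders (default 70%)
gain N(0.19, 0.05) fitness per session, non-responders N(0.01, 0.02). Per
session the cardiac and gait channels see `f` through independent N(0, 0.08)
perturbations, so chronotropic response and effort are correlated but not
collinear — without this no variable-selection experiment is meaningful.
Fitness maps linearly to physiology: `hr_rest = 76 − 12f` bpm,
`hr_plateau = 95 + 40f` bpm (so CR = 19 + 52f), cadence `1.4 + 0.6f` steps/s,
step amplitude `0.22 + 0.18f` g, recovery τ `90 − 40f` s. The measured
distance is `300 + 2·CR + 20·effort_scale + patient effect (SD 40 m) +
session noise (SD 20 m)` meters, with `effort_scale = (f_gait − 0.5)/0.25`.
These defaults produce an expected first-to-last cohort gain of ~100 m
(closed form in `expected_final_gain`), resting HR in the 60–80 bpm range,
and distances spanning roughly 250–550 m — the regime of a rehabilitation
cohort. `apply_saturating_outcome` swaps the linear outcome for a logistic
function of effort to create a cohort where a nonlinear kernel should win.

**What the simulator does not emulate** — and hence what passing tests do
not show about clinical data: pathological rhythms (AF, bigeminy),
detector-specific R-peak error structure, non-stationary walking (pauses,
turns at track ends), device orientation drift, and any nonlinearity in the
true distance–biomarker relation beyond the optional logistic link. Results
on real recordings depend on an upstream R-peak detector not included here.

## Numerical and design notes

- Phase boundaries are half-open `[start, end)` everywhere; time origin 0 s
  at recording start.
- `hr_max` ties break to the earliest bin; recuperation elapsed time is
  measured from the first evaluated bin, so a threshold met immediately
  yields exactly 0.
- Serialization uses `%.17g`; readers parse with round-trip float precision,
  so write→read is bit-exact (fuzz-tested).
- t-SNE uses the exact gradient because the Barnes–Hut approximation is
  unavailable for 3-D output; at ~450 points this costs seconds.
- With the default `hrv_sd = 15` ms, the extracted chronotropic response
  carries a positive bias of a few bpm (maximum of ~240 noisy bin values at
  plateau); this is a property of any max-based HR_max estimator and is
  nearly constant across sessions, so regression slopes are unaffected.
  Artifact-mitigation checks therefore isolate ectopy (jitter off) from
  jitter effects.
- Problem sizes in the test suite: full-scale runs use the default 89 × 5
  cohort; kernel-comparison checks use 5–20 split repeats; statistical
  recovery checks use 50–100 independent replicates. These sizes keep every
  Monte-Carlo bound at least ~2 SE away from its pass/fail boundary under
  the stated generator defaults.

## Known limitations

- The RR cleaning rule handles isolated ectopics and dropouts; runs of
  consecutive ectopic beats can leave residual rate spikes.
- Stepwise selection inherits the classical multiplicity caveat above;
  selection-rate guarantees degrade with many noise candidates.
- The SVM grid treats hyperparameters beyond the RBF scale as fixed
  defaults; no nested search over C or ε is performed.
- t-SNE coordinates are run-specific (seed-dependent): maps from different
  seeds are not comparable, and trajectories must always be read together
  with the feature deltas, which are embedding-independent.
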