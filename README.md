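# cardiowalk

Wearable-sensor analysis of six-minute walk tests (6MWT) for cardiac
rehabilitation follow-up.

Patients in a cardiac rehabilitation program perform serial 6MWTs while
wearing a chest sensor that records a lead-II ECG and triaxial acceleration
(32 Hz) over a 5-min rest / 6-min walk / 5-min recovery protocol. From the
R-peak stream and the acceleration signal, `cardiowalk` extracts
physiological biomarkers, predicts the six-minute walking distance (6MWD, a
standard functional-capacity measure), and maps each patient's progression
through rehabilitation:

- **Biomarkers** — a 150 ms-binned local heart-rate series yields HR_rest,
  HR_max (last 2 min of the walk), HR_avg, the *chronotropic response*
  `CR = HR_max − HR_rest`, the time to HR_max, and the *recuperation time*
  (time after the walk for HR to shed 66.6% of the exercise range);
  *effort* is the summed squared acceleration `Σ_k (X_k² + Y_k² + Z_k²)`
  over 2-min walk windows, gravity-corrected by per-axis mean removal.
- **Models** — stepwise linear regression of 6MWD on anthropometric, ECG-
  and accelerometer-derived candidates (reported with R² and RMSE), and an
  ε-SVM regression grid over five kernels × six feature sets validated with
  repeated 80/20 *by-subject* splits (MAE ± SD).
- **Tracking** — (CR, effort, session number) composites, z-scored and
  embedded into 3-D with t-SNE; the walking distance never enters the
  embedding and is only used for coloring. Per-patient trajectories report
  first-to-last changes, tagged against the 50 m clinically significant
  6MWD threshold.

Since no clinical recordings ship with the package, a fully seeded
synthetic-data module generates cohorts (default 89 patients × 5 sessions)
with known ground truth — exponential HR kinetics, RR jitter, ectopic
beats, gait-modulated acceleration, and a distance outcome driven by
chronotropic response and effort. All claims in the test suite are verified
against this generator and against exact oracles. See `docs/methods.md` for
the model details and `docs/FORMATS.md` for the on-disk formats.

## Worked example

```python
import warnings; warnings.filterwarnings("ignore")
from cardiowalk import synthdata, features, models, tracking

config = synthdata.CohortConfig(n_patients=20, rng_seed=0)
recordings, truth = synthdata.simulate_cohort(config)
table = features.extract_cohort(recordings)

fv = table.iloc[0]
print(f"P001 s1: HR_rest {fv.hr_rest:.1f} bpm, HR_max {fv.hr_max:.1f} bpm, "
      f"CR {fv.chronotropic_response:.1f} bpm, "
      f"recuperation {fv.time_to_recuperation:.1f} s, "
      f"effort(last 2 min) {fv.effort_win3:.0f} g^2")

report = models.fit_stepwise_linear(table)
print(f"stepwise: {report.selected_features}, R2={report.r_squared:.3f}, "
      f"RMSE={report.rmse:.1f} m")

grid = models.run_kernel_comparison(table, n_repeats=5, seed=0)
cell = grid.cell("effort+cr", "rbf")
print(f"SVM (RBF, effort+CR): MAE {cell.mae_mean:.1f} +/- {cell.mae_sd:.1f} m")

X, ids = tracking.build_composites(table)
emb = tracking.embed_tsne(X, ids, seed=0)
traj = tracking.extract_trajectory(emb, table, "P003")
print(f"P003: {traj.classification}, d6MWD={traj.delta_six_mwd:+.1f} m, "
      f"dCR={traj.delta_chronotropic:+.1f} bpm")
```

prints

```
P001 s1: HR_rest 68.5 bpm, HR_max 121.1 bpm, CR 52.5 bpm, recuperation 22.9 s, effort(last 2 min) 157 g^2
stepwise: ['chronotropic_response', 'weight_kg'], R2=0.660, RMSE=39.3 m
SVM (RBF, effort+CR): MAE 43.2 +/- 28.8 m
P003: responder, d6MWD=+178.1 m, dCR=+50.3 bpm
```

Reading: the first session shows a healthy 52.5 bpm chronotropic rise and a
fast (22.9 s) recovery. On this 20-patient cohort the stepwise model keeps
the chronotropic response (plus weight) and explains 66% of the distance
variance with a 39 m residual error; the RBF-kernel SVM on effort + CR
predicts held-out patients' distances to ~43 m on average. Patient P003
gained 178 m from first to last session — above the 50 m clinically
significant threshold, hence a responder — alongside a 50 bpm gain in
chronotropic response.

The same workflow is available from the shell:

```bash
cardiowalk simulate --config cohort.cfg --out sessions/ --seed 7
cardiowalk validate sessions/P001_s1
cardiowalk extract --sessions sessions/ --out features.csv
cardiowalk fit-linear --features features.csv --out linear.json
cardiowalk compare-kernels --features features.csv --repeats 20 --seed 1 --out grid.csv
cardiowalk embed --features features.csv --seed 1 --out embedding.csv
cardiowalk track --features features.csv --embedding embedding.csv --patient P003 --out traj.json
```

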