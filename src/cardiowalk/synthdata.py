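"""Synthetic multi-session 6MWT wearable recordings with known ground truth.

No clinical recordings are distributed with this package, so analyses are
developed and validated against a simulator that emulates the statistical
structure a rehabilitation 6MWT study produces:

* heart-rate dynamics over the 5-min rest / 6-min walk / 5-min recovery
  protocol: constant resting HR, mono-exponential rise to an exercise
  plateau, mono-exponential recovery;
* beat-to-beat variability, ectopic beats (an early beat at 0.6x the local
  interval followed by a compensatory pause) and missed detections;
* gait-modulated triaxial acceleration at 32 Hz during the walk, gravity plus
  white noise otherwise;
* a cohort of patients measured over several serial tests whose latent
  fitness improves over the program for "responders", driving resting HR
  down and chronotropic response, cadence and step amplitude up, with the
  measured walking distance an affine function of chronotropic response and
  (standardized) effort plus patient-level and session-level noise.

All randomness flows from explicit integer seeds; a fixed seed reproduces a
cohort bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterator

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .session_io import (
    Anthropometrics,
    PhaseTimes,
    SessionRecording,
    write_session,
)

__all__ = [
    "HRDynamicsParams",
    "GaitParams",
    "CohortConfig",
    "simulate_hr_profile",
    "simulate_r_peaks",
    "simulate_accelerometer",
    "simulate_session",
    "simulate_cohort",
    "simulate_cohort_truth",
    "truth_to_feature_table",
    "apply_saturating_outcome",
    "expected_final_gain",
    "write_ground_truth",
]

MAX_SEED = 2**31 - 1

# Latent-fitness -> physiology mapping.  Fitness f is a dimensionless scalar
# centred near 0.5 for a typical rehabilitation entrant; one unit of fitness
# moves resting HR by -12 bpm, the exercise plateau by +40 bpm (so the
# chronotropic response by +52 bpm), and the standardized effort scale by +4.
HR_REST_BASE = 76.0
HR_REST_PER_FITNESS = -12.0
HR_PLATEAU_BASE = 95.0
HR_PLATEAU_PER_FITNESS = 40.0
CR_PER_FITNESS = HR_PLATEAU_PER_FITNESS - HR_REST_PER_FITNESS  # 52 bpm / unit
EFFORT_CENTER = 0.5
EFFORT_SCALE_PER_FITNESS = 4.0  # effort_scale = (f - 0.5) / 0.25
CADENCE_BASE = 1.4
CADENCE_PER_FITNESS = 0.6
STEP_AMP_BASE = 0.22
STEP_AMP_PER_FITNESS = 0.18
RECOVERY_TAU_BASE = 90.0
RECOVERY_TAU_PER_FITNESS = -40.0


@dataclass(frozen=True)
class HRDynamicsParams:
    """Latent heart-rate dynamics of one session.

    hrv_sd is the beat-to-beat (RR) jitter standard deviation in milliseconds
    *at rest*; the jitter applied to an interval is scaled by RR/RR_rest so
    that variability shrinks as HR rises, as it does physiologically under
    sympathetic drive.
    """

    hr_rest: float = 70.0
    hr_plateau: float = 115.0
    rise_tau: float = 45.0
    recovery_tau: float = 80.0
    hrv_sd: float = 15.0  # ms
    ectopic_rate: float = 0.01
    dropout_rate: float = 0.002

    def __post_init__(self) -> None:
        if self.hr_rest <= 0:
            raise ConfigurationError("hr_rest must be > 0")
        if self.hr_plateau < self.hr_rest:
            raise ConfigurationError("hr_plateau must be >= hr_rest")
        if self.rise_tau <= 0 or self.recovery_tau <= 0:
            raise ConfigurationError("time constants must be > 0")
        if self.hrv_sd < 0:
            raise ConfigurationError("hrv_sd must be >= 0")
        for name in ("ectopic_rate", "dropout_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 0.1:
                raise ConfigurationError(f"{name} must be in [0, 0.1], got {v}")


@dataclass(frozen=True)
class GaitParams:
    """Walking-phase accelerometer model parameters (units of g)."""

    cadence: float = 1.7  # steps / s
    step_amplitude: float = 0.3  # g
    noise_sd: float = 0.02  # g
    gravity_axis: str = "Z"

    def __post_init__(self) -> None:
        if not 0.5 <= self.cadence <= 3.0:
            raise ConfigurationError(f"cadence must be in [0.5, 3.0], got {self.cadence}")
        if self.step_amplitude < 0:
            raise ConfigurationError("step_amplitude must be >= 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.gravity_axis not in ("X", "Y", "Z"):
            raise ConfigurationError("gravity_axis must be one of X, Y, Z")


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level generative configuration.

    ``improvement_per_session`` and ``nonresponder_gain`` are (mean, sd) of
    the per-session latent-fitness gain of responders and non-responders.
    The measured walking distance is

        6MWD = intercept + coef_chronotropic * CR
             + coef_effort * effort_scale + patient effect + noise,

    with CR in bpm and effort_scale the standardized latent effort.
    """

    n_patients: int = 89
    n_sessions: int = 5
    outcome_intercept: float = 300.0  # m
    coef_chronotropic: float = 2.0  # m per bpm
    coef_effort: float = 20.0  # m per standardized effort unit
    outcome_noise_sd: float = 20.0  # m
    patient_effect_sd: float = 40.0  # m
    improvement_per_session: tuple[float, float] = (0.19, 0.05)
    nonresponder_gain: tuple[float, float] = (0.01, 0.02)
    responder_fraction: float = 0.7
    channel_noise_sd: float = 0.08  # session-level fitness jitter per channel
    hrv_sd: float = 15.0  # ms
    ectopic_rate: float = 0.01
    dropout_rate: float = 0.002
    accel_noise_sd: float = 0.02  # g
    sampling_rate: float = 32.0  # Hz
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ConfigurationError("n_patients must be >= 2")
        if self.n_sessions < 1:
            raise ConfigurationError("n_sessions must be >= 1")
        if self.outcome_noise_sd < 0:
            raise ConfigurationError("outcome_noise_sd must be >= 0")
        if not 0 <= self.responder_fraction <= 1:
            raise ConfigurationError("responder_fraction must be in [0, 1]")


def simulate_hr_profile(
    params: HRDynamicsParams, phases: PhaseTimes | None = None
) -> Callable[[np.ndarray], np.ndarray]:
    """Continuous instantaneous-HR function over the recording.

    Rest: constant ``hr_rest``.  Walk: exponential approach to
    ``hr_plateau`` with time constant ``rise_tau``.  Recovery: exponential
    decay from the HR reached at walk end back to ``hr_rest`` with time
    constant ``recovery_tau``.  Continuous at both boundaries.
    """
    phases = phases or PhaseTimes()
    hr0, hr1 = params.hr_rest, params.hr_plateau
    t_walk, t_rec = phases.walk_start, phases.walk_end
    rng_range = hr1 - hr0
    hr_walk_end = hr1 - rng_range * math.exp(-(t_rec - t_walk) / params.rise_tau)

    def hr(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.full_like(t, hr0)
        walk = (t >= t_walk) & (t < t_rec)
        out = np.where(
            walk, hr1 - rng_range * np.exp(-(t - t_walk) / params.rise_tau), out
        )
        rec = t >= t_rec
        out = np.where(
            rec, hr0 + (hr_walk_end - hr0) * np.exp(-(t - t_rec) / params.recovery_tau), out
        )
        return out if out.ndim else float(out)

    return hr


def simulate_r_peaks(
    hr_profile: Callable[[float], float],
    params: HRDynamicsParams,
    seed: int,
    phases: PhaseTimes | None = None,
) -> np.ndarray:
    """Ordered R-peak timestamps driven by an instantaneous-HR function.

    Successive intervals follow 60/HR evaluated at the interval midpoint
    (one fixed-point refinement), with Gaussian RR jitter, occasional ectopic
    beats (early beat at 0.6x the interval, compensatory pause restoring the
    underlying phase) and occasional missed beats.  Timestamps are strictly
    increasing and reproducible for a fixed seed.
    """
    phases = phases or PhaseTimes()
    t_end = phases.record_end
    rng = np.random.default_rng(seed)
    rr_rest = 60.0 / params.hr_rest
    sd_s = params.hrv_sd / 1000.0

    beats: list[float] = [phases.rest_start]
    t = phases.rest_start
    while True:
        rr0 = 60.0 / float(hr_profile(t))
        rr = 60.0 / float(hr_profile(min(t + rr0 / 2.0, t_end)))
        jitter = rng.normal(0.0, sd_s * (rr / rr_rest))
        ectopic = rng.random() < params.ectopic_rate
        dropout = rng.random() < params.dropout_rate
        rr = max(rr + jitter, 0.25)
        if ectopic:
            early = t + 0.6 * rr
            nxt = t + 2.0 * rr
            if early < t_end:
                beats.append(early)
            if nxt >= t_end:
                break
            beats.append(nxt)
            t = nxt
        else:
            nxt = t + rr
            if nxt >= t_end:
                break
            t = nxt
            if not dropout:
                beats.append(nxt)
    return np.asarray(beats)


_AXES = ("X", "Y", "Z")
# Relative sinusoid weights of the gait model: lateral/frontal axes carry the
# step frequency; the gravity axis carries step frequency plus its double
# (impact harmonic).  Scaled by GaitParams.step_amplitude.
_LATERAL_WEIGHTS = (0.5, 0.35)
_GRAVITY_WEIGHTS = (0.4, 0.6)  # (cadence, 2 * cadence)


def simulate_accelerometer(
    gait: GaitParams,
    phases: PhaseTimes | None = None,
    sampling_rate: float = 32.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Triaxial acceleration in g at ``sampling_rate`` over the recording.

    The gravity axis carries a constant 1 g offset throughout; during the
    walk phase sinusoids at the step frequency (and its double on the gravity
    axis) with random phases model gait; white noise is added everywhere.
    """
    if sampling_rate <= 0:
        raise ConfigurationError("sampling_rate must be > 0")
    phases = phases or PhaseTimes()
    rng = np.random.default_rng(seed)
    n = int(round(sampling_rate * phases.total_duration))
    t = phases.rest_start + np.arange(n) / sampling_rate
    walk = (t >= phases.walk_start) & (t < phases.walk_end)

    sig = rng.normal(0.0, gait.noise_sd, size=(n, 3))
    phase_offsets = rng.uniform(0.0, 2.0 * np.pi, size=4)
    w = 2.0 * np.pi * gait.cadence * t
    g_idx = _AXES.index(gait.gravity_axis)
    lat = [i for i in range(3) if i != g_idx]
    for k, i in enumerate(lat):
        sig[walk, i] += (
            gait.step_amplitude
            * _LATERAL_WEIGHTS[k]
            * np.sin(w[walk] + phase_offsets[k])
        )
    sig[walk, g_idx] += gait.step_amplitude * (
        _GRAVITY_WEIGHTS[0] * np.sin(w[walk] + phase_offsets[2])
        + _GRAVITY_WEIGHTS[1] * np.sin(2.0 * w[walk] + phase_offsets[3])
    )
    sig[:, g_idx] += 1.0

    return pd.DataFrame({"t": t, "x": sig[:, 0], "y": sig[:, 1], "z": sig[:, 2]})


def simulate_session(
    patient_id: str,
    session_index: int,
    hr_params: HRDynamicsParams,
    gait: GaitParams,
    anthropometrics: Anthropometrics,
    six_mwd: float | None,
    seed: int,
    phases: PhaseTimes | None = None,
    sampling_rate: float = 32.0,
) -> SessionRecording:
    """Assemble one full synthetic session recording."""
    phases = phases or PhaseTimes()
    rng = np.random.default_rng(seed)
    peak_seed = int(rng.integers(0, MAX_SEED))
    accel_seed = int(rng.integers(0, MAX_SEED))
    profile = simulate_hr_profile(hr_params, phases)
    r_peaks = simulate_r_peaks(profile, hr_params, peak_seed, phases)
    accel = simulate_accelerometer(gait, phases, sampling_rate, accel_seed)
    return SessionRecording(
        patient_id=patient_id,
        session_index=session_index,
        phases=phases,
        r_peaks=r_peaks,
        accel=accel,
        anthropometrics=anthropometrics,
        six_mwd_measured=six_mwd,
    )


TRUTH_COLUMNS = [
    "patient_id",
    "session_index",
    "responder",
    "fitness",
    "hr_rest_true",
    "hr_plateau_true",
    "chronotropic_true",
    "effort_scale_true",
    "six_mwd_true",
    "cadence_true",
    "step_amplitude_true",
    "recovery_tau_true",
    "age",
    "height_m",
    "weight_kg",
    "sex",
]


def simulate_cohort_truth(config: CohortConfig) -> pd.DataFrame:
    """Latent ground truth of a cohort, without signal synthesis.

    One row per (patient, session).  This is the cheap entry point for
    model-level experiments where the raw sensor streams are not needed;
    :func:`simulate_cohort` builds the matching recordings on top of it.
    """
    rng = np.random.default_rng(config.rng_seed)
    n_p, n_s = config.n_patients, config.n_sessions

    f_base = np.clip(rng.normal(0.5, 0.15, n_p), 0.05, None)
    responder = rng.random(n_p) < config.responder_fraction
    gain = np.where(
        responder,
        rng.normal(*config.improvement_per_session, n_p),
        rng.normal(*config.nonresponder_gain, n_p),
    )
    patient_effect = rng.normal(0.0, config.patient_effect_sd, n_p)
    age = np.clip(rng.normal(61.0, 9.0, n_p), 30.0, 85.0)
    height = np.clip(rng.normal(1.72, 0.09, n_p), 1.45, 2.05)
    weight = np.clip(rng.normal(82.0, 13.0, n_p), 45.0, 140.0)
    sex = np.where(rng.random(n_p) < 0.8, "M", "F")

    rows = []
    for p in range(n_p):
        pid = f"P{p + 1:03d}"
        for s in range(1, n_s + 1):
            f = max(f_base[p] + gain[p] * (s - 1), 0.02)
            # the cardiac and gait channels track the same latent fitness but
            # with independent day-to-day variation, so chronotropic response
            # and effort are correlated without being collinear
            f_hr = max(f + rng.normal(0.0, config.channel_noise_sd), 0.02)
            f_gait = max(f + rng.normal(0.0, config.channel_noise_sd), 0.02)
            hr_rest = HR_REST_BASE + HR_REST_PER_FITNESS * f_hr
            hr_plateau = max(HR_PLATEAU_BASE + HR_PLATEAU_PER_FITNESS * f_hr, hr_rest)
            cr = hr_plateau - hr_rest
            eff = (f_gait - EFFORT_CENTER) * EFFORT_SCALE_PER_FITNESS
            six_mwd = (
                config.outcome_intercept
                + config.coef_chronotropic * cr
                + config.coef_effort * eff
                + patient_effect[p]
                + rng.normal(0.0, config.outcome_noise_sd)
            )
            rows.append(
                {
                    "patient_id": pid,
                    "session_index": s,
                    "responder": bool(responder[p]),
                    "fitness": f,
                    "hr_rest_true": hr_rest,
                    "hr_plateau_true": hr_plateau,
                    "chronotropic_true": cr,
                    "effort_scale_true": eff,
                    "six_mwd_true": max(six_mwd, 50.0),
                    "cadence_true": float(
                        np.clip(CADENCE_BASE + CADENCE_PER_FITNESS * f_gait, 0.5, 3.0)
                    ),
                    "step_amplitude_true": STEP_AMP_BASE + STEP_AMP_PER_FITNESS * f_gait,
                    "recovery_tau_true": max(
                        RECOVERY_TAU_BASE + RECOVERY_TAU_PER_FITNESS * f_hr, 20.0
                    ),
                    "age": age[p],
                    "height_m": height[p],
                    "weight_kg": weight[p],
                    "sex": str(sex[p]),
                }
            )
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def iter_cohort_sessions(
    config: CohortConfig, truth: pd.DataFrame | None = None
) -> Iterator[SessionRecording]:
    """Yield the session recordings of a cohort one at a time.

    Memory-friendly equivalent of :func:`simulate_cohort`; the signal-level
    seeds are derived deterministically from ``config.rng_seed`` and the
    (patient, session) position, so both entry points produce identical
    recordings.
    """
    if truth is None:
        truth = simulate_cohort_truth(config)
    seed_rng = np.random.default_rng((config.rng_seed, 0xC0FFEE))
    seeds = seed_rng.integers(0, MAX_SEED, size=len(truth))
    for i, row in enumerate(truth.itertuples(index=False)):
        hr_params = HRDynamicsParams(
            hr_rest=row.hr_rest_true,
            hr_plateau=row.hr_plateau_true,
            rise_tau=45.0,
            recovery_tau=row.recovery_tau_true,
            hrv_sd=config.hrv_sd,
            ectopic_rate=config.ectopic_rate,
            dropout_rate=config.dropout_rate,
        )
        gait = GaitParams(
            cadence=row.cadence_true,
            step_amplitude=row.step_amplitude_true,
            noise_sd=config.accel_noise_sd,
        )
        anthro = Anthropometrics(
            age=row.age, height_m=row.height_m, weight_kg=row.weight_kg, sex=row.sex
        )
        yield simulate_session(
            patient_id=row.patient_id,
            session_index=row.session_index,
            hr_params=hr_params,
            gait=gait,
            anthropometrics=anthro,
            six_mwd=row.six_mwd_true,
            seed=int(seeds[i]),
            sampling_rate=config.sampling_rate,
        )


def simulate_cohort(config: CohortConfig) -> tuple[list[SessionRecording], pd.DataFrame]:
    """Full cohort: session recordings plus the ground-truth table."""
    truth = simulate_cohort_truth(config)
    recordings = list(iter_cohort_sessions(config, truth))
    return recordings, truth


def truth_to_feature_table(truth: pd.DataFrame) -> pd.DataFrame:
    """Map a ground-truth table onto the cohort-feature-table column layout.

    Useful for model- and embedding-level experiments that do not need the
    signal-extraction stage: the true chronotropic response and effort scale
    stand in for their extracted estimates.
    """
    table = pd.DataFrame(
        {
            "patient_id": truth["patient_id"],
            "session_index": truth["session_index"],
            "hr_rest": truth["hr_rest_true"],
            "hr_max": truth["hr_plateau_true"],
            "chronotropic_response": truth["chronotropic_true"],
            "effort_win3": truth["effort_scale_true"],
            "effort_total": truth["effort_scale_true"],
            "age": truth["age"],
            "height_m": truth["height_m"],
            "weight_kg": truth["weight_kg"],
            "sex": truth["sex"],
            "six_mwd_measured": truth["six_mwd_true"],
        }
    )
    return table


def apply_saturating_outcome(
    table: pd.DataFrame,
    effort_col: str = "effort_total",
    floor: float = 250.0,
    span: float = 300.0,
    rate: float = 1.5,
    noise_sd: float = 15.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Replace the outcome with a logistic (saturating) function of effort.

    6MWD = floor + span / (1 + exp(-rate * z(effort))) + N(0, noise_sd).
    Produces a cohort whose effort->distance relation plateaus, which a
    linear predictor cannot capture.
    """
    rng = np.random.default_rng(seed)
    out = table.copy()
    e = out[effort_col].to_numpy(dtype=float)
    z = (e - e.mean()) / e.std()
    out["six_mwd_measured"] = (
        floor + span / (1.0 + np.exp(-rate * z)) + rng.normal(0.0, noise_sd, len(out))
    )
    return out


def expected_final_gain(config: CohortConfig) -> float:
    """Analytic expected cohort-mean 6MWD gain, last minus first session.

    E[gain] = (coef_cr * dCR/df + coef_eff * dEffort/df) * E[delta fitness],
    ignoring the (rare) clipping of latent fitness at its floor.
    """
    d_f = (
        config.responder_fraction * config.improvement_per_session[0]
        + (1.0 - config.responder_fraction) * config.nonresponder_gain[0]
    ) * (config.n_sessions - 1)
    per_f = (
        config.coef_chronotropic * CR_PER_FITNESS
        + config.coef_effort * EFFORT_SCALE_PER_FITNESS
    )
    return per_f * d_f


GROUND_TRUTH_EXPORT = [
    "patient_id",
    "session",
    "hr_rest_true",
    "hr_plateau_true",
    "chronotropic_true",
    "effort_scale_true",
    "six_mwd_true",
]


def write_ground_truth(truth: pd.DataFrame, path: str | Path) -> Path:
    """Export the ground-truth table (documented header) as CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = truth.rename(columns={"session_index": "session"})[GROUND_TRUTH_EXPORT]
    out.to_csv(path, index=False, float_format="%.17g")
    return path
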