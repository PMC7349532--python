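"""ECG- and accelerometer-derived 6MWT biomarkers.

The heart-rate pipeline operates on R-peak timestamps:

1. ``clean_rr`` removes beats whose RR interval deviates from a running
   median — a reproducible stand-in for interactive artifact correction;
2. ``compute_local_hr`` turns the cleaned beats into a *local HR* series:
   the instantaneous rate 60/RR, treated as a step function over the beat
   intervals, time-averaged inside contiguous 150 ms bins (the width of the
   widest plausible QRS complex), which damps the influence of any residual
   aberrant beat on downstream statistics;
3. ``compute_hr_features`` reduces the local HR series to scalar parameters:
   resting HR, maximal HR over the last 2 min of the walk, whole-recording
   average HR, the chronotropic response HR_max - HR_rest, the time from
   walk start to HR_max, and the recuperation time (how long after the walk
   HR needs to shed 66.6% of the exercise range).

The accelerometer pipeline quantifies *effort* as the sum of squared
triaxial samples over a window (three consecutive 2-min walk windows plus
the full walk).  By default each axis is de-meaned over the walk phase first
so the static gravity component does not dominate the sum; pass
``demean=False`` for the literal raw-sample definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ValidationError
from .session_io import PhaseTimes, SessionRecording, validate_cohort_table

__all__ = [
    "LocalHRSeries",
    "HRFeatures",
    "FeatureVector",
    "clean_rr",
    "compute_local_hr",
    "compute_hr_features",
    "compute_effort",
    "extract_features",
    "extract_cohort",
    "FEATURE_COLUMNS",
]

DEFAULT_BIN_WIDTH = 0.150  # s; QRS-width-matched local-HR bin
RECOVERY_FRACTION = 0.666  # fraction of the HR range shed at "recuperation"
RECUPERATION_DELAY = 5.0  # s after walk end before the recovery clock starts


@dataclass(frozen=True)
class LocalHRSeries:
    """Binned local heart rate: one value per contiguous ``bin_width`` bin."""

    bin_starts: np.ndarray  # s
    hr: np.ndarray  # bpm
    bin_width: float = DEFAULT_BIN_WIDTH

    def __post_init__(self) -> None:
        if len(self.bin_starts) != len(self.hr):
            raise ValidationError("bin_starts and hr must have equal length")
        if np.any(self.hr <= 0):
            raise ValidationError("local HR values must be > 0")

    def mask(self, t0: float, t1: float) -> np.ndarray:
        """Boolean mask of bins whose start lies in [t0, t1)."""
        return (self.bin_starts >= t0) & (self.bin_starts < t1)


def _running_median(rr: np.ndarray, half_window: int = 5) -> np.ndarray:
    """Median of an 11-interval window centred on each RR (edges truncated)."""
    n = len(rr)
    if n >= 2 * half_window + 1:
        med = np.empty(n)
        from numpy.lib.stride_tricks import sliding_window_view

        core = np.median(sliding_window_view(rr, 2 * half_window + 1), axis=1)
        med[half_window:-half_window] = core
        for i in range(half_window):
            med[i] = np.median(rr[: i + half_window + 1])
            med[n - 1 - i] = np.median(rr[n - 1 - i - half_window :])
    else:
        med = np.array([np.median(rr)] * n)
    return med


def clean_rr(
    r_peaks: np.ndarray, deviation_threshold: float = 0.3
) -> tuple[np.ndarray, int]:
    """Remove artifactual beats from an R-peak sequence.

    An interval is flagged when it deviates from the running 11-interval
    median by more than ``deviation_threshold`` (relative).  Beats interior
    to a run of two or more consecutive flagged intervals are removed: an
    ectopic beat produces the classic short/long pair and is excised exactly,
    while an isolated long interval (a missed beat) has no interior beat and
    is left alone.  Idempotent on clean input.

    Returns (cleaned timestamps, number of beats removed).
    """
    r_peaks = np.asarray(r_peaks, dtype=float)
    if len(r_peaks) < 3:
        raise InsufficientDataError("need at least 3 beats to clean RR intervals")
    if not np.all(np.diff(r_peaks) > 0):
        raise ValidationError("r_peaks must be strictly increasing")

    rr = np.diff(r_peaks)
    med = _running_median(rr)
    flagged = np.abs(rr - med) > deviation_threshold * med

    remove: set[int] = set()
    i = 0
    n = len(rr)
    while i < n:
        if flagged[i]:
            j = i
            while j + 1 < n and flagged[j + 1]:
                j += 1
            if j > i:  # run of >= 2 flagged intervals: drop interior beats
                remove.update(range(i + 1, j + 1))
            i = j + 1
        else:
            i += 1

    keep = np.setdiff1d(np.arange(len(r_peaks)), np.fromiter(remove, int, len(remove)))
    return r_peaks[keep], len(remove)


def compute_local_hr(
    r_peaks: np.ndarray,
    t_range: tuple[float, float] = (0.0, 960.0),
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> LocalHRSeries:
    """Bin the instantaneous-HR step function into contiguous bins.

    The instantaneous rate is HR(t) = 60/RR_i for t in [R_i, R_{i+1});
    each bin value is the exact time-average of that step function over the
    bin, computed from the cumulative integral evaluated at the bin edges.
    Before the first (after the last) beat the nearest interval's rate is
    extended, so every bin in ``t_range`` is defined.
    """
    p = np.asarray(r_peaks, dtype=float)
    inside = p[(p >= t_range[0] - 60.0) & (p <= t_range[1] + 60.0)]
    if len(inside) < 2:
        raise InsufficientDataError("need at least 2 beats inside the time range")
    p = inside
    rr = np.diff(p)
    rates = 60.0 / rr  # bpm per interval

    # Cumulative integral of the step function at knots, with edge extension.
    t0, t1 = t_range
    lo = min(t0, p[0]) - bin_width
    hi = max(t1, p[-1]) + bin_width
    knots = np.concatenate(([lo], p, [hi]))
    seg = np.concatenate(
        ([rates[0] * (p[0] - lo)], rates * rr, [rates[-1] * (hi - p[-1])])
    )
    cum = np.concatenate(([0.0], np.cumsum(seg)))

    n_bins = int(round((t1 - t0) / bin_width))
    edges = t0 + bin_width * np.arange(n_bins + 1)
    f_edges = np.interp(edges, knots, cum)
    hr = np.diff(f_edges) / bin_width
    return LocalHRSeries(bin_starts=edges[:-1], hr=hr, bin_width=bin_width)


@dataclass(frozen=True)
class HRFeatures:
    hr_rest: float
    hr_max: float
    hr_avg: float
    chronotropic_response: float
    time_to_hr_max: float
    time_to_recuperation: float  # NaN when not reached before record end
    recuperation_reached: bool


def compute_hr_features(
    local_hr: LocalHRSeries,
    phases: PhaseTimes | None = None,
    recovery_fraction: float = RECOVERY_FRACTION,
    recuperation_delay: float = RECUPERATION_DELAY,
) -> HRFeatures:
    """Scalar HR parameters from the binned local HR series.

    * hr_rest: mean over the rest phase;
    * hr_max: maximum over the final 2 min of the walk phase (earliest
      maximizing bin breaks ties);
    * hr_avg: mean over the whole recording;
    * time_to_hr_max: maximizing bin start minus walk start;
    * time_to_recuperation: starting ``recuperation_delay`` s after walk end,
      time until the first bin at or below
      hr_max - recovery_fraction * (hr_max - hr_rest).  A negative
      chronotropic response is permitted (the threshold then sits above
      hr_max and is met immediately); a recovery that never reaches the
      threshold yields NaN with ``recuperation_reached=False``.
    """
    phases = phases or PhaseTimes()
    rest = local_hr.mask(phases.rest_start, phases.walk_start)
    last2 = local_hr.mask(phases.walk_end - 120.0, phases.walk_end)
    full = local_hr.mask(phases.rest_start, phases.record_end)
    if not rest.any() or not last2.any():
        raise InsufficientDataError("local HR series does not cover all phases")

    hr_rest = float(local_hr.hr[rest].mean())
    idx_last2 = np.flatnonzero(last2)
    k = idx_last2[int(np.argmax(local_hr.hr[idx_last2]))]
    hr_max = float(local_hr.hr[k])
    hr_avg = float(local_hr.hr[full].mean())
    time_to_hr_max = float(local_hr.bin_starts[k] - phases.walk_start)

    threshold = hr_max - recovery_fraction * (hr_max - hr_rest)
    rec_mask = local_hr.bin_starts >= phases.walk_end + recuperation_delay
    rec_idx = np.flatnonzero(rec_mask)
    reached = False
    t_rec = float("nan")
    if rec_idx.size:
        below = local_hr.hr[rec_idx] <= threshold
        if below.any():
            first = rec_idx[int(np.argmax(below))]
            # elapsed from the first evaluated bin to the first qualifying bin
            t_rec = float(local_hr.bin_starts[first] - local_hr.bin_starts[rec_idx[0]])
            reached = True

    return HRFeatures(
        hr_rest=hr_rest,
        hr_max=hr_max,
        hr_avg=hr_avg,
        chronotropic_response=hr_max - hr_rest,
        time_to_hr_max=time_to_hr_max,
        time_to_recuperation=t_rec,
        recuperation_reached=reached,
    )


def compute_effort(
    accel: pd.DataFrame,
    window: tuple[float, float],
    demean: bool = True,
    axis_means: tuple[float, float, float] | None = None,
) -> float:
    """Summed squared triaxial acceleration over a half-open time window.

    effort = sum_k (x_k^2 + y_k^2 + z_k^2) over samples with t in
    [window[0], window[1]).  With ``demean`` the per-axis means are removed
    first; pass ``axis_means`` (e.g. computed once over the walk phase) to
    make the statistic exactly additive over disjoint sub-windows.
    """
    t = accel["t"].to_numpy()
    m = (t >= window[0]) & (t < window[1])
    if not m.any():
        raise InsufficientDataError(f"no accelerometer samples in window {window}")
    xyz = accel.loc[m, ["x", "y", "z"]].to_numpy(dtype=float)
    if demean:
        means = np.asarray(axis_means) if axis_means is not None else xyz.mean(axis=0)
        xyz = xyz - means
    return float(np.einsum("ij,ij->", xyz, xyz))


FEATURE_COLUMNS = [
    "patient_id",
    "session_index",
    "hr_rest",
    "hr_max",
    "hr_avg",
    "chronotropic_response",
    "time_to_hr_max",
    "time_to_recuperation",
    "recuperation_reached",
    "effort_win1",
    "effort_win2",
    "effort_win3",
    "effort_total",
    "n_artifacts_removed",
    "age",
    "height_m",
    "weight_kg",
    "sex",
    "six_mwd_measured",
]


@dataclass(frozen=True)
class FeatureVector:
    """Per-session biomarker set plus anthropometrics and outcome."""

    patient_id: str
    session_index: int
    hr_rest: float
    hr_max: float
    hr_avg: float
    chronotropic_response: float
    time_to_hr_max: float
    time_to_recuperation: float
    recuperation_reached: bool
    effort_win1: float
    effort_win2: float
    effort_win3: float
    effort_total: float
    n_artifacts_removed: int
    age: float
    height_m: float
    weight_kg: float
    sex: str
    six_mwd_measured: float | None

    def to_row(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


def extract_features(
    recording: SessionRecording,
    bin_width: float = DEFAULT_BIN_WIDTH,
    demean: bool = True,
    deviation_threshold: float = 0.3,
) -> FeatureVector:
    """Run the full per-session extraction pipeline.

    clean_rr -> compute_local_hr -> compute_hr_features, and compute_effort
    on the three 2-min walk windows and the full walk (sharing one set of
    walk-phase axis means so the windowed efforts sum to the total exactly).
    Deterministic: identical recordings give identical feature vectors.
    """
    ph = recording.phases
    try:
        cleaned, n_removed = clean_rr(recording.r_peaks, deviation_threshold)
        local_hr = compute_local_hr(
            cleaned, (ph.rest_start, ph.record_end), bin_width=bin_width
        )
        hrf = compute_hr_features(local_hr, ph)

        t = recording.accel["t"].to_numpy()
        walk = (t >= ph.walk_start) & (t < ph.walk_end)
        if demean and walk.any():
            means = tuple(
                recording.accel.loc[walk, ["x", "y", "z"]].mean(axis=0).to_numpy()
            )
        else:
            means = None
        w0 = ph.walk_start
        thirds = (ph.walk_end - ph.walk_start) / 3.0
        efforts = [
            compute_effort(
                recording.accel,
                (w0 + i * thirds, w0 + (i + 1) * thirds),
                demean=demean,
                axis_means=means,
            )
            for i in range(3)
        ]
        effort_total = compute_effort(
            recording.accel, (ph.walk_start, ph.walk_end), demean=demean, axis_means=means
        )
    except (InsufficientDataError, ValidationError) as exc:
        raise type(exc)(
            f"patient {recording.patient_id} session {recording.session_index}: {exc}"
        ) from exc

    return FeatureVector(
        patient_id=recording.patient_id,
        session_index=recording.session_index,
        hr_rest=hrf.hr_rest,
        hr_max=hrf.hr_max,
        hr_avg=hrf.hr_avg,
        chronotropic_response=hrf.chronotropic_response,
        time_to_hr_max=hrf.time_to_hr_max,
        time_to_recuperation=hrf.time_to_recuperation,
        recuperation_reached=hrf.recuperation_reached,
        effort_win1=efforts[0],
        effort_win2=efforts[1],
        effort_win3=efforts[2],
        effort_total=effort_total,
        n_artifacts_removed=n_removed,
        age=recording.anthropometrics.age,
        height_m=recording.anthropometrics.height_m,
        weight_kg=recording.anthropometrics.weight_kg,
        sex=recording.anthropometrics.sex,
        six_mwd_measured=recording.six_mwd_measured,
    )


def extract_cohort(
    recordings: Iterable[SessionRecording], **kwargs
) -> pd.DataFrame:
    """Extract features for many sessions into one cohort table."""
    rows = [extract_features(rec, **kwargs).to_row() for rec in recordings]
    table = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    return validate_cohort_table(table)
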