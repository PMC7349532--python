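"""Predicting 6-min walking distance from session biomarkers.

Two model families:

* a stepwise linear regression (forward entry on the partial t-test at
  ``p_enter``, backward removal at ``p_remove``) over the anthropometric,
  ECG-derived and accelerometer-derived candidate pool, reported with R²
  and RMSE of the final fit;
* epsilon-insensitive SVM regression compared across five kernels (RBF,
  linear, polynomial of degree 2/3/4) and six feature combinations, with
  repeated random 80/20 *by-subject* splits (all sessions of a patient stay
  on one side) and test-set mean absolute error pooled across repeats.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.metrics import pairwise_distances
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .errors import ConfigurationError, InsufficientDataError, ValidationError

__all__ = [
    "StepwiseReport",
    "KernelComparisonReport",
    "SVMPredictor",
    "DEFAULT_CANDIDATES",
    "FEATURE_SET_PRESETS",
    "KERNELS",
    "prepare_model_table",
    "fit_stepwise_linear",
    "split_by_subject",
    "fit_svm",
    "run_kernel_comparison",
]

OUTCOME = "six_mwd_measured"

# Candidate pool: anthropometrics, ECG-derived, accelerometer-derived.
DEFAULT_CANDIDATES = [
    "age",
    "height_m",
    "weight_kg",
    "sex_male",
    "hr_max",
    "hr_rest",
    "hr_avg",
    "chronotropic_response",
    "time_to_recuperation",
    "time_to_hr_max",
    "effort_total",
]

KERNELS = ("rbf", "linear", "poly2", "poly3", "poly4")

# The six feature combinations of the kernel-comparison grid.
FEATURE_SET_PRESETS: dict[str, list[str]] = {
    "effort+cr": ["effort_total", "chronotropic_response"],
    "effort+height": ["effort_total", "height_m"],
    "effort": ["effort_total"],
    "effort+cr+height": ["effort_total", "chronotropic_response", "height_m"],
    "cr": ["chronotropic_response"],
    "cr+height": ["chronotropic_response", "height_m"],
}


def prepare_model_table(table: pd.DataFrame, outcome: str = OUTCOME) -> pd.DataFrame:
    """Encode sex as a binary indicator and drop rows without an outcome."""
    out = table.copy()
    if "sex" in out.columns and "sex_male" not in out.columns:
        out["sex_male"] = (out["sex"] == "M").astype(float)
    if outcome in out.columns:
        out = out[out[outcome].notna()].reset_index(drop=True)
    return out


@dataclass
class StepwiseReport:
    selected_features: list[str]
    coefficients: dict[str, float]
    intercept: float
    r_squared: float
    rmse: float
    history: list[tuple[str, str, float]]  # (action, feature, p-value)
    n_rows: int

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        y = np.full(len(table), self.intercept)
        for name, coef in self.coefficients.items():
            y = y + coef * table[name].to_numpy(dtype=float)
        return y


def _is_collinear(x_new: np.ndarray, design: np.ndarray) -> bool:
    """True when x_new is (numerically) in the span of the current design."""
    coef, *_ = np.linalg.lstsq(design, x_new, rcond=None)
    resid = x_new - design @ coef
    scale = np.var(x_new) if np.var(x_new) > 0 else 1.0
    return float(np.var(resid)) / scale < 1e-10


def fit_stepwise_linear(
    cohort: pd.DataFrame,
    candidates: list[str] | None = None,
    outcome: str = OUTCOME,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
) -> StepwiseReport:
    """Forward-entry / backward-removal stepwise OLS.

    At each forward step the candidate with the smallest partial t-test
    p-value enters if that p-value is below ``p_enter``; after each entry,
    selected features whose p-value exceeds ``p_remove`` are removed (worst
    first).  Candidates numerically collinear with the current design are
    skipped with a warning, so of a duplicated predictor pair exactly one
    copy can enter.  Terminates when a pass changes nothing or a selection
    state repeats.
    """
    table = prepare_model_table(cohort, outcome)
    cand = list(candidates) if candidates is not None else [
        c for c in DEFAULT_CANDIDATES if c in table.columns
    ]
    missing = [c for c in cand if c not in table.columns]
    if missing:
        raise ValidationError(f"candidate columns not in table: {missing}")
    rows = table[[outcome, *cand]].dropna().reset_index(drop=True)
    if len(rows) < 10:
        raise InsufficientDataError(
            f"need >= 10 complete rows for stepwise fitting, got {len(rows)}"
        )
    y = rows[outcome].to_numpy(dtype=float)
    X = {c: rows[c].to_numpy(dtype=float) for c in cand}

    selected: list[str] = []
    history: list[tuple[str, str, float]] = []
    seen_states: set[frozenset] = set()

    def design(names: list[str]) -> np.ndarray:
        cols = [np.ones(len(y))] + [X[n] for n in names]
        return np.column_stack(cols)

    while True:
        changed = False
        # forward entry
        best_p, best_c = None, None
        cur = design(selected)
        for c in cand:
            if c in selected:
                continue
            if _is_collinear(X[c], cur):
                warnings.warn(
                    f"candidate {c!r} is collinear with the current design; skipped"
                )
                continue
            fit = sm.OLS(y, np.column_stack([cur, X[c]])).fit()
            p = float(fit.pvalues[-1])
            if best_p is None or p < best_p:
                best_p, best_c = p, c
        if best_c is not None and best_p < p_enter:
            selected.append(best_c)
            history.append(("enter", best_c, best_p))
            changed = True
        # backward removal
        while selected:
            fit = sm.OLS(y, design(selected)).fit()
            pvals = fit.pvalues[1:]
            worst = int(np.argmax(pvals))
            if float(pvals[worst]) > p_remove:
                removed = selected.pop(worst)
                history.append(("remove", removed, float(pvals[worst])))
                changed = True
            else:
                break
        state = frozenset(selected)
        if not changed or state in seen_states:
            break
        seen_states.add(state)

    if selected:
        fit = sm.OLS(y, design(selected)).fit()
        coefs = dict(zip(selected, map(float, fit.params[1:])))
        intercept = float(fit.params[0])
        r2 = float(fit.rsquared)
        resid = fit.resid
    else:
        coefs, intercept = {}, float(y.mean())
        r2, resid = 0.0, y - y.mean()
    rmse = float(np.sqrt(np.mean(resid**2)))
    return StepwiseReport(
        selected_features=selected,
        coefficients=coefs,
        intercept=intercept,
        r_squared=r2,
        rmse=rmse,
        history=history,
        n_rows=len(rows),
    )


def split_by_subject(
    cohort: pd.DataFrame, train_fraction: float = 0.8, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Partition patients (not sessions) into train and test sets.

    The train count rounds the fraction to the nearest patient with ties
    going to the test side; e.g. 89 patients at 0.8 give 71 train / 18 test.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ConfigurationError("train_fraction must be in (0, 1)")
    patients = sorted(pd.unique(cohort["patient_id"]))
    n = len(patients)
    if n < 5:
        raise InsufficientDataError(f"need >= 5 patients to split, got {n}")
    n_train = int(math.ceil(train_fraction * n - 0.5))  # half rounds down
    n_train = min(max(n_train, 1), n - 1)
    order = np.random.default_rng(seed).permutation(n)
    train = sorted(patients[i] for i in order[:n_train])
    test = sorted(patients[i] for i in order[n_train:])
    return train, test


@dataclass
class SVMPredictor:
    """A fitted SVM regressor bound to its train-set standardization."""

    feature_names: list[str]
    scaler: StandardScaler
    model: SVR
    kernel_type: str
    epsilon: float
    gamma: float | None = None

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        X = table[self.feature_names].to_numpy(dtype=float)
        return self.model.predict(self.scaler.transform(X))


def _median_pairwise_gamma(X: np.ndarray, rng: np.random.Generator) -> float:
    """RBF gamma from the median pairwise distance of a train subsample."""
    sub = X if len(X) <= 256 else X[rng.choice(len(X), 256, replace=False)]
    d = pairwise_distances(sub)
    med = float(np.median(d[np.triu_indices_from(d, k=1)]))
    if med <= 0:
        med = 1.0
    return 1.0 / (2.0 * med**2)


def fit_svm(
    train: pd.DataFrame,
    feature_set: list[str],
    kernel_type: str = "rbf",
    outcome: str = OUTCOME,
    epsilon: float | None = None,
    c: float | None = None,
    gamma_grid: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0, 4.0),
    seed: int = 0,
) -> SVMPredictor:
    """Fit an epsilon-insensitive SVM regressor on train rows.

    Features are standardized with train-set statistics only; constant
    features are dropped with a warning.  Defaults: epsilon = 0.1 x the
    train outcome SD; C = max|mean(y) +/- 3 sd(y)|.  For the RBF kernel the
    scale starts at the median-pairwise-distance heuristic and is refined by
    a small grid search on a train-internal by-subject split.
    """
    if kernel_type not in KERNELS:
        raise ConfigurationError(f"kernel_type must be one of {KERNELS}")
    rows = train[train[outcome].notna()]
    feats = list(feature_set)
    for f in feature_set:
        if rows[f].std() == 0 or rows[f].isna().any():
            warnings.warn(f"feature {f!r} is degenerate on the train set; dropped")
            feats.remove(f)
    if not feats:
        raise InsufficientDataError("no usable features remain after dropping")

    y = rows[outcome].to_numpy(dtype=float)
    X = rows[feats].to_numpy(dtype=float)
    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    eps = float(epsilon) if epsilon is not None else 0.1 * float(y.std())
    C = float(c) if c is not None else max(abs(y.mean() + 3 * y.std()), abs(y.mean() - 3 * y.std()))

    def make(kind: str, gamma: float | None) -> SVR:
        if kind == "rbf":
            return SVR(kernel="rbf", gamma=gamma, C=C, epsilon=eps)
        if kind == "linear":
            return SVR(kernel="linear", C=C, epsilon=eps)
        degree = int(kind[-1])
        return SVR(kernel="poly", degree=degree, gamma=1.0, coef0=1.0, C=C, epsilon=eps)

    gamma = None
    if kernel_type == "rbf":
        rng = np.random.default_rng(seed)
        gamma0 = _median_pairwise_gamma(Xs, rng)
        candidates = [gamma0 * g for g in gamma_grid]
        if "patient_id" in rows.columns and rows["patient_id"].nunique() >= 5:
            tr_ids, va_ids = split_by_subject(rows, 0.75, seed=seed)
            tr_m = rows["patient_id"].isin(tr_ids).to_numpy()
        else:
            idx = rng.permutation(len(rows))
            tr_m = np.zeros(len(rows), bool)
            tr_m[idx[: max(int(0.75 * len(rows)), 1)]] = True
        best, gamma = np.inf, candidates[0]
        if tr_m.all() or not tr_m.any():
            gamma = gamma0
        else:
            for g in candidates:
                m = make("rbf", g).fit(Xs[tr_m], y[tr_m])
                mae = float(np.mean(np.abs(m.predict(Xs[~tr_m]) - y[~tr_m])))
                if mae < best:
                    best, gamma = mae, g

    model = make(kernel_type, gamma).fit(Xs, y)
    return SVMPredictor(
        feature_names=feats,
        scaler=scaler,
        model=model,
        kernel_type=kernel_type,
        epsilon=eps,
        gamma=gamma,
    )


@dataclass
class KernelComparisonReport:
    """MAE grid over (feature_set, kernel) cells.

    ``cells`` holds the pooled mean +/- SD of test-set absolute errors;
    ``per_repeat`` the per-repeat mean MAEs; ``test_patients`` the test-side
    patient ids of every repeat.
    """

    cells: pd.DataFrame
    per_repeat: pd.DataFrame
    test_patients: dict[int, list[str]]
    n_repeats: int

    def cell(self, feature_set: str, kernel: str) -> pd.Series:
        m = (self.cells["feature_set"] == feature_set) & (self.cells["kernel"] == kernel)
        return self.cells[m].iloc[0]


def run_kernel_comparison(
    cohort: pd.DataFrame,
    feature_sets: dict[str, list[str]] | None = None,
    kernels: tuple[str, ...] = KERNELS,
    n_repeats: int = 20,
    train_fraction: float = 0.8,
    outcome: str = OUTCOME,
    seed: int = 0,
) -> KernelComparisonReport:
    """Repeated by-subject 80/20 validation of every (feature set, kernel).

    Each repeat draws a fresh patient-level split; each cell's model is fit
    on the train sessions and scored on the held-out sessions.  Absolute
    errors are pooled across repeats for the cell mean +/- SD.  A failed fit
    records a flagged cell with NaN statistics, never a silent omission.
    """
    feature_sets = feature_sets or FEATURE_SET_PRESETS
    table = prepare_model_table(cohort, outcome)
    rng = np.random.default_rng(seed)
    split_seeds = rng.integers(0, 2**31 - 1, size=n_repeats)

    abs_errors: dict[tuple[str, str], list[np.ndarray]] = {
        (fs, k): [] for fs in feature_sets for k in kernels
    }
    failed: set[tuple[str, str]] = set()
    per_repeat_rows = []
    test_patients: dict[int, list[str]] = {}

    for rep in range(n_repeats):
        train_ids, test_ids = split_by_subject(table, train_fraction, int(split_seeds[rep]))
        assert not set(train_ids) & set(test_ids)
        test_patients[rep] = test_ids
        tr = table[table["patient_id"].isin(train_ids)]
        te = table[table["patient_id"].isin(test_ids)]
        for fs_name, feats in feature_sets.items():
            for k in kernels:
                try:
                    pred = fit_svm(
                        tr, feats, k, outcome=outcome, seed=int(split_seeds[rep])
                    )
                    err = np.abs(pred.predict(te) - te[outcome].to_numpy(dtype=float))
                except Exception as exc:  # flagged cell, never silent
                    warnings.warn(f"fit failed for ({fs_name}, {k}) repeat {rep}: {exc}")
                    failed.add((fs_name, k))
                    continue
                abs_errors[(fs_name, k)].append(err)
                per_repeat_rows.append(
                    {
                        "repeat": rep,
                        "feature_set": fs_name,
                        "kernel": k,
                        "mae": float(err.mean()),
                    }
                )

    cell_rows = []
    for (fs_name, k), chunks in abs_errors.items():
        if chunks:
            pooled = np.concatenate(chunks)
            cell_rows.append(
                {
                    "feature_set": fs_name,
                    "kernel": k,
                    "mae_mean": float(pooled.mean()),
                    "mae_sd": float(pooled.std(ddof=1)),
                    "n_errors": int(len(pooled)),
                    "failed": (fs_name, k) in failed,
                }
            )
        else:
            cell_rows.append(
                {
                    "feature_set": fs_name,
                    "kernel": k,
                    "mae_mean": float("nan"),
                    "mae_sd": float("nan"),
                    "n_errors": 0,
                    "failed": True,
                }
            )
    return KernelComparisonReport(
        cells=pd.DataFrame(cell_rows),
        per_repeat=pd.DataFrame(per_repeat_rows),
        test_patients=test_patients,
        n_repeats=n_repeats,
    )
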