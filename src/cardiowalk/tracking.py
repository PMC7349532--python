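"""Low-dimensional progression maps of serial 6MWT sessions.

Each session is reduced to a three-feature *composite* — chronotropic
response, walking effort, and session number — z-scored and embedded with
t-SNE into a 3-D map (the measured walking distance never enters the
embedding; it is only ever used to color points).  Per-patient trajectories
through the map, ordered by session, visualize rehabilitation progression;
the first-to-last change in 6MWD against the ~50 m clinically significant
threshold tags each patient as responder or limited-response.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE

from .errors import InsufficientDataError, ValidationError

__all__ = [
    "EmbeddingResult",
    "Trajectory",
    "build_composites",
    "embed_tsne",
    "color_code",
    "extract_trajectory",
    "RESPONDER_THRESHOLD_M",
]

logger = logging.getLogger(__name__)

COMPOSITE_FEATURES = ("chronotropic_response", "effort", "session_index")
DEFAULT_EFFORT_COLUMN = "effort_win3"  # effort over the last 2 min of the walk
RESPONDER_THRESHOLD_M = 50.0


def build_composites(
    cohort: pd.DataFrame, effort_col: str = DEFAULT_EFFORT_COLUMN
) -> tuple[np.ndarray, pd.DataFrame]:
    """Standardized (chronotropic response, effort, session number) matrix.

    Each column is z-scored over all rows; rows with missing values in any
    of the three inputs are excluded with a logged count.  The outcome
    (6MWD) is deliberately never part of the matrix.

    Returns (matrix, ids) where ids holds patient_id and session_index per
    retained row.
    """
    needed = ["chronotropic_response", effort_col, "session_index"]
    for col in needed + ["patient_id"]:
        if col not in cohort.columns:
            raise ValidationError(f"cohort table missing column {col!r}")
    sub = cohort[["patient_id", *needed]]
    complete = sub[needed].notna().all(axis=1)
    n_excluded = int((~complete).sum())
    if n_excluded:
        logger.info("build_composites: excluded %d incomplete rows", n_excluded)
    sub = sub[complete]
    X = sub[needed].to_numpy(dtype=float)
    sd = X.std(axis=0)
    for j, col in enumerate(needed):
        if sd[j] == 0:
            raise ValidationError(f"composite input column {col!r} has zero variance")
    Z = (X - X.mean(axis=0)) / sd
    ids = sub[["patient_id", "session_index"]].reset_index(drop=True)
    return Z, ids


@dataclass
class EmbeddingResult:
    """t-SNE coordinates with provenance (seed, perplexity, input hash)."""

    ids: pd.DataFrame  # patient_id, session_index
    coordinates: np.ndarray  # (n, out_dims), dimensionless
    seed: int
    perplexity: float
    input_matrix_hash: str

    def to_frame(self) -> pd.DataFrame:
        out = self.ids.copy()
        for d in range(self.coordinates.shape[1]):
            out[f"dim{d + 1}"] = self.coordinates[:, d]
        return out


def embed_tsne(
    matrix: np.ndarray,
    ids: pd.DataFrame,
    out_dims: int = 3,
    perplexity: float = 30.0,
    seed: int = 0,
    n_iter: int = 1000,
) -> EmbeddingResult:
    """Embed the composite matrix with t-SNE.

    Deterministic for a fixed seed; the perplexity is shrunk with a warning
    when the row count is below 3 x perplexity.  Axes of the result are
    dimensionless composite coordinates, not distances or times.
    """
    matrix = np.ascontiguousarray(matrix, dtype=float)
    n = len(matrix)
    if n < 10:
        raise InsufficientDataError(
            f"t-SNE needs at least 10 rows, got {n}; embed more sessions"
        )
    if len(ids) != n:
        raise ValidationError("ids and matrix row counts differ")
    if n < 3 * perplexity + 1:
        new_p = max((n - 1) / 3.0, 2.0)
        warnings.warn(
            f"perplexity {perplexity} too large for {n} rows; shrunk to {new_p:.1f}"
        )
        perplexity = new_p
    # method="exact" supports any output dimension (barnes_hut is 2/3-D
    # approximate and not available above 3)
    tsne = TSNE(
        n_components=out_dims,
        perplexity=perplexity,
        random_state=seed,
        method="exact",
        init="pca",
        max_iter=n_iter,
    )
    coords = tsne.fit_transform(matrix)
    digest = hashlib.sha256(matrix.tobytes()).hexdigest()
    logger.info(
        "embed_tsne: n=%d out_dims=%d perplexity=%.1f seed=%d n_iter=%d",
        n, out_dims, perplexity, seed, n_iter,
    )
    return EmbeddingResult(
        ids=ids.reset_index(drop=True),
        coordinates=np.asarray(coords, dtype=float),
        seed=seed,
        perplexity=perplexity,
        input_matrix_hash=digest,
    )


def color_code(
    embedding: EmbeddingResult,
    cohort: pd.DataFrame,
    feature_name: str,
    out_path: str | Path | None = None,
):
    """3-D scatter of the embedding colored by a cohort feature.

    Returns (figure, table); the table lists ids, coordinates and the color
    value per point.  Coloring never alters coordinates.  With ``out_path``
    the figure is also written to disk.
    """
    if feature_name not in cohort.columns:
        raise ValidationError(
            f"unknown feature {feature_name!r}; available: "
            f"{sorted(c for c in cohort.columns if c not in ('patient_id',))}"
        )
    cols = list(dict.fromkeys(["patient_id", "session_index", feature_name]))
    table = embedding.to_frame().merge(
        cohort[cols], on=["patient_id", "session_index"], how="left"
    )
    if table[feature_name].isna().any():
        raise ValidationError(
            f"feature {feature_name!r} missing for some embedded sessions"
        )

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig = plt.figure(figsize=(7, 6))
    ndim = embedding.coordinates.shape[1]
    vals = table[feature_name].to_numpy(dtype=float)
    if ndim >= 3:
        ax = fig.add_subplot(111, projection="3d")
        sc = ax.scatter(
            table["dim1"], table["dim2"], table["dim3"], c=vals, cmap="viridis", s=18
        )
        ax.set_zlabel("dim 3")
    else:
        ax = fig.add_subplot(111)
        sc = ax.scatter(table["dim1"], table["dim2"], c=vals, cmap="viridis", s=18)
    ax.set_xlabel("dim 1")
    ax.set_ylabel("dim 2")
    ax.set_title(f"Session composites colored by {feature_name}")
    fig.colorbar(sc, ax=ax, label=feature_name, shrink=0.7)
    if out_path is not None:
        fig.savefig(out_path, dpi=120, bbox_inches="tight")
    return fig, table


@dataclass
class Trajectory:
    """One patient's ordered path through the embedding."""

    patient_id: str
    points: pd.DataFrame  # session_index, coordinates, 6MWD, CR, effort
    delta_six_mwd: float
    delta_chronotropic: float
    delta_effort: float
    classification: str  # "responder" | "limited-response"


def extract_trajectory(
    embedding: EmbeddingResult,
    cohort: pd.DataFrame,
    patient_id: str,
    effort_col: str = DEFAULT_EFFORT_COLUMN,
    responder_threshold: float = RESPONDER_THRESHOLD_M,
) -> Trajectory:
    """Ordered session points and first-to-last deltas for one patient.

    Deltas are exact differences of the cohort table (last minus first
    session) and do not depend on the embedding.  A 6MWD gain at or above
    the ~50 m clinically significant threshold tags the patient a responder.
    """
    emb = embedding.to_frame()
    pts = emb[emb["patient_id"] == patient_id]
    if pts.empty:
        known = sorted(emb["patient_id"].unique())
        raise ValidationError(
            f"unknown patient {patient_id!r} (cohort has {len(known)} patients)"
        )
    if len(pts) < 2:
        raise InsufficientDataError(
            f"patient {patient_id!r} has {len(pts)} embedded session(s); need >= 2"
        )
    feats = cohort[cohort["patient_id"] == patient_id][
        ["session_index", "six_mwd_measured", "chronotropic_response", effort_col]
    ]
    points = (
        pts.merge(feats, on="session_index", how="left")
        .sort_values("session_index")
        .reset_index(drop=True)
    )
    first, last = points.iloc[0], points.iloc[-1]
    d_mwd = float(last["six_mwd_measured"] - first["six_mwd_measured"])
    d_cr = float(last["chronotropic_response"] - first["chronotropic_response"])
    d_eff = float(last[effort_col] - first[effort_col])
    tag = "responder" if d_mwd >= responder_threshold else "limited-response"
    return Trajectory(
        patient_id=patient_id,
        points=points,
        delta_six_mwd=d_mwd,
        delta_chronotropic=d_cr,
        delta_effort=d_eff,
        classification=tag,
    )
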