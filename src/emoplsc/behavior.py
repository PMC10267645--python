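"""Behavior matrix assembly, within-subject normalization, emotion centroids.

The behavior block is the M x 34 matrix of 32 GRID item ratings plus the two
event-aggregated physiology measures, joined on (subject, event).  Columns
are normalized to within-subject z-scores before any multivariate analysis,
which removes per-subject location and scale exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .containers import BehaviorMatrix, BrainMatrix
from .features import (
    EMOTION_CATEGORIES,
    FEATURE_IDS,
    FEATURES,
    GRID_FEATURE_IDS,
    PHYSIO_FEATURE_IDS,
)

__all__ = [
    "assemble_behavior_matrix",
    "zscore_within_subject",
    "EmotionCentroids",
    "emotion_centroids",
]

log = logging.getLogger(__name__)


def assemble_behavior_matrix(
    ratings: pd.DataFrame, event_physio: pd.DataFrame
) -> BehaviorMatrix:
    """Join ratings and per-event physiology into the canonical M x 34 matrix.

    Columns follow the canonical feature order (32 GRID items, then
    heart_rate, respiration_rate); rows are sorted by (subject, session,
    event).  Raises on missing feature columns, duplicated (subject, event)
    pairs, or events without physiology values.
    """
    missing_cols = [c for c in GRID_FEATURE_IDS if c not in ratings.columns]
    if missing_cols:
        raise KeyError(f"ratings table lacks feature columns: {missing_cols}")
    for col in ("subject_id", "event_id"):
        if col not in ratings.columns:
            raise KeyError(f"ratings table lacks required column {col!r}")

    dup = ratings.duplicated(subset=["subject_id", "event_id"])
    if dup.any():
        pairs = ratings.loc[dup, ["subject_id", "event_id"]].values.tolist()
        raise ValueError(f"duplicated (subject, event) rows: {pairs[:5]}")

    physio_cols = [c for c in ("heart_rate", "respiration_rate") if c in event_physio.columns]
    if len(physio_cols) != 2:
        raise KeyError("event physiology must provide heart_rate and respiration_rate")

    merged = ratings.merge(
        event_physio[["subject_id", "event_id", "heart_rate", "respiration_rate"]],
        on=["subject_id", "event_id"],
        how="left",
        validate="one_to_one",
    )
    absent = merged["heart_rate"].isna() | merged["respiration_rate"].isna()
    if absent.any():
        bad = merged.loc[absent, ["subject_id", "event_id"]].iloc[0]
        raise ValueError(
            "physiology missing for event "
            f"(subject {bad['subject_id']}, event {bad['event_id']})"
        )

    sort_cols = [c for c in ("subject_id", "session", "event_id") if c in merged.columns]
    merged = merged.sort_values(sort_cols, kind="stable").reset_index(drop=True)

    index_cols = {"subject": merged["subject_id"]}
    for col in ("session", "video_id", "primary_emotion", "secondary_emotion"):
        if col in merged.columns:
            index_cols[col.replace("video_id", "video")] = merged[col]
    index_cols["event_id"] = merged["event_id"]
    index = pd.DataFrame(index_cols)

    values = merged[list(FEATURE_IDS)].to_numpy(dtype=float)
    return BehaviorMatrix(
        values=values,
        index=index,
        feature_ids=FEATURE_IDS,
        components=tuple(f.component for f in FEATURES),
    )


def zscore_within_subject(matrix, ddof: int = 0):
    """Z-score each column separately within each subject's rows.

    Uses the population standard deviation (``ddof=0``) by default.  Columns
    constant within a subject are set to 0 (shape-preserving) with a logged
    warning.  Subjects contributing a single row cannot be normalized and
    raise an error.
    """
    if not isinstance(matrix, (BehaviorMatrix, BrainMatrix)):
        raise TypeError("expected a BehaviorMatrix or BrainMatrix")
    values = matrix.values.copy()
    subjects = matrix.subjects
    for s in np.unique(subjects):
        rows = np.flatnonzero(subjects == s)
        if len(rows) < 2:
            raise ValueError(f"subject {s!r} has a single observation; cannot z-score")
        block = values[rows]
        mu = block.mean(axis=0)
        sd = block.std(axis=0, ddof=ddof)
        flat = sd == 0
        if flat.any():
            log.warning(
                "subject %r: %d constant column(s) set to 0 during z-scoring",
                s,
                int(flat.sum()),
            )
            sd = np.where(flat, 1.0, sd)
        values[rows] = (block - mu) / sd
        if flat.any():
            values[np.ix_(rows, np.flatnonzero(flat))] = 0.0
    return replace(matrix, values=values, zscored=True)


@dataclass
class EmotionCentroids:
    """Per-category mean feature profiles (categories x N)."""

    values: np.ndarray
    categories: tuple[str, ...]
    counts: np.ndarray
    feature_ids: tuple[str, ...]
    empty_categories: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=list(self.categories),
                          columns=list(self.feature_ids))
        df.insert(0, "n_events", self.counts)
        return df


def emotion_centroids(
    matrix: BehaviorMatrix,
    labels=None,
    categories: tuple[str, ...] = EMOTION_CATEGORIES,
) -> EmotionCentroids:
    """Mean feature profile of each discrete emotion category.

    ``labels`` defaults to the ``primary_emotion`` column of the observation
    index.  Empty categories are reported (zero rows, listed in
    ``empty_categories``), never silently dropped.
    """
    if labels is None:
        if "primary_emotion" not in matrix.index.columns:
            raise KeyError("no labels given and index lacks 'primary_emotion'")
        labels = matrix.index["primary_emotion"].to_numpy()
    labels = np.asarray(labels)
    if len(labels) != matrix.n_observations:
        raise ValueError("labels length does not match observation count")
    unknown = set(labels) - set(categories)
    if unknown:
        raise ValueError(f"labels outside the category vocabulary: {sorted(unknown)}")

    values = np.zeros((len(categories), matrix.n_features))
    counts = np.zeros(len(categories), dtype=int)
    empty = []
    for i, cat in enumerate(categories):
        rows = labels == cat
        counts[i] = int(rows.sum())
        if counts[i] == 0:
            empty.append(cat)
        else:
            values[i] = matrix.values[rows].mean(axis=0)
    if empty:
        log.warning("empty emotion categories: %s", empty)
    return EmotionCentroids(
        values=values,
        categories=tuple(categories),
        counts=counts,
        feature_ids=matrix.feature_ids,
        empty_categories=tuple(empty),
    )
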