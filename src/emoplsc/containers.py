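"""In-memory containers shared across pipeline stages.

``BehaviorMatrix`` holds the M x N event-by-feature block (N = 34), and
``BrainMatrix`` the M x V event-by-voxel block of contrast values.  Rows of
the two are aligned one-to-one on behavioral observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["BehaviorMatrix", "BrainMatrix"]


def _check_index(index: pd.DataFrame, n_rows: int) -> None:
    required = {"subject", "event_id"}
    missing = required - set(index.columns)
    if missing:
        raise ValueError(f"observation index lacks columns: {sorted(missing)}")
    if len(index) != n_rows:
        raise ValueError(
            f"observation index has {len(index)} rows, values have {n_rows}"
        )


@dataclass
class BehaviorMatrix:
    """M x N behavioral feature matrix with per-row observation metadata.

    Parameters
    ----------
    values : (M, N) array
    index : DataFrame with at least ``subject`` and ``event_id`` columns,
        one row per observation, aligned with ``values``.
    feature_ids : length-N feature identifiers (canonical order).
    components : CPM component per feature (same length as ``feature_ids``).
    zscored : whether within-subject z-scoring has been applied.
    """

    values: np.ndarray
    index: pd.DataFrame
    feature_ids: tuple[str, ...]
    components: tuple[str, ...] = field(default=())
    zscored: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        _check_index(self.index, self.values.shape[0])
        if len(self.feature_ids) != self.values.shape[1]:
            raise ValueError("feature_ids length does not match column count")
        if self.components and len(self.components) != len(self.feature_ids):
            raise ValueError("components length does not match feature_ids")
        if not np.isfinite(self.values).all():
            raise ValueError("behavior matrix contains non-finite values")

    @property
    def n_observations(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def subjects(self) -> np.ndarray:
        return self.index["subject"].to_numpy()

    def subset_features(self, feature_subset: list[str] | tuple[str, ...]) -> "BehaviorMatrix":
        """Restrict to a subset of feature columns (order as given)."""
        if len(feature_subset) == 0:
            raise ValueError("feature subset is empty")
        unknown = [f for f in feature_subset if f not in self.feature_ids]
        if unknown:
            raise KeyError(f"unknown feature ids: {unknown}")
        idx = [self.feature_ids.index(f) for f in feature_subset]
        comps = tuple(self.components[i] for i in idx) if self.components else ()
        return replace(
            self,
            values=self.values[:, idx],
            feature_ids=tuple(feature_subset),
            components=comps,
        )

    def to_frame(self) -> pd.DataFrame:
        df = self.index.reset_index(drop=True).copy()
        for j, fid in enumerate(self.feature_ids):
            df[fid] = self.values[:, j]
        return df


@dataclass
class BrainMatrix:
    """M x V matrix of per-event voxel contrast values.

    ``mask``/``affine`` carry the volumetric geometry when maps came from (or
    should be written back to) NIfTI volumes; both may be ``None`` for flat
    containers.
    """

    values: np.ndarray
    index: pd.DataFrame
    mask: np.ndarray | None = None
    affine: np.ndarray | None = None
    zscored: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        _check_index(self.index, self.values.shape[0])
        if not np.isfinite(self.values).all():
            raise ValueError("brain matrix contains non-finite values")
        if self.mask is not None:
            n_mask = int(np.count_nonzero(self.mask))
            if n_mask != self.values.shape[1]:
                raise ValueError(
                    f"mask selects {n_mask} voxels but matrix has {self.values.shape[1]}"
                )

    @property
    def n_observations(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]

    @property
    def subjects(self) -> np.ndarray:
        return self.index["subject"].to_numpy()
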