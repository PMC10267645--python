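"""First-level event GLM and framewise-displacement screening.

Each fMRI run (one video) is modeled with one boxcar-times-HRF regressor per
emotional event plus one for the 30 s washout clip, six motion nuisance
regressors, an intercept, and a discrete-cosine high-pass basis (0.004 Hz
cutoff, i.e. periods above 250 s).  Per-voxel OLS betas feed an
event-minus-washout contrast, one map per event.  Head motion is screened
with the Power and Jenkinson framewise-displacement metrics (default
thresholds 0.5 mm and 0.2 mm); runs with more than 20% displaced frames are
flagged but not dropped by default.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "canonical_hrf",
    "DesignMatrix",
    "build_design",
    "fit_glm",
    "contrast_event_vs_washout",
    "FDSeries",
    "framewise_displacement",
    "flag_runs",
]

log = logging.getLogger(__name__)

#: default thresholds per FD metric (mm)
FD_THRESHOLDS = {"power": 0.5, "jenkinson": 0.2}
ROTATION_RADIUS_MM = 50.0   # Power metric: rotations mapped to arc length
SPHERE_RADIUS_MM = 80.0     # Jenkinson metric: RMS over a sphere


def canonical_hrf(
    t,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    peak_disp: float = 1.0,
    undershoot_disp: float = 1.0,
    peak_undershoot_ratio: float = 6.0,
) -> np.ndarray:
    """Canonical double-gamma hemodynamic response, unit peak amplitude.

    Difference of two gamma densities peaking near ``peak_delay`` (~5-6 s)
    with an undershoot near ``undershoot_delay``; zero for t <= 0.
    """
    from scipy.stats import gamma

    t = np.asarray(t, dtype=float)
    peak = gamma.pdf(t, peak_delay / peak_disp, scale=peak_disp)
    under = gamma.pdf(t, undershoot_delay / undershoot_disp, scale=undershoot_disp)
    h = peak - under / peak_undershoot_ratio
    h = np.where(t > 0, h, 0.0)
    m = h.max()
    return h / m if m > 0 else h


@dataclass
class DesignMatrix:
    """T x P design with column roles and the TR it was sampled at."""

    matrix: np.ndarray
    columns: list[str]
    tr: float
    frame_times: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def column_index(self, name: str) -> int:
        return self.columns.index(name)

    @property
    def event_columns(self) -> list[str]:
        return [c for c in self.columns if c.startswith("event_")]

    def is_full_rank(self) -> bool:
        return np.linalg.matrix_rank(self.matrix) == self.n_columns


def _dct_highpass_basis(n_frames: int, tr: float, cutoff_hz: float) -> np.ndarray:
    """SPM-style discrete cosine high-pass basis (constant term excluded).

    Keeps cosines with period longer than 1 / cutoff_hz.
    """
    duration = n_frames * tr
    order = int(np.floor(2 * duration * cutoff_hz))
    t = np.arange(n_frames)
    basis = [
        np.sqrt(2.0 / n_frames) * np.cos(np.pi * k * (2 * t + 1) / (2 * n_frames))
        for k in range(1, order + 1)
    ]
    return np.column_stack(basis) if basis else np.empty((n_frames, 0))


def _convolved_boxcar(
    frame_times: np.ndarray, onset: float, duration: float, tr: float,
    oversample: int = 16,
) -> np.ndarray:
    """Boxcar convolved with the canonical HRF, sampled at frame times."""
    dt = tr / oversample
    t_hi = np.arange(0.0, frame_times[-1] + tr, dt)
    box = ((t_hi >= onset) & (t_hi < onset + duration)).astype(float)
    hrf = canonical_hrf(np.arange(0.0, 32.0 + dt, dt))
    conv = np.convolve(box, hrf)[: len(t_hi)] * dt
    return np.interp(frame_times, t_hi, conv)


def build_design(
    run_events: pd.DataFrame,
    motion: np.ndarray | None,
    tr: float,
    n_frames: int,
    highpass_hz: float | None = 0.004,
) -> DesignMatrix:
    """Assemble the run design matrix.

    ``run_events`` needs columns onset, duration, event_id, and (for the
    washout regressor) washout_onset / washout_duration.  Events must not
    overlap.
    """
    frame_times = np.arange(n_frames) * tr
    ev = run_events.sort_values("onset").reset_index(drop=True)
    ends = ev["onset"] + ev["duration"]
    if (ev["onset"].values[1:] < ends.values[:-1] - 1e-9).any():
        raise ValueError("overlapping event windows in run design")

    cols, names = [], []
    for _, row in ev.iterrows():
        cols.append(_convolved_boxcar(frame_times, row["onset"], row["duration"], tr))
        names.append(f"event_{int(row['event_id'])}")
    if len(ev):
        w_on = float(ev["washout_onset"].iloc[0])
        w_dur = float(ev["washout_duration"].iloc[0])
    else:
        w_on, w_dur = frame_times[-1] - 30.0, 30.0
    cols.append(_convolved_boxcar(frame_times, w_on, w_dur, tr))
    names.append("washout")

    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape != (n_frames, 6):
            raise ValueError(f"motion series must be ({n_frames}, 6), got {motion.shape}")
        for j, nm in enumerate(("tx", "ty", "tz", "rx", "ry", "rz")):
            cols.append(motion[:, j])
            names.append(f"motion_{nm}")

    if highpass_hz:
        dct = _dct_highpass_basis(n_frames, tr, highpass_hz)
        for k in range(dct.shape[1]):
            cols.append(dct[:, k])
            names.append(f"drift_dct{k + 1}")

    cols.append(np.ones(n_frames))
    names.append("intercept")

    dm = DesignMatrix(
        matrix=np.column_stack(cols), columns=names, tr=tr, frame_times=frame_times
    )
    if not dm.is_full_rank():
        log.warning("design matrix is rank-deficient (%d columns)", dm.n_columns)
    return dm


def fit_glm(bold: np.ndarray, design: DesignMatrix) -> np.ndarray:
    """Per-voxel OLS betas (P x V).  Whole-volume fit, no mask.

    Falls back to the pseudo-inverse (with a warning) on rank deficiency.
    """
    bold = np.asarray(bold, dtype=float)
    if bold.shape[0] != design.n_frames:
        raise ValueError(
            f"BOLD has {bold.shape[0]} frames, design {design.n_frames}"
        )
    Xd = design.matrix
    if not design.is_full_rank():
        warnings.warn("rank-deficient design: using pseudo-inverse", RuntimeWarning)
        return np.linalg.pinv(Xd) @ bold
    beta, *_ = np.linalg.lstsq(Xd, bold, rcond=None)
    return beta


def contrast_event_vs_washout(
    betas: np.ndarray, design: DesignMatrix, event_id: int
) -> np.ndarray:
    """Event-minus-washout contrast map (+1 on the event column, -1 on washout)."""
    contrast = np.zeros(design.n_columns)
    contrast[design.column_index(f"event_{int(event_id)}")] = 1.0
    contrast[design.column_index("washout")] = -1.0
    return contrast @ betas


@dataclass
class FDSeries:
    """Per-frame displacement for one run (first frame 0 by convention)."""

    fd: np.ndarray
    metric: str
    threshold: float

    @property
    def flagged_fraction(self) -> float:
        return float((self.fd > self.threshold).mean())


def framewise_displacement(
    motion: np.ndarray, metric: str = "power", threshold: float | None = None
) -> FDSeries:
    """Framewise displacement from a 6-parameter motion series.

    Power: L1 norm of parameter differences with rotations (rad) scaled to
    arc length on a 50 mm sphere.  Jenkinson: RMS displacement of the
    frame-to-frame rigid transform over an 80 mm-radius sphere,
    ``sqrt(r^2/5 * Tr(A^T A) + t^T t)`` for the differential affine
    ``[A t] = T_i T_{i-1}^{-1} - I``.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion series must have 6 columns")
    if metric not in FD_THRESHOLDS:
        raise ValueError(f"unknown FD metric {metric!r}")
    thr = FD_THRESHOLDS[metric] if threshold is None else float(threshold)

    if metric == "power":
        d = np.diff(motion, axis=0)
        fd = np.abs(d[:, :3]).sum(axis=1) + ROTATION_RADIUS_MM * np.abs(d[:, 3:]).sum(axis=1)
    else:
        mats = [_rigid_transform(p) for p in motion]
        fd = np.empty(len(motion) - 1)
        for i in range(1, len(motion)):
            diff = mats[i] @ np.linalg.inv(mats[i - 1]) - np.eye(4)
            A = diff[:3, :3]
            t = diff[:3, 3]
            fd[i - 1] = np.sqrt(
                SPHERE_RADIUS_MM**2 / 5.0 * np.trace(A.T @ A) + t @ t
            )
    return FDSeries(fd=np.concatenate(([0.0], fd)), metric=metric, threshold=thr)


def _rigid_transform(params: np.ndarray) -> np.ndarray:
    """4x4 rigid transform from (tx, ty, tz, rx, ry, rz), rotations in rad."""
    tx, ty, tz, rx, ry, rz = params
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    T = np.eye(4)
    T[:3, :3] = Rz @ Ry @ Rx
    T[:3, 3] = (tx, ty, tz)
    return T


def flag_runs(
    fd_per_run: dict, frame_fraction: float = 0.20
) -> pd.DataFrame:
    """Flag runs whose fraction of displaced frames exceeds ``frame_fraction``.

    ``fd_per_run`` maps run keys to :class:`FDSeries`.  Flagged runs are
    reported, not dropped.
    """
    rows = []
    for key, fds in fd_per_run.items():
        frac = fds.flagged_fraction
        rows.append(
            {
                "run": key,
                "metric": fds.metric,
                "threshold": fds.threshold,
                "flagged_fraction": frac,
                "flagged": frac > frame_fraction,
            }
        )
    report = pd.DataFrame(rows)
    n_flagged = int(report["flagged"].sum()) if len(report) else 0
    log.info("FD screening: %d of %d runs flagged", n_flagged, len(report))
    return report
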