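"""In-scanner physiology: from raw traces to per-event HR/RR values.

Raw pulse and respiration traces (sampled at >= 240 Hz, typically 5 kHz) are
downsampled to 120 Hz, comb-filtered at the slice frequency (17.5 Hz = 35
slices / 2 s TR) and its harmonics, band-passed per channel (1-40 Hz cardiac,
0.05-1 Hz respiratory), and converted to instantaneous rates by peak
detection.  Rates outside the physiologic gate (60-100 bpm for HR by
default) are flagged and repaired by interpolation; event-window means are
then residualized against per-event motion summaries.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "PhysioTrace",
    "RateSeries",
    "preprocess_trace",
    "bandpass",
    "detect_peaks_and_rate",
    "validate_rate",
    "event_rates",
    "orthogonalize_to_motion",
]

log = logging.getLogger(__name__)

TARGET_RATE_HZ = 120.0
SLICE_FREQ_HZ = 17.5  # 35 slices / 2 s TR
CHANNEL_BANDS = {"pulse": (1.0, 40.0), "respiration": (0.05, 1.0)}
CHANNEL_MAX_RATE = {"pulse": 180.0, "respiration": 60.0}


@dataclass
class PhysioTrace:
    """A sampled physiological channel."""

    samples: np.ndarray
    sample_rate: float
    channel: str  # 'pulse' | 'respiration'
    run_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not np.isfinite(self.samples).all():
            raise ValueError("trace contains non-finite samples")
        if self.channel not in CHANNEL_BANDS:
            raise ValueError(f"unknown channel {self.channel!r}")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sample_rate


@dataclass
class RateSeries:
    """Uniformly sampled instantaneous rate (bpm or breaths/min)."""

    times: np.ndarray
    rate: np.ndarray
    valid: np.ndarray
    channel: str
    corrected_fraction: float = 0.0


def _comb_notch(x: np.ndarray, fs: float, f0: float, q: float) -> np.ndarray:
    """Cascaded zero-phase notches at f0 and harmonics below Nyquist."""
    nyq = fs / 2.0
    k = 1
    while k * f0 < nyq * 0.98:
        b, a = signal.iirnotch(k * f0, q, fs=fs)
        x = signal.filtfilt(b, a, x)
        k += 1
    return x


def preprocess_trace(
    trace: PhysioTrace,
    target_rate: float = TARGET_RATE_HZ,
    comb_f0: float = SLICE_FREQ_HZ,
    comb_q: float = 30.0,
) -> PhysioTrace:
    """Anti-aliased downsampling to 120 Hz plus comb filtering of scanner
    artifacts at the slice frequency and harmonics."""
    if trace.sample_rate < 2 * target_rate:
        raise ValueError(
            f"input rate {trace.sample_rate} Hz below 2 x target {target_rate} Hz"
        )
    frac = Fraction(target_rate / trace.sample_rate).limit_denominator(10000)
    x = signal.resample_poly(trace.samples, frac.numerator, frac.denominator)
    x = _comb_notch(x, target_rate, comb_f0, comb_q)
    return replace(trace, samples=x, sample_rate=target_rate)


def bandpass(
    trace: PhysioTrace,
    low: float | None = None,
    high: float | None = None,
    order: int = 4,
) -> PhysioTrace:
    """Zero-phase Butterworth band-pass; band defaults to the channel band."""
    if low is None or high is None:
        low, high = CHANNEL_BANDS[trace.channel]
    nyq = trace.sample_rate / 2.0
    if not 0 < low < high < nyq:
        raise ValueError(f"invalid band ({low}, {high}) for fs={trace.sample_rate}")
    sos = signal.butter(order, (low, high), btype="bandpass", fs=trace.sample_rate,
                        output="sos")
    return replace(trace, samples=signal.sosfiltfilt(sos, trace.samples))


def detect_peaks_and_rate(
    trace: PhysioTrace,
    max_rate: float | None = None,
    prominence_mad: float = 1.0,
    grid_rate: float = 4.0,
) -> RateSeries:
    """Peak detection and conversion to an instantaneous rate series.

    Peaks must be at least ``60 / max_rate`` seconds apart; the prominence
    threshold adapts to the trace MAD.  Inter-peak intervals become rates in
    per-minute units, interpolated to a uniform ``grid_rate`` Hz grid.
    """
    if max_rate is None:
        max_rate = CHANNEL_MAX_RATE[trace.channel]
    min_dist = max(1, int(round(trace.sample_rate * 60.0 / max_rate)))
    # Adaptive prominence: MAD floor, plus a robust peak-height scale so the
    # filter's ringing side lobes between sharp pulses are rejected (the MAD
    # of a pulse train reflects only its baseline).
    med = np.median(trace.samples)
    mad = np.median(np.abs(trace.samples - med))
    height_scale = np.quantile(trace.samples, 0.995) - med
    prominence = max(prominence_mad * mad, 0.4 * height_scale)
    if prominence <= 0:
        prominence = None
    peaks, _ = signal.find_peaks(trace.samples, distance=min_dist,
                                 prominence=prominence)
    if len(peaks) < 2:
        raise ValueError(f"run {trace.run_id!r}: fewer than 2 peaks detected")
    peak_times = peaks / trace.sample_rate
    inst_rate = 60.0 / np.diff(peak_times)
    mid_times = 0.5 * (peak_times[1:] + peak_times[:-1])
    times = np.arange(0.0, trace.duration, 1.0 / grid_rate)
    rate = np.interp(times, mid_times, inst_rate)
    return RateSeries(
        times=times,
        rate=rate,
        valid=np.ones_like(rate, dtype=bool),
        channel=trace.channel,
    )


def validate_rate(series: RateSeries, low: float = 60.0, high: float = 100.0) -> RateSeries:
    """Gate rates to a physiologic range; out-of-range samples are flagged and
    replaced by interpolation from in-range neighbors (automated stand-in for
    visual inspection and manual repair).  The corrected fraction is recorded.
    """
    ok = (series.rate >= low) & (series.rate <= high)
    frac = float(1.0 - ok.mean())
    rate = series.rate.copy()
    if not ok.all():
        if not ok.any():
            raise ValueError("no in-range samples to interpolate from")
        rate[~ok] = np.interp(
            series.times[~ok], series.times[ok], series.rate[ok]
        )
        log.info("rate gating (%s): corrected %.1f%% of samples",
                 series.channel, 100 * frac)
    return replace(series, rate=rate, valid=ok, corrected_fraction=frac)


def event_rates(series: RateSeries, events: pd.DataFrame) -> pd.DataFrame:
    """Mean rate over each event window (onset, onset + duration), clipped to
    the run bounds.  ``events`` needs columns event_id, onset, duration."""
    rows = []
    t = series.times
    t_end = t[-1] if len(t) else 0.0
    for _, ev in events.iterrows():
        lo = max(0.0, float(ev["onset"]))
        hi = min(t_end, float(ev["onset"]) + float(ev["duration"]))
        sel = (t >= lo) & (t <= hi)
        if not sel.any():
            raise ValueError(f"event {ev['event_id']} window outside the run")
        rows.append({"event_id": int(ev["event_id"]),
                     "mean_rate": float(series.rate[sel].mean())})
    return pd.DataFrame(rows)


def orthogonalize_to_motion(
    values: np.ndarray,
    motion_summaries: np.ndarray,
    subjects: np.ndarray | None = None,
    ridge: float = 1e-8,
) -> np.ndarray:
    """Residualize per-event values against per-event motion summaries.

    Per subject (or globally when ``subjects`` is None), values are OLS
    residuals of a regression on the six motion summaries plus an intercept;
    residuals are exactly orthogonal to every motion column.  A ridge
    fallback handles rank-deficient motion designs (with a warning).
    """
    values = np.asarray(values, dtype=float)
    motion_summaries = np.asarray(motion_summaries, dtype=float)
    if motion_summaries.shape[0] != values.shape[0]:
        raise ValueError("motion summaries and values are not row-aligned")
    out = np.empty_like(values)
    groups = (
        [np.arange(len(values))]
        if subjects is None
        else [np.flatnonzero(np.asarray(subjects) == s) for s in np.unique(subjects)]
    )
    for rows in groups:
        D = np.column_stack([np.ones(len(rows)), motion_summaries[rows]])
        if np.linalg.matrix_rank(D) < D.shape[1]:
            warnings.warn("rank-deficient motion design: ridge fallback", RuntimeWarning)
            coef = np.linalg.solve(D.T @ D + ridge * np.eye(D.shape[1]), D.T @ values[rows])
        else:
            coef, *_ = np.linalg.lstsq(D, values[rows], rcond=None)
        out[rows] = values[rows] - D @ coef
    return out
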