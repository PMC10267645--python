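"""Pulse and respiration waveform simulation with known event-wise rates.

The cardiac channel is a sharp periodic pulse train whose instantaneous
period tracks 60 / rate(t), with baseline drift, a comb-structured scanner
artifact at the slice frequency (17.5 Hz) and harmonics, and broadband
noise.  Respiration is a quasi-sinusoid at rate(t) / 60 Hz.  The
ground-truth mean rate over every event window is recorded for recovery
tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..physio import PhysioTrace, SLICE_FREQ_HZ
from .design import StudyDesign
from .scenario import GroundTruth, ScenarioConfig

__all__ = ["PhysioPair", "simulate_physio"]

RATE_BOUNDS_BPM = (30.0, 200.0)
RAMP_S = 3.0  # transition time into/out of event windows


@dataclass
class PhysioPair:
    """Simulated pulse + respiration for one run, with event-rate truth."""

    pulse: PhysioTrace
    respiration: PhysioTrace
    truth: pd.DataFrame  # event_id, hr_bpm, rr_bpm (window-mean ground truth)


def _rate_profile(
    times: np.ndarray, events: pd.DataFrame, rates: np.ndarray, baseline: float
) -> np.ndarray:
    """Piecewise rate curve: baseline outside events, per-event plateau inside,
    linear ramps of RAMP_S seconds at the window edges."""
    knots_t = [times[0]]
    knots_r = [baseline]
    for (_, ev), r in zip(events.iterrows(), rates):
        on, off = float(ev["onset"]), float(ev["onset"]) + float(ev["duration"])
        knots_t += [on - RAMP_S, on, off, off + RAMP_S]
        knots_r += [baseline, r, r, baseline]
    knots_t.append(times[-1])
    knots_r.append(baseline)
    return np.interp(times, knots_t, knots_r)


def simulate_physio(
    design: StudyDesign,
    truth: GroundTruth,
    config: ScenarioConfig,
    session: int,
    video: int,
    sample_rate: float = 500.0,
    artifact_amplitude: float = 0.3,
    drift_amplitude: float = 0.2,
    noise_sd: float = 0.05,
    pulse_sharpness: float = 20.0,
    hr_baseline: float = 72.0,
    rr_baseline: float = 15.0,
    seed: int | None = None,
) -> PhysioPair:
    """Simulate the physiology channels of one run (one video).

    Event rates come from the scenario ground truth; they must lie inside the
    physiologic range (30-200 bpm).
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed if seed is None else seed, 59, session, video])
    )
    ev = design.run_events(session, video)
    hr = truth.event_rates["hr_bpm"][ev["event_id"].to_numpy() - 1]
    rr = truth.event_rates["rr_bpm"][ev["event_id"].to_numpy() - 1]
    lo, hi = RATE_BOUNDS_BPM
    if ((hr < lo) | (hr > hi)).any() or ((rr < lo / 10) | (rr > hi)).any():
        raise ValueError("event rates outside the physiologic range")

    n = int(round(config.run_duration * sample_rate))
    t = np.arange(n) / sample_rate

    hr_t = _rate_profile(t, ev, hr, hr_baseline)
    rr_t = _rate_profile(t, ev, rr, rr_baseline)

    # integrate instantaneous frequency -> phase; pulse peaks at integer phase
    hr_phase = np.cumsum(hr_t / 60.0) / sample_rate
    pulse = np.exp(pulse_sharpness * (np.cos(2 * np.pi * hr_phase) - 1.0))
    resp = np.sin(2 * np.pi * np.cumsum(rr_t / 60.0) / sample_rate)

    artifact = artifact_amplitude * (
        np.sin(2 * np.pi * SLICE_FREQ_HZ * t)
        + 0.5 * np.sin(2 * np.pi * 2 * SLICE_FREQ_HZ * t + 0.7)
        + 0.3 * np.sin(2 * np.pi * 3 * SLICE_FREQ_HZ * t + 1.3)
    )
    drift = drift_amplitude * np.sin(2 * np.pi * 0.01 * t)

    pulse_out = pulse + artifact + drift + noise_sd * rng.standard_normal(n)
    resp_out = resp + 0.3 * artifact + noise_sd * rng.standard_normal(n)

    rows = []
    for _, e in ev.iterrows():
        sel = (t >= e["onset"]) & (t <= e["onset"] + e["duration"])
        rows.append(
            {
                "event_id": int(e["event_id"]),
                "hr_bpm": float(hr_t[sel].mean()),
                "rr_bpm": float(rr_t[sel].mean()),
            }
        )
    run_id = f"sub-all_ses-{session}_vid-{video}"
    return PhysioPair(
        pulse=PhysioTrace(pulse_out, sample_rate, "pulse", run_id),
        respiration=PhysioTrace(resp_out, sample_rate, "respiration", run_id),
        truth=pd.DataFrame(rows),
    )
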