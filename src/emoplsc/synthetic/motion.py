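"""Motion-series fixture with planted high-motion runs.

One 6-parameter series per analyzable run (770 under defaults: 20 subjects x
40 runs minus the 30 runs of the missing sessions).  Ordinary runs are
smooth random walks with per-frame steps clipped so the Power framewise
displacement stays below 0.18 mm regardless of seed; a documented fixed set
of five runs receives alternating translation jumps that guarantee more than
20% of frames exceed the 0.5 mm threshold for any seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import StudyDesign
from .scenario import ScenarioConfig

__all__ = ["MotionFixture", "simulate_motion", "PLANTED_BAD_RUNS"]

#: documented planted high-motion runs: (subject, session, video)
PLANTED_BAD_RUNS = (
    (3, 1, 5),
    (7, 2, 14),
    (12, 3, 26),
    (15, 4, 33),
    (18, 2, 17),
)

TRANS_STEP_SD = 0.008      # mm
ROT_STEP_SD = 8e-5         # rad
TRANS_STEP_CLIP = 0.04     # mm -> per-frame Power FD <= 3*0.04 + 50*3*4e-4 = 0.18
ROT_STEP_CLIP = 4e-4       # rad
SPIKE_AMPLITUDE = 0.6      # mm; alternating jumps give FD >= 0.56 at every spike frame
SPIKE_FRACTION = 0.22      # fraction of frames inside the spike block


@dataclass
class MotionFixture:
    """All run motion series of one scenario plus the planted truth."""

    runs: dict[tuple[int, int, int], np.ndarray]  # (subject, session, video) -> T x 6
    planted_bad: tuple[tuple[int, int, int], ...]
    n_frames: int

    @property
    def n_runs(self) -> int:
        return len(self.runs)


def _smooth_walk(rng: np.random.Generator, n_frames: int) -> np.ndarray:
    steps = np.empty((n_frames, 6))
    steps[:, :3] = np.clip(
        rng.standard_normal((n_frames, 3)) * TRANS_STEP_SD,
        -TRANS_STEP_CLIP, TRANS_STEP_CLIP,
    )
    steps[:, 3:] = np.clip(
        rng.standard_normal((n_frames, 3)) * ROT_STEP_SD,
        -ROT_STEP_CLIP, ROT_STEP_CLIP,
    )
    steps[0] = 0.0
    return np.cumsum(steps, axis=0)


def simulate_motion(
    design: StudyDesign, config: ScenarioConfig, seed: int | None = None
) -> MotionFixture:
    """Generate the full motion fixture for ``design``'s analyzable runs."""
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed if seed is None else seed, 71])
    )
    n_frames = int(round(config.run_duration / config.tr))
    n_spike = int(np.ceil(SPIKE_FRACTION * n_frames))
    vps = config.videos_per_session

    runs: dict[tuple[int, int, int], np.ndarray] = {}
    for subject in range(1, config.n_subjects + 1):
        missing = config.missing_sessions.get(subject, frozenset())
        for session in range(1, config.n_sessions + 1):
            if session in missing:
                continue
            for video in range((session - 1) * vps + 1, session * vps + 1):
                series = _smooth_walk(rng, n_frames)
                key = (subject, session, video)
                if key in PLANTED_BAD_RUNS:
                    start = 20
                    for i in range(n_spike):
                        if (i % 2) == 0:
                            series[start + i, 0] += SPIKE_AMPLITUDE
                runs[key] = series

    planted = tuple(k for k in PLANTED_BAD_RUNS if k in runs)
    return MotionFixture(runs=runs, planted_bad=planted, n_frames=n_frames)
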