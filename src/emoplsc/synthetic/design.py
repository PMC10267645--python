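"""Study design: sessions, videos, events, and the missingness pattern.

The within-subject layout is fixed: 4 sessions of 10 videos each, 1-4 rated
events per video (12 s, non-overlapping), one fMRI run per video ending in a
30 s washout clip.  Session event totals default to (34, 15, 35, 35) = 119;
with the documented missing sessions (subject 1 misses session 1, subject 2
misses sessions 3 and 4) the default design yields exactly 2,276
observations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..features import EMOTION_CATEGORIES
from .scenario import ScenarioConfig

__all__ = ["StudyDesign", "make_design", "allocate_events"]

#: spacing of consecutive event onsets within a run (12 s event + 12 s gap)
EVENT_STRIDE = 24.0
FIRST_ONSET = 10.0


def allocate_events(total: int, n_videos: int, max_per_video: int = 4) -> list[int]:
    """Deterministically split ``total`` events over ``n_videos`` videos.

    Starts from one event per video and adds events round-robin, so the
    allocation is unique and reproducible.  ``total`` must lie in
    ``[n_videos, max_per_video * n_videos]``.
    """
    if not n_videos <= total <= max_per_video * n_videos:
        raise ValueError(
            f"cannot place {total} events on {n_videos} videos with "
            f"1..{max_per_video} events each"
        )
    counts = [1] * n_videos
    remaining = total - n_videos
    j = 0
    while remaining > 0:
        if counts[j] < max_per_video:
            counts[j] += 1
            remaining -= 1
        j = (j + 1) % n_videos
    return counts


@dataclass(frozen=True)
class StudyDesign:
    """Event layout shared by all subjects plus the missingness pattern.

    ``events`` has one row per within-subject event (119 under defaults):
    session, video, event_id (global, 1-based), onset/duration in run time,
    category.  ``videos`` maps each video to its session and emotion
    category.
    """

    events: pd.DataFrame
    videos: pd.DataFrame
    config: ScenarioConfig

    @property
    def n_events(self) -> int:
        return len(self.events)

    def observations(self) -> pd.DataFrame:
        """One row per (subject, event) after applying missing sessions.

        Rows sorted by (subject, session, event_id); 2,276 rows under
        defaults.
        """
        cfg = self.config
        frames = []
        for subject in range(1, cfg.n_subjects + 1):
            missing = cfg.missing_sessions.get(subject, frozenset())
            sub_events = self.events[~self.events["session"].isin(missing)].copy()
            sub_events.insert(0, "subject", subject)
            frames.append(sub_events)
        obs = pd.concat(frames, ignore_index=True)
        obs = obs.sort_values(["subject", "session", "event_id"], kind="stable")
        return obs.reset_index(drop=True)

    def run_events(self, session: int, video: int) -> pd.DataFrame:
        """Events of one fMRI run (one video)."""
        sel = (self.events["session"] == session) & (self.events["video"] == video)
        return self.events[sel].reset_index(drop=True)


def make_design(config: ScenarioConfig) -> StudyDesign:
    """Build the deterministic study design for ``config``.

    Raises a ``ValueError`` for infeasible per-session event totals (outside
    ``[videos_per_session, 4 * videos_per_session]``).
    """
    vps = config.videos_per_session
    n_cat = config.n_categories
    if len(EMOTION_CATEGORIES) < n_cat:
        raise ValueError("more categories requested than the label vocabulary")

    video_rows = []
    event_rows = []
    event_id = 0
    video_id = 0
    for s_idx, total in enumerate(config.events_per_session):
        session = s_idx + 1
        counts = allocate_events(int(total), vps)
        for j in range(vps):
            video_id += 1
            # Latin-square style category rotation: each session covers every
            # category once; each category lands on exactly 4 videos overall.
            category = EMOTION_CATEGORIES[(j + s_idx) % n_cat]
            video_rows.append(
                {"video": video_id, "session": session, "category": category}
            )
            for e in range(counts[j]):
                event_id += 1
                onset = FIRST_ONSET + e * EVENT_STRIDE
                if onset + config.event_duration > config.video_duration:
                    raise ValueError("events do not fit inside the video window")
                event_rows.append(
                    {
                        "session": session,
                        "video": video_id,
                        "event_in_video": e + 1,
                        "event_id": event_id,
                        "onset": onset,
                        "duration": config.event_duration,
                        "washout_onset": config.video_duration,
                        "washout_duration": config.washout_duration,
                        "category": category,
                    }
                )

    events = pd.DataFrame(event_rows)
    videos = pd.DataFrame(video_rows)
    if len(events) != config.n_events:
        raise AssertionError("event allocation does not match configured totals")
    return StudyDesign(events=events, videos=videos, config=config)
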