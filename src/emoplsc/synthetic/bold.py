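"""BOLD run simulation with planted event betas.

Per voxel the run signal is ``design_regressors @ planted_betas`` plus a
linear drift and AR(1) noise.  Planted event betas come from the scenario's
voxel saliences and the event's latent score, so GLM contrast maps should
recover the same voxel patterns as the directly simulated contrast maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..glm import build_design, DesignMatrix
from .scenario import GroundTruth, ScenarioConfig

__all__ = ["BoldRun", "simulate_bold_run"]


@dataclass
class BoldRun:
    """One simulated run: data, nuisance motion, and the planted truth."""

    data: np.ndarray            # T x V
    motion: np.ndarray          # T x 6
    design: DesignMatrix
    betas_true: np.ndarray      # P x V planted betas (design column order)
    event_ids: list[int]
    washout_beta: np.ndarray    # V


def simulate_bold_run(
    run_events: pd.DataFrame,
    truth: GroundTruth,
    config: ScenarioConfig,
    event_latents: np.ndarray | None = None,
    noise_sd: float = 0.5,
    drift_amplitude: float = 0.3,
    ar_coef: float = 0.3,
    motion_sd: float = 0.01,
    seed: int | None = None,
) -> BoldRun:
    """Simulate one fMRI run for the events of a single video.

    ``event_latents`` is the (n_events, K) latent score block for this run's
    events; when omitted it is drawn from the scenario latent prior.  Events
    must not overlap and must fit inside the run.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed if seed is None else seed, 47])
    )
    ev = run_events.sort_values("onset").reset_index(drop=True)
    n_events = len(ev)
    last_offset = float((ev["onset"] + ev["duration"]).max()) if n_events else 0.0
    if last_offset + config.washout_duration > config.run_duration + 1e-9:
        raise ValueError("run too short for events plus washout")

    n_frames = int(round(config.run_duration / config.tr))
    # allow fewer voxels than the scenario's map space: take the leading rows
    # of the planted voxel saliences (orthonormality is irrelevant for GLM
    # recovery, only the planted beta values matter)
    V = min(config.n_voxels, truth.W_true.shape[0])
    W = truth.W_true[:V]

    # smooth nuisance motion (translations mm, rotations rad)
    steps = rng.standard_normal((n_frames, 6)) * motion_sd
    steps[:, 3:] *= 0.01
    motion = np.cumsum(steps, axis=0)

    design = build_design(ev, motion, config.tr, n_frames)

    if event_latents is None:
        event_latents = rng.standard_normal((n_events, truth.n_components)) * truth.c
    if event_latents.shape[0] != n_events:
        raise ValueError("event_latents rows must match the run's event count")

    betas = np.zeros((design.n_columns, V))
    event_ids = [int(e) for e in ev["event_id"]]
    washout_beta = np.zeros(V)
    for i, eid in enumerate(event_ids):
        col = design.column_index(f"event_{eid}")
        betas[col] = W @ (truth.g * event_latents[i])
    betas[design.column_index("washout")] = washout_beta

    clean = design.matrix @ betas
    drift = drift_amplitude * np.linspace(-1, 1, n_frames)[:, None] * np.ones((1, V))
    if noise_sd > 0:
        eps = rng.standard_normal((n_frames, V)) * noise_sd
        noise = np.empty_like(eps)
        noise[0] = eps[0]
        for t_i in range(1, n_frames):
            noise[t_i] = ar_coef * noise[t_i - 1] + eps[t_i]
    else:
        noise = 0.0
    data = clean + (drift if drift_amplitude else 0.0) + noise

    return BoldRun(
        data=data,
        motion=motion,
        design=design,
        betas_true=betas,
        event_ids=event_ids,
        washout_beta=washout_beta,
    )
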