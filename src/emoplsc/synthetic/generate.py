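"""Event-level ratings and brain contrast maps with planted cross-covariance.

Per observation m a latent vector ``t_m ~ Normal(0, diag(c^2))`` drives both
blocks: ratings ``y_m = U_true @ t_m + subject_offset + eps`` and contrast
maps ``x_m = W_true @ (g * t_m) + eta``.  The shared latents induce the
planted cross-covariance ``E[Y^T X] / M = U_true diag(c^2 * g) W_true^T``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..containers import BehaviorMatrix, BrainMatrix
from ..features import (
    EMOTION_CATEGORIES,
    FEATURE_IDS,
    FEATURES,
    GRID_FEATURE_IDS,
    N_FEATURES,
    PHYSIO_FEATURE_IDS,
)
from .design import StudyDesign, make_design
from .scenario import GroundTruth, ScenarioConfig, make_ground_truth

__all__ = ["simulate_ratings", "simulate_brain_maps", "simulate_scenario", "SimulatedRatings"]

# affine placement of the standardized physiology features on physical scales
HR_CENTER, HR_SCALE = 76.0, 5.0  # bpm
RR_CENTER, RR_SCALE = 16.0, 1.5  # breaths/min
LIKERT_CENTER, LIKERT_SCALE = 4.0, 1.2


@dataclass
class SimulatedRatings:
    """Ratings table + event physiology + the latent scores that generated them."""

    ratings: pd.DataFrame       # subject_id, session, video_id, event_id, labels, 32 GRID cols
    event_physio: pd.DataFrame  # subject_id, event_id, heart_rate, respiration_rate
    latents: np.ndarray         # M x K true latent scores t_m
    raw: np.ndarray             # M x N feature values before Likert quantization
    observations: pd.DataFrame  # design observation rows aligned with the above


def simulate_ratings(
    design: StudyDesign, truth: GroundTruth, config: ScenarioConfig
) -> SimulatedRatings:
    """Simulate the behavioral block of one scenario."""
    if config.noise_sd_behavior < 0:
        raise ValueError("noise_sd_behavior must be non-negative")
    N, K = truth.U_true.shape
    if N != config.n_features or K != config.n_components:
        raise ValueError("ground truth dimensions inconsistent with config")

    obs = design.observations()
    M = len(obs)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 23]))

    # Draw latent scores and standardize the realization within each subject
    # (centered columns, exactly orthonormal after scaling).  The pipeline
    # normalizes both data blocks to within-subject z-scores, so planting the
    # latents with exact within-subject covariance diag(c^2) makes the
    # planted cross-covariance hold exactly (not just in expectation) in the
    # noiseless limit and keeps the covariance-explained spectrum stable
    # across draws.
    subjects_arr = obs["subject"].to_numpy()
    latents = np.empty((M, K))
    for s in np.unique(subjects_arr):
        rows = np.flatnonzero(subjects_arr == s)
        T_raw = rng.standard_normal((len(rows), K))
        T_raw -= T_raw.mean(axis=0)
        Qs, _ = np.linalg.qr(T_raw)
        latents[rows] = Qs * np.sqrt(len(rows)) * truth.c
    # Balance noise variance across features: feature i carries planted signal
    # power q_i = sum_k U_ik^2 c_k^2, so give it noise variance
    # sigma^2 + mean(q) - q_i (floored).  Every column then has the same total
    # variance and within-subject z-scoring applies a near-uniform rescaling,
    # making the planted covariance-explained spectrum insensitive to the
    # particular salience draw.
    if config.noise_sd_behavior > 0:
        if config.balance_noise:
            q = (truth.U_true**2) @ truth.c**2
            noise_var = np.maximum(config.noise_sd_behavior**2 + q.mean() - q, 0.05)
        else:
            noise_var = np.full(N, config.noise_sd_behavior**2)
        noise = rng.standard_normal((M, N)) * np.sqrt(noise_var)
    else:
        noise = np.zeros((M, N))  # exact noiseless limit
    offsets = truth.subject_offsets[obs["subject"].to_numpy() - 1]
    raw = latents @ truth.U_true.T + offsets + noise

    values = raw.copy()
    if config.likert_mode == "quantized" and N == N_FEATURES:
        grid_idx = [FEATURE_IDS.index(f) for f in GRID_FEATURE_IDS]
        q = np.rint(LIKERT_CENTER + LIKERT_SCALE * values[:, grid_idx])
        values[:, grid_idx] = np.clip(q, 1, 7)

    if N == N_FEATURES:
        hr_col = FEATURE_IDS.index("heart_rate")
        rr_col = FEATURE_IDS.index("respiration_rate")
        values[:, hr_col] = HR_CENTER + HR_SCALE * raw[:, hr_col]
        values[:, rr_col] = RR_CENTER + RR_SCALE * raw[:, rr_col]
        grid_cols = list(GRID_FEATURE_IDS)
        grid_idx = [FEATURE_IDS.index(f) for f in grid_cols]
    else:
        hr_col = rr_col = None
        grid_cols = [f"feature_{i:02d}" for i in range(N)]
        grid_idx = list(range(N))

    categories = obs["category"].to_numpy()
    secondary = np.array(
        [
            EMOTION_CATEGORIES[(EMOTION_CATEGORIES.index(c) + 1) % config.n_categories]
            for c in categories
        ]
    )
    ratings = pd.DataFrame(
        {
            "subject_id": obs["subject"].to_numpy(),
            "session": obs["session"].to_numpy(),
            "video_id": obs["video"].to_numpy(),
            "event_id": obs["event_id"].to_numpy(),
            "primary_emotion": categories,
            "secondary_emotion": secondary,
        }
    )
    for name, j in zip(grid_cols, grid_idx):
        ratings[name] = values[:, j]

    if hr_col is not None:
        event_physio = pd.DataFrame(
            {
                "subject_id": obs["subject"].to_numpy(),
                "event_id": obs["event_id"].to_numpy(),
                "heart_rate": values[:, hr_col],
                "respiration_rate": values[:, rr_col],
            }
        )
    else:
        event_physio = pd.DataFrame(
            {"subject_id": obs["subject"], "event_id": obs["event_id"]}
        )

    return SimulatedRatings(
        ratings=ratings,
        event_physio=event_physio,
        latents=latents,
        raw=raw,
        observations=obs,
    )


def simulate_brain_maps(
    design: StudyDesign,
    truth: GroundTruth,
    config: ScenarioConfig,
    latents: np.ndarray,
) -> BrainMatrix:
    """Simulate the voxel block sharing latent scores with the ratings."""
    obs = design.observations()
    M = len(obs)
    if latents.shape[0] != M:
        raise ValueError(
            f"latent scores have {latents.shape[0]} rows but design yields {M} observations"
        )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 31]))
    X = (latents * truth.g) @ truth.W_true.T
    if config.noise_sd_brain > 0:
        # same per-column noise balancing as the behavior block
        if config.balance_noise:
            q = (truth.W_true**2) @ (truth.c * truth.g) ** 2
            noise_var = np.maximum(config.noise_sd_brain**2 + q.mean() - q, 0.05)
        else:
            noise_var = np.full(X.shape[1], config.noise_sd_brain**2)
        X = X + rng.standard_normal(X.shape) * np.sqrt(noise_var)
    index = obs.rename(columns={"subject": "subject"})[
        ["subject", "session", "video", "event_id"]
    ]
    return BrainMatrix(values=X, index=index)


def simulate_scenario(
    config: ScenarioConfig | None = None,
) -> tuple[StudyDesign, GroundTruth, SimulatedRatings, BrainMatrix]:
    """Convenience wrapper: design + truth + both data blocks for a scenario."""
    cfg = config if config is not None else ScenarioConfig()
    design = make_design(cfg)
    truth = make_ground_truth(cfg)
    sim = simulate_ratings(design, truth, cfg)
    brain = simulate_brain_maps(design, truth, cfg, sim.latents)
    return design, truth, sim, brain
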