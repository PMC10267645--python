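"""Scenario configuration and planted ground truth.

The default scenario (``cpm_default``) reproduces the study conditions the
pipeline is built for: 20 subjects x 40 videos x 119 events over 4 sessions,
with subject 1 missing session 1 and subject 2 missing sessions 3-4, which
leaves 2,276 behavioral observations.  The behavior (N = 34) and voxel
(V = 2,000) spaces share a planted rank-6 cross-covariance whose
covariance-explained spectrum is calibrated to
(19.0, 11.0, 6.0, 5.1, 4.6, 3.4) percent.

Calibration: the per-component latent amplitudes below were fitted once by
iterative pilot simulation (``scripts/calibrate_spectrum.py``) so that the
empirical covariance-explained fractions of the z-scored data match the
target spectrum; they are part of the scenario definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ..features import (
    COMPONENTS,
    FEATURE_IDS,
    FEATURES,
    N_FEATURES,
    feelings_indices,
)

__all__ = ["ScenarioConfig", "GroundTruth", "make_ground_truth", "cpm_default"]

#: covariance-explained targets for the six planted components (fractions)
DEFAULT_SPECTRUM = (0.190, 0.110, 0.060, 0.051, 0.046, 0.034)

# Calibrated per-component signal amplitudes (see module docstring).
# c[k] is the latent standard deviation feeding the behavior block, and
# g[k] the brain-side gain; the planted cross-covariance singular values are
# proportional to c**2 * g.
CALIBRATED_C = (1.5882, 1.3075, 1.0202, 0.9405, 0.9103, 0.7041)
CALIBRATED_G = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)

# Relative loading weight of the six feelings items in planted components 1
# and 3 (the two components with feelings support); > 1 concentrates salience
# mass on feelings so the feelings-only control analysis retains both.
FEELINGS_WEIGHT = {0: 2.0, 2: 2.8}


@dataclass(frozen=True)
class ScenarioConfig:
    """Full parameterization of one synthetic study."""

    n_subjects: int = 20
    n_videos: int = 40
    n_categories: int = 10
    events_per_session: tuple[int, ...] = (34, 15, 35, 35)
    missing_sessions: dict[int, frozenset[int]] = field(
        default_factory=lambda: {1: frozenset({1}), 2: frozenset({3, 4})}
    )
    n_features: int = N_FEATURES
    n_voxels: int = 2000
    n_components: int = 6
    component_spectrum: tuple[float, ...] = DEFAULT_SPECTRUM
    noise_sd_behavior: float = 1.0
    noise_sd_brain: float = 1.0
    balance_noise: bool = True
    likert_mode: str = "continuous"  # or "quantized"
    event_duration: float = 12.0
    washout_duration: float = 30.0
    video_duration: float = 111.0
    run_duration: float = 164.0
    tr: float = 2.0
    seed: int = 7081

    def __post_init__(self) -> None:
        if self.noise_sd_behavior < 0 or self.noise_sd_brain < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if self.likert_mode not in ("continuous", "quantized"):
            raise ValueError("likert_mode must be 'continuous' or 'quantized'")
        if len(self.component_spectrum) != self.n_components:
            raise ValueError("component_spectrum length must equal n_components")
        spec = np.asarray(self.component_spectrum)
        if (spec <= 0).any() or spec.sum() > 1 + 1e-12:
            raise ValueError("component_spectrum entries must be positive and sum <= 1")
        if self.n_videos % self.n_categories != 0:
            raise ValueError("n_videos must be a multiple of n_categories")

    @property
    def n_sessions(self) -> int:
        return len(self.events_per_session)

    @property
    def videos_per_session(self) -> int:
        return self.n_videos // self.n_sessions

    @property
    def n_events(self) -> int:
        return int(sum(self.events_per_session))

    def with_(self, **kwargs) -> "ScenarioConfig":
        return replace(self, **kwargs)


def cpm_default(seed: int | None = None, **overrides) -> ScenarioConfig:
    """The calibrated default scenario ('cpm-default')."""
    cfg = ScenarioConfig()
    if seed is not None:
        cfg = cfg.with_(seed=seed)
    if overrides:
        cfg = cfg.with_(**overrides)
    return cfg


@dataclass(frozen=True)
class GroundTruth:
    """Planted generating model of one scenario.

    ``U_true`` (N x K) and ``W_true`` (V x K) have orthonormal columns; the
    population cross-covariance of the raw (un-normalized) blocks is
    ``U_true @ diag(c**2 * g) @ W_true.T``.
    """

    U_true: np.ndarray
    W_true: np.ndarray
    c: np.ndarray
    g: np.ndarray
    component_membership: dict[str, str]
    subject_offsets: np.ndarray
    event_rates: "np.ndarray"  # structured per-event (hr_bpm, rr_bpm)

    def __post_init__(self) -> None:
        for M_ in (self.U_true, self.W_true):
            gram = M_.T @ M_
            if not np.allclose(gram, np.eye(M_.shape[1]), atol=1e-10):
                raise ValueError("salience columns must be orthonormal to 1e-10")
        if (self.c <= 0).any() or (self.g <= 0).any():
            raise ValueError("c and g must be strictly positive")

    @property
    def n_components(self) -> int:
        return self.U_true.shape[1]

    @property
    def signal_singular_values(self) -> np.ndarray:
        """Population singular values of the raw cross-covariance (c^2 * g)."""
        return self.c**2 * self.g


def _orthonormalize_with_support(U_raw: np.ndarray, zero_rows: np.ndarray,
                                 zero_cols: list[int]) -> np.ndarray:
    """Orthonormalize columns while keeping ``zero_rows`` exactly zero in
    ``zero_cols``.

    Columns in ``zero_cols`` are orthonormalized first among themselves (any
    linear combination keeps the planted zero rows); the remaining columns are
    then orthogonalized against them and each other, which leaves their
    support unconstrained.
    """
    n, k = U_raw.shape
    free_cols = [j for j in range(k) if j not in zero_cols]
    U = np.empty_like(U_raw)
    basis: list[np.ndarray] = []
    for j in zero_cols + free_cols:
        v = U_raw[:, j].copy()
        for b in basis:
            v -= (b @ v) * b
        nrm = np.linalg.norm(v)
        if nrm < 1e-12:
            raise ValueError("degenerate salience columns; change seed")
        v /= nrm
        U[:, j] = v
        basis.append(v)
    if not np.allclose(U[np.ix_(zero_rows, zero_cols)], 0.0, atol=1e-12):
        raise AssertionError("support constraint violated during orthonormalization")
    return U


def make_ground_truth(config: ScenarioConfig, design=None) -> GroundTruth:
    """Draw the planted generating model for ``config`` (seeded)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    N, V, K = config.n_features, config.n_voxels, config.n_components

    feel_idx = feelings_indices() if N == N_FEATURES else np.array([], dtype=int)
    U_raw = rng.standard_normal((N, K))
    zero_cols: list[int] = []
    if feel_idx.size:
        # feelings items load only on components 1 and 3
        zero_cols = [j for j in range(K) if j not in FEELINGS_WEIGHT]
        for j in zero_cols:
            U_raw[feel_idx, j] = 0.0
        for j, w in FEELINGS_WEIGHT.items():
            if j < K:
                U_raw[feel_idx, j] *= w
        U_true = _orthonormalize_with_support(U_raw, feel_idx, zero_cols)
    else:
        U_true, _ = np.linalg.qr(U_raw)
        U_true = U_true[:, :K]

    W_raw = rng.standard_normal((V, K))
    W_true, _ = np.linalg.qr(W_raw)
    W_true = W_true[:, :K]

    if K == len(CALIBRATED_C) and config.component_spectrum == DEFAULT_SPECTRUM:
        c = np.array(CALIBRATED_C)
        g = np.array(CALIBRATED_G)
    else:
        # uncalibrated fallback: symmetric split, amplitudes proportional to
        # the square root of the target spectrum
        base = np.sqrt(np.asarray(config.component_spectrum))
        d = 4.0 * base / base[0]
        c = np.sqrt(d)
        g = 1.0 / np.sqrt(d)

    membership = (
        {f.id: f.component for f in FEATURES}
        if N == N_FEATURES
        else {f"feature_{i:02d}": COMPONENTS[i % len(COMPONENTS)] for i in range(N)}
    )

    subject_offsets = 0.5 * rng.standard_normal((config.n_subjects, N))

    n_events = config.n_events
    event_rates = np.empty(n_events, dtype=[("hr_bpm", float), ("rr_bpm", float)])
    event_rates["hr_bpm"] = rng.uniform(64.0, 96.0, n_events)
    event_rates["rr_bpm"] = rng.uniform(12.0, 20.0, n_events)

    return GroundTruth(
        U_true=U_true,
        W_true=W_true,
        c=c,
        g=g,
        component_membership=membership,
        subject_offsets=subject_offsets,
        event_rates=event_rates,
    )
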