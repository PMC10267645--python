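"""Shared fixtures: the default calibrated scenario (session-scoped, built
once) and a reduced-voxel variant for cheap resampling tests."""

from __future__ import annotations

import numpy as np
import pytest

from emoplsc import assemble_behavior_matrix, zscore_within_subject
from emoplsc.synthetic import cpm_default, make_design, make_ground_truth
from emoplsc.synthetic.generate import simulate_brain_maps, simulate_ratings


@pytest.fixture(scope="session")
def default_scenario():
    """Full 'cpm-default' scenario: design, truth, ratings, brain maps."""
    cfg = cpm_default()
    design = make_design(cfg)
    truth = make_ground_truth(cfg)
    sim = simulate_ratings(design, truth, cfg)
    brain = simulate_brain_maps(design, truth, cfg, sim.latents)
    return cfg, design, truth, sim, brain


@pytest.fixture(scope="session")
def prepared_blocks(default_scenario):
    """Within-subject z-scored behavior and brain blocks of the default
    scenario."""
    _, _, _, sim, brain = default_scenario
    Yz = zscore_within_subject(assemble_behavior_matrix(sim.ratings, sim.event_physio))
    Xz = zscore_within_subject(brain)
    return Xz, Yz


@pytest.fixture(scope="session")
def small_scenario():
    """Reduced-voxel scenario for resampling-heavy tests."""
    cfg = cpm_default(seed=5, n_voxels=200)
    design = make_design(cfg)
    truth = make_ground_truth(cfg)
    sim = simulate_ratings(design, truth, cfg)
    brain = simulate_brain_maps(design, truth, cfg, sim.latents)
    return cfg, design, truth, sim, brain


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
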