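"""Synthetic-data generator: design arithmetic, planted cross-covariance,
waveforms, motion fixture, BOLD runs."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

from emoplsc.features import FEATURE_IDS, GRID_FEATURE_IDS, feelings_indices
from emoplsc.glm import fit_glm, contrast_event_vs_washout, framewise_displacement
from emoplsc.synthetic import (
    cpm_default,
    make_design,
    make_ground_truth,
    simulate_bold_run,
    simulate_motion,
    simulate_physio,
)
from emoplsc.synthetic.design import allocate_events
from emoplsc.synthetic.generate import simulate_brain_maps, simulate_ratings
from emoplsc.synthetic.motion import PLANTED_BAD_RUNS


class TestDesign:
    def test_default_design_counts(self, default_scenario):
        cfg, design, *_ = default_scenario
        assert design.n_events == 119
        assert design.events["session"].nunique() == 4
        assert design.videos["video"].nunique() == 40

    def test_observation_count_after_missingness(self, default_scenario):
        _, design, *_ = default_scenario
        obs = design.observations()
        assert len(obs) == 2276

    def test_single_subject_no_missingness(self):
        cfg = cpm_default(n_subjects=1, missing_sessions={})
        obs = make_design(cfg).observations()
        assert len(obs) == 119

    def test_events_per_video_between_1_and_4(self, default_scenario):
        _, design, *_ = default_scenario
        per_video = design.events.groupby("video").size()
        assert per_video.between(1, 4).all()
        assert 2.8 < per_video.mean() < 3.0

    def test_four_videos_per_category(self, default_scenario):
        _, design, *_ = default_scenario
        assert (design.videos.groupby("category").size() == 4).all()

    def test_infeasible_session_totals_rejected(self):
        with pytest.raises(ValueError):
            allocate_events(9, 10)
        with pytest.raises(ValueError):
            allocate_events(41, 10)

    def test_event_windows_do_not_overlap(self, default_scenario):
        _, design, *_ = default_scenario
        for (_, _), run in design.events.groupby(["session", "video"]):
            run = run.sort_values("onset")
            ends = (run["onset"] + run["duration"]).to_numpy()
            assert (run["onset"].to_numpy()[1:] >= ends[:-1]).all()


class TestGroundTruth:
    def test_salience_columns_orthonormal(self, default_scenario):
        _, _, truth, *_ = default_scenario
        for Mat in (truth.U_true, truth.W_true):
            assert np.allclose(Mat.T @ Mat, np.eye(Mat.shape[1]), atol=1e-10)

    def test_feelings_rows_supported_on_components_1_and_3_only(self, default_scenario):
        _, _, truth, *_ = default_scenario
        fi = feelings_indices()
        sub = truth.U_true[fi]
        assert np.allclose(sub[:, [1, 3, 4, 5]], 0.0, atol=1e-12)
        assert np.linalg.matrix_rank(sub) == 2

    def test_amplitudes_strictly_positive(self, default_scenario):
        _, _, truth, *_ = default_scenario
        assert (truth.c > 0).all() and (truth.g > 0).all()


class TestRatings:
    def test_noiseless_cross_covariance_identity(self):
        """With zero noise the singular values of Y^T X / M equal c^2 * g
        exactly and the singular subspaces match the planted saliences."""
        cfg = cpm_default(seed=3, n_voxels=300,
                          noise_sd_behavior=0.0, noise_sd_brain=0.0)
        design = make_design(cfg)
        truth = make_ground_truth(cfg)
        sim = simulate_ratings(design, truth, cfg)
        brain = simulate_brain_maps(design, truth, cfg, sim.latents)
        R = sim.raw.T @ brain.values / len(sim.raw)
        sv = np.linalg.svd(R, compute_uv=False)[:6]
        expect = np.sort(truth.c**2 * truth.g)[::-1]
        assert np.allclose(sv, expect, atol=1e-8)
        U, _, _ = np.linalg.svd(R, full_matrices=False)
        # subspace congruence between estimated and planted behavior saliences
        s = np.linalg.svd(U[:, :6].T @ truth.U_true, compute_uv=False)
        assert s.min() > 0.999

    def test_subject_column_means_track_offsets(self, default_scenario):
        _, design, truth, sim, _ = default_scenario
        subs = sim.observations["subject"].to_numpy()
        means = np.array([sim.raw[subs == s].mean(axis=0)
                          for s in range(1, 21)])
        r = np.corrcoef(means.ravel(), truth.subject_offsets.ravel())[0, 1]
        assert r > 0.95

    def test_quantized_mode_yields_integer_likert(self):
        cfg = cpm_default(seed=2, likert_mode="quantized", n_voxels=50)
        design = make_design(cfg)
        truth = make_ground_truth(cfg)
        sim = simulate_ratings(design, truth, cfg)
        vals = sim.ratings[list(GRID_FEATURE_IDS)].to_numpy()
        assert np.array_equal(vals, np.rint(vals))
        assert vals.min() >= 1 and vals.max() <= 7

    def test_single_planted_component_dominates(self):
        cfg = cpm_default(seed=4, n_voxels=100, n_components=1,
                          component_spectrum=(0.5,),
                          noise_sd_behavior=0.05, noise_sd_brain=0.05,
                          balance_noise=False)
        design = make_design(cfg)
        truth = make_ground_truth(cfg)
        sim = simulate_ratings(design, truth, cfg)
        brain = simulate_brain_maps(design, truth, cfg, sim.latents)
        sv = np.linalg.svd(sim.raw.T @ brain.values, compute_uv=False)
        assert sv[0] > 10 * sv[1]

    def test_rows_align_between_blocks(self, default_scenario):
        _, design, truth, sim, brain = default_scenario
        assert len(sim.ratings) == brain.n_observations == 2276

    def test_mismatched_latents_rejected(self, default_scenario):
        cfg, design, truth, sim, _ = default_scenario
        with pytest.raises(ValueError):
            simulate_brain_maps(design, truth, cfg, sim.latents[:-1])

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            cpm_default(noise_sd_behavior=-1.0)

    def test_reproducibility_bit_identical(self):
        cfg = cpm_default(seed=9, n_voxels=60)
        out = []
        for _ in range(2):
            design = make_design(cfg)
            truth = make_ground_truth(cfg)
            sim = simulate_ratings(design, truth, cfg)
            brain = simulate_brain_maps(design, truth, cfg, sim.latents)
            out.append((sim.raw, brain.values))
        assert np.array_equal(out[0][0], out[1][0])
        assert np.array_equal(out[0][1], out[1][1])


class TestBold:
    def test_run_length_82_volumes(self, default_scenario):
        cfg, design, truth, *_ = default_scenario
        small = dataclasses.replace(cfg, n_voxels=20)
        run = simulate_bold_run(design.run_events(1, 1), truth, small)
        assert run.data.shape[0] == 82  # about 164 s at TR 2 s

    def test_noiseless_glm_recovers_planted_betas(self, default_scenario):
        cfg, design, truth, *_ = default_scenario
        small = dataclasses.replace(cfg, n_voxels=30)
        run = simulate_bold_run(
            design.run_events(1, 2), truth, small,
            noise_sd=0.0, drift_amplitude=0.0,
        )
        betas = fit_glm(run.data, run.design)
        assert np.abs(betas - run.betas_true).max() < 1e-8

    def test_zero_betas_give_zero_contrast(self, default_scenario):
        cfg, design, truth, *_ = default_scenario
        small = dataclasses.replace(cfg, n_voxels=10)
        ev = design.run_events(1, 3)
        run = simulate_bold_run(
            ev, truth, small,
            event_latents=np.zeros((len(ev), truth.n_components)),
            noise_sd=0.0, drift_amplitude=0.0,
        )
        betas = fit_glm(run.data, run.design)
        cmap = contrast_event_vs_washout(betas, run.design, run.event_ids[0])
        assert np.abs(cmap).max() < 1e-10

    def test_overlapping_events_rejected(self, default_scenario):
        cfg, design, truth, *_ = default_scenario
        ev = design.run_events(1, 1).copy()
        ev.loc[1, "onset"] = float(ev.loc[0, "onset"]) + 1.0
        with pytest.raises(ValueError):
            simulate_bold_run(ev, truth, dataclasses.replace(cfg, n_voxels=5))


class TestPhysioSim:
    def test_constant_rate_peak_count(self, default_scenario):
        """A clean constant-72 bpm pulse carries 72 +/- 1 peaks per minute."""
        from scipy.signal import find_peaks

        cfg, design, truth, *_ = default_scenario
        rates = truth.event_rates.copy()
        rates["hr_bpm"][:] = 72.0
        t72 = dataclasses.replace(truth, event_rates=rates)
        pair = simulate_physio(
            design, t72, cfg, session=1, video=1, hr_baseline=72.0,
            artifact_amplitude=0.0, noise_sd=0.0, drift_amplitude=0.0,
        )
        n_sec = 60.0
        n = int(n_sec * pair.pulse.sample_rate)
        peaks, _ = find_peaks(pair.pulse.samples[:n], height=0.5)
        assert abs(len(peaks) - 72) <= 1

    def test_event_rates_within_normal_range(self, default_scenario):
        _, _, truth, *_ = default_scenario
        hr = truth.event_rates["hr_bpm"]
        assert (hr >= 60).all() and (hr <= 100).all()

    def test_out_of_range_rates_rejected(self, default_scenario):
        cfg, design, truth, *_ = default_scenario
        rates = truth.event_rates.copy()
        rates["hr_bpm"][0] = 250.0
        bad = dataclasses.replace(truth, event_rates=rates)
        with pytest.raises(ValueError):
            simulate_physio(design, bad, cfg, session=1, video=1)

    def test_truth_table_has_one_row_per_event(self, default_scenario):
        cfg, design, truth, *_ = default_scenario
        pair = simulate_physio(design, truth, cfg, session=2, video=12)
        assert len(pair.truth) == len(design.run_events(2, 12))


class TestMotionFixture:
    def test_flagged_runs_equal_planted(self, default_scenario):
        cfg, design, *_ = default_scenario
        fix = simulate_motion(design, cfg)
        assert fix.n_runs == 770
        flagged = []
        for key, series in fix.runs.items():
            fd = framewise_displacement(series, "power")
            if (fd.fd > 0.5).mean() > 0.20:
                flagged.append(key)
        assert sorted(flagged) == sorted(PLANTED_BAD_RUNS)

    def test_spike_free_runs_under_threshold_any_seed(self, default_scenario):
        cfg, design, *_ = default_scenario
        for seed in (0, 99):
            fix = simulate_motion(design, cpm_default(seed=seed))
            clean = next(
                v for k, v in fix.runs.items() if k not in PLANTED_BAD_RUNS
            )
            assert framewise_displacement(clean, "power").fd.max() < 0.5

    def test_planted_run_exceeds_threshold_any_seed(self, default_scenario):
        cfg, design, *_ = default_scenario
        for seed in (0, 99):
            fix = simulate_motion(design, cpm_default(seed=seed))
            bad = fix.runs[PLANTED_BAD_RUNS[0]]
            fd = framewise_displacement(bad, "power")
            assert (fd.fd > 0.5).mean() > 0.20
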