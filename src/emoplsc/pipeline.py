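"""Pipeline orchestration: configuration, stage ordering, report bundle.

Stages run in dependency order (simulate/load -> physio -> glm -> prep ->
plsc -> inference -> descriptives); any stage can be skipped when its inputs
are supplied precomputed.  Every run writes its resolved configuration (with
hash) next to the outputs, and all counts and exclusions are logged.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior import assemble_behavior_matrix, emotion_centroids, zscore_within_subject
from .containers import BehaviorMatrix, BrainMatrix
from .descriptives import (
    anova_eta_squared,
    efa_varimax,
    kaiser_count,
    lv_emotion_correlation,
    ward_cluster,
)
from .inference import bootstrap_stability, permutation_test
from .io import read_brain_maps, read_ratings, write_salience_maps
from .plsc import fit_plsc
from .synthetic import cpm_default, make_design, make_ground_truth
from .synthetic.generate import simulate_brain_maps, simulate_ratings

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved pipeline configuration.

    Unknown keys are rejected when loading from YAML; the config hash is
    stamped on every output table for provenance.
    """

    # inputs (None -> simulate with the default scenario)
    ratings_path: str | None = None
    physio_path: str | None = None
    brain_path: str | None = None
    output_dir: str = "emoplsc_out"
    # stage toggles
    run_inference: bool = True
    run_descriptives: bool = True
    drop_flagged_runs: bool = False
    # numeric defaults
    n_permutations: int = 1000
    n_bootstrap: int = 1000
    alpha: float = 0.01
    stability_threshold: float = 2.5
    bootstrap_subset: int | None = None
    fd_threshold_mm: float = 0.5
    fd_frame_fraction: float = 0.20
    scenario_seed: int = 7081
    analysis_seed: int = 1
    likert_mode: str = "continuous"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class ReportBundle:
    """All tables produced by one pipeline run."""

    significance: pd.DataFrame
    covariance_explained: pd.DataFrame
    behavior_stability: pd.DataFrame | None
    centroids: pd.DataFrame | None
    cluster_newick: str | None
    efa_loadings: pd.DataFrame | None
    lv_emotion: pd.DataFrame | None
    anova: dict | None
    config: PipelineConfig
    n_retained: int
    written: list[Path] = field(default_factory=list)

    def write(self, out_dir) -> list[Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        stamp = f"# config_hash={self.config.config_hash} seed={self.config.analysis_seed} version={__version__}\n"

        def dump(df: pd.DataFrame | None, name: str, index=True):
            if df is None:
                return
            p = out / name
            with open(p, "w") as fh:
                fh.write(stamp)
                df.to_csv(fh, sep="\t", index=index)
            self.written.append(p)

        dump(self.significance, "lv_significance.tsv", index=False)
        dump(self.covariance_explained, "covariance_explained.tsv", index=False)
        dump(self.behavior_stability, "behavior_stability.tsv")
        dump(self.centroids, "emotion_centroids.tsv")
        dump(self.efa_loadings, "efa_loadings.tsv")
        dump(self.lv_emotion, "lv_emotion_correlation.tsv")
        if self.cluster_newick:
            p = out / "emotion_dendrogram.nwk"
            p.write_text(self.cluster_newick + "\n")
            self.written.append(p)
        if self.anova is not None:
            p = out / "physio_anova.json"
            p.write_text(json.dumps(self.anova, indent=2))
            self.written.append(p)
        p = out / "resolved_config.yaml"
        p.write_text(yaml.safe_dump({**self.config.to_dict(), "config_hash": self.config.config_hash}))
        self.written.append(p)
        return self.written


def _load_or_simulate(config: PipelineConfig):
    if config.ratings_path is None or config.brain_path is None:
        log.info("no input paths given: simulating the default scenario")
        cfg = cpm_default(seed=config.scenario_seed, likert_mode=config.likert_mode)
        design = make_design(cfg)
        truth = make_ground_truth(cfg)
        sim = simulate_ratings(design, truth, cfg)
        brain = simulate_brain_maps(design, truth, cfg, sim.latents)
        return sim.ratings, sim.event_physio, brain
    ratings = read_ratings(config.ratings_path, likert_mode=config.likert_mode)
    if config.physio_path is None:
        raise ValueError("ratings supplied without event physiology table")
    event_physio = pd.read_csv(config.physio_path)
    brain = read_brain_maps(config.brain_path)
    return ratings, event_physio, brain


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute the configured stages and write the report bundle."""
    ratings, event_physio, brain = _load_or_simulate(config)

    Y = assemble_behavior_matrix(ratings, event_physio)
    log.info("behavior matrix: %d observations x %d features", *Y.values.shape)
    if brain.n_observations != Y.n_observations:
        raise ValueError(
            f"brain maps ({brain.n_observations}) and behavior rows "
            f"({Y.n_observations}) are not aligned"
        )
    Yz = zscore_within_subject(Y)
    Xz = zscore_within_subject(brain)

    model = fit_plsc(Xz, Yz)
    cov = pd.DataFrame(
        {
            "lv": np.arange(1, model.n_components + 1),
            "singular_value": model.singular_values,
            "covariance_explained_pct": 100 * model.covariance_explained,
        }
    )

    n_retained = 0
    sig = pd.DataFrame({"lv": cov["lv"], "p_value": np.nan, "significant": False})
    stability_df = None
    if config.run_inference:
        report = permutation_test(
            Xz, Yz, n=config.n_permutations, alpha=config.alpha,
            seed=config.analysis_seed,
        )
        n_retained = report.n_retained
        sig = pd.DataFrame(
            {
                "lv": cov["lv"],
                "singular_value": report.singular_values,
                "p_value": report.p_values,
                "significant": report.significant,
                "retained": [i < n_retained for i in range(model.n_components)],
            }
        )
        log.info("permutation test: %d LVs retained at alpha=%s", n_retained, config.alpha)
        boot = bootstrap_stability(
            Xz, Yz,
            n=config.n_bootstrap,
            subset_size=config.bootstrap_subset,
            n_components=max(n_retained, 1),
            threshold=config.stability_threshold,
            seed=config.analysis_seed,
        )
        stability_df = pd.DataFrame(
            boot.stability_u,
            index=list(Yz.feature_ids),
            columns=[f"LV{k + 1}" for k in range(boot.U.shape[1])],
        )

    centroids_df = cluster_newick = efa_df = lv_emotion = anova = None
    if config.run_descriptives:
        cents = emotion_centroids(Yz)
        centroids_df = cents.to_frame()
        cluster_newick = ward_cluster(cents).to_newick()
        n_factors = max(kaiser_count(Yz.values), 1)
        efa = efa_varimax(Yz.values, n_factors, feature_ids=Yz.feature_ids)
        efa_df = efa.to_frame()
        lv_emotion = lv_emotion_correlation(model, cents, n_components=max(n_retained, 1))
        hr = Yz.values[:, list(Yz.feature_ids).index("heart_rate")]
        labels = Yz.index["primary_emotion"].to_numpy()
        a = anova_eta_squared(hr, labels)
        anova = {
            "F": a.F,
            "df": [a.df_between, a.df_within],
            "p_value": a.p_value,
            "eta_squared": a.eta_squared,
        }

    bundle = ReportBundle(
        significance=sig,
        covariance_explained=cov,
        behavior_stability=stability_df,
        centroids=centroids_df,
        cluster_newick=cluster_newick,
        efa_loadings=efa_df,
        lv_emotion=lv_emotion,
        anova=anova,
        config=config,
        n_retained=n_retained,
    )
    bundle.write(config.output_dir)
    if config.run_inference and n_retained > 0:
        bundle.written += write_salience_maps(
            model, brain, Path(config.output_dir) / "maps", range(n_retained)
        )
    return bundle
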