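"""End-to-end orchestration.

``run_pipeline`` executes preprocess -> feature maps -> gridding ->
models -> consistency -> ratings -> physio on a (simulated or loaded)
study, writes TSV/JSON results plus a run manifest, and is bit-identical
under a fixed master seed.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .consistency import consistency_alpha, icc, per_unit_fits, pmm_impute
from .glmm import MODEL_TERMS, bootstrap_series
from .gridding import build_observation_matrix, label_frames, looked_at_saliency
from .io import write_table
from .preprocess import TrialGaze, align_gaze_to_frames, correct_trials
from .ratings import reclassify_all
from .physio import trial_autonomic_summary
from .synthetic import SimulatedStudy, StudyConfig, make_study

log = logging.getLogger("gazescape")


@dataclass
class PipelineConfig:
    study_dir: str | None = None  # load a saved study; otherwise simulate
    study: StudyConfig = field(default_factory=StudyConfig)
    seed: int = 0
    n_bootstrap: int = 10
    m_imputations: int = 5
    output_dir: str = "results/run"

    def __post_init__(self) -> None:
        if self.n_bootstrap < 2:
            raise ValueError("n_bootstrap must be >= 2")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        study_raw = raw.pop("study", None)
        cfg = cls(**raw)
        if study_raw:
            from .synthetic import GazeSimOptions, GroundTruth, SceneSpec

            kwargs = dict(study_raw)
            if "scene" in kwargs:
                kwargs["scene"] = SceneSpec(**kwargs["scene"])
            if "truth" in kwargs:
                kwargs["truth"] = GroundTruth(**kwargs["truth"])
            if "gaze" in kwargs:
                kwargs["gaze"] = GazeSimOptions(**kwargs["gaze"])
            cfg.study = StudyConfig(**kwargs)
        return cfg


def preprocess_study_gaze(study: SimulatedStudy) -> pd.DataFrame:
    """Raw gaze -> drift-corrected per-frame gaze table for all trials."""
    video_px = (study.config.scene.width_px, study.config.scene.height_px)
    fps = study.config.scene.fps
    n_frames = study.config.scene.n_frames
    frames_parts = []
    for pid, pgrp in study.gaze.groupby("participant", sort=True):
        trials = [
            TrialGaze(pid, vid, g["t_ms"].to_numpy(), g["x_px"].to_numpy(),
                      g["y_px"].to_numpy(), g["valid"].to_numpy())
            for vid, g in pgrp.groupby("video", sort=True)
        ]
        for trial in correct_trials(trials, video_px=video_px):
            frames_parts.append(
                align_gaze_to_frames(trial, fps=fps, n_frames=n_frames, video_px=video_px)
            )
    return pd.concat(frames_parts, ignore_index=True)


def run_pipeline(config: PipelineConfig) -> dict:
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": []}

    def stage(name: str):
        log.info("stage: %s", name)
        manifest["stages"].append(name)

    stage("study")
    if config.study_dir:
        from .io import load_study

        study = load_study(config.study_dir)
    else:
        study = make_study(config.study, seed=config.seed)
    grid = study.config.grid

    stage("preprocess")
    frame_gaze = preprocess_study_gaze(study)
    labels = label_frames(frame_gaze, grid)

    stage("looked_at_saliency")
    sal_rows = []
    for (pid, vid), grp in frame_gaze.groupby(["participant", "video"], sort=True):
        try:
            m = looked_at_saliency(grp, study.maps[vid]["saliency"])
        except ValueError:
            continue
        sal_rows.append((pid, vid, study.social[vid], m))
    looked = pd.DataFrame(sal_rows, columns=["participant", "video", "social", "mean_saliency"])
    write_table(looked, out_dir / "looked_at_saliency.tsv")

    stage("models")
    social_videos = [v for v in study.video_ids if study.social[v]]
    social_labels = labels.loc[labels["video"].isin(social_videos)].reset_index(drop=True)
    summary = bootstrap_series(
        study.cell_tables, social_labels, study.ratings, grid,
        n_iter=config.n_bootstrap, seed=config.seed, models=MODEL_TERMS,
    )
    write_table(summary.to_frame(), out_dir / "model_weights.tsv")

    stage("consistency")
    obs = build_observation_matrix(
        study.cell_tables, social_labels, study.ratings, seed=config.seed, grid=grid
    )
    weights = per_unit_fits(obs.rows)
    if weights.n_missing and weights.n_missing < len(weights.entries):
        completed = pmm_impute(weights, m=config.m_imputations, seed=config.seed)
    else:
        completed = [weights]
    try:
        alphas = consistency_alpha(completed)
        alpha_out = {
            t: {"alpha": a.alpha, "ci": list(a.ci), "n_datasets": a.n_datasets}
            for t, a in alphas.items()
        }
    except ValueError as exc:  # mini studies can be too small for alpha
        alpha_out = {"error": str(exc)}
    manifest["n_unit_fits"] = len(weights.entries) // 3
    manifest["n_nonconverged_units"] = int(weights.n_missing // 3)

    stage("ratings")
    categories = reclassify_all(study.ratings)
    categories.to_csv(out_dir / "valence_categories.csv", index=False)
    rating_mat = study.ratings.pivot(index="participant", columns="video", values="valence")
    icc_val, icc_ci = icc(rating_mat)

    stage("physio")
    phys_rows = []
    for pid, ph in study.physio.items():
        for j, onset in enumerate(ph.onsets_s):
            vid = study.video_ids[j]
            try:
                s = trial_autonomic_summary(ph.r_times, ph.eda_t_s, ph.eda_uS, onset)
            except ValueError:
                continue
            phys_rows.append((pid, vid, s.hr_mean_delta, s.eda_mean_delta))
    write_table(
        pd.DataFrame(phys_rows, columns=["participant", "video", "hr_delta_bpm", "eda_delta_uS"]),
        out_dir / "physio_summary.tsv",
    )

    results = {
        "looked_at_saliency_mean": float(looked["mean_saliency"].mean()),
        "model_summary": {
            "n_iterations": summary.n_iterations,
            "n_failed": summary.n_failed,
            "r2_mean": summary.r2_mean,
            "term_mean": summary.term_mean,
            "term_ci": {str(i + 1): {t: list(ci) for t, ci in d.items()}
                         for i, d in enumerate(summary.term_ci)},
        },
        "consistency_alpha": alpha_out,
        "icc_valence": {"icc": icc_val, "ci": list(icc_ci)},
    }
    manifest["n_models"] = len(MODEL_TERMS)
    (out_dir / "summary.json").write_text(json.dumps(results, indent=2, sort_keys=True))
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return results
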