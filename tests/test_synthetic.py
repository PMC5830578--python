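"""Generators: scenes, gaze, ratings, whole-study assembly."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace
from scipy.stats import chisquare

from gazescape.features import FeatureMapStack, normalize_mean1
from gazescape.gridding import (
    GridSpec,
    aggregate_to_grid,
    build_observation_matrix,
    label_frames,
    looked_at_saliency,
)
from gazescape.preprocess import TrialGaze, align_gaze_to_frames
from gazescape.synthetic import (
    GazeSimOptions,
    GroundTruth,
    SceneSpec,
    StudyConfig,
    cell_probabilities,
    default_video_means,
    draw_fixated_cells,
    make_scene,
    make_study,
    simulate_gaze,
    simulate_ratings,
)


class TestMakeScene:
    def test_empty_scene_uniform_frames_empty_roi(self):
        spec = SceneSpec(width_px=64, height_px=36, n_frames=5, n_blobs=0, n_heads=0)
        frames, roi = make_scene(spec, seed=0)
        assert roi.empty
        assert np.allclose(frames, 0.5)

    def test_one_head_one_roi_row_per_frame(self):
        spec = SceneSpec(width_px=64, height_px=36, n_frames=7, n_blobs=1, n_heads=1,
                         head_radius_px=5)
        _, roi = make_scene(spec, seed=1)
        assert len(roi) == 7
        assert sorted(roi["frame"]) == list(range(7))

    def test_deterministic_given_seed(self):
        spec = SceneSpec(width_px=64, height_px=36, n_frames=4)
        a, roi_a = make_scene(spec, seed=5)
        b, roi_b = make_scene(spec, seed=5)
        assert np.array_equal(a, b)
        pd.testing.assert_frame_equal(roi_a, roi_b)

    def test_trajectories_stay_in_bounds(self):
        spec = SceneSpec(width_px=64, height_px=36, n_frames=200, n_heads=2,
                         head_radius_px=6, motion_speed_px_per_frame=5.0)
        _, roi = make_scene(spec, seed=2)
        assert (roi["cx"] >= roi["r"]).all() and (roi["cx"] <= 64 - 1 - roi["r"] + 1e-9).all()
        assert (roi["cy"] >= roi["r"]).all() and (roi["cy"] <= 36 - 1 - roi["r"] + 1e-9).all()


def _random_cell_tables(rng, n_frames, grid):
    return {
        name: rng.uniform(size=(n_frames, grid.n_cells))
        for name in ("centrality", "saliency", "roi")
    }


class TestCellSelection:
    def test_null_model_uniform_over_576_cells(self):
        grid = GridSpec(cell_px=10, n_cols=32, n_rows=18)
        rng = np.random.default_rng(0)
        tables = _random_cell_tables(rng, 1, grid)
        truth = GroundTruth(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
        probs = np.repeat(cell_probabilities(tables, truth), 100_000 // 576 * 576 // 1, 0)[:100_000]
        cells = draw_fixated_cells(probs, rng)
        counts = np.bincount(cells, minlength=576)
        assert chisquare(counts).pvalue > 0.01

    def test_dominant_centrality_picks_central_cell(self):
        # odd cell counts give a unique central cell for the dominance limit
        from gazescape.features import centrality_map

        grid = GridSpec(cell_px=10, n_cols=9, n_rows=5)
        rng = np.random.default_rng(1)
        tables = _random_cell_tables(rng, 1, grid)
        tables["centrality"] = aggregate_to_grid(centrality_map(90, 50), grid)
        truth = GroundTruth(10.0, 0.0, 0.0, 0.0, 0.0, 0.0)
        probs = np.repeat(cell_probabilities(tables, truth), 2000, axis=0)
        cells = draw_fixated_cells(probs, rng)
        top = np.argmax(tables["centrality"][0])
        assert top == 2 * grid.n_cols + 4  # centre cell of the 9 x 5 grid
        assert (cells == top).mean() > 0.99

    def test_zero_variance_predictor_dropped_with_warning(self):
        grid = GridSpec(cell_px=10, n_cols=32, n_rows=18)
        rng = np.random.default_rng(2)
        tables = _random_cell_tables(rng, 3, grid)
        tables["roi"] = np.zeros_like(tables["roi"])
        with pytest.warns(UserWarning, match="roi"):
            cell_probabilities(tables, GroundTruth())


class TestSimulateGaze:
    def test_stream_structure_and_baseline_segment(self):
        grid = GridSpec(cell_px=10, n_cols=32, n_rows=18)
        rng = np.random.default_rng(3)
        tables = _random_cell_tables(rng, 30, grid)
        samples, cells = simulate_gaze(
            tables, GroundTruth(), "p00", "v00", grid, fps=30.0, rng=rng
        )
        assert cells.shape == (30,)
        assert (samples["t_ms"] < 0).any() and (samples["t_ms"] >= 0).any()
        stim = samples.loc[samples["t_ms"] >= 0]
        assert stim["valid"].all()
        w, h = grid.video_px
        assert stim["x_px"].between(0, w).all() and stim["y_px"].between(0, h).all()

    def test_null_gaze_mean_looked_at_saliency_near_one(self):
        # beta = 0, no drift/jitter: gaze lands on uniformly drawn cells, so
        # the mean saliency at the gazed pixel converges to the map mean of 1
        grid = GridSpec.for_video(64, 36)
        n_frames = 4000
        rng = np.random.default_rng(4)
        sal = normalize_mean1(rng.uniform(0.2, 1.8, size=(n_frames, 36, 64)))
        tables = {
            "centrality": rng.uniform(size=(n_frames, grid.n_cells)),
            "saliency": aggregate_to_grid(sal, grid),
            "roi": rng.uniform(size=(n_frames, grid.n_cells)),
        }
        truth = GroundTruth(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
        opts = GazeSimOptions(jitter_px=0.0, drift_sd_px=0.0, baseline_contamination=0.0)
        samples, _ = simulate_gaze(tables, truth, "p", "v", grid, 30.0, rng, options=opts)
        stim = samples.loc[samples["t_ms"] >= 0]
        trial = TrialGaze("p", "v", stim["t_ms"].to_numpy(), stim["x_px"].to_numpy(),
                          stim["y_px"].to_numpy(), stim["valid"].to_numpy())
        frame_gaze = align_gaze_to_frames(trial, fps=30.0, n_frames=n_frames, video_px=(64, 36))
        assert looked_at_saliency(frame_gaze, sal) == pytest.approx(1.0, abs=0.05)


class TestSimulateRatings:
    def test_noise_free_reproduces_rounded_means(self):
        means = np.array([2.0, 4.4, 6.6, 8.0])
        df = simulate_ratings(5, 4, means, rater_noise_sd=0.0, seed=0, rater_bias_sd=0.0)
        expected = np.rint(means).astype(int)
        for i in range(5):
            got = df.loc[df["participant"] == f"p{i:02d}"].sort_values("video")["valence"]
            assert list(got) == list(expected)

    def test_huge_noise_destroys_consistency(self):
        from gazescape.consistency import icc

        means = default_video_means(90, seed=1)
        df = simulate_ratings(32, 90, means, rater_noise_sd=50.0, seed=1)
        mat = df.pivot(index="participant", columns="video", values="valence")
        val, _ = icc(mat)
        assert abs(val) < 0.1

    def test_default_noise_hits_icc_target(self):
        from gazescape.consistency import icc

        means = default_video_means(90, seed=2)
        df = simulate_ratings(32, 90, means, rater_noise_sd=1.15, seed=2)
        mat = df.pivot(index="participant", columns="video", values="valence")
        val, _ = icc(mat)
        assert val == pytest.approx(0.65, abs=0.1)

    def test_out_of_scale_means_rejected(self):
        with pytest.raises(ValueError):
            simulate_ratings(2, 2, np.array([0.5, 5.0]), 1.0, 0)


class TestMakeStudy:
    def test_mini_study_shapes(self, mini_study):
        cfg = mini_study.config
        assert len(mini_study.video_ids) == cfg.n_videos
        assert sum(mini_study.social.values()) == cfg.n_social
        assert len(mini_study.participants) == cfg.n_participants
        assert set(mini_study.ratings.groupby(["participant", "video"]).size()) == {1}

    def test_seed_reproducibility(self):
        cfg = StudyConfig(
            n_participants=2, n_videos=2, n_social=1,
            scene=SceneSpec(width_px=64, height_px=36, n_frames=12),
        )
        a = make_study(cfg, seed=3)
        b = make_study(cfg, seed=3)
        pd.testing.assert_frame_equal(a.gaze, b.gaze)
        pd.testing.assert_frame_equal(a.ratings, b.ratings)
        for vid in a.video_ids:
            assert np.array_equal(a.frames[vid], b.frames[vid])
            assert np.array_equal(a.physio["p00"].r_times, b.physio["p00"].r_times)

    def test_observation_row_count_arithmetic(self):
        # drift-free generation: every post-onset frame usable, so the matrix
        # has participants x videos x usable-frames x 2 rows exactly; the
        # 150 ms onset exclusion removes frames 0-3 entirely at 30 fps
        from gazescape.pipeline import preprocess_study_gaze

        cfg = StudyConfig(
            n_participants=2, n_videos=3, n_social=2,
            scene=SceneSpec(width_px=64, height_px=36, n_frames=30),
            gaze=GazeSimOptions(jitter_px=0.2, drift_sd_px=0.0, baseline_contamination=0.0),
        )
        study = make_study(cfg, seed=7)
        labels = label_frames(preprocess_study_gaze(study), cfg.grid)
        obs = build_observation_matrix(
            study.cell_tables, labels, study.ratings, seed=0, grid=cfg.grid
        )
        assert len(obs) == 2 * 3 * (30 - 4) * 2

    def test_mini_study_rows_bounded_by_arithmetic(self, mini_study, mini_labels):
        # with drift and baseline contamination on, a few edge-cell frames may
        # drop out, but never more than a small fraction
        cfg = mini_study.config
        obs = build_observation_matrix(
            mini_study.cell_tables, mini_labels, mini_study.ratings,
            seed=0, grid=cfg.grid,
        )
        full = cfg.n_participants * cfg.n_videos * (cfg.scene.n_frames - 4) * 2
        assert 0.97 * full <= len(obs) <= full

    def test_gaze_samples_in_bounds_or_invalid(self, mini_study):
        g = mini_study.gaze
        w, h = mini_study.config.scene.width_px, mini_study.config.scene.height_px
        ok = g.loc[g["valid"] & (g["t_ms"] >= 0)]
        assert ok["x_px"].between(0, w).all() and ok["y_px"].between(0, h).all()
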