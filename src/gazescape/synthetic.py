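"""Synthetic study generator with known ground truth.

Emulates the ingredients of a free-viewing video experiment so every
downstream stage can be tested without external data:

* scenes — moving Gaussian luminance blobs on a grey background, plus
  circular "head" discs tracked as social ROIs (reflecting boundaries);
* gaze — per video frame one grid cell is fixated, drawn from a softmax
  over cells whose linear predictor combines the standardized cell-level
  centrality, saliency and ROI values with ground-truth weights; samples
  are placed at the cell centre with small jitter. Each trial carries a
  pre-stimulus fixation segment with a per-trial drift offset and
  configurable blink/outlier contamination, so drift correction has
  something to correct;
* ratings — video-level means plus rater bias and noise, rounded and
  clamped to the 1-9 scale, with noise calibrated to a target
  inter-rater consistency;
* physiology — R-peak trains whose rate dips by a programmed amount
  after each stimulus onset, and an EDA trace with stimulus-locked
  exponentially decaying responses.

Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from .features import (
    FeatureMapStack,
    centrality_map,
    normalize_mean1,
    roi_mask_stack,
    saliency_pipeline,
    temporal_blur,
)
from .gridding import PREDICTORS, GridSpec, aggregate_to_grid


@dataclass(frozen=True)
class SceneSpec:
    width_px: int = 320
    height_px: int = 180
    n_frames: int = 60
    fps: float = 30.0
    n_blobs: int = 3
    n_heads: int = 1
    head_radius_px: float = 18.0
    motion_speed_px_per_frame: float = 2.0

    def __post_init__(self) -> None:
        if min(self.width_px, self.height_px, self.n_frames) < 1:
            raise ValueError("dimensions and frame count must be >= 1")
        if self.head_radius_px <= 0:
            raise ValueError("head_radius_px must be positive")


#: Full-experiment scene geometry: 1280 x 720 at 30 fps for 20 s.
FULL_SCALE_SCENE = SceneSpec(width_px=1280, height_px=720, n_frames=600, fps=30.0)


@dataclass(frozen=True)
class GroundTruth:
    beta_centrality: float = 0.3
    beta_saliency: float = 0.5
    beta_roi: float = 0.5
    beta_interaction: float = 0.0
    participant_sd: float = 0.3
    video_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.participant_sd < 0 or self.video_sd < 0:
            raise ValueError("random-intercept SDs must be non-negative")

    @property
    def betas(self) -> dict[str, float]:
        return {
            "centrality": self.beta_centrality,
            "saliency": self.beta_saliency,
            "roi": self.beta_roi,
            "interaction": self.beta_interaction,
        }


def _reflected_position(p0: float, v: float, t: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Constant-velocity motion with reflecting boundaries on [lo, hi]."""
    span = hi - lo
    if span <= 0:
        return np.full_like(t, (lo + hi) / 2.0)
    x = (p0 - lo) + v * t
    period = 2.0 * span
    x = np.mod(x, period)
    return lo + np.where(x <= span, x, period - x)


def make_scene(spec: SceneSpec, seed: int) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a scene; returns (frames, ROI table).

    Frames are float32 RGB in [0, 1], shape (n_frames, h, w, 3). The ROI
    table has one row per head per frame: (frame, cx, cy, r). Blob and
    head trajectories reflect off the frame bounds.
    """
    rng = np.random.default_rng(seed)
    w, h, n = spec.width_px, spec.height_px, spec.n_frames
    t = np.arange(n, dtype=float)
    frames = np.full((n, h, w, 3), 0.5, dtype=np.float32)
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float32)

    for _ in range(spec.n_blobs):
        sigma = rng.uniform(0.04, 0.10) * min(w, h)
        amp = rng.uniform(0.2, 0.45)
        tint = rng.uniform(0.5, 1.0, size=3)
        angle = rng.uniform(0, 2 * np.pi)
        vx = spec.motion_speed_px_per_frame * np.cos(angle)
        vy = spec.motion_speed_px_per_frame * np.sin(angle)
        px = _reflected_position(rng.uniform(0, w), vx, t, 0.0, float(w - 1))
        py = _reflected_position(rng.uniform(0, h), vy, t, 0.0, float(h - 1))
        for k in range(n):
            g = np.exp(-((xx - px[k]) ** 2 + (yy - py[k]) ** 2) / (2 * sigma**2))
            frames[k] += (amp * g)[..., None] * tint[None, None, :]

    roi_rows = []
    head_tint = np.array([0.85, 0.65, 0.5], dtype=np.float32)
    for _ in range(spec.n_heads):
        r = spec.head_radius_px
        angle = rng.uniform(0, 2 * np.pi)
        speed = 0.6 * spec.motion_speed_px_per_frame
        px = _reflected_position(rng.uniform(r, w - r), speed * np.cos(angle), t, r, float(w - 1 - r))
        py = _reflected_position(rng.uniform(r, h - r), speed * np.sin(angle), t, r, float(h - 1 - r))
        for k in range(n):
            disc = (xx - px[k]) ** 2 + (yy - py[k]) ** 2 <= r * r
            frames[k][disc] = 0.5 * frames[k][disc] + 0.5 * head_tint
            roi_rows.append((k, float(px[k]), float(py[k]), float(r)))
    np.clip(frames, 0.0, 1.0, out=frames)
    roi = pd.DataFrame(roi_rows, columns=["frame", "cx", "cy", "r"])
    return frames, roi


def proxy_saliency(frames: np.ndarray, sd_frames: float = 2.0) -> FeatureMapStack:
    """Fast conspicuity stand-in for the graph-based saliency chain.

    Local luminance deviation from the frame mean plus flicker, temporally
    blurred and mean-1 normalized. Used by the generator so large
    simulated studies do not pay the full graph-based cost per frame; the
    graph-based algorithm is exercised separately and available via
    ``saliency_mode='gbvs'``.
    """
    lum = frames.mean(axis=-1) if frames.ndim == 4 else np.asarray(frames, float)
    dev = np.abs(lum - lum.mean(axis=(1, 2), keepdims=True))
    flick = np.zeros_like(lum)
    flick[1:] = np.abs(np.diff(lum, axis=0))
    raw = dev + flick + 1e-6
    return normalize_mean1(temporal_blur(FeatureMapStack(raw, kind="saliency"), sd_frames))


def cell_probabilities(
    cell_predictors: dict[str, np.ndarray], truth: GroundTruth, offset: float = 0.0
) -> np.ndarray:
    """Softmax cell-selection probabilities per frame.

    Cell predictors are z-standardized over all frames x cells of the
    video; a predictor with zero variance is dropped with a warning. The
    linear predictor is beta . z plus the (constant) intercept offset,
    which cancels in the within-frame softmax.
    """
    betas = {
        "centrality": truth.beta_centrality,
        "saliency": truth.beta_saliency,
        "roi": truth.beta_roi,
    }
    z: dict[str, np.ndarray] = {}
    eta = np.zeros_like(next(iter(cell_predictors.values())), dtype=float) + offset
    for name, beta in betas.items():
        x = np.asarray(cell_predictors[name], float)
        sd = x.std()
        if sd <= 1e-12:
            warnings.warn(f"predictor {name!r} has zero variance; dropped from the generator")
            continue
        z[name] = (x - x.mean()) / sd
        eta += beta * z[name]
    if truth.beta_interaction and "saliency" in z and "roi" in z:
        eta += truth.beta_interaction * z["saliency"] * z["roi"]
    eta -= eta.max(axis=1, keepdims=True)
    p = np.exp(eta)
    p /= p.sum(axis=1, keepdims=True)
    return p


def draw_fixated_cells(probs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One cell index per frame from per-frame probability rows."""
    u = rng.random(probs.shape[0])
    cum = np.cumsum(probs, axis=1)
    return (u[:, None] > cum).sum(axis=1)


@dataclass
class GazeSimOptions:
    """Gaze placement around the fixated cell centre.

    ``jitter_px`` defaults to 5 px at the full 40 px cell size; scaled-down
    scenes should scale it with the cell (see :class:`StudyConfig`), keeping
    the jitter-to-cell ratio of the full geometry.
    """

    sampling_rate_hz: float = 250.0
    jitter_px: float = 5.0
    baseline_ms: float = 1000.0
    baseline_contamination: float = 0.10
    drift_sd_px: float = 8.0
    outlier_px: float = 200.0


def simulate_gaze(
    cell_predictors: dict[str, np.ndarray],
    truth: GroundTruth,
    participant: str,
    video: str,
    grid: GridSpec,
    fps: float,
    rng: np.random.Generator,
    options: GazeSimOptions | None = None,
    intercept_offset: float = 0.0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Simulate one trial's raw gaze stream.

    Returns (samples, true fixated cell per frame). The samples table has
    columns participant, video, t_ms, x_px, y_px, valid and includes a
    pre-stimulus fixation segment (t_ms < 0) at the frame centre shifted
    by a per-trial drift offset and contaminated by blinks/outliers. The
    same drift applies to the stimulus segment, so baseline subtraction
    recovers the generated positions.
    """
    opt = options or GazeSimOptions()
    if opt.sampling_rate_hz < fps:
        raise ValueError("sampling rate must be at least the frame rate")
    probs = cell_probabilities(cell_predictors, truth, offset=intercept_offset)
    n_frames = probs.shape[0]
    cells = draw_fixated_cells(probs, rng)
    w, h = grid.video_px
    drift = rng.normal(0.0, opt.drift_sd_px, size=2)

    step_ms = 1000.0 / opt.sampling_rate_hz
    t_stim = np.arange(0.0, n_frames / fps * 1000.0, step_ms)
    frame_of = np.minimum((t_stim / 1000.0 * fps).astype(int), n_frames - 1)
    cols = cells[frame_of] % grid.n_cols
    rows = cells[frame_of] // grid.n_cols
    cx = (cols + 0.5) * grid.cell_px
    cy = (rows + 0.5) * grid.cell_px
    x = cx + rng.normal(0, opt.jitter_px, size=cx.size) + drift[0]
    y = cy + rng.normal(0, opt.jitter_px, size=cy.size) + drift[1]
    np.clip(x, 0, w - 1e-6, out=x)
    np.clip(y, 0, h - 1e-6, out=y)
    stim = pd.DataFrame(
        {"t_ms": t_stim, "x_px": x, "y_px": y, "valid": True}
    )

    t_base = np.arange(-opt.baseline_ms, 0.0, step_ms)
    bx = w / 2.0 + drift[0] + rng.normal(0, 2.0, size=t_base.size)
    by = h / 2.0 + drift[1] + rng.normal(0, 2.0, size=t_base.size)
    valid = np.ones(t_base.size, dtype=bool)
    contaminated = rng.random(t_base.size) < opt.baseline_contamination
    as_blink = rng.random(t_base.size) < 0.5
    valid[contaminated & as_blink] = False
    outlier = contaminated & ~as_blink
    bx[outlier] += rng.choice([-1, 1], outlier.sum()) * opt.outlier_px
    by[outlier] += rng.choice([-1, 1], outlier.sum()) * opt.outlier_px
    base = pd.DataFrame({"t_ms": t_base, "x_px": bx, "y_px": by, "valid": valid})

    out = pd.concat([base, stim], ignore_index=True)
    out.insert(0, "video", video)
    out.insert(0, "participant", participant)
    return out, cells


def simulate_ratings(
    n_participants: int,
    n_videos: int,
    video_means: np.ndarray,
    rater_noise_sd: float,
    seed: int,
    rater_bias_sd: float = 0.5,
) -> pd.DataFrame:
    """Ratings = round(clamp(video mean + rater bias + noise, 1, 9)).

    With the default video-mean spread (uniform on [2, 8]) a noise SD of
    about 1.15 and bias SD 0.5 yield a single-rater ICC near 0.65, the
    level of agreement typical of valence ratings.
    """
    means = np.asarray(video_means, float)
    if means.shape != (n_videos,):
        raise ValueError("video_means must have length n_videos")
    if means.min() < 1 or means.max() > 9:
        raise ValueError("video_means must lie in [1, 9]")
    rng = np.random.default_rng(seed)
    bias = rng.normal(0, rater_bias_sd, size=n_participants)
    noise = rng.normal(0, rater_noise_sd, size=(n_participants, n_videos))
    raw = means[None, :] + bias[:, None] + noise
    vals = np.clip(np.rint(raw), 1, 9).astype(int)
    recs = [
        (f"p{i:02d}", f"v{j:02d}", int(vals[i, j]))
        for i in range(n_participants)
        for j in range(n_videos)
    ]
    return pd.DataFrame(recs, columns=["participant", "video", "valence"])


def default_video_means(n_videos: int, seed: int) -> np.ndarray:
    """Evenly spread valence means on [2, 8], shuffled deterministically."""
    means = np.linspace(2.0, 8.0, n_videos)
    np.random.default_rng(seed).shuffle(means)
    return means


@dataclass
class PhysioSim:
    r_times: np.ndarray
    ecg_t_s: np.ndarray
    ecg: np.ndarray
    eda_t_s: np.ndarray
    eda_uS: np.ndarray
    onsets_s: np.ndarray


def synthesize_ecg(r_times: np.ndarray, fs: float, duration_s: float) -> tuple[np.ndarray, np.ndarray]:
    """Template-beat ECG: a narrow positive R spike at each peak time."""
    t = np.arange(0.0, duration_s, 1.0 / fs)
    ecg = np.zeros_like(t)
    width = 0.012  # ~12 ms R wave
    for rt in r_times:
        ecg += np.exp(-0.5 * ((t - rt) / width) ** 2)
    return t, ecg


def simulate_physio(
    onsets_s: np.ndarray,
    hr_baseline_bpm: float = 70.0,
    deceleration_bpm: float = 5.0,
    decel_window_s: tuple[float, float] = (2.0, 7.0),
    eda_amp: float = 0.3,
    eda_baseline_uS: float = 2.0,
    seed: int = 0,
    duration_s: float | None = None,
    ecg_fs: float = 500.0,
    eda_fs: float = 50.0,
    trial_s: float = 20.0,
) -> PhysioSim:
    """Stimulus-locked autonomic traces.

    The programmed instantaneous rate is ``hr_baseline_bpm`` minus
    ``deceleration_bpm`` during ``decel_window_s`` after each onset; the
    trial-mean baseline-corrected HR change is therefore
    ``-deceleration * window_length / 20`` bpm. EDA responses are
    gamma-shaped (1 s latency, 3 s time-to-peak) scaled by ``eda_amp``.
    """
    if hr_baseline_bpm <= 0:
        raise ValueError("baseline bpm must be positive")
    onsets = np.asarray(onsets_s, float)
    if duration_s is None:
        duration_s = float(onsets.max() + trial_s + 5.0) if onsets.size else 60.0
    rng = np.random.default_rng(seed)

    def bpm_at(t: float) -> float:
        dip = 0.0
        for o in onsets:
            if o + decel_window_s[0] <= t < o + decel_window_s[1]:
                dip = deceleration_bpm
                break
        return hr_baseline_bpm - dip

    r_times = []
    t = float(rng.uniform(0, 0.5))
    while t < duration_s:
        r_times.append(t)
        t += 60.0 / bpm_at(t)
    r_times = np.asarray(r_times)
    ecg_t, ecg = synthesize_ecg(r_times, ecg_fs, duration_s)

    eda_t = np.arange(0.0, duration_s, 1.0 / eda_fs)
    eda = np.full_like(eda_t, eda_baseline_uS)
    lat, tau = 1.0, 3.0
    for o in onsets:
        rel = eda_t - o - lat
        resp = np.where(rel > 0, (rel / tau) * np.exp(1.0 - rel / tau), 0.0)
        eda += eda_amp * resp
    return PhysioSim(r_times=r_times, ecg_t_s=ecg_t, ecg=ecg,
                     eda_t_s=eda_t, eda_uS=eda, onsets_s=onsets)


# ---------------------------------------------------------------------------
# Whole-study assembly
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StudyConfig:
    """Mini-study defaults: 4 participants x 6 videos (half social), with
    scenes scaled to 320 x 180 so the 32 x 18 grid uses 10 px cells."""

    n_participants: int = 4
    n_videos: int = 6
    n_social: int = 3
    scene: SceneSpec = field(default_factory=SceneSpec)
    truth: GroundTruth = field(default_factory=GroundTruth)
    # 10 px cells -> jitter scaled from the full-scale 5 px / 40 px ratio
    gaze: GazeSimOptions = field(default_factory=lambda: GazeSimOptions(jitter_px=1.25))
    saliency_mode: str = "proxy"  # or "gbvs"
    rater_noise_sd: float = 1.15
    hr_baseline_bpm: float = 70.0
    deceleration_bpm: float = 5.0
    eda_amp: float = 0.3
    keep_frames: bool = True

    def __post_init__(self) -> None:
        if self.n_social > self.n_videos:
            raise ValueError("n_social cannot exceed n_videos")
        if self.saliency_mode not in ("proxy", "gbvs"):
            raise ValueError("saliency_mode must be 'proxy' or 'gbvs'")

    @property
    def grid(self) -> GridSpec:
        return GridSpec.for_video(self.scene.width_px, self.scene.height_px)


@dataclass
class SimulatedStudy:
    config: StudyConfig
    truth: GroundTruth
    video_ids: list[str]
    social: dict[str, bool]
    frames: dict[str, np.ndarray]
    roi: dict[str, pd.DataFrame]
    maps: dict[str, dict[str, FeatureMapStack]]
    cell_tables: dict[str, dict[str, np.ndarray]]
    gaze: pd.DataFrame
    true_cells: dict[tuple[str, str], np.ndarray]
    ratings: pd.DataFrame
    physio: dict[str, PhysioSim]

    @property
    def participants(self) -> list[str]:
        return sorted(self.gaze["participant"].unique())

    def save(self, directory) -> None:
        from . import io as gio

        gio.save_study(self, directory)


def make_study(config: StudyConfig, seed: int) -> SimulatedStudy:
    """Generate a full synthetic study (scenes, maps, gaze, ratings, physio)."""
    root = np.random.SeedSequence(seed)
    s_scene, s_gaze, s_rate, s_phys, s_int = root.spawn(5)
    truth = replace(config.truth, seed=seed)
    grid = config.grid

    video_ids = [f"v{j:02d}" for j in range(config.n_videos)]
    social = {vid: j < config.n_social for j, vid in enumerate(video_ids)}
    frames: dict[str, np.ndarray] = {}
    roi: dict[str, pd.DataFrame] = {}
    maps: dict[str, dict[str, FeatureMapStack]] = {}
    cell_tables: dict[str, dict[str, np.ndarray]] = {}
    scene_seeds = s_scene.generate_state(config.n_videos)
    for j, vid in enumerate(video_ids):
        spec = config.scene if social[vid] else replace(config.scene, n_heads=0)
        frm, ann = make_scene(spec, int(scene_seeds[j] % 2**31))
        if config.keep_frames:
            frames[vid] = frm
        roi[vid] = ann
        sal = (
            saliency_pipeline(frm)
            if config.saliency_mode == "gbvs"
            else proxy_saliency(frm)
        )
        cen = centrality_map(spec.width_px, spec.height_px, n_frames=spec.n_frames)
        msk = roi_mask_stack(ann, spec.width_px, spec.height_px, spec.n_frames)
        maps[vid] = {"centrality": cen, "saliency": sal, "roi": msk}
        cell_tables[vid] = {name: aggregate_to_grid(maps[vid][name], grid) for name in PREDICTORS}

    part_ids = [f"p{i:02d}" for i in range(config.n_participants)]
    rng_int = np.random.default_rng(s_int)
    a_p = rng_int.normal(0, truth.participant_sd, size=config.n_participants)
    b_v = rng_int.normal(0, truth.video_sd, size=config.n_videos)
    gaze_parts = []
    true_cells: dict[tuple[str, str], np.ndarray] = {}
    gaze_streams = s_gaze.spawn(config.n_participants * config.n_videos)
    k = 0
    for i, pid in enumerate(part_ids):
        for j, vid in enumerate(video_ids):
            with warnings.catch_warnings():
                # non-social videos have an all-zero ROI channel by design
                warnings.simplefilter("ignore")
                samples, cells = simulate_gaze(
                    cell_tables[vid], truth, pid, vid, grid, config.scene.fps,
                    np.random.default_rng(gaze_streams[k]), options=config.gaze,
                    intercept_offset=float(a_p[i] + b_v[j]),
                )
            gaze_parts.append(samples)
            true_cells[(pid, vid)] = cells
            k += 1
    gaze = pd.concat(gaze_parts, ignore_index=True)

    means = default_video_means(config.n_videos, int(s_rate.generate_state(1)[0] % 2**31))
    ratings = simulate_ratings(
        config.n_participants, config.n_videos, means, config.rater_noise_sd,
        int(s_rate.generate_state(2)[1] % 2**31),
    )

    physio: dict[str, PhysioSim] = {}
    # physiology follows the protocol's 20 s trial structure even when the
    # rendered scenes are shorter; the autonomic summaries cover 20 s windows
    trial_s = 20.0
    onsets = 10.0 + np.arange(config.n_videos) * (trial_s + 10.0)
    phys_seeds = s_phys.generate_state(config.n_participants)
    for i, pid in enumerate(part_ids):
        physio[pid] = simulate_physio(
            onsets, hr_baseline_bpm=config.hr_baseline_bpm,
            deceleration_bpm=config.deceleration_bpm, eda_amp=config.eda_amp,
            seed=int(phys_seeds[i] % 2**31), trial_s=trial_s,
        )

    return SimulatedStudy(
        config=config, truth=truth, video_ids=video_ids, social=social,
        frames=frames, roi=roi, maps=maps, cell_tables=cell_tables,
        gaze=gaze, true_cells=true_cells, ratings=ratings, physio=physio,
    )


def ground_truth_json(truth: GroundTruth) -> str:
    return json.dumps(asdict(truth), indent=2, sort_keys=True)
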