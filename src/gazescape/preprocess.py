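"""Raw gaze cleaning.

Each trial carries a pre-stimulus fixation-cross segment (t_ms < 0) and a
stimulation segment. Cleaning proceeds per participant:

1. a per-trial baseline is the mean valid gaze position in the last
   300 ms before stimulus onset, after a recursive outlier trim per axis;
2. trials whose baseline window contains blinks (invalid samples) get the
   mean of that participant's valid baselines instead;
3. the offset of the baseline from the fixation-cross position (screen
   centre) is subtracted from every sample — drift correction;
4. the first 150 ms after stimulus onset are excluded (minimum reaction
   time to leave the fixation cross);
5. samples are averaged within video-frame intervals for modelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ONSET_EXCLUSION_MS = 150.0
BASELINE_WINDOW_MS = 300.0


@dataclass
class TrialGaze:
    """One participant x video gaze stream, onset-relative times in ms."""

    participant: str
    video: str
    t_ms: np.ndarray
    x_px: np.ndarray
    y_px: np.ndarray
    valid: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.x_px = np.asarray(self.x_px, dtype=float)
        self.y_px = np.asarray(self.y_px, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.t_ms)
        if not (len(self.x_px) == len(self.y_px) == len(self.valid) == n):
            raise ValueError("sample arrays must have equal length")
        if np.any(np.diff(self.t_ms) <= 0):
            raise ValueError("t_ms must be strictly increasing")


@dataclass
class BaselineResult:
    bx_px: float
    by_px: float
    valid: bool
    n_used: tuple[int, int]  # samples retained on (x, y)

    def __post_init__(self) -> None:
        if self.valid and not (np.isfinite(self.bx_px) and np.isfinite(self.by_px)):
            raise ValueError("valid baseline must have finite coordinates")


def recursive_outlier_trim(values, return_flag: bool = False):
    """Recursive min/max trimming with a 3-SD re-entry test.

    Each round removes the current minimum and maximum from the working
    multiset, then tests each removed value against mean +/- 3 SD of the
    remaining values (sample SD, n-1 denominator; with SD = 0 only values
    equal to the mean re-enter). Values passing the test re-enter; the
    recursion stops once both the removed minimum and maximum pass.
    Returns the retained values (input order preserved).
    """
    arr = np.asarray(values, dtype=float)
    finite = np.isfinite(arr)
    work = arr[finite]
    if work.size < 3:
        kept = arr[finite]
        return (kept, True) if return_flag else kept

    keep = np.ones(work.size, dtype=bool)
    while keep.sum() >= 3:
        idx = np.flatnonzero(keep)
        vals = work[idx]
        i_min = idx[np.argmin(vals)]
        i_max = idx[np.argmax(vals)]
        keep[i_min] = keep[i_max] = False
        rest = work[keep]
        if rest.size < 2:
            keep[i_min] = keep[i_max] = True
            break
        mu = rest.mean()
        sd = rest.std(ddof=1)
        ok_min = abs(work[i_min] - mu) <= 3.0 * sd
        ok_max = abs(work[i_max] - mu) <= 3.0 * sd
        if ok_min:
            keep[i_min] = True
        if ok_max:
            keep[i_max] = True
        if ok_min and ok_max:
            break
    kept = work[keep]
    return (kept, False) if return_flag else kept


def compute_baseline(trial: TrialGaze, window_ms: float = BASELINE_WINDOW_MS) -> BaselineResult:
    """Trimmed mean gaze in the last ``window_ms`` before stimulus onset.

    The baseline is invalid when the window is empty, contains blink
    (invalid) samples, or an axis retains no sample after trimming.
    """
    in_win = (trial.t_ms >= -window_ms) & (trial.t_ms < 0)
    if not in_win.any():
        return BaselineResult(np.nan, np.nan, False, (0, 0))
    has_blink = bool((~trial.valid[in_win]).any())
    sel = in_win & trial.valid
    if not sel.any():
        return BaselineResult(np.nan, np.nan, False, (0, 0))
    kept_x = recursive_outlier_trim(trial.x_px[sel])
    kept_y = recursive_outlier_trim(trial.y_px[sel])
    if kept_x.size == 0 or kept_y.size == 0:
        return BaselineResult(np.nan, np.nan, False, (kept_x.size, kept_y.size))
    return BaselineResult(
        float(kept_x.mean()), float(kept_y.mean()), not has_blink, (kept_x.size, kept_y.size)
    )


def correct_trials(
    trials: list[TrialGaze],
    cross_px: tuple[float, float] | None = None,
    video_px: tuple[int, int] = (1280, 720),
    onset_exclusion_ms: float = ONSET_EXCLUSION_MS,
) -> list[TrialGaze]:
    """Drift-correct one participant's trials and apply onset exclusion.

    Invalid baselines are replaced by the per-axis mean of the
    participant's valid baselines; the offset (baseline - fixation cross)
    is subtracted from all samples; samples with t_ms < 150 are dropped.
    With no valid baseline at all the trials are returned uncorrected and
    flagged in ``meta['uncorrected']``.
    """
    if cross_px is None:
        cross_px = (video_px[0] / 2.0, video_px[1] / 2.0)
    baselines = [compute_baseline(t) for t in trials]
    valid_b = [(b.bx_px, b.by_px) for b in baselines if b.valid]
    out = []
    for trial, b in zip(trials, baselines):
        keep = trial.t_ms >= onset_exclusion_ms
        meta = dict(trial.meta)
        if b.valid:
            bx, by = b.bx_px, b.by_px
            meta["baseline_imputed"] = False
        elif valid_b:
            bx = float(np.mean([v[0] for v in valid_b]))
            by = float(np.mean([v[1] for v in valid_b]))
            meta["baseline_imputed"] = True
        else:
            meta["uncorrected"] = True
            out.append(
                TrialGaze(trial.participant, trial.video, trial.t_ms[keep],
                          trial.x_px[keep], trial.y_px[keep], trial.valid[keep], meta)
            )
            continue
        dx, dy = bx - cross_px[0], by - cross_px[1]
        meta["baseline_px"] = (bx, by)
        out.append(
            TrialGaze(trial.participant, trial.video, trial.t_ms[keep],
                      trial.x_px[keep] - dx, trial.y_px[keep] - dy, trial.valid[keep], meta)
        )
    return out


def align_gaze_to_frames(
    trial: TrialGaze, fps: float = 30.0, n_frames: int | None = None,
    video_px: tuple[int, int] = (1280, 720),
) -> pd.DataFrame:
    """Average valid in-bounds samples within each video-frame interval.

    Frame k covers [k/fps, (k+1)/fps) seconds. Frames with no usable
    sample are marked missing so they can be excluded downstream.
    """
    w, h = video_px
    t_s = trial.t_ms / 1000.0
    frame_idx = np.floor(t_s * fps).astype(int)
    usable = (
        trial.valid
        & (t_s >= 0)
        & (trial.x_px >= 0) & (trial.x_px < w)
        & (trial.y_px >= 0) & (trial.y_px < h)
    )
    if n_frames is None:
        n_frames = int(frame_idx[usable].max()) + 1 if usable.any() else 0
    rows = []
    for k in range(n_frames):
        sel = usable & (frame_idx == k)
        if sel.any():
            rows.append((trial.participant, trial.video, k,
                         float(trial.x_px[sel].mean()), float(trial.y_px[sel].mean()), False))
        else:
            rows.append((trial.participant, trial.video, k, np.nan, np.nan, True))
    return pd.DataFrame(rows, columns=["participant", "video", "frame", "x_px", "y_px", "missing"])
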