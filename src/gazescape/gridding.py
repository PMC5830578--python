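"""Grid collapse and case-control observation matrix.

Predictor maps are collapsed onto a 32 x 18 grid of square cells (40 px at
full video resolution). Per frame the fixated cell (case) is paired with
exactly one uniformly drawn non-fixated cell (control), giving both
response states equal weight in the probit models. Predictors are
z-standardized over the emitted rows; the constants are stored so control
redraws during bootstrapping reuse the same machinery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import FeatureMapStack

PREDICTORS = ("centrality", "saliency", "roi")


@dataclass(frozen=True)
class GridSpec:
    """Square-cell grid covering the video exactly (no partial cells)."""

    cell_px: int = 40
    n_cols: int = 32
    n_rows: int = 18

    @property
    def n_cells(self) -> int:
        return self.n_cols * self.n_rows

    @property
    def video_px(self) -> tuple[int, int]:
        return self.n_cols * self.cell_px, self.n_rows * self.cell_px

    @classmethod
    def for_video(cls, width_px: int, height_px: int, n_cols: int = 32, n_rows: int = 18):
        if width_px % n_cols or height_px % n_rows:
            raise ValueError("video dimensions are not divisible by the grid")
        cell_w, cell_h = width_px // n_cols, height_px // n_rows
        if cell_w != cell_h:
            raise ValueError("grid cells must be square")
        return cls(cell_px=cell_w, n_cols=n_cols, n_rows=n_rows)


def aggregate_to_grid(stack: FeatureMapStack | np.ndarray, grid: GridSpec) -> np.ndarray:
    """Mean within each cell; returns (n_frames, n_cells), row-major cells."""
    values = stack.values if isinstance(stack, FeatureMapStack) else np.asarray(stack, float)
    if values.ndim == 2:
        values = values[None]
    n, h, w = values.shape
    if h != grid.n_rows * grid.cell_px or w != grid.n_cols * grid.cell_px:
        raise ValueError(
            f"map of {w}x{h} px does not tile into {grid.n_cols}x{grid.n_rows} "
            f"cells of {grid.cell_px} px"
        )
    cells = values.reshape(n, grid.n_rows, grid.cell_px, grid.n_cols, grid.cell_px).mean(axis=(2, 4))
    return cells.reshape(n, grid.n_cells)


def label_fixated_cell(x_px: float, y_px: float, grid: GridSpec) -> int:
    """Half-open cell membership: col = floor(x / cell), row-major index."""
    w, h = grid.video_px
    if not (0 <= x_px < w and 0 <= y_px < h):
        raise ValueError("gaze point outside the video")
    col = int(x_px // grid.cell_px)
    row = int(y_px // grid.cell_px)
    return row * grid.n_cols + col


def label_frames(frame_gaze: pd.DataFrame, grid: GridSpec) -> pd.DataFrame:
    """Fixated-cell labels for a per-frame gaze table; out-of-bounds -> missing."""
    out = frame_gaze.copy()
    cells = np.full(len(out), -1, dtype=int)
    w, h = grid.video_px
    for i, (x, y, miss) in enumerate(zip(out["x_px"], out["y_px"], out["missing"])):
        if miss or not (0 <= x < w and 0 <= y < h):
            continue
        cells[i] = label_fixated_cell(x, y, grid)
    out["cell"] = cells
    out["missing"] = cells < 0
    return out


@dataclass
class ObservationMatrix:
    """Long-format case-control rows plus the standardization constants."""

    rows: pd.DataFrame
    standardization: dict[str, tuple[float, float]]
    grid: GridSpec
    seed: int

    def __len__(self) -> int:
        return len(self.rows)


def full_scale_row_count(n_participants: int, n_videos: int, n_frames: int) -> int:
    """Rows in a complete case-control matrix (one case + one control per frame)."""
    return n_participants * n_videos * n_frames * 2


def _control_rng(seed: int, participant: str, video: str) -> np.random.Generator:
    """Independent seeded stream per participant x video for control draws.

    Keys use a stable digest (not the process-salted builtin hash) so the
    same seed reproduces the same controls in any session.
    """
    import hashlib

    digest = hashlib.blake2s(f"{participant}\x00{video}".encode(), digest_size=4).digest()
    key = int.from_bytes(digest, "little") % (2**31)
    return np.random.default_rng(np.random.SeedSequence([seed % (2**31), key]))


def build_observation_matrix(
    cell_tables: dict[str, dict[str, np.ndarray]],
    labels: pd.DataFrame,
    ratings: pd.DataFrame | None,
    seed: int,
    grid: GridSpec,
) -> ObservationMatrix:
    """Assemble the balanced case-control matrix with z-scored predictors.

    Parameters
    ----------
    cell_tables
        Per video: predictor name -> (n_frames, n_cells) grid values.
    labels
        Columns participant, video, frame, cell, missing (from
        :func:`label_frames`); missing frames are skipped.
    ratings
        Optional per participant x video valence ratings (columns
        participant, video, valence) attached and z-scored like predictors.
    seed
        Master seed; each participant x video gets an independent control
        stream so redraws with a new seed change only control rows.
    """
    usable = labels.loc[~labels["missing"]]
    parts = []
    for (participant, video), grp in usable.groupby(["participant", "video"], sort=True):
        rng = _control_rng(seed, str(participant), str(video))
        tables = cell_tables[video]
        frames = grp["frame"].to_numpy(int)
        fix = grp["cell"].to_numpy(int)
        # uniform control among the n_cells - 1 non-fixated cells
        draw = rng.integers(0, grid.n_cells - 1, size=len(frames))
        ctrl = np.where(draw >= fix, draw + 1, draw)
        for cells, fixated in ((fix, 1), (ctrl, 0)):
            block = pd.DataFrame(
                {
                    "participant": participant,
                    "video": video,
                    "frame": frames,
                    "cell": cells,
                    "fixated": fixated,
                }
            )
            for name in PREDICTORS:
                block[name] = tables[name][frames, cells]
            parts.append(block)
    rows = pd.concat(parts, ignore_index=True)
    rows.sort_values(["participant", "video", "frame", "fixated"],
                     ascending=[True, True, True, False], inplace=True, ignore_index=True)

    if ratings is not None:
        val = ratings.set_index(["participant", "video"])["valence"]
        rows["valence"] = val.reindex(
            pd.MultiIndex.from_arrays([rows["participant"], rows["video"]])
        ).to_numpy()

    standardization: dict[str, tuple[float, float]] = {}
    cols = list(PREDICTORS) + (["valence"] if ratings is not None else [])
    for name in cols:
        x = rows[name].to_numpy(float)
        mu, sd = float(np.mean(x)), float(np.std(x))
        standardization[name] = (mu, sd)
        if sd <= 1e-12:
            rows[name + "_z"] = 0.0
            standardization[name] = (mu, 0.0)  # degenerate predictor flag
        else:
            rows[name + "_z"] = (x - mu) / sd
    return ObservationMatrix(rows=rows, standardization=standardization, grid=grid, seed=seed)


def looked_at_saliency(
    frame_gaze: pd.DataFrame, saliency: FeatureMapStack
) -> float:
    """Mean normalized saliency at the gazed pixel over non-missing frames.

    With the per-frame mean fixed at 1, the expected value for viewing
    unguided by saliency is 1; guided viewing yields values above 1.
    """
    w, h = saliency.shape_px
    ok = frame_gaze.loc[~frame_gaze["missing"]]
    if ok.empty:
        raise ValueError("trial has no usable frames")
    xs = np.clip(np.rint(ok["x_px"].to_numpy(float)).astype(int), 0, w - 1)
    ys = np.clip(np.rint(ok["y_px"].to_numpy(float)).astype(int), 0, h - 1)
    fr = ok["frame"].to_numpy(int)
    return float(saliency.values[fr, ys, xs].mean())
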