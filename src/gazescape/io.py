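"""On-disk formats for the pipeline.

Gaze: CSV ``participant,video,t_ms,x_px,y_px,valid``.
ROI annotations: CSV ``video,frame,cx_px,cy_px,r_px``.
Ratings: CSV ``participant,video,valence``.
Frames and feature maps: one HDF5 container with per-video groups
(``/videos/<id>/frames``, ``.../saliency|centrality|roi``).
Ground truth and study layout: JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .features import FeatureMapStack
from .gridding import PREDICTORS, aggregate_to_grid
from .synthetic import (
    GazeSimOptions,
    GroundTruth,
    PhysioSim,
    SceneSpec,
    SimulatedStudy,
    StudyConfig,
)


def save_study(study: SimulatedStudy, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    gaze = study.gaze.copy()
    gaze["valid"] = gaze["valid"].astype(int)
    gaze.to_csv(d / "gaze.csv", index=False, float_format="%.4f")

    roi_rows = []
    for vid in study.video_ids:
        ann = study.roi[vid]
        for _, r in ann.iterrows():
            roi_rows.append((vid, int(r["frame"]), r["cx"], r["cy"], r["r"]))
    pd.DataFrame(roi_rows, columns=["video", "frame", "cx_px", "cy_px", "r_px"]).to_csv(
        d / "roi.csv", index=False, float_format="%.3f"
    )

    study.ratings.to_csv(d / "ratings.csv", index=False)

    with h5py.File(d / "maps.h5", "w") as f:
        for vid in study.video_ids:
            grp = f.create_group(f"videos/{vid}")
            if vid in study.frames:
                grp.create_dataset("frames", data=study.frames[vid], compression="gzip")
            for name in PREDICTORS:
                grp.create_dataset(
                    name, data=study.maps[vid][name].values.astype(np.float32),
                    compression="gzip",
                )

    peaks, eda = [], []
    for pid, ph in study.physio.items():
        for t in ph.r_times:
            peaks.append((pid, t))
        for t, v in zip(ph.eda_t_s, ph.eda_uS):
            eda.append((pid, t, v))
    pd.DataFrame(peaks, columns=["participant", "t_s"]).to_csv(
        d / "rpeaks.csv", index=False, float_format="%.5f"
    )
    pd.DataFrame(eda, columns=["participant", "t_s", "uS"]).to_csv(
        d / "eda.csv", index=False, float_format="%.5f"
    )

    meta = {
        "ground_truth": asdict(study.truth),
        "config": _config_dict(study.config),
        "video_ids": study.video_ids,
        "social": study.social,
        "onsets_s": {pid: list(map(float, ph.onsets_s)) for pid, ph in study.physio.items()},
    }
    (d / "study.json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def _config_dict(config: StudyConfig) -> dict:
    out = asdict(config)
    return out


def load_study(directory) -> SimulatedStudy:
    d = Path(directory)
    meta = json.loads((d / "study.json").read_text())
    config = StudyConfig(
        **{
            **{k: v for k, v in meta["config"].items() if k not in ("scene", "truth", "gaze")},
            "scene": SceneSpec(**meta["config"]["scene"]),
            "truth": GroundTruth(**meta["config"]["truth"]),
            "gaze": GazeSimOptions(**meta["config"]["gaze"]),
        }
    )
    truth = GroundTruth(**meta["ground_truth"])
    gaze = pd.read_csv(d / "gaze.csv")
    gaze["valid"] = gaze["valid"].astype(bool)
    ratings = pd.read_csv(d / "ratings.csv")
    roi_all = pd.read_csv(d / "roi.csv")
    video_ids = meta["video_ids"]
    frames, roi, maps, cell_tables = {}, {}, {}, {}
    grid = config.grid
    with h5py.File(d / "maps.h5", "r") as f:
        for vid in video_ids:
            grp = f[f"videos/{vid}"]
            if "frames" in grp:
                frames[vid] = grp["frames"][...]
            sub = roi_all.loc[roi_all["video"] == vid]
            roi[vid] = sub.rename(
                columns={"cx_px": "cx", "cy_px": "cy", "r_px": "r"}
            )[["frame", "cx", "cy", "r"]].reset_index(drop=True)
            maps[vid] = {
                name: FeatureMapStack(grp[name][...].astype(float), kind=name)
                for name in PREDICTORS
            }
            cell_tables[vid] = {
                name: aggregate_to_grid(maps[vid][name], grid) for name in PREDICTORS
            }
    physio = {}
    peaks = pd.read_csv(d / "rpeaks.csv")
    eda = pd.read_csv(d / "eda.csv")
    for pid in sorted(gaze["participant"].unique()):
        onsets = np.asarray(meta["onsets_s"][pid], float)
        r_times = peaks.loc[peaks["participant"] == pid, "t_s"].to_numpy(float)
        sub = eda.loc[eda["participant"] == pid]
        physio[pid] = PhysioSim(
            r_times=r_times, ecg_t_s=np.array([]), ecg=np.array([]),
            eda_t_s=sub["t_s"].to_numpy(float), eda_uS=sub["uS"].to_numpy(float),
            onsets_s=onsets,
        )
    return SimulatedStudy(
        config=config, truth=truth, video_ids=video_ids, social=meta["social"],
        frames=frames, roi=roi, maps=maps, cell_tables=cell_tables, gaze=gaze,
        true_cells={}, ratings=ratings, physio=physio,
    )


def write_corrected_gaze(frame_gaze: pd.DataFrame, path) -> None:
    frame_gaze.to_csv(path, index=False, float_format="%.4f")


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
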