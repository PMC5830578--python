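"""Incremental probit mixed models of fixation selection with bootstrap CIs.

For the social videos, each frame's fixated grid cell is paired with one
randomly drawn non-fixated cell; the nested 5-model series (centrality ->
+saliency -> +ROI -> +saliency x ROI -> +saliency x valence) is refit over
repeated control redraws. Writes the model-weight table (the machine twin
of a standardized-weights results table) to results/model_weights.tsv.
"""

import sys
from pathlib import Path

import pandas as pd

from gazescape.glmm import MODEL_TERMS, bootstrap_series
from gazescape.gridding import label_frames
from gazescape.io import load_study, write_table

STUDY = Path("results/study")
OUT = Path("results/model_weights.tsv")
N_BOOT = int(sys.argv[1]) if len(sys.argv) > 1 else 10


def main() -> None:
    study = load_study(STUDY)
    frame_gaze = pd.read_csv("results/frame_gaze.csv")
    grid = study.config.grid
    labels = label_frames(frame_gaze, grid)
    social = [v for v in study.video_ids if study.social[v]]
    labels = labels.loc[labels["video"].isin(social)].reset_index(drop=True)
    summary = bootstrap_series(
        study.cell_tables, labels, study.ratings, grid,
        n_iter=N_BOOT, seed=0, models=MODEL_TERMS,
    )
    table = summary.to_frame()
    write_table(table, OUT)
    print(f"{summary.n_iterations} bootstrap redraws, {summary.n_failed} failed")
    for i, r2 in enumerate(summary.r2_mean, start=1):
        print(f"  model {i}: R^2 = {r2:.3f}")
    gain = summary.r2_mean[2] - summary.r2_mean[1]
    print(f"gain in explained variance from social ROI: {100 * gain:.2f}%")
    print(f"-> {OUT}")


if __name__ == "__main__":
    main()
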