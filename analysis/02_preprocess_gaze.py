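"""Clean the raw gaze streams and align them to video frames.

Baselines from the last 300 ms of the fixation cross (recursive outlier
trim, blink-invalidated baselines replaced by the participant mean) are
subtracted, the first 150 ms after onset are dropped, and samples are
averaged per frame. Writes results/frame_gaze.csv.
"""

from pathlib import Path

from gazescape.io import load_study
from gazescape.pipeline import preprocess_study_gaze

STUDY = Path("results/study")
OUT = Path("results/frame_gaze.csv")


def main() -> None:
    study = load_study(STUDY)
    frame_gaze = preprocess_study_gaze(study)
    frame_gaze.to_csv(OUT, index=False, float_format="%.4f")
    n_missing = int(frame_gaze["missing"].sum())
    print(f"{len(frame_gaze)} frame rows; {n_missing} missing "
          f"({100 * n_missing / len(frame_gaze):.1f}%) -> {OUT}")


if __name__ == "__main__":
    main()
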