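"""Generate and save the synthetic free-viewing study.

A mini-study of 4 participants x 6 videos (3 with social content) with
ground-truth predictor weights, drift-contaminated baselines, affective
ratings and autonomic traces. All later steps read the saved study, so
every analysis is reproducible from this one seed.
"""

import sys
from pathlib import Path

from gazescape.synthetic import StudyConfig, make_study

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path("results/study")


def main() -> None:
    config = StudyConfig()
    study = make_study(config, seed=SEED)
    study.save(OUT)
    n_samples = len(study.gaze)
    print(f"simulated {config.n_participants} participants x {config.n_videos} videos "
          f"({config.n_social} social) at seed {SEED}")
    print(f"gaze stream: {n_samples} samples incl. pre-stimulus baselines")
    print(f"ground truth: {study.truth}")
    print(f"written to {OUT}/")


if __name__ == "__main__":
    main()
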