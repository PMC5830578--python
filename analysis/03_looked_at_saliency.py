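"""Mean low-level saliency at the gazed pixel, per trial.

With per-frame mean-1 normalized saliency maps, 1 is the chance level for
viewing unguided by saliency; values above 1 indicate saliency-guided
viewing. Writes results/looked_at_saliency.tsv grouped by social content.
"""

from pathlib import Path

import pandas as pd

from gazescape.gridding import looked_at_saliency
from gazescape.io import load_study, write_table

STUDY = Path("results/study")
OUT = Path("results/looked_at_saliency.tsv")


def main() -> None:
    study = load_study(STUDY)
    frame_gaze = pd.read_csv("results/frame_gaze.csv")
    rows = []
    for (pid, vid), grp in frame_gaze.groupby(["participant", "video"]):
        try:
            m = looked_at_saliency(grp, study.maps[vid]["saliency"])
        except ValueError:
            continue
        rows.append((pid, vid, study.social[vid], m))
    table = pd.DataFrame(rows, columns=["participant", "video", "social", "mean_saliency"])
    write_table(table, OUT)
    by_social = table.groupby("social")["mean_saliency"].mean()
    print(f"mean looked-at saliency: {table['mean_saliency'].mean():.3f} "
          f"(chance level = 1)")
    for social, m in by_social.items():
        print(f"  {'social' if social else 'non-social'} videos: {m:.3f}")
    print(f"-> {OUT}")


if __name__ == "__main__":
    main()
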