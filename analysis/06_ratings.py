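"""Affective ratings: inter-rater agreement and individualized valence categories.

ICC(2,1) quantifies how consistently participants rate the videos'
valence; the reclassifier splits each participant's 1-9 ratings into
negative/neutral/positive at the thresholds that balance category sizes.
Writes results/valence_categories.csv.
"""

from pathlib import Path

from gazescape.consistency import icc
from gazescape.io import load_study
from gazescape.ratings import reclassify_all

STUDY = Path("results/study")
OUT = Path("results/valence_categories.csv")


def main() -> None:
    study = load_study(STUDY)
    mat = study.ratings.pivot(index="participant", columns="video", values="valence")
    icc_val, (lo, hi) = icc(mat)
    print(f"valence ICC(2,1) = {icc_val:.3f} [{lo:.2f}, {hi:.2f}] "
          f"({mat.shape[0]} raters x {mat.shape[1]} videos)")
    categories = reclassify_all(study.ratings)
    categories.to_csv(OUT, index=False)
    counts = categories.groupby(["participant", "category"]).size().unstack(fill_value=0)
    print("per-participant category sizes:")
    print(counts.to_string())
    print(f"-> {OUT}")


if __name__ == "__main__":
    main()
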