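"""Individualized valence reclassification.

Valence is rated on a 1-9 scale, but raters use the scale differently
(e.g., avoiding the extremes, or with a positivity bias). Instead of
fixed a-priori cut points, each participant's ratings are split into
negative / neutral / positive by the threshold pair that balances the
three category sizes as evenly as possible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

A_PRIORI_THRESHOLDS = (3, 6)


@dataclass
class ValenceCategories:
    t1: int
    t2: int
    categories: pd.Series  # per-video category label
    sizes: dict[str, int]
    objective: int


def _category_sizes(ratings: np.ndarray, t1: int, t2: int) -> tuple[int, int, int]:
    neg = int((ratings <= t1).sum())
    neu = int(((ratings > t1) & (ratings <= t2)).sum())
    pos = int((ratings > t2).sum())
    return neg, neu, pos


def reclassify_valence(ratings: pd.Series | np.ndarray) -> ValenceCategories:
    """Balanced three-way split of one participant's valence ratings.

    All threshold pairs (t1, t2) with 1 <= t1 < t2 <= 8 are evaluated; a
    rating r falls in `negative` if r <= t1, `neutral` if t1 < r <= t2,
    `positive` otherwise. The objective is the total pairwise absolute
    difference in category sizes; ties are broken by distance to the
    a-priori pair (3, 6) (L1 on the thresholds), then lexicographically.
    """
    values = np.asarray(ratings, dtype=int)
    if values.size < 3:
        raise ValueError("need at least 3 rated videos")
    if values.min() < 1 or values.max() > 9:
        raise ValueError("ratings must lie in 1..9")
    best = None
    for t1 in range(1, 9):
        for t2 in range(t1 + 1, 9):
            neg, neu, pos = _category_sizes(values, t1, t2)
            obj = abs(neg - neu) + abs(neg - pos) + abs(neu - pos)
            dist = abs(t1 - A_PRIORI_THRESHOLDS[0]) + abs(t2 - A_PRIORI_THRESHOLDS[1])
            key = (obj, dist, t1, t2)
            if best is None or key < best[0]:
                best = (key, (t1, t2), (neg, neu, pos))
    (obj, _, _, _), (t1, t2), (neg, neu, pos) = best
    labels = np.where(values <= t1, "negative", np.where(values <= t2, "neutral", "positive"))
    index = ratings.index if isinstance(ratings, pd.Series) else pd.RangeIndex(values.size)
    return ValenceCategories(
        t1=t1, t2=t2, categories=pd.Series(labels, index=index),
        sizes={"negative": neg, "neutral": neu, "positive": pos}, objective=obj,
    )


def reclassify_all(ratings: pd.DataFrame) -> pd.DataFrame:
    """Apply the reclassifier per participant.

    ``ratings`` has columns participant, video, valence; the result adds
    category and the participant's thresholds.
    """
    parts = []
    for participant, grp in ratings.groupby("participant", sort=True):
        cats = reclassify_valence(grp["valence"])
        out = grp[["participant", "video"]].copy()
        out["category"] = cats.categories.to_numpy()
        out["t1"] = cats.t1
        out["t2"] = cats.t2
        parts.append(out)
    return pd.concat(parts, ignore_index=True)
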