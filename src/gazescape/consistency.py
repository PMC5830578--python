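"""Intra-individual stability of predictor weights.

Each participant x social-video unit gets its own probit GLM with the
three predictors centrality, saliency and social ROI. Non-converging
units leave missing weights, which are completed by predictive mean
matching (PMM, m imputed datasets). Weights are then z-standardized
along the video dimension (removing per-video level differences while
keeping each participant's ordering) and their consistency across videos
is summarized by Cronbach's alpha, treating videos as items and
participants as cases. Inter-rater agreement of the affective ratings is
quantified with a two-way random-effects, absolute-agreement, single-
rater ICC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .glmm import ModelSpec, fit_probit_glm

UNIT_TERMS = ("centrality", "saliency", "roi")


@dataclass
class WeightTable:
    """Per participant x video predictor weights; NaN where the fit failed."""

    entries: pd.DataFrame  # columns: participant, video, term, weight, converged

    def pivot(self, term: str) -> pd.DataFrame:
        """Participants x videos matrix for one term."""
        sub = self.entries.loc[self.entries["term"] == term]
        return sub.pivot(index="participant", columns="video", values="weight")

    @property
    def n_missing(self) -> int:
        return int(self.entries["weight"].isna().sum())


@dataclass
class AlphaResult:
    alpha: float
    ci: tuple[float, float]
    n_datasets: int


def per_unit_fits(rows: pd.DataFrame, terms: tuple[str, ...] = UNIT_TERMS) -> WeightTable:
    """One probit GLM per participant x video on its case-control rows.

    Random intercepts are unidentifiable with a single participant and a
    single video per fit, so plain GLMs are used; units that do not
    converge (including separation) are recorded as missing.
    """
    spec = ModelSpec(fixed_terms=terms)
    recs = []
    for (participant, video), grp in rows.groupby(["participant", "video"], sort=True):
        try:
            fit = fit_probit_glm(grp, spec)
            ok = fit.converged
            weights = fit.fixed_effects
        except (ValueError, np.linalg.LinAlgError):
            ok, weights = False, {t: np.nan for t in terms}
        for t in terms:
            w = weights.get(t, np.nan)
            recs.append((participant, video, t, w if ok and np.isfinite(w) else np.nan, ok))
    return WeightTable(
        pd.DataFrame(recs, columns=["participant", "video", "term", "weight", "converged"])
    )


def _pmm_draw(
    predicted: float,
    observed_values: np.ndarray,
    observed_predicted: np.ndarray,
    k_donors: int,
    rng: np.random.Generator,
) -> float:
    """Draw uniformly from the k observed donors nearest in predicted value."""
    order = np.argsort(np.abs(observed_predicted - predicted), kind="stable")
    pool = observed_values[order[:k_donors]]
    return float(rng.choice(pool))


def pmm_impute(
    table: WeightTable, m: int = 5, k_donors: int = 5, seed: int = 0
) -> list[WeightTable]:
    """Predictive mean matching: ``m`` completed copies of the weight table.

    Per term, a linear model predicts the weight from the participant's
    and the video's mean observed weight for that term; each missing
    entry is filled by a uniform draw among the ``k_donors`` observed
    entries with the nearest predicted value. Observed entries are never
    altered.
    """
    rng = np.random.default_rng(seed)
    base = table.entries
    completed = [base.copy() for _ in range(m)]
    for term in base["term"].unique():
        sub = base.loc[base["term"] == term]
        obs = sub.dropna(subset=["weight"])
        if obs.empty:
            raise ValueError(f"no observed weights for term {term!r}")
        if len(obs) < k_donors:
            raise ValueError(f"need at least {k_donors} observed weights for term {term!r}")
        p_mean = obs.groupby("participant")["weight"].mean()
        v_mean = obs.groupby("video")["weight"].mean()
        grand = obs["weight"].mean()

        def covariates(df: pd.DataFrame) -> np.ndarray:
            pm = df["participant"].map(p_mean).fillna(grand).to_numpy(float)
            vm = df["video"].map(v_mean).fillna(grand).to_numpy(float)
            return np.column_stack([np.ones(len(df)), pm, vm])

        X_obs = covariates(obs)
        beta, *_ = np.linalg.lstsq(X_obs, obs["weight"].to_numpy(float), rcond=None)
        obs_pred = X_obs @ beta
        obs_vals = obs["weight"].to_numpy(float)
        miss = sub.loc[sub["weight"].isna()]
        if miss.empty:
            continue
        miss_pred = covariates(miss) @ beta
        for dataset in completed:
            for idx, pred in zip(miss.index, miss_pred):
                dataset.loc[idx, "weight"] = _pmm_draw(pred, obs_vals, obs_pred, k_donors, rng)
    return [WeightTable(df) for df in completed]


def cronbach_alpha(items: np.ndarray) -> float:
    """Cronbach's alpha for a cases x items matrix (sample variances, n-1)."""
    items = np.asarray(items, float)
    n_cases, k = items.shape
    if k < 2 or n_cases < 2:
        raise ValueError("need at least 2 items and 2 cases")
    item_var = items.var(axis=0, ddof=1).sum()
    total_var = items.sum(axis=1).var(ddof=1)
    if total_var <= 1e-12:
        raise ValueError("zero total variance; alpha undefined")
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def zscore_by_video(matrix: pd.DataFrame) -> pd.DataFrame:
    """Z-standardize each video's column of weights across participants."""
    mu = matrix.mean(axis=0)
    sd = matrix.std(axis=0, ddof=1)
    if (sd <= 1e-12).any():
        raise ValueError("a video has zero weight variance across participants")
    return (matrix - mu) / sd


def consistency_alpha(
    tables: list[WeightTable], terms: tuple[str, ...] = UNIT_TERMS
) -> dict[str, AlphaResult]:
    """Alpha per predictor across completed weight tables.

    Per table: pivot to participants x videos, z-standardize along the
    video dimension, and compute alpha with videos as items. The result
    per term is the mean alpha with the 2.5/97.5 percentile interval
    across tables.
    """
    out: dict[str, AlphaResult] = {}
    for term in terms:
        alphas = []
        for tbl in tables:
            mat = tbl.pivot(term)
            if mat.isna().any().any():
                raise ValueError("consistency_alpha requires completed tables")
            alphas.append(cronbach_alpha(zscore_by_video(mat).to_numpy()))
        alphas = np.asarray(alphas)
        if len(alphas) >= 2:
            lo, hi = np.percentile(alphas, [2.5, 97.5])
        else:
            lo = hi = alphas[0]
        out[term] = AlphaResult(float(alphas.mean()), (float(lo), float(hi)), len(alphas))
    return out


def icc(ratings: pd.DataFrame) -> tuple[float, tuple[float, float]]:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``ratings`` is a participants (raters) x videos (targets) table with
    no missing cells. Returns the estimate and its F-based 95% CI.
    """
    import pingouin as pg

    mat = np.asarray(ratings, float)
    if np.isnan(mat).any():
        raise ValueError("ICC requires a complete table")
    n_raters, n_targets = mat.shape
    long = pd.DataFrame(
        {
            "targets": np.tile(np.arange(n_targets), n_raters),
            "raters": np.repeat(np.arange(n_raters), n_targets),
            "score": mat.ravel(),
        }
    )
    res = pg.intraclass_corr(data=long, targets="targets", raters="raters", ratings="score")
    res["Type"] = res["Type"].astype(str)
    mask = res["Type"].isin(["ICC2", "ICC(A,1)"])
    row = res.loc[mask].iloc[0]
    ci_col = "CI95%" if "CI95%" in res.columns else "CI95"
    lo, hi = row[ci_col]
    return float(row["ICC"]), (float(lo), float(hi))
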