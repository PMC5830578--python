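"""Probit fitting: IRLS GLM vs oracles, Laplace GLMM, series, bootstrap, R²."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from gazescape.glmm import (
    MODEL_TERMS,
    ModelSpec,
    bootstrap_series,
    design_matrix,
    fit_probit_glm,
    fit_probit_glmm,
    incremental_series,
    r_squared,
)


def grid_search_probit(X, y, lo=-3.0, hi=3.0, rounds=6, n_points=11):
    """Independent coarse-to-fine grid maximizer of the probit log-likelihood."""
    p = X.shape[1]
    centre = np.zeros(p)
    half = (hi - lo) / 2.0
    best = None
    for _ in range(rounds):
        grids = [np.linspace(c - half, c + half, n_points) for c in centre]
        mesh = np.meshgrid(*grids, indexing="ij")
        betas = np.column_stack([m.ravel() for m in mesh])
        eta = np.clip(X @ betas.T, -8, 8)
        mu = np.clip(norm.cdf(eta), 1e-10, 1 - 1e-10)
        ll = (y[:, None] * np.log(mu) + (1 - y[:, None]) * np.log(1 - mu)).sum(0)
        k = np.argmax(ll)
        centre = betas[k]
        best = ll[k]
        half = half * 2.0 / (n_points - 1)  # shrink around the winner
    return centre, best


def _make_rows(rng, n, betas, intercept=0.0):
    cols = {f"{name}_z": rng.normal(size=n) for name in betas}
    df = pd.DataFrame(cols)
    eta = intercept + sum(b * df[f"{name}_z"] for name, b in betas.items())
    df["fixated"] = (rng.random(n) < norm.cdf(eta)).astype(int)
    return df


class TestProbitGLM:
    def test_balanced_null_gives_zero_intercept(self):
        df = pd.DataFrame({"fixated": [0, 1] * 50, "centrality_z": 0.0})
        fit = fit_probit_glm(df, ModelSpec(()))
        assert fit.intercept == pytest.approx(0.0, abs=1e-8)

    def test_matches_grid_search_oracle_on_20_designs(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = int(rng.integers(150, 300))
            betas = {"centrality": rng.uniform(-1, 1), "saliency": rng.uniform(-1, 1)}
            df = _make_rows(rng, n, betas, intercept=rng.uniform(-0.5, 0.5))
            fit = fit_probit_glm(df, ModelSpec(("centrality", "saliency")))
            if not fit.converged:
                continue
            X = design_matrix(df, ("centrality", "saliency"))
            beta_hat = np.array(
                [fit.intercept, fit.fixed_effects["centrality"], fit.fixed_effects["saliency"]]
            )
            beta_grid, _ = grid_search_probit(X, df["fixated"].to_numpy(float))
            assert np.allclose(beta_hat, beta_grid, atol=1e-3)

    def test_matches_statsmodels(self, probit_rows):
        import statsmodels.api as sm

        terms = ("centrality", "saliency", "roi")
        fit = fit_probit_glm(probit_rows, ModelSpec(terms))
        X = sm.add_constant(probit_rows[[t + "_z" for t in terms]])
        ref = sm.GLM(
            probit_rows["fixated"], X,
            family=sm.families.Binomial(sm.families.links.Probit()),
        ).fit()
        ours = [fit.intercept] + [fit.fixed_effects[t] for t in terms]
        assert np.allclose(ours, ref.params.to_numpy(), atol=1e-6)

    def test_separation_flagged(self):
        df = pd.DataFrame({"centrality_z": np.linspace(-2, 2, 40)})
        df["fixated"] = (df["centrality_z"] > 0).astype(int)
        fit = fit_probit_glm(df, ModelSpec(("centrality",)))
        assert not fit.converged

    def test_probit_sign_symmetry(self, probit_rows):
        terms = ("centrality", "saliency", "roi")
        fit = fit_probit_glm(probit_rows, ModelSpec(terms))
        flipped = probit_rows.copy()
        for t in terms:
            flipped[t + "_z"] = -flipped[t + "_z"]
        flipped["fixated"] = 1 - flipped["fixated"]
        fit2 = fit_probit_glm(flipped, ModelSpec(terms))
        assert fit2.intercept == pytest.approx(-fit.intercept, abs=1e-7)
        for t in terms:
            assert fit2.fixed_effects[t] == pytest.approx(fit.fixed_effects[t], abs=1e-7)

    def test_single_response_level_rejected(self):
        df = pd.DataFrame({"centrality_z": [0.1, 0.2], "fixated": [1, 1]})
        with pytest.raises(ValueError):
            fit_probit_glm(df, ModelSpec(("centrality",)))


def _glmm_data(rng, n, part_sd, vid_sd, npart=8, nvid=10, betas=(0.5, -0.3)):
    a = rng.normal(0, part_sd, npart)
    b = rng.normal(0, vid_sd, nvid)
    pi = rng.integers(0, npart, n)
    vi = rng.integers(0, nvid, n)
    x1, x2 = rng.normal(size=n), rng.normal(size=n)
    eta = 0.1 + betas[0] * x1 + betas[1] * x2 + a[pi] + b[vi]
    return pd.DataFrame(
        {
            "centrality_z": x1,
            "saliency_z": x2,
            "fixated": (rng.random(n) < norm.cdf(eta)).astype(int),
            "participant": pd.Series(pi).map("p{:02d}".format),
            "video": pd.Series(vi).map("v{:02d}".format),
        }
    )


SPEC_MIXED = ModelSpec(("centrality", "saliency"), ("participant", "video"))


class TestProbitGLMM:
    def test_zero_variance_limit_matches_glm(self):
        rng = np.random.default_rng(0)
        df = _glmm_data(rng, 50_000, 0.0, 0.0)
        mixed = fit_probit_glmm(df, SPEC_MIXED)
        plain = fit_probit_glm(df, ModelSpec(("centrality", "saliency")))
        assert mixed.random_variances["participant"] <= 0.05
        assert mixed.random_variances["video"] <= 0.05
        for t in ("centrality", "saliency"):
            assert mixed.fixed_effects[t] == pytest.approx(plain.fixed_effects[t], abs=0.1)

    def test_participant_variance_recovered(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            df = _glmm_data(rng, 8000, 0.5, 0.0)
            fit = fit_probit_glmm(df, SPEC_MIXED)
            if 0.1 <= fit.random_variances["participant"] <= 0.6:
                hits += 1
        assert hits >= 8

    def test_matches_lme4_glmer(self, tmp_path):
        """Independent cross-check against the reference mixed-model fitter."""
        rng = np.random.default_rng(7)
        df = _glmm_data(rng, 4000, 0.4, 0.25, npart=6, nvid=8)
        fit = fit_probit_glmm(df, SPEC_MIXED)
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = textwrap.dedent(
            f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- glmer(fixated ~ centrality_z + saliency_z + (1|participant) + (1|video),
                       data=d, family=binomial(link="probit"),
                       control=glmerControl(optimizer="bobyqa"))
            cat(fixef(m), unlist(VarCorr(m)), sep="\\n")
            """
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        vals = [float(v) for v in out.stdout.split()]
        ref_fixed, ref_vars = vals[:3], vals[3:]
        ours = [fit.intercept, fit.fixed_effects["centrality"], fit.fixed_effects["saliency"]]
        assert np.allclose(ours, ref_fixed, atol=0.01)
        assert np.allclose(
            sorted(fit.random_variances.values()), sorted(ref_vars), atol=0.02
        )

    def test_single_level_factor_rejected(self):
        df = pd.DataFrame(
            {
                "centrality_z": [0.0, 1.0, -1.0, 0.5],
                "saliency_z": [0.2, -0.1, 0.3, 0.0],
                "fixated": [0, 1, 0, 1],
                "participant": "p0",
                "video": "v0",
            }
        )
        with pytest.raises(ValueError):
            fit_probit_glmm(df, SPEC_MIXED)


class TestRSquared:
    def test_perfect_prediction(self):
        assert r_squared([0, 1, 0, 1], [0.0, 1.0, 0.0, 1.0]) == pytest.approx(1.0)

    def test_constant_prediction_degenerate(self):
        with pytest.warns(UserWarning):
            assert r_squared([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.0

    def test_hand_computed_example(self):
        assert r_squared([0, 0, 1, 1], [0.2, 0.4, 0.6, 0.8]) == pytest.approx(0.8)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            r_squared([0, 1], [0.5])


class TestModelSpec:
    def test_interaction_requires_main_effect(self):
        with pytest.raises(ValueError):
            ModelSpec(("saliency_x_roi",))

    def test_valence_interaction_without_valence_main_is_legal(self):
        ModelSpec(("centrality", "saliency", "roi", "saliency_x_roi", "saliency_x_valence"))

    def test_series_term_sets(self):
        assert MODEL_TERMS[2] == ("centrality", "saliency", "roi")
        for a, b in zip(MODEL_TERMS, MODEL_TERMS[1:]):
            assert set(a) < set(b)


@pytest.fixture(scope="module")
def series_rows():
    rng = np.random.default_rng(5)
    n = 3000
    df = _glmm_data(rng, n, 0.2, 0.2, npart=4, nvid=5, betas=(0.4, 0.3))
    df["roi_z"] = rng.normal(size=n)
    df["valence_z"] = rng.normal(size=n)
    eta = norm.ppf(np.clip(df["fixated"] * 0.6 + 0.2, 0.01, 0.99)) + 0.5 * df["roi_z"]
    df["fixated"] = (rng.random(n) < norm.cdf(eta)).astype(int)
    return df


class TestIncrementalSeries:
    def test_loglik_nondecreasing(self, series_rows):
        fits = incremental_series(series_rows)
        lls = [f.loglik for f in fits]
        for a, b in zip(lls, lls[1:]):
            assert b >= a - 1e-2

    def test_five_models_with_expected_terms(self, series_rows):
        fits = incremental_series(series_rows)
        assert [f.spec.fixed_terms for f in fits] == MODEL_TERMS


class TestBootstrapSeries:
    def _setup(self, seed=3, n_frames=60):
        from gazescape.gridding import GridSpec

        grid = GridSpec(cell_px=10, n_cols=32, n_rows=18)
        rng = np.random.default_rng(seed)
        tables = {
            v: {name: rng.uniform(size=(n_frames, grid.n_cells))
                for name in ("centrality", "saliency", "roi")}
            for v in ("v00", "v01")
        }
        labels = pd.concat(
            [
                pd.DataFrame(
                    {
                        "participant": p,
                        "video": v,
                        "frame": np.arange(n_frames),
                        "cell": rng.integers(0, grid.n_cells, n_frames),
                        "missing": False,
                    }
                )
                for p in ("p00", "p01", "p02")
                for v in ("v00", "v01")
            ],
            ignore_index=True,
        )
        return grid, tables, labels

    def test_n_iterations_reported(self):
        grid, tables, labels = self._setup()
        s = bootstrap_series(
            tables, labels, None, grid, n_iter=3, seed=0,
            models=[("centrality",)], random_factors=(),
        )
        assert s.n_iterations == 3 and s.n_failed == 0

    def test_interval_orders_and_contains_mean(self):
        grid, tables, labels = self._setup()
        s = bootstrap_series(
            tables, labels, None, grid, n_iter=8, seed=0,
            models=[("centrality", "saliency")], random_factors=(),
        )
        for t in ("centrality", "saliency"):
            lo, hi = s.term_ci[0][t]
            assert lo <= s.term_mean[0][t] <= hi

    def test_too_few_iterations_rejected(self):
        grid, tables, labels = self._setup()
        with pytest.raises(ValueError):
            bootstrap_series(tables, labels, None, grid, n_iter=1, seed=0)
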