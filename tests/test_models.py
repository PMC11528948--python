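"""Linear and proportional-odds fits, backward stepwise selection, and the
dual-basis comparison, validated against independent likelihood oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit

from phenoconv.models import (
    BARS_LEVELS,
    ModelError,
    ModelSpec,
    backward_stepwise,
    compare_phenotype_models,
    fit_cumulative_logit,
    fit_linear_model,
)


def make_frame(n=60, seed=0, ppt_from_gpt=True):
    rng = np.random.default_rng(seed)
    gpt = rng.choice(["PM", "IM", "NM"], size=n, p=[0.1, 0.4, 0.5])
    df = pd.DataFrame(
        {
            "patient_id": [f"m{i}" for i in range(n)],
            "gPT": gpt,
            "pPT": gpt if ppt_from_gpt else gpt,
            "age": rng.normal(30, 7, n).round(1),
            "illness_duration": rng.normal(4, 2, n).round(1),
            "n_medications_total": rng.poisson(3, n),
            "n_treatment_drugs": 1 + rng.poisson(0.4, n),
            "cpz_equivalent_dose": rng.uniform(50, 700, n).round(0),
            "sex": rng.choice(["male", "female"], n),
            "smoking": rng.choice(["smoker", "non-smoker"], n),
            "ethnicity": rng.choice(["white", "mixed"], n, p=[0.8, 0.2]),
            "birth_control": rng.integers(0, 2, n),
        }
    )
    return df, rng


class TestLinearModel:
    def test_exact_fit_recovered(self):
        df, _ = make_frame(40, seed=1)
        df["aims"] = 2 * df["age"] + 1  # noiseless line
        spec = ModelSpec("aims", "gPT", ("phenotype", "age"))
        fit = fit_linear_model(spec, df)
        assert fit.params["age"] == pytest.approx(2.0)
        assert fit.params["const"] == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_aic_matches_closed_form_gaussian_likelihood(self):
        """AIC recomputed from the residuals by an independent formula."""
        df, rng = make_frame(50, seed=2)
        df["aims"] = 1 + 0.2 * df["age"] + rng.normal(0, 1, len(df))
        spec = ModelSpec("aims", "gPT", ("phenotype", "age", "sex"))
        fit = fit_linear_model(spec, df)
        X = np.column_stack(
            [
                np.ones(len(df)),
                (df["gPT"] == "PM").astype(float),
                (df["gPT"] == "IM").astype(float),
                df["age"],
                (df["sex"] == "female").astype(float),
            ]
        )
        beta, *_ = np.linalg.lstsq(X, df["aims"], rcond=None)
        rss = float(((df["aims"] - X @ beta) ** 2).sum())
        n = len(df)
        llf = -0.5 * n * (np.log(2 * np.pi * rss / n) + 1)
        k = X.shape[1] + 1
        assert fit.log_likelihood == pytest.approx(llf, abs=1e-8)
        assert fit.aic == pytest.approx(2 * k - 2 * llf, abs=1e-8)
        assert abs(fit.aic - (2 * fit.k - 2 * fit.log_likelihood)) < 1e-8

    def test_row_permutation_invariance(self):
        df, rng = make_frame(45, seed=3)
        df["updrs"] = 5 + 0.1 * df["age"] + rng.normal(0, 2, len(df))
        spec = ModelSpec("updrs", "gPT", ("phenotype", "age"))
        a = fit_linear_model(spec, df)
        b = fit_linear_model(spec, df.sample(frac=1, random_state=9))
        assert np.allclose(a.params, b.params)
        assert a.aic == pytest.approx(b.aic)

    def test_rank_deficiency_names_collinear_columns(self):
        df, rng = make_frame(30, seed=4)
        df["aims"] = rng.normal(size=len(df))
        df["n_medications_total"] = df["age"]  # exact duplicate of age
        spec = ModelSpec("aims", "gPT", ("phenotype", "age", "n_medications_total"))
        with pytest.raises(ModelError, match="n_medications_total|age"):
            fit_linear_model(spec, df)


def ordinal_frame(levels, x, y_codes):
    return pd.DataFrame(
        {
            "patient_id": [f"o{i}" for i in range(len(x))],
            "gPT": "NM",
            "pPT": "NM",
            "age": x,
            "bars": [levels[c] for c in y_codes],
        }
    )


class TestCumulativeLogit:
    def test_two_level_outcome_equals_binary_logistic(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=80)
        y = (rng.random(80) < expit(0.8 * x - 0.3)).astype(int)
        df = ordinal_frame(["none", "mild"], x, y)
        spec = ModelSpec("bars", "gPT", ("age",), forced_terms=())
        fit = fit_cumulative_logit(spec, df)
        logit = sm.Logit(y, sm.add_constant(x)).fit(disp=False)
        assert fit.log_likelihood == pytest.approx(logit.llf, abs=1e-6)
        assert fit.params["age"] == pytest.approx(logit.params[1], abs=1e-4)
        # the single threshold is the negated logistic intercept
        assert fit.thresholds[0] == pytest.approx(-logit.params[0], abs=1e-4)

    def test_mle_matches_grid_search_oracle(self):
        """Optimum log-likelihood reproduced by a refined dense grid over
        (threshold1, threshold2, slope), computed from the cumulative-logistic
        probabilities directly."""
        x = np.array([-1.2, -0.5, 0.3, 0.8, 1.5, -0.9, 0.1, 2.0, -0.2])
        y = np.array([0, 1, 1, 2, 1, 0, 0, 2, 1])  # classes overlap in x
        df = ordinal_frame(["none", "mild", "severe"], x, y)
        spec = ModelSpec("bars", "gPT", ("age",), forced_terms=())
        fit = fit_cumulative_logit(spec, df)

        def grid_llf(t1g, t2g, bg):
            T1, T2, B = np.meshgrid(t1g, t2g, bg, indexing="ij")
            ll = np.zeros_like(T1)
            for xi, yi in zip(x, y):
                c1 = expit(T1 - B * xi)
                c2 = expit(T2 - B * xi)
                p = np.where(yi == 0, c1, np.where(yi == 1, c2 - c1, 1 - c2))
                ll += np.log(np.clip(p, 1e-300, None))
            ll[T2 <= T1] = -np.inf
            return ll

        centers, width = np.array([0.0, 1.0, 0.0]), 4.0
        best = -np.inf
        for _ in range(4):
            grids = [np.linspace(c - width, c + width, 41) for c in centers]
            ll = grid_llf(*grids)
            best = ll.max()
            i, j, k = np.unravel_index(np.argmax(ll), ll.shape)
            centers = np.array([grids[0][i], grids[1][j], grids[2][k]])
            width /= 10
        assert fit.log_likelihood == pytest.approx(best, abs=1e-3)

    def test_zero_effect_covariate_shrinks_with_n(self):
        rng = np.random.default_rng(6)
        n = 4000
        x = rng.normal(size=n)
        latent = rng.logistic(size=n)  # x plays no role
        y = np.searchsorted([-1.0, 0.5], latent)
        df = ordinal_frame(["none", "mild", "severe"], x, y)
        spec = ModelSpec("bars", "gPT", ("age",), forced_terms=())
        fit = fit_cumulative_logit(spec, df)
        assert abs(fit.params["age"]) < 0.08

    def test_thresholds_strictly_increasing(self):
        rng = np.random.default_rng(7)
        n = 300
        x = rng.normal(size=n)
        latent = 0.7 * x + rng.logistic(size=n)
        y = np.searchsorted([-2, -1, 0, 1, 2], latent)
        df = ordinal_frame(BARS_LEVELS, x, y)
        spec = ModelSpec("bars", "gPT", ("age",), forced_terms=())
        fit = fit_cumulative_logit(spec, df)
        assert np.all(np.diff(fit.thresholds) > 0)
        assert abs(fit.aic - (2 * fit.k - 2 * fit.log_likelihood)) < 1e-8

    def test_single_level_outcome_rejected(self):
        df = ordinal_frame(["none"], np.arange(5.0), [0] * 5)
        spec = ModelSpec("bars", "gPT", ("age",), forced_terms=())
        with pytest.raises(ModelError):
            fit_cumulative_logit(spec, df)


class TestBackwardStepwise:
    def test_all_terms_forced_returns_initial_model(self):
        df, rng = make_frame(50, seed=8)
        df["aims"] = rng.normal(size=len(df))
        spec = ModelSpec(
            "aims", "gPT", ("phenotype", "age"), forced_terms=("phenotype", "age")
        )
        fit = backward_stepwise(spec, df)
        assert set(fit.spec.terms) == {"phenotype", "age"}
        assert len(fit.stepwise_path) == 1

    def test_noise_covariates_dropped_signal_kept(self):
        df, rng = make_frame(1000, seed=9)
        df["swn20"] = 50 + 3.0 * df["illness_duration"] + rng.normal(0, 2, len(df))
        spec = ModelSpec(
            "swn20", "gPT", ("phenotype", "age", "illness_duration", "n_medications_total")
        )
        fit = backward_stepwise(spec, df)
        assert "illness_duration" in fit.spec.terms
        assert "age" not in fit.spec.terms
        assert "n_medications_total" not in fit.spec.terms
        assert "phenotype" in fit.spec.terms  # forced

    def test_matches_exhaustive_subset_enumeration(self):
        """With four independent free terms the greedy path reaches the
        global AIC minimum over the full subset lattice."""
        df, rng = make_frame(200, seed=10)
        df["updrs"] = (
            10
            + 0.4 * df["age"]
            + 1.5 * df["illness_duration"]
            + rng.normal(0, 3, len(df))
        )
        free = ("age", "illness_duration", "n_medications_total", "n_treatment_drugs")
        spec = ModelSpec("updrs", "gPT", ("phenotype", *free))
        fit = backward_stepwise(spec, df)
        best = np.inf
        for r in range(len(free) + 1):
            for subset in itertools.combinations(free, r):
                sub = ModelSpec("updrs", "gPT", ("phenotype", *subset))
                best = min(best, fit_linear_model(sub, df).aic)
        assert fit.aic == pytest.approx(best, abs=1e-6)

    def test_aic_trajectory_nonincreasing(self):
        df, rng = make_frame(300, seed=11)
        df["panss_pos"] = 14 + rng.normal(0, 5, len(df))
        spec = ModelSpec(
            "panss_pos",
            "gPT",
            ("phenotype", "age", "sex", "smoking", "cpz_equivalent_dose"),
        )
        fit = backward_stepwise(spec, df)
        aics = [a for _, a in fit.stepwise_path]
        assert all(b <= a + 1e-9 for a, b in zip(aics, aics[1:]))
        assert fit.aic <= aics[0] + 1e-6


class TestComparePhenotypeModels:
    def test_identical_bases_are_indistinguishable(self):
        df, rng = make_frame(120, seed=12)  # pPT identical to gPT
        df["aims"] = 2 + rng.normal(0, 1, len(df))
        cmp = compare_phenotype_models(df, "aims", covariates=("age", "sex"))
        assert cmp.delta_aic == pytest.approx(0.0, abs=1e-8)
        assert cmp.indistinguishable and cmp.preferred == "neither"

    def test_delta_just_below_two_is_indistinguishable(self):
        from phenoconv.models import ModelComparison, ModelFit

        df, rng = make_frame(60, seed=13)
        df["aims"] = rng.normal(size=len(df))
        spec = ModelSpec("aims", "gPT", ("phenotype",))
        fit = fit_linear_model(spec, df)
        cmp = ModelComparison(
            fit_g=fit, fit_p=fit, delta_aic=1.9, indistinguishable=abs(1.9) < 2, preferred="neither"
        )
        assert cmp.indistinguishable
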