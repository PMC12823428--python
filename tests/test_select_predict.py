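"""Penalized selection, stability subsampling, stepwise refits, evaluation."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.optimize import brentq
from scipy.special import expit

from triagen import select_predict as sp


def binary_world(rng, n, betas, prevalence=0.10, p_extra=0):
    p = len(betas) + p_extra
    X = rng.normal(size=(n, p))
    eta = X[:, : len(betas)] @ np.asarray(betas, dtype=float)
    c0 = brentq(lambda c: expit(c + eta).mean() - prevalence, -25, 25)
    y = (rng.random(n) < expit(c0 + eta)).astype(float)
    return X, y


class TestSplit:
    def _frame(self, n=100, cases=20):
        y = np.zeros(n)
        y[:cases] = 1
        return pd.DataFrame({"y": y, "x": np.arange(n, dtype=float)})

    def test_sizes(self):
        train, test = sp.split(self._frame(10, 4), "y", 0.2, seed=2)
        assert len(test) == 2 and len(train) == 8

    def test_printed_case_split_arithmetic(self):
        assert 541 - 436 == 105

    def test_deterministic(self):
        d = self._frame()
        a1, b1 = sp.split(d, "y", seed=5)
        a2, b2 = sp.split(d, "y", seed=5)
        pd.testing.assert_frame_equal(a1, a2)
        pd.testing.assert_frame_equal(b1, b2)

    def test_partitions_disjoint_and_complete(self):
        d = self._frame()
        train, test = sp.split(d, "y", seed=1)
        assert len(train) + len(test) == len(d)
        assert set(train["x"]).isdisjoint(test["x"])

    def test_rejects_too_few_cases(self):
        with pytest.raises(ValueError, match="two cases"):
            sp.split(self._frame(100, 1), "y")


class TestLassoLogistic:
    def test_vanishing_penalty_matches_unpenalized(self, rng):
        X, y = binary_world(rng, 200, [0.5, -0.3, 0.0, 0.0, 0.0], prevalence=0.4)
        _, beta, ok = sp.lasso_logistic(X, y, 1e-9)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        assert ok
        np.testing.assert_allclose(beta, ref.params[1:], atol=1e-4)

    def test_full_shrinkage_above_critical_penalty(self, rng):
        X, y = binary_world(rng, 300, [0.5, -0.3], prevalence=0.3, p_extra=3)
        _, beta, _ = sp.lasso_logistic(X, y, 1.0)
        assert np.all(beta == 0.0)

    def test_penalty_factor_zero_leaves_feature_unpenalized(self, rng):
        X, y = binary_world(rng, 500, [0.8, 0.0, 0.0], prevalence=0.3)
        pf = np.array([0.0, 1.0, 1.0])
        _, beta, _ = sp.lasso_logistic(X, y, 0.5, penalty_factor=pf)
        assert beta[0] != 0.0  # survives a penalty that kills everything else
        assert np.all(beta[1:] == 0.0)

    def test_matches_sklearn_at_uniform_penalty(self, rng):
        from sklearn.linear_model import LogisticRegression

        X, y = binary_world(rng, 400, [0.6, -0.4, 0.0, 0.0], prevalence=0.35)
        lam = 0.02
        _, beta, _ = sp.lasso_logistic(X, y, lam)
        ref = LogisticRegression(
            l1_ratio=1.0, C=1.0 / (len(y) * lam), solver="saga",
            tol=1e-10, max_iter=20_000,
        ).fit(X, y)
        np.testing.assert_allclose(beta, ref.coef_[0], atol=1e-6)


class TestLassoCv:
    def test_one_se_rule_and_grid(self, rng):
        X, y = binary_world(rng, 800, [1.0, -0.8], prevalence=0.3, p_extra=18)
        path = sp.lasso_cv(X, y, grid=sp.default_grid(40), folds=5, seed=0)
        assert path.lambda_1se >= path.lambda_min
        i1se = int(np.argmin(np.abs(path.grid - path.lambda_1se)))
        imin = int(np.argmin(path.cv_loss))
        assert path.cv_loss[i1se] <= path.cv_loss[imin] + path.cv_se[imin] + 1e-12

    def test_default_grid_shape(self):
        g = sp.default_grid()
        assert len(g) == 100
        assert g.max() == pytest.approx(0.07)
        assert g.min() == pytest.approx(1e-6)
        assert np.allclose(np.diff(np.log(g)), np.diff(np.log(g))[0])

    def test_recovers_active_proteins_at_lambda_1se(self, rng):
        """Active predictors among noise survive the 1-SE penalty."""
        found = 0
        for seed in range(5):
            r = np.random.default_rng(seed)
            X, y = binary_world(r, 3000, [0.4, 0.4, 0.4, -0.4, -0.4],
                                prevalence=0.25, p_extra=45)
            path = sp.lasso_cv(X, y, grid=sp.default_grid(30), folds=5, seed=seed)
            _, beta, _ = sp.lasso_logistic(X, y, path.lambda_1se)
            found += int(np.sum(beta[:5] != 0) >= 4)
        assert found >= 4


class TestStability:
    def test_threshold_is_at_least_half(self, rng):
        X, y = binary_world(rng, 600, [2.0], prevalence=0.3, p_extra=9)
        cols = [f"p{i}" for i in range(10)]
        res = sp.stability_select(
            pd.DataFrame(X, columns=cols), y, penalty=0.02, n_iter=10, seed=0
        )
        # a feature with frequency exactly at the threshold is selected
        res.frequency["p1"] = 0.5
        selected = sorted(
            res.frequency.index[(res.frequency >= res.threshold)]
        )
        assert "p1" in selected

    def test_refuses_fewer_controls_than_cases(self, rng):
        X = rng.normal(size=(30, 3))
        y = np.array([1] * 20 + [0] * 10, dtype=float)
        with pytest.raises(ValueError, match="without\\s+replacement"):
            sp.stability_select(pd.DataFrame(X), y, penalty=0.01)

    def test_seed_stability(self, rng):
        X, y = binary_world(rng, 500, [1.5], prevalence=0.3, p_extra=5)
        df = pd.DataFrame(X, columns=[f"p{i}" for i in range(6)])
        a = sp.stability_select(df, y, 0.02, n_iter=20, seed=3)
        b = sp.stability_select(df, y, 0.02, n_iter=20, seed=3)
        pd.testing.assert_series_equal(a.frequency, b.frequency)


class TestRefit:
    def _train(self, rng, n=2000):
        X, y = binary_world(rng, n, [0.8, 0.0], prevalence=0.2, p_extra=0)
        return pd.DataFrame(
            {
                "y": y,
                "protA": X[:, 0],
                "protB": X[:, 1],
                "age": rng.normal(60, 8, n),
                "sex": rng.integers(0, 2, n).astype(float),
                "bmi": rng.normal(27, 4, n),
                "hap_count": rng.binomial(2, 0.15, n).astype(float),
            }
        )

    def test_basic_model_has_three_predictors(self, rng):
        models = sp.refit_models(self._train(rng), "y", [])
        assert models["basic"].predictors == ["age", "sex", "bmi"]
        assert set(models) == {"basic"}

    def test_four_models_and_forced_terms(self, rng):
        models = sp.refit_models(self._train(rng), "y", ["protA", "protB"])
        assert set(models) == {
            "basic", "proteomic", "proteomic+basic", "apoe+proteomic+basic",
        }
        m4 = models["apoe+proteomic+basic"]
        assert {"age", "sex", "bmi", "hap_count"} <= set(m4.predictors)

    def test_null_protein_usually_eliminated(self):
        dropped = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            models = sp.refit_models(self._train(rng, n=4000), "y", ["protA", "protB"])
            if "protB" not in models["proteomic+basic"].predictors:
                dropped += 1
        assert dropped >= 8

    def test_aic_path_strictly_decreasing(self, rng):
        train = self._train(rng, n=3000)
        model = sp.stepwise_aic(train, "y", ["protA", "protB"], ["age"], "m")
        assert all(b < a for a, b in zip(model.aic_path, model.aic_path[1:]))


class TestEvaluate:
    def test_perfect_separation_scores(self):
        y = np.array([0, 0, 1, 1])
        assert sp.roc_auc(y, np.array([0.1, 0.2, 0.8, 0.9])) == 1.0
        assert sp.pr_auc(y, np.array([0.1, 0.2, 0.8, 0.9])) == 1.0

    def test_auc_equals_concordance_enumeration(self):
        y = np.array([0, 0, 1, 1, 0, 1, 0, 1])
        s = np.array([0.1, 0.4, 0.35, 0.8, 0.2, 0.7, 0.55, 0.55])
        conc = sum(
            (si > sj) + 0.5 * (si == sj) for si in s[y == 1] for sj in s[y == 0]
        )
        assert sp.roc_auc(y, s) == pytest.approx(conc / 16, abs=1e-12)

    def test_auc_invariant_under_monotone_transform(self, rng):
        y = rng.integers(0, 2, 200)
        s = rng.normal(size=200)
        base = sp.roc_auc(y, s)
        assert sp.roc_auc(y, np.exp(s)) == pytest.approx(base, abs=1e-12)
        assert sp.roc_auc(y, s**3) == pytest.approx(base, abs=1e-12)

    def test_pr_auc_of_constant_score_is_prevalence(self):
        y = np.array([1] * 10 + [0] * 90)
        assert sp.pr_auc(y, np.zeros(100)) == pytest.approx(0.1, abs=1e-12)

    def test_pr_auc_matches_sklearn_average_precision(self, rng):
        from sklearn.metrics import average_precision_score

        y = rng.integers(0, 2, 300)
        s = rng.normal(size=300)
        assert sp.pr_auc(y, s) == pytest.approx(
            average_precision_score(y, s), abs=1e-10
        )

    def test_delong_identical_scores(self, rng):
        y = rng.integers(0, 2, 100)
        s = rng.normal(size=100)
        delta, p = sp.delong_test(y, s, s)
        assert delta == 0.0 and p == 1.0

    def test_delong_detects_clear_difference(self, rng):
        n = 600
        y = rng.integers(0, 2, n)
        good = y + rng.normal(0, 0.5, n)
        junk = rng.normal(size=n)
        delta, p = sp.delong_test(y, good, junk)
        assert delta > 0.2 and p < 1e-6

    def test_single_class_test_set_rejected(self, rng):
        model = sp.FittedModel("m", ["x"], 0.0, np.array([1.0]), 0.0)
        df = pd.DataFrame({"x": rng.normal(size=10), "y": np.zeros(10)})
        with pytest.raises(ValueError, match="single class"):
            sp.evaluate({"m": model}, df, "y")


class TestPipelineProperty:
    def test_protein_models_beat_basic_when_signal_present(self):
        """With generated protein signal, the protein+demographic models beat
        demographics alone on held-out AUC in nearly all replicates."""
        wins = 0
        reps = 8
        for seed in range(reps):
            rng = np.random.default_rng(100 + seed)
            n = 4000
            prots = rng.normal(size=(n, 20))
            eta = 0.8 * prots[:, 0] + 0.6 * prots[:, 1]
            age = rng.normal(60, 8, n)
            eta_full = eta + 0.02 * (age - 60)
            c0 = brentq(lambda c: expit(c + eta_full).mean() - 0.15, -25, 25)
            y = (rng.random(n) < expit(c0 + eta_full)).astype(float)
            data = pd.DataFrame(
                {"y": y, "age": age,
                 "sex": rng.integers(0, 2, n).astype(float),
                 "bmi": rng.normal(27, 4, n),
                 "hap_count": rng.binomial(2, 0.15, n).astype(float)}
            )
            for k in range(20):
                data[f"prot{k:02d}"] = prots[:, k]
            train, test = sp.split(data, "y", seed=seed)
            stab = sp.stability_select(
                train[[f"prot{k:02d}" for k in range(20)]],
                train["y"], penalty=0.02, n_iter=30, seed=seed,
            )
            models = sp.refit_models(train, "y", stab.selected)
            ev = sp.evaluate(models, test, "y").metrics.set_index("model")
            if "proteomic+basic" in ev.index:
                wins += int(
                    ev.loc["proteomic+basic", "roc_auc"]
                    > ev.loc["basic", "roc_auc"]
                )
        assert wins >= reps - 1
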