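"""Forward-stepwise selection, R-squared curves and AUC machinery."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import frailty_audit as fa


def _orthonormal_design(n, p, seed):
    rng = np.random.default_rng(seed)
    Q, _ = np.linalg.qr(rng.standard_normal((n, p)))
    Q -= Q.mean(axis=0)
    Q /= np.linalg.norm(Q, axis=0)
    return pd.DataFrame(Q, columns=[f"c{i:02d}" for i in range(p)])


class TestForwardStepwiseLinear:
    def test_perfect_predictor_chosen_first_and_path_stops(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.standard_normal((200, 4)),
                         columns=list("abcd"))
        y = X["c"].to_numpy()
        path = fa.forward_stepwise(y, X, family="linear")
        assert path.selected[0] == "c"
        assert path.steps["r2"].iloc[0] > 1 - 1e-10
        assert len(path) == 1

    def test_orthonormal_selection_order_matches_correlation_ranking(self):
        X = _orthonormal_design(300, 6, seed=1)
        beta = np.array([0.0, 3.0, 1.0, 2.5, 0.5, 2.0])
        rng = np.random.default_rng(2)
        y = X.to_numpy() @ beta + 0.05 * rng.standard_normal(300)
        path = fa.forward_stepwise(y, X, family="linear")
        corr = np.abs(X.to_numpy().T @ (y - y.mean()))
        expected = [X.columns[i] for i in np.argsort(-corr)]
        assert path.selected == expected[: len(path.selected)]

    def test_each_step_matches_exhaustive_single_step_search(self):
        # oracle: at every step, refit current set + each remaining
        # candidate by brute force and confirm the selector's choice
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.standard_normal((250, 7)),
                         columns=[f"v{i}" for i in range(7)])
        y = (1.2 * X["v1"] - 0.8 * X["v4"] + 0.5 * X["v6"]
             + rng.standard_normal(250))
        path = fa.forward_stepwise(y, X, family="linear")
        current: list[str] = []
        for _, row in path.steps.iterrows():
            best_aic, best_name = np.inf, None
            for cand in sorted(c for c in X.columns if c not in current):
                design = sm.add_constant(X[current + [cand]])
                aic = sm.OLS(y, design).fit().aic
                if aic < best_aic - 1e-12:
                    best_aic, best_name = aic, cand
            assert row["variable"] == best_name
            assert row["aic"] == pytest.approx(best_aic, abs=1e-6)
            current.append(best_name)

    def test_pure_noise_candidates_rarely_accepted_and_aic_decreases(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.standard_normal((500, 10)),
                         columns=[f"n{i}" for i in range(10)])
        y = rng.standard_normal(500)
        path = fa.forward_stepwise(y, X, family="linear")
        assert len(path) <= 3
        aics = [path.null_aic] + path.steps["aic"].tolist()
        assert all(b < a for a, b in zip(aics, aics[1:]))
        # oracle: recompute AIC of each accepted model from its likelihood
        current = []
        for _, row in path.steps.iterrows():
            current.append(row["variable"])
            res = sm.OLS(y, sm.add_constant(X[current])).fit()
            assert row["aic"] == pytest.approx(2 * (len(current) + 1) - 2 * res.llf,
                                               abs=1e-6)

    def test_constant_response_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            fa.forward_stepwise(np.ones(3), X)

    def test_candidate_order_invariance(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.standard_normal((200, 5)),
                         columns=list("edcba"))
        y = X["b"].to_numpy() + 0.3 * rng.standard_normal(200)
        p1 = fa.forward_stepwise(y, X)
        p2 = fa.forward_stepwise(y, X[sorted(X.columns)])
        assert p1.selected == p2.selected


class TestForwardStepwiseLogistic:
    def test_driver_selected_first_with_auc_recorded(self):
        rng = np.random.default_rng(6)
        n = 600
        X = pd.DataFrame(rng.standard_normal((n, 4)), columns=list("wxyz"))
        p = 1 / (1 + np.exp(-(1.5 * X["x"])))
        y = (rng.random(n) < p).astype(int)
        path = fa.forward_stepwise(y, X, family="logistic")
        assert path.selected[0] == "x"
        assert 0.5 < path.steps["auc"].iloc[0] <= 1.0
        assert 0.0 < path.steps["pseudo_r2"].iloc[0] < 1.0

    def test_separating_candidate_skipped_not_crashed(self):
        rng = np.random.default_rng(7)
        n = 200
        X = pd.DataFrame({"noise": rng.standard_normal(n)})
        y = (rng.random(n) < 0.4).astype(int)
        X["copy_of_y"] = y.astype(float)  # perfectly separating
        path = fa.forward_stepwise(y, X, family="logistic")
        assert "copy_of_y" not in path.selected or len(path) >= 1

    def test_dummy_block_enters_as_group(self):
        rng = np.random.default_rng(8)
        n = 400
        g = rng.integers(0, 3, n)
        X = pd.DataFrame({
            "g_1": (g == 1).astype(float),
            "g_2": (g == 2).astype(float),
            "other": rng.standard_normal(n),
        })
        y = 1.0 * (g == 2) + rng.standard_normal(n)
        path = fa.forward_stepwise(
            y, X, family="linear",
            candidate_groups={"g": ["g_1", "g_2"], "other": ["other"]},
        )
        assert path.selected[0] == "g"


class TestCurveAndReach:
    def test_r2_curve_non_decreasing_and_matches_refit(self, indexed_small):
        from frailty_audit.variables import model_input_design_columns
        design = indexed_small.copy()
        design["sex"] = (design["sex"] == "female").astype(float)
        cols = model_input_design_columns(fa.FD_MODEL)
        y = indexed_small["index__FD"].to_numpy()
        path = fa.forward_stepwise(y, design[cols], family="linear")
        curve = fa.r2_curve(path)["statistic"].to_numpy()
        assert (np.diff(curve) > -1e-12).all()
        # oracle: refit each cumulative set from scratch
        for step in range(1, len(path) + 1):
            sel = path.selected[:step]
            Xc = np.column_stack(
                [np.ones(len(y)), design[sel].to_numpy(dtype=float)]
            )
            beta, *_ = np.linalg.lstsq(Xc, y, rcond=None)
            rss = np.sum((y - Xc @ beta) ** 2)
            r2 = 1 - rss / np.sum((y - y.mean()) ** 2)
            assert curve[step - 1] == pytest.approx(r2, abs=1e-8)

    def test_variables_to_reach(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.standard_normal((200, 3)), columns=list("abc"))
        y = X["a"].to_numpy()
        path = fa.forward_stepwise(y, X)
        assert fa.variables_to_reach(path, 0.9) == 1
        with pytest.raises(ValueError):
            fa.variables_to_reach(path, 1.5)

    def test_exchangeable_burden_items_can_be_simplified(self):
        # 24 exchangeable binary items: far fewer than 24 are needed to
        # reach 90% of the attainable R-squared of their equal-weight sum
        rng = np.random.default_rng(10)
        n = 1500
        z = rng.standard_normal(n)
        items = pd.DataFrame(
            {f"i{j:02d}": (rng.random(n) < 1 / (1 + np.exp(-z))).astype(float)
             for j in range(24)}
        )
        y = items.sum(axis=1) / 24.0
        path = fa.forward_stepwise(y, items, family="linear")
        reach90 = fa.variables_to_reach(path, 0.90)
        reach100 = fa.variables_to_reach(path, 1.0)
        assert reach90 < 24
        assert reach100 == len(path)


class TestAuc:
    def test_perfect_separation(self):
        out = fa.auc_with_ci([0.9, 0.8, 0.7, 0.1], [1, 1, 0, 0])
        assert out["auc"] == 1.0

    def test_tiny_instance(self):
        out = fa.auc_with_ci([0.9, 0.8, 0.7, 0.1], [1, 1, 0, 0])
        assert out["auc"] == 1.0
        assert out["ci_high"] <= 1.0

    def test_null_scores_cover_half(self):
        rng = np.random.default_rng(11)
        scores = rng.random(2000)
        labels = rng.integers(0, 2, 2000)
        out = fa.auc_with_ci(scores, labels)
        assert out["ci_low"] <= 0.5 <= out["ci_high"]
        # Mann-Whitney oracle
        from scipy.stats import mannwhitneyu
        u = mannwhitneyu(scores[labels == 1], scores[labels == 0]).statistic
        n1, n0 = (labels == 1).sum(), (labels == 0).sum()
        assert out["auc"] == pytest.approx(u / (n1 * n0), abs=1e-12)

    @pytest.mark.parametrize("seed", [12, 13, 14])
    def test_matches_brute_force_pairwise(self, seed):
        rng = np.random.default_rng(seed)
        n = 150
        scores = np.round(rng.random(n), 1)  # force ties
        labels = rng.integers(0, 2, n)
        pos, neg = scores[labels == 1], scores[labels == 0]
        brute = np.mean(
            [(1.0 if p > q else 0.5 if p == q else 0.0) for p in pos for q in neg]
        )
        assert fa.auc_with_ci(scores, labels)["auc"] == pytest.approx(brute)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fa.auc_with_ci([0.1, 0.2], [1, 1])
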