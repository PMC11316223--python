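"""Shapley attributions, feature ranking, ANOVA/Dunnett."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from sklearn.ensemble import GradientBoostingClassifier

from fibromorph import (
    FEATURE_NAMES,
    TreeShapExplainer,
    ValidationError,
    anova_dunnett,
    anova_f,
    exact_shapley,
    rank_features_shap,
)


class TestExactShapley:
    def test_symmetric_players_get_equal_shares(self):
        phi = exact_shapley(lambda s: float(len(s) > 0), 4)
        np.testing.assert_allclose(phi, phi[0])
        assert phi.sum() == pytest.approx(1.0)

    def test_dummy_player_gets_zero(self):
        phi = exact_shapley(lambda s: float(0 in s), 3)
        assert phi[0] == pytest.approx(1.0)
        np.testing.assert_allclose(phi[1:], 0.0, atol=1e-12)

    def test_additive_game_returns_weights(self):
        w = [2.0, 3.0, 5.0]
        phi = exact_shapley(lambda s: sum(w[i] for i in s), 3)
        np.testing.assert_allclose(phi, w)

    def test_rejects_large_n(self):
        with pytest.raises(ValidationError):
            exact_shapley(lambda s: 0.0, 11)


@pytest.fixture(scope="module")
def fitted_model():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(160, 8))
    y = (X[:, 2] + 0.6 * X[:, 5] + 0.4 * rng.normal(size=160) > 0).astype(int)
    model = GradientBoostingClassifier(n_estimators=40, max_depth=3, random_state=0)
    model.fit(X, y)
    return model, X


class TestTreeShapExplainer:
    def test_matches_exact_enumeration_on_8_features(self, fitted_model):
        model, X = fitted_model
        bg = X[:20]
        explainer = TreeShapExplainer(model, bg)
        phi, _ = explainer.shap_values(X[:3])
        for i in range(3):
            x = X[i]

            def value(S, x=x):
                Xm = np.tile(x, (len(bg), 1))
                for j in range(8):
                    if j not in S:
                        Xm[:, j] = bg[:, j]
                return model.decision_function(Xm).mean()

            phi_exact = exact_shapley(value, 8)
            np.testing.assert_allclose(phi[i], phi_exact, atol=1e-6)

    def test_local_accuracy_on_ten_samples(self, fitted_model):
        model, X = fitted_model
        explainer = TreeShapExplainer(model, X[:32])
        phi, base = explainer.shap_values(X[:10])
        f = model.decision_function(X[:10])
        np.testing.assert_allclose(base + phi.sum(axis=1), f, rtol=1e-6)

    def test_additive_linear_value_function(self):
        # a stump ensemble on independent features is additive; attributions
        # must then equal the per-feature contribution differences
        rng = np.random.default_rng(1)
        X = rng.normal(size=(400, 3))
        y = (X[:, 0] > 0).astype(int)
        model = GradientBoostingClassifier(n_estimators=20, max_depth=1, random_state=0)
        model.fit(X, y)
        explainer = TreeShapExplainer(model, X[:50])
        phi, base = explainer.shap_values(X[:5])
        # depth-1 trees split only on the informative feature
        np.testing.assert_allclose(phi[:, 1:], 0.0, atol=1e-9)
        np.testing.assert_allclose(
            base + phi[:, 0], model.decision_function(X[:5]), rtol=1e-9
        )


def feature_frame(X, labels):
    df = pd.DataFrame(X, columns=FEATURE_NAMES[: X.shape[1]])
    df.insert(0, "condition", labels)
    return df


class TestRankFeatures:
    def test_planted_discriminative_feature_ranks_first(self):
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            n = 60
            X = rng.normal(size=(2 * n, 12))
            labels = np.array(["control"] * n + ["treated"] * n)
            X[n:, 4] += 3.0  # single 3-SD shifted feature
            report = rank_features_shap(
                feature_frame(X, labels), control="control", seed=seed
            )
            wins += report.ranking[0] == FEATURE_NAMES[4]
        assert wins >= 19

    def test_permuted_labels_flag_near_chance_model(self):
        rng = np.random.default_rng(5)
        n = 60
        X = rng.normal(size=(2 * n, 10))
        X[n:, 2] += 3.0
        labels = np.array(["control"] * n + ["treated"] * n)
        perm = rng.permutation(labels)
        report = rank_features_shap(feature_frame(X, perm), control="control", seed=0)
        assert not report.reliable

    def test_constant_features_dropped_with_warning(self):
        rng = np.random.default_rng(6)
        n = 30
        X = rng.normal(size=(2 * n, 8))
        X[:, 3] = 1.0
        X[n:, 0] += 3.0
        labels = np.array(["control"] * n + ["treated"] * n)
        report = rank_features_shap(feature_frame(X, labels), control="control", seed=0)
        assert FEATURE_NAMES[3] in report.dropped_features
        assert FEATURE_NAMES[3] not in report.ranking

    def test_single_condition_rejected(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(20, 5))
        with pytest.raises(ValidationError):
            rank_features_shap(feature_frame(X, ["only"] * 20), seed=0)


class TestAnovaDunnett:
    def test_identical_groups_give_f_zero_p_one(self):
        res = anova_dunnett({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]}, "a", seed=0)
        assert res.f_statistic == 0.0
        assert res.anova_p == 1.0
        assert np.all(res.dunnett["p_adjusted"] == 1.0)

    def test_f_matches_sum_of_squares_oracle(self):
        groups = {"a": np.array([1.0, 2, 3]), "b": np.array([2.0, 3, 4]), "c": np.array([3.0, 4, 5])}
        # explicit between/within sums of squares
        allv = np.concatenate(list(groups.values()))
        grand = allv.mean()
        ssb = sum(len(v) * (v.mean() - grand) ** 2 for v in groups.values())
        ssw = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
        f_expected = (ssb / 2) / (ssw / 6)
        f, p = anova_f(groups)
        assert f == pytest.approx(f_expected)
        f_sp, p_sp = sps.f_oneway(*groups.values())
        assert f == pytest.approx(f_sp)
        assert p == pytest.approx(p_sp)

    def test_adjusted_p_at_least_unadjusted_on_random_data(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            k = rng.integers(3, 6)
            groups = {
                f"g{i}": rng.normal(rng.uniform(-0.5, 0.5), 1.0, size=rng.integers(5, 12))
                for i in range(k)
            }
            res = anova_dunnett(groups, "g0", seed=1, n_mc=100_000)
            assert np.all(
                res.dunnett["p_adjusted"].to_numpy()
                >= res.dunnett["p_unadjusted"].to_numpy() - 1e-9
            )

    def test_monte_carlo_close_to_scipy_reference(self):
        rng = np.random.default_rng(3)
        groups = {
            "ctrl": rng.normal(0, 1, 12),
            "t1": rng.normal(0.8, 1, 10),
            "t2": rng.normal(-0.3, 1, 11),
        }
        res = anova_dunnett(groups, "ctrl", seed=0, n_mc=200_000)
        ref = sps.dunnett(groups["t1"], groups["t2"], control=groups["ctrl"])
        np.testing.assert_allclose(
            res.dunnett["p_adjusted"].to_numpy(), ref.pvalue, atol=0.01
        )

    def test_seed_reproducible(self):
        groups = {"a": [1.0, 2, 3, 4], "b": [2.0, 4, 5, 6], "c": [0.5, 1, 2, 2.5]}
        r1 = anova_dunnett(groups, "a", seed=9)
        r2 = anova_dunnett(groups, "a", seed=9)
        pd.testing.assert_frame_equal(r1.dunnett, r2.dunnett)

    def test_adjusted_p_grows_with_comparison_count(self):
        rng = np.random.default_rng(4)
        base = {"ctrl": rng.normal(0, 1, 10), "g1": rng.normal(0.7, 1, 10)}
        extra = {"g2": rng.normal(0.1, 1, 10), "g3": rng.normal(-0.2, 1, 10)}
        p2 = anova_dunnett(base, "ctrl", seed=0).dunnett.set_index("group")["p_adjusted"]["g1"]
        p4 = anova_dunnett({**base, **extra}, "ctrl", seed=0).dunnett.set_index("group")[
            "p_adjusted"
        ]["g1"]
        assert p4 >= p2 - 1e-3

    def test_small_groups_rejected(self):
        with pytest.raises(ValidationError):
            anova_dunnett({"a": [1.0], "b": [1.0, 2.0]}, "a", seed=0)
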