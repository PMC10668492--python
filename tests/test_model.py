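"""Registries, selection oracles, cross-validation, PSM, embedding, grouping."""

import numpy as np
import pandas as pd
import pytest

from dualdelta import model


@pytest.fixture(scope="module")
def registries():
    return model.default_selector_registry(), model.default_classifier_registry()


def planted_table(n=500, p=100, k_inf=5, effect=1.2, seed=0):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    X = pd.DataFrame(rng.normal(size=(n, p)),
                     columns=[f"c{i}" for i in range(p)])
    for i in range(k_inf):
        X[f"c{i}"] += effect * y
    return X, y


class TestGrid:
    def test_default_grid_has_1440_combinations(self, registries):
        sel, clf = registries
        assert len(sel) == 45
        assert len(clf) == 32
        assert len(model.enumerate_grid(sel, clf)) == 1440

    def test_small_cross_product(self):
        sel = model.SelectorRegistry(
            {n: model.Selector(n, lambda X, y: np.ones(X.shape[1])) for n in "ab"})
        clf = model.ClassifierRegistry({n: object() for n in "xyz"})
        combos = model.enumerate_grid(sel, clf)
        assert len(combos) == 6
        assert combos == model.enumerate_grid(sel, clf)  # stable order

    def test_empty_registry_rejected(self, registries):
        sel, _ = registries
        with pytest.raises(ValueError, match="nonempty"):
            model.enumerate_grid(sel, model.ClassifierRegistry({}))

    def test_run_grid_separable_and_consistency(self, registries):
        sel_reg, clf_reg = registries
        X, y = planted_table(n=120, p=20, effect=3.0, seed=1)
        small_sel = model.SelectorRegistry({"anova_f": sel_reg["anova_f"]})
        small_clf = model.ClassifierRegistry({"lda": clf_reg["lda"]})
        grid = model.run_grid(X, y, small_sel, small_clf, replications=2, seed=0,
                              n_features=10)
        assert grid.best == ("anova_f", "lda")
        assert grid.best_auc >= 0.99
        direct = model.crossval_auc(sel_reg["anova_f"], clf_reg["lda"], X, y,
                                    replications=2, seed=0, n_features=10)
        assert grid.best_auc == pytest.approx(direct.mean_auc)

    def test_run_grid_null_labels_bounded(self, registries):
        """Selection bias over a small grid cannot manufacture large AUC."""
        sel_reg, clf_reg = registries
        sub_sel = model.SelectorRegistry(
            {k: sel_reg[k] for k in ("anova_f", "pearson_r", "variance")})
        sub_clf = model.ClassifierRegistry(
            {k: clf_reg[k] for k in ("logreg_C1.0", "lda", "gaussian_nb")})
        best = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.normal(size=(300, 30)),
                             columns=[f"n{i}" for i in range(30)])
            y = rng.integers(0, 2, 300)
            grid = model.run_grid(X, y, sub_sel, sub_clf, replications=1,
                                  seed=seed, n_features=10)
            best.append(grid.best_auc)
        assert max(best) <= 0.65


class TestLassoSelect:
    def test_planted_signal_recovery_across_seeds(self):
        hits = 0
        for seed in range(20):
            X, y = planted_table(n=500, p=100, k_inf=5, effect=1.2, seed=seed)
            res = model.lasso_select(X, y, alpha=0.5, seed=seed)
            found = sum(f"c{i}" in res.selected for i in range(5))
            hits += found >= 4
        assert hits >= 18  # >= 90% of seeds

    def test_collinear_duplicate_stays_finite(self):
        X, y = planted_table(n=200, p=20, seed=2)
        X["dup"] = X["c0"]
        res = model.lasso_select(X, y, alpha=0.5)
        assert np.isfinite(res.coefficients).all()
        assert len(res.selected) < X.shape[1]

    def test_zero_variance_column_never_selected(self):
        X, y = planted_table(n=200, p=20, seed=3)
        X["flat"] = 1.0
        res = model.lasso_select(X, y, alpha=0.5)
        assert "flat" not in res.selected

    def test_trajectory_exported(self):
        X, y = planted_table(n=100, p=10, seed=4)
        res = model.lasso_select(X, y)
        assert res.coef_path.shape[0] == 10
        assert len(res.alphas) == len(res.mse_path)
        assert res.alpha_min in res.alphas


class TestReliefF:
    def test_label_identical_feature_wins(self, rng):
        y = rng.integers(0, 2, 60)
        X = pd.DataFrame(rng.normal(size=(60, 5)),
                         columns=[f"f{i}" for i in range(5)])
        X["oracle"] = y.astype(float)
        w = model.relieff_rank(X, y, K=5)
        assert w.index[0] == "oracle"
        assert w.iloc[0] > 0.5

    def test_null_feature_weight_near_zero(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 1000)
        X = pd.DataFrame({"noise": rng.normal(size=1000),
                          "noise2": rng.uniform(size=1000)})
        w = model.relieff_rank(X, y, K=10)
        assert np.abs(w).max() < 0.05

    def test_matches_manual_nearest_hit_miss(self):
        # 6 samples, 1 feature, K=1: hand-computable
        X = pd.DataFrame({"f": [0.0, 0.1, 0.5, 0.55, 0.9, 1.0]})
        y = np.array([0, 0, 1, 1, 0, 0])
        w = model.relieff_rank(X, y, K=1)
        # manual computation over all 6 instances (range = 1.0, m = 6)
        manual = 0.0
        vals = X["f"].to_numpy()
        for i in range(6):
            d = np.abs(vals - vals[i])
            d_inf = d.copy()
            d_inf[i] = np.inf
            same = np.where(y == y[i])[0]
            hit = same[np.argmin(d_inf[same])]
            other = np.where(y != y[i])[0]
            miss = other[np.argmin(d_inf[other])]
            p_miss = (y == y[miss]).mean() / (1 - (y == y[i]).mean())
            manual += (-d[hit] + p_miss * d[miss]) / 6
        assert w["f"] == pytest.approx(manual, abs=1e-12)

    def test_k_too_large_rejected(self):
        X = pd.DataFrame({"f": np.arange(8.0)})
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        with pytest.raises(ValueError, match="K="):
            model.relieff_rank(X, y, K=4)


class TestCrossvalAUC:
    def test_perfect_scores_give_auc_one(self, registries):
        sel_reg, clf_reg = registries
        X, y = planted_table(n=80, p=5, effect=50.0, seed=5)
        rep = model.crossval_auc(None, clf_reg["lda"], X, y, replications=2, seed=0)
        assert rep.mean_auc == 1.0

    def test_null_labels_near_half(self, registries):
        _, clf_reg = registries
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(500, 10)),
                         columns=[f"f{i}" for i in range(10)])
        y = rng.integers(0, 2, 500)
        rep = model.crossval_auc(None, clf_reg["logreg_C1.0"], X, y,
                                 replications=5, seed=0)
        assert 0.45 <= rep.mean_auc <= 0.55

    def test_auc_equals_concordant_pair_counting(self):
        from sklearn.metrics import roc_auc_score

        scores = np.array([0.1, 0.4, 0.35, 0.8, 0.65, 0.2, 0.9, 0.5, 0.3, 0.7])
        y = np.array([0, 0, 1, 1, 0, 0, 1, 1, 0, 1])
        pairs = concordant = 0
        for i in np.where(y == 1)[0]:
            for j in np.where(y == 0)[0]:
                pairs += 1
                if scores[i] > scores[j]:
                    concordant += 1
                elif scores[i] == scores[j]:
                    concordant += 0.5
        assert roc_auc_score(y, scores) == pytest.approx(concordant / pairs)

    def test_leakage_canary_many_noise_features(self, registries):
        """In-fold selection over many pure-noise columns must not inflate
        AUC the way whole-dataset selection would."""
        sel_reg, clf_reg = registries
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(100, 300)),
                         columns=[f"n{i}" for i in range(300)])
        y = rng.integers(0, 2, 100)
        rep = model.crossval_auc(sel_reg["anova_f"], clf_reg["lda"], X, y,
                                 replications=3, seed=0, n_features=10)
        assert rep.mean_auc < 0.65

    def test_too_few_minority_samples_rejected(self, registries):
        _, clf_reg = registries
        X = pd.DataFrame({"f": np.arange(10.0)})
        y = np.array([1, 0, 0, 0, 0, 0, 0, 0, 0, 0])
        with pytest.raises(ValueError, match="minority"):
            model.crossval_auc(None, clf_reg["lda"], X, y, folds=5)


class TestConfusionMetrics:
    def test_all_correct(self):
        m = model.confusion_metrics([1, 1, 0, 0], [1, 1, 0, 0])
        assert (m["accuracy"], m["sensitivity"], m["specificity"]) == (1, 1, 1)

    def test_all_predicted_negative(self):
        m = model.confusion_metrics([0, 0, 0, 0], [1, 0, 1, 0])
        assert m["sensitivity"] == 0.0
        assert m["specificity"] == 1.0

    def test_hand_built_counts(self):
        y = np.array([1] * 17 + [0] * 52)
        pred = np.array([1] * 12 + [0] * 5 + [1] * 4 + [0] * 48)
        m = model.confusion_metrics(pred, y)
        assert m["accuracy"] == pytest.approx(60 / 69)
        assert m["sensitivity"] == pytest.approx(12 / 17)
        assert m["specificity"] == pytest.approx(48 / 52)
        np.testing.assert_array_equal(m["matrix"], [[48, 4], [5, 12]])


class TestPSM:
    def test_identical_distributions_match_fully(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(400, 6)),
                         columns=list(model.DEFAULT_PSM_COVARIATES))
        y = np.array([1] * 120 + [0] * 280)
        res = model.psm_match(X, y)
        assert len(res.pairs) >= 110
        # 1:1 matching balances the propensity score; per-covariate SMD can
        # retain sampling noise of order sqrt(2/n_pairs) ~ 0.13
        assert res.smd_after.mean() < res.smd_before.mean()
        assert res.smd_after.abs().max() < 0.15
        # equal group sizes by construction
        assert len(res.matched_ids) == 2 * len(res.pairs)

    def test_disjoint_supports_yield_warning_and_few_matches(self):
        X = pd.DataFrame(np.zeros((40, 6)),
                         columns=list(model.DEFAULT_PSM_COVARIATES))
        X.iloc[:20] += 100.0
        y = np.array([1] * 20 + [0] * 20)
        with pytest.warns(UserWarning, match="matched"):
            res = model.psm_match(X, y, caliper_sd=0.01)
        assert len(res.pairs) < 20

    def test_missing_covariates_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2.0]})
        with pytest.raises(ValueError, match="missing"):
            model.psm_match(X, np.array([0, 1]))


class TestEmbedding:
    def test_shape_and_reproducibility(self, rng):
        X = pd.DataFrame(rng.normal(size=(90, 10)))
        a = model.embed_features(X, perplexity=10, seed=0)
        b = model.embed_features(X, perplexity=10, seed=0)
        assert a.shape == (90, 2)
        np.testing.assert_array_equal(a, b)

    def test_planted_clusters_remain_separated(self):
        from sklearn.metrics import silhouette_score

        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 1, (60, 8)), rng.normal(10, 1, (60, 8))])
        labels = np.array([0] * 60 + [1] * 60)
        emb = model.embed_features(pd.DataFrame(X), perplexity=15, seed=0)
        assert silhouette_score(emb, labels) > 0.5

    def test_too_few_samples_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 4)))
        with pytest.raises(ValueError, match="perplexity"):
            model.embed_features(X, perplexity=10, seed=0)


class TestIntervalGroups:
    @pytest.mark.parametrize("days,group", [
        (30, "A"), (90, "A"), (91, "B"), (364, "B"), (365, "C"),
        (400, "C"), (729, "C"),
    ])
    def test_boundary_convention(self, days, group):
        out = model.group_by_interval(pd.DataFrame({"interval_days": [days]}))
        assert out.iloc[0] == group

    @pytest.mark.parametrize("days", [10, 730, 1000])
    def test_out_of_range_excluded(self, days):
        out = model.group_by_interval(pd.DataFrame({"interval_days": [days]}))
        assert pd.isna(out.iloc[0])
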