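"""Bootstrap splits, importance ranking, relevance testing, tier selection."""

import numpy as np
import pytest

from metabosig.signature import (
    SelectorConfig, half_interval_search, importance_rank, relevance_test,
    select_signature, signature_performance, stratified_bootstrap_split,
    confusion_metrics,
)

from conftest import make_class_table


class TestBootstrapSplit:
    def test_class_ratio_preserved(self):
        y = np.array([0] * 38 + [1] * 36)
        rng = np.random.default_rng(0)
        tr, te = stratified_bootstrap_split(y, 0.2, rng)
        assert len(tr) == 74
        assert abs(int((y[tr] == 0).sum()) - 38) <= 1

    def test_test_set_is_out_of_bag(self):
        y = np.array([0] * 20 + [1] * 20)
        rng = np.random.default_rng(1)
        for _ in range(20):
            tr, te = stratified_bootstrap_split(y, 0.25, rng)
            assert len(np.intersect1d(tr, te)) == 0
            assert len(np.unique(te)) == len(te)
            assert len(np.unique(y[te])) == 2
            assert len(np.unique(y[tr])) == 2

    def test_seeded_reproducibility(self):
        y = np.array([0] * 15 + [1] * 15)
        a = stratified_bootstrap_split(y, 0.2, np.random.default_rng(42))
        b = stratified_bootstrap_split(y, 0.2, np.random.default_rng(42))
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_tiny_class_errors(self):
        with pytest.raises(ValueError):
            stratified_bootstrap_split(np.array([0, 0, 0, 1]), 0.2,
                                       np.random.default_rng(0))


class TestImportanceRank:
    @pytest.mark.parametrize("clf", ["plsda", "random_forest", "svm"])
    def test_single_informative_feature_ranks_first(self, clf):
        tab = make_class_table(2, n_per=30, n_noise=10, n_informative=1,
                               effect=2.5)
        ranked = importance_rank(clf, tab.X, tab.y, tab.features,
                                 np.random.default_rng(0))
        assert ranked[0] == "inf0"

    def test_duplicated_columns_adjacent_under_plsda(self):
        tab = make_class_table(3, n_per=20, n_noise=6, n_informative=1)
        X = np.hstack([tab.X, tab.X[:, [0]]])
        feats = tab.features + ["inf0_copy"]
        ranked = importance_rank("plsda", X, tab.y, feats)
        assert abs(ranked.index("inf0") - ranked.index("inf0_copy")) == 1

    def test_noise_ranking_unstable_across_seeds(self):
        tops = set()
        for seed in range(20):
            tab = make_class_table(50 + seed, n_per=20, n_noise=30)
            ranked = importance_rank("plsda", tab.X, tab.y, tab.features)
            tops.add(ranked[0])
        assert len(tops) > 5  # no stable top feature on pure noise


class _PrefixModel:
    """Predicts from one designated column's sign."""

    def __init__(self, col):
        self.col = col

    def predict(self, X):
        return (X[:, self.col] > 0).astype(int)


class _SpreadModel:
    """Mean of many columns; destroyed by permuting any large subset."""

    def predict(self, X):
        return (X.mean(axis=1) > 0).astype(int)


class TestRelevance:
    def _data(self, seed, n=60, p=12):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, p))
        return X, rng

    def test_single_feature_model_feature_relevant(self):
        X, rng = self._data(4)
        y = (X[:, 3] > 0).astype(int)
        assert relevance_test(_PrefixModel(3), X, y, [3], 0.05, rng)

    def test_spread_model_single_candidate_fails(self):
        rng = np.random.default_rng(5)
        n, p = 100, 10
        latent = rng.standard_normal(n)
        X = latent[:, None] + 0.8 * rng.standard_normal((n, p))
        y = (X.mean(axis=1) > 0).astype(int)
        assert not relevance_test(_SpreadModel(), X, y, [0], 0.05, rng)

    def test_alpha_one_degenerate_everything_relevant(self):
        X, rng = self._data(6)
        y = rng.integers(0, 2, len(X))
        assert relevance_test(_PrefixModel(0), X, y, [0], 1.0, rng)

    def test_small_test_set_errors(self):
        X = np.zeros((4, 3))
        with pytest.raises(ValueError):
            relevance_test(_PrefixModel(0), X, np.zeros(4), [0], 0.05,
                           np.random.default_rng(0))


class TestHalfIntervalSearch:
    def test_matches_exhaustive_scan_on_monotone_oracles(self):
        # independent oracle: linear scan over all prefixes
        rng = np.random.default_rng(7)
        for _ in range(50):
            p = int(rng.integers(1, 40))
            thr = int(rng.integers(1, p + 1))
            ranked = [f"f{i}" for i in range(p)]
            calls = []

            def oracle(prefix, thr=thr, calls=calls):
                calls.append(len(prefix))
                return len(prefix) >= thr

            got = half_interval_search(ranked, oracle)
            linear = next(
                (ranked[:k] for k in range(1, p + 1) if k >= thr), []
            )
            assert got == linear
            assert len(set(calls)) <= int(np.ceil(np.log2(max(p, 2)))) + 1

    def test_never_relevant_gives_empty(self):
        assert half_interval_search(list("abcd"), lambda _: False) == []

    def test_always_relevant_gives_top_feature(self):
        assert half_interval_search(list("abcd"), lambda _: True) == ["a"]


class TestSelectSignature:
    def test_recovers_planted_discriminants(self):
        tab = make_class_table(8, n_per=40, n_noise=60, n_informative=3,
                               effect=1.5)
        tiers = select_signature(tab, SelectorConfig(seed=8))
        truth = {"inf0", "inf1", "inf2"}
        best = max(len(tiers.tier_set(c, "S") & truth) for c in tiers.tiers)
        assert best >= 2

    def test_tier_exclusivity_and_containment(self):
        tab = make_class_table(9, n_per=25, n_noise=40, n_informative=2)
        tiers = select_signature(tab, SelectorConfig(seed=9))
        for clf, fmap in tiers.tiers.items():
            s = tiers.tier_set(clf, "S")
            final = set(tiers.selections[clf][-1]) if tiers.selections[clf] else set()
            assert s <= final
            counts = {}
            for t in fmap.values():
                counts[t] = counts.get(t, 0) + 1
            assert sum(v for k, v in counts.items() if k != "none") \
                == len(s) + len(tiers.tier_set(clf, "A")) + len(tiers.tier_set(clf, "E"))

    def test_seeded_run_reproducible(self):
        tab = make_class_table(10, n_per=20, n_noise=25, n_informative=2)
        cfg = SelectorConfig(seed=11, n_boot=20)
        a = select_signature(tab, cfg)
        b = select_signature(tab, cfg)
        assert a.tiers == b.tiers
        assert a.selections == b.selections

    def test_column_order_invariance(self):
        tab = make_class_table(12, n_per=25, n_noise=20, n_informative=2,
                               effect=2.0)
        perm = list(np.random.default_rng(0).permutation(tab.n_features))
        shuffled = tab.select([tab.features[j] for j in perm])
        cfg = SelectorConfig(seed=13, n_boot=20, classifiers=("plsda",))
        a = select_signature(tab, cfg)
        b = select_signature(shuffled, cfg)
        assert a.tier_set("plsda", "S") == b.tier_set("plsda", "S")

    def test_too_few_samples_errors(self):
        tab = make_class_table(14, n_per=4, n_noise=5)
        with pytest.raises(ValueError):
            select_signature(tab, SelectorConfig(seed=0))


class TestSignaturePerformance:
    def test_confusion_arithmetic(self):
        m = confusion_metrics(tp=2, fn=1, tn=2, fp=1)
        assert m["sensitivity"] == pytest.approx(66.7, abs=0.05)
        assert m["specificity"] == pytest.approx(66.7, abs=0.05)

    def test_undefined_metrics_are_nan_not_zero(self):
        m = confusion_metrics(tp=0, fn=0, tn=3, fp=2)
        assert np.isnan(m["sensitivity"])
        assert not np.isnan(m["npv"])

    def test_perfect_separator_scores_100(self):
        tab = make_class_table(15, n_per=20, n_noise=4, n_informative=1,
                               effect=30.0)
        perf = signature_performance(tab, ["inf0"],
                                     SelectorConfig(seed=1, n_boot=20))
        for k in ("sensitivity", "specificity", "ppv", "npv"):
            assert perf[k] == pytest.approx(100.0)

    def test_random_classifier_near_chance(self):
        tab = make_class_table(16, n_per=100, n_noise=3, n_informative=0)
        perf = signature_performance(
            tab, ["noise0"], SelectorConfig(seed=2, n_boot=50, test_fraction=0.4)
        )
        for k in ("sensitivity", "specificity", "ppv", "npv"):
            assert 35.0 < perf[k] < 65.0

    def test_empty_signature_errors(self, cohort):
        tab = make_class_table(17, n_per=10, n_noise=4)
        with pytest.raises(ValueError):
            signature_performance(tab, [])
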