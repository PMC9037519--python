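import numpy as np
import pandas as pd
import pytest

import gutmint as gm
from gutmint.svm_ensemble import (
    RfeResult,
    _run_protocol,
    _scale_train_test,
    default_cost_grid,
)


def pair_count_auc(scores, labels):
    """O(n^2) oracle: wins + half-ties over positive/negative pairs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for sp in pos:
        for sn in neg:
            wins += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return wins / (len(pos) * len(neg))


class TestCostGrid:
    def test_default_grid_shape(self):
        g = default_cost_grid()
        assert len(g) == 13
        assert g[0] == pytest.approx(0.001)
        np.testing.assert_allclose(g[1:] / g[:-1], 10.0)

    def test_non_increasing_grid_rejected(self):
        with pytest.raises(ValueError):
            gm.tune_cost(
                np.zeros((20, 2)), np.repeat([0, 1], 10), grid=[1.0, 0.5]
            )


class TestMakeSplits:
    def test_split_sizes(self):
        plan = gm.make_splits(np.repeat([0, 1], 5), n_resamples=4, seed=0)
        for tr, te in plan.splits:
            assert len(tr) == 8 and len(te) == 2
            assert len(np.intersect1d(tr, te)) == 0
            assert len(np.union1d(tr, te)) == 10

    def test_stratification_one_per_class(self):
        y = np.repeat([0, 1], 5)
        plan = gm.make_splits(y, n_resamples=20, seed=1)
        for _, te in plan.splits:
            assert sorted(y[te]) == [0, 1]

    def test_determinism_and_plan_identity(self):
        y = np.repeat([0, 1], 20)
        a = gm.make_splits(y, n_resamples=5, seed=7)
        b = gm.make_splits(y, n_resamples=5, seed=7)
        assert a.plan_id == b.plan_id
        for (ta, ea), (tb, eb) in zip(a.splits, b.splits):
            np.testing.assert_array_equal(ta, tb)
            np.testing.assert_array_equal(ea, eb)
        c = gm.make_splits(y, n_resamples=5, seed=8)
        assert c.plan_id != a.plan_id

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError, match="< 2"):
            gm.make_splits(np.array([0, 1, 1, 1, 1]), n_resamples=1)


class TestTuneCost:
    def test_separable_data_ties_resolve_to_smallest(self, rng):
        X = np.vstack([rng.normal(-5, 0.1, (20, 2)), rng.normal(5, 0.1, (20, 2))])
        y = np.repeat([0, 1], 20)
        assert gm.tune_cost(X, y, seed=0) == pytest.approx(0.001)

    def test_returned_value_in_grid(self, rng):
        X = rng.normal(size=(40, 5))
        y = rng.integers(0, 2, size=40)
        while min((y == 0).sum(), (y == 1).sum()) < 5:
            y = rng.integers(0, 2, size=40)
        assert gm.tune_cost(X, y, seed=3) in default_cost_grid()

    def test_pure_noise_accuracy_near_chance(self, rng):
        X = rng.normal(size=(100, 10))
        y = np.repeat([0, 1], 50)
        # chance-level CV accuracy regardless of cost: the chosen cost's
        # accuracy cannot be extreme
        cost = gm.tune_cost(X, y, seed=5)
        assert cost in default_cost_grid()


class TestRfe:
    def test_elimination_order_is_permutation(self, rng):
        X = rng.normal(size=(60, 12))
        y = np.repeat([0, 1], 30)
        res = gm.rfe(X, y, cost=1.0, seed=2)
        assert sorted(res.elimination_order) == list(range(12))
        assert isinstance(res, RfeResult)

    def test_constant_feature_eliminated_before_informative(self, rng):
        n = 80
        informative = np.repeat([0.0, 3.0], n // 2) + rng.normal(0, 0.5, n)
        X = np.column_stack(
            [informative, np.zeros(n), rng.normal(size=(n, 3))]
        )
        y = np.repeat([0, 1], n // 2)
        res = gm.rfe(X, y, cost=1.0, seed=4)
        order = res.elimination_order
        assert order.index(1) < order.index(0)
        assert 0 in res.selected

    def test_perfect_feature_survives(self, rng):
        """A perfectly separating feature among 20 noise features reaches
        the selected subset in nearly every replicate."""
        wins = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            n = 200
            sep = np.repeat([-2.0, 2.0], n // 2)
            X = np.column_stack([sep, r.normal(size=(n, 20))])
            y = np.repeat([0, 1], n // 2)
            res = gm.rfe(X, y, cost=1.0, seed=seed)
            wins += 0 in res.selected
        assert wins >= 9


class TestAuc:
    def test_perfect_ranking(self):
        assert gm.auc([0.9, 0.8, 0.3, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_ties_half(self):
        assert gm.auc([1.0, 1.0, 1.0, 1.0], [1, 1, 0, 0]) == 0.5

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 13))
            labels = np.zeros(n, dtype=int)
            labels[: max(1, n // 2)] = 1
            rng.shuffle(labels)
            if labels.sum() in (0, n):
                continue
            scores = np.round(rng.normal(size=n), 1)  # force some ties
            assert gm.auc(scores, labels) == pytest.approx(
                pair_count_auc(scores, labels), abs=1e-12
            )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            gm.auc([0.1, 0.2], [1, 1])


class TestCompareAucs:
    def test_identical_results_p_one(self):
        x = np.linspace(0.6, 0.9, 50)
        stat, p, p_adj = gm.compare_aucs(x, x.copy())
        assert p == 1.0 and p_adj == 1.0

    def test_constant_shift_highly_significant(self):
        rng = np.random.default_rng(0)
        b = 0.6 + 0.05 * rng.random(100)
        a = b + 0.05
        _, p, _ = gm.compare_aucs(a, b)
        assert p < 1e-10

    def test_bonferroni_monotone(self, rng):
        a = rng.random(60)
        b = a + rng.normal(0, 0.01, 60)
        _, p, p_adj = gm.compare_aucs(a, b, n_comparisons=7)
        assert p_adj >= p
        assert p_adj <= 1.0

    def test_plan_identity_enforced(self, small_cohort):
        table = gm.aggregate_to_rank(
            small_cohort["microbiome"], small_cohort["lineage"], "family"
        )
        labels = small_cohort["truth"].class_labels
        plan_a = gm.make_splits(labels, n_resamples=3, seed=0)
        plan_b = gm.make_splits(labels, n_resamples=3, seed=99)
        res_a = gm.run_ensemble(table, labels, plan_a, seed=0)
        res_b = gm.run_ensemble(table, labels, plan_b, seed=0)
        with pytest.raises(ValueError, match="split plans"):
            gm.compare_aucs(res_a, res_b)


class TestRunEnsemble:
    def test_reproducible_and_well_formed(self, small_cohort):
        table = gm.aggregate_to_rank(
            small_cohort["microbiome"], small_cohort["lineage"], "family"
        )
        labels = small_cohort["truth"].class_labels
        plan = gm.make_splits(labels, n_resamples=4, seed=3)
        res1 = gm.run_ensemble(table, labels, plan, seed=3)
        res2 = gm.run_ensemble(table, labels, plan, seed=3)
        np.testing.assert_array_equal(res1.metric_post, res2.metric_post)
        np.testing.assert_array_equal(res1.weights, res2.weights)
        assert ((res1.metric_pre >= 0) & (res1.metric_pre <= 1)).all()
        assert res1.selected.any(axis=1).all()  # every resample selects >= 1
        assert res1.plan_id == plan.plan_id

    def test_no_leakage_from_test_samples(self, rng):
        """Corrupting test-sample features changes no fitted parameter,
        chosen cost, scaler statistic or selected feature set."""
        n, p = 60, 8
        X = rng.normal(size=(n, p))
        y = np.repeat([0, 1], n // 2)
        labels = pd.Series(y, index=[f"s{i}" for i in range(n)])
        table = gm.FeatureTable(
            pd.DataFrame(
                X, index=labels.index, columns=[f"f{j}" for j in range(p)]
            ),
            blocks="metabolite",
        )
        plan = gm.make_splits(labels, n_resamples=1, seed=1)
        res = gm.run_ensemble(table, labels, plan, seed=1)

        corrupted = table.data.copy()
        _, te = plan.splits[0]
        corrupted.iloc[te] += rng.normal(5, 3, size=(len(te), p))
        res_c = gm.run_ensemble(
            gm.FeatureTable(corrupted, blocks="metabolite"),
            labels,
            plan,
            seed=1,
        )
        np.testing.assert_array_equal(res.costs_pre, res_c.costs_pre)
        np.testing.assert_array_equal(res.costs_post, res_c.costs_post)
        np.testing.assert_array_equal(res.selected, res_c.selected)
        np.testing.assert_allclose(res.weights, res_c.weights)

    def test_scaling_helper_train_only(self, rng):
        Xtr = rng.normal(3, 2, size=(50, 4))
        Xte = rng.normal(3, 2, size=(10, 4))
        str_, ste = _scale_train_test(Xtr, Xte)
        np.testing.assert_allclose(str_.mean(0), 0, atol=1e-9)
        np.testing.assert_allclose(str_.std(0), 1, atol=1e-9)
        str2, _ = _scale_train_test(Xtr, Xte * 100)
        np.testing.assert_allclose(str_, str2)


class TestRankScan:
    def test_species_rank_equals_direct_run(self, small_cohort):
        table = small_cohort["microbiome"]
        labels = small_cohort["truth"].class_labels
        plan = gm.make_splits(labels, n_resamples=2, seed=5)
        scan = gm.rank_scan(
            table,
            small_cohort["lineage"],
            labels,
            plan,
            seed=5,
            ranks=["family", "species"],
        )
        direct = gm.run_ensemble(table, labels, plan, seed=5)
        np.testing.assert_allclose(
            scan.results["species"].metric_post, direct.metric_post
        )
        assert set(scan.results) == {"family", "species"}
        assert set(scan.comparisons) == {"family", "species"}
        assert not scan.auc_table().empty


class TestAssociatePhenotype:
    def test_phenotype_equal_to_feature_is_found(self, rng):
        n, p = 120, 6
        X = rng.normal(size=(n, p))
        pheno = X[:, 2] + rng.normal(0, 0.1, n)
        ids = [f"s{i}" for i in range(n)]
        table = gm.FeatureTable(
            pd.DataFrame(X, index=ids, columns=[f"f{j}" for j in range(p)]),
            blocks="metabolite",
        )
        res = gm.associate_phenotype(
            table,
            pd.Series(pheno, index=ids),
            "continuous",
            n_resamples=10,
            seed=2,
        )
        assert res.metric_name == "pearson_r"
        assert res.selection_frequency.index[0] == "f2"
        assert res.metric_post.mean() > 0.8

    def test_null_phenotype_near_zero_r(self, rng):
        n, p = 150, 10
        X = rng.normal(size=(n, p))
        pheno = rng.normal(size=n)
        ids = [f"s{i}" for i in range(n)]
        table = gm.FeatureTable(
            pd.DataFrame(X, index=ids, columns=[f"f{j}" for j in range(p)]),
            blocks="metabolite",
        )
        res = gm.associate_phenotype(
            table, pd.Series(pheno, index=ids), "continuous",
            n_resamples=30, seed=4,
        )
        assert -0.15 <= res.metric_post.mean() <= 0.15

    def test_binary_path_equals_run_ensemble(self, rng):
        n, p = 60, 5
        X = rng.normal(size=(n, p))
        y = np.repeat([0, 1], n // 2)
        ids = [f"s{i}" for i in range(n)]
        table = gm.FeatureTable(
            pd.DataFrame(X, index=ids, columns=[f"f{j}" for j in range(p)]),
            blocks="metabolite",
        )
        assoc = gm.associate_phenotype(
            table, pd.Series(y, index=ids), "binary", n_resamples=3, seed=6
        )
        plan = gm.make_splits(
            pd.Series(y, index=ids), n_resamples=3, seed=6
        )
        direct = _run_protocol(
            X, y, list(table.feature_ids), ids, plan, None,
            classifier=True, seed=6, step_fraction=0.1, cv=5,
        )
        np.testing.assert_allclose(assoc.metric_post, direct.metric_post)
        np.testing.assert_allclose(assoc.weights, direct.weights)

    def test_missing_dropped_before_split(self, rng):
        n = 40
        ids = [f"s{i}" for i in range(n)]
        X = rng.normal(size=(n, 4))
        table = gm.FeatureTable(
            pd.DataFrame(X, index=ids, columns=list("abcd")),
            blocks="metabolite",
        )
        pheno = pd.Series(rng.normal(size=n), index=ids)
        pheno.iloc[:25] = np.nan
        with pytest.raises(ValueError, match="non-missing"):
            gm.associate_phenotype(
                table, pheno, "continuous", n_resamples=2, seed=1
            )
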