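import dataclasses

import numpy as np
import pytest

import ldaeagcn as L
from ldaeagcn.evaluation import mean_report


def brute_force_auc(scores, labels):
    """Independent oracle: enumerate every positive-negative pair."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestKfoldSplit:
    def test_balanced_twenty_samples(self):
        labels = np.array([1] * 10 + [0] * 10)
        plan = L.kfold_split(labels, 10, seed=0)
        for train, test in plan.folds:
            assert len(test) == 2
            assert sorted(labels[test]) == [0, 1]
            assert set(train) | set(test) == set(range(20))
            assert not set(train) & set(test)

    def test_same_seed_same_plan(self):
        labels = np.array([1] * 12 + [0] * 15)
        p1 = L.kfold_split(labels, 5, seed=3)
        p2 = L.kfold_split(labels, 5, seed=3)
        assert p1.folds == p2.folds

    def test_union_of_test_folds_is_everything(self):
        labels = np.array([1] * 17 + [0] * 23)
        plan = L.kfold_split(labels, 7, seed=1)
        seen = sorted(i for _, test in plan.folds for i in test)
        assert seen == list(range(40))

    def test_small_class_rejected(self):
        labels = np.array([1] * 3 + [0] * 20)
        with pytest.raises(ValueError, match="fewer than k"):
            L.kfold_split(labels, 5, seed=0)


class TestRocAuc:
    def test_perfect_separation(self):
        assert L.roc_auc([0.9, 0.8, 0.4, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert L.roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_hand_enumeration(self):
        assert L.roc_auc([0.9, 0.8, 0.7, 0.1], [1, 0, 1, 0]) == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            L.roc_auc([0.1, 0.2], [1, 1])

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_pairwise_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 200))
        # quantized scores force plenty of ties
        scores = rng.integers(0, 8, size=n) / 8.0
        labels = rng.integers(0, 2, size=n)
        if labels.sum() in (0, n):
            labels[0] = 1 - labels[0]
        assert L.roc_auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_complement_identity_for_tie_free_scores(self, seed):
        rng = np.random.default_rng(100 + seed)
        scores = rng.permutation(np.linspace(0.01, 0.99, 30))
        labels = rng.integers(0, 2, size=30)
        if labels.sum() in (0, 30):
            labels[0] = 1 - labels[0]
        total = L.roc_auc(scores, labels) + L.roc_auc(scores, 1 - labels)
        assert total == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_sklearn_cross_check(self, seed):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(200 + seed)
        scores = rng.integers(0, 12, size=80) / 12.0
        labels = rng.integers(0, 2, size=80)
        labels[0], labels[1] = 1, 0
        assert L.roc_auc(scores, labels) == pytest.approx(
            sklearn_metrics.roc_auc_score(labels, scores), abs=1e-12)

    def test_invariant_to_sample_order(self):
        rng = np.random.default_rng(8)
        scores = rng.random(50)
        labels = rng.integers(0, 2, size=50)
        labels[0], labels[1] = 1, 0
        perm = rng.permutation(50)
        assert L.roc_auc(scores, labels) == pytest.approx(
            L.roc_auc(scores[perm], labels[perm]), abs=1e-12)


class TestPrAuc:
    def test_perfect_separation(self):
        assert L.pr_auc([0.9, 0.8, 0.4, 0.2], [1, 1, 0, 0]) == pytest.approx(1.0)

    def test_single_positive_ranked_first(self):
        assert L.pr_auc([0.9, 0.5, 0.4], [1, 0, 0]) == pytest.approx(1.0)

    def test_random_scores_approach_prevalence(self):
        rng = np.random.default_rng(0)
        n = 10_000
        scores = rng.random(n)
        labels = (rng.random(n) < 0.3).astype(int)
        prevalence = labels.mean()
        assert L.pr_auc(scores, labels) == pytest.approx(prevalence, abs=0.05)

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            L.pr_auc([0.5, 0.6], [0, 0])


class TestBinaryMetrics:
    def test_hand_confusion_counts(self):
        # TP=3, FP=1, TN=4, FN=2
        scores = [0.9, 0.8, 0.7, 0.6, 0.4, 0.3, 0.2, 0.1, 0.05, 0.01]
        labels = [1, 1, 1, 0, 1, 1, 0, 0, 0, 0]
        rep = L.binary_metrics(scores, labels, threshold=0.5)
        assert (rep.tp, rep.fp, rep.tn, rep.fn) == (3, 1, 4, 2)
        assert rep.acc == pytest.approx(0.7)
        assert rep.sen == pytest.approx(0.6)
        assert rep.spec == pytest.approx(0.8)
        assert rep.prec == pytest.approx(0.75)
        assert rep.mcc == pytest.approx(10 / np.sqrt(600), abs=1e-4)

    def test_perfect_prediction(self):
        rep = L.binary_metrics([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        for name in ("acc", "sen", "spec", "prec", "mcc", "auc", "aupr"):
            assert getattr(rep, name) == pytest.approx(1.0)

    def test_zero_denominator_flagged(self):
        rep = L.binary_metrics([0.1, 0.2, 0.3, 0.4], [0, 0, 1, 1], threshold=0.9)
        assert rep.prec == 0.0
        assert any("prec" in f for f in rep.flags)
        assert rep.mcc == 0.0

    def test_order_invariance(self):
        rng = np.random.default_rng(2)
        scores = rng.random(40)
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        perm = rng.permutation(40)
        a = L.binary_metrics(scores, labels)
        b = L.binary_metrics(scores[perm], labels[perm])
        assert a.as_dict() == pytest.approx(b.as_dict())


class TestCrossValidationHarness:
    def test_mean_row_is_arithmetic_mean(self, small_dataset, fast_model_config):
        _, dataset = small_dataset
        rep = L.cross_validate(dataset, fast_model_config, k=5, seed=2)
        for key, value in rep["mean"].items():
            assert value == pytest.approx(
                np.mean([getattr(f, key) for f in rep["folds"]]))

    def test_five_and_ten_fold_both_run(self, small_dataset, fast_model_config):
        _, dataset = small_dataset
        r5 = L.cross_validate(dataset, fast_model_config, k=5, seed=2)
        r10 = L.cross_validate(dataset, fast_model_config, k=10, seed=2)
        assert len(r5["folds"]) == 5 and len(r10["folds"]) == 10

    def test_independent_split_rows(self, small_dataset, fast_model_config):
        _, dataset = small_dataset
        rows = L.independent_split_evaluate(dataset, fast_model_config, seed=4)
        assert set(rows) == {"train", "test", "validation"}
        n_eval = sum(r.tp + r.fp + r.tn + r.fn for r in rows.values())
        assert n_eval == len(dataset.labels)

    def test_ablation_settings_and_core_protection(self, small_dataset,
                                                   fast_model_config):
        _, dataset = small_dataset
        reports = L.ablate_edges(dataset, [set(), {"ll_att", "dd_att"}],
                                 fast_model_config, k=3, seed=5)
        assert len(reports) == 2
        baseline = L.cross_validate(dataset, fast_model_config, k=3, seed=5)
        assert reports[0]["mean"] == pytest.approx(baseline["mean"])
        with pytest.raises(ValueError, match="core_att"):
            L.ablate_edges(dataset, [{"core_att"}], fast_model_config, k=3)

    def test_permuted_labels_keep_graphs(self, small_dataset):
        _, dataset = small_dataset
        permuted = L.with_permuted_labels(dataset, seed=3)
        assert sorted(permuted.labels) == sorted(dataset.labels)
        for g0, g1 in zip(dataset.graphs()[:5], permuted.graphs()[:5]):
            assert np.array_equal(g0.nomal_att, g1.nomal_att)


@pytest.fixture(scope="module")
def trained(small_dataset, fast_model_config):
    _, dataset = small_dataset
    params, _ = L.train_model(dataset.graphs(), fast_model_config)
    return params, dataset


class TestRankCandidates:
    def test_known_partners_excluded_and_sorted(self, trained, fast_model_config):
        params, dataset = trained
        disease = dataset.table.disease_ids[0]
        j = 0
        ranking = L.rank_candidates(params, fast_model_config, dataset, disease,
                                    top_k=10)
        assert len(ranking) == 10
        known = {dataset.table.lncrna_ids[i]
                 for i in range(dataset.table.n_lncrnas) if dataset.ldcm[i, j] == 1}
        assert not {name for name, _ in ranking} & known
        scores = [s for _, s in ranking]
        assert scores == sorted(scores, reverse=True)

    def test_top_k_larger_than_candidates_gives_full_list(self, trained,
                                                          fast_model_config):
        params, dataset = trained
        disease = dataset.table.disease_ids[1]
        n_candidates = int((dataset.ldcm[:, 1] == 0).sum())
        ranking = L.rank_candidates(params, fast_model_config, dataset, disease,
                                    top_k=10_000)
        assert len(ranking) == n_candidates

    def test_unknown_disease_rejected(self, trained, fast_model_config):
        params, dataset = trained
        with pytest.raises(KeyError):
            L.rank_candidates(params, fast_model_config, dataset, "no-such-disease")


def test_mean_report_arithmetic():
    reports = [
        L.binary_metrics([0.9, 0.1], [1, 0]),
        L.binary_metrics([0.4, 0.6], [1, 0]),
    ]
    mean = mean_report(reports)
    assert mean["acc"] == pytest.approx(0.5)
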