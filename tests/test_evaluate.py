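import warnings

import numpy as np
import pandas as pd
import pytest

import fsnorm as fn
from fsnorm.io import ExpressionMatrix, LabelVector
from fsnorm.evaluate import CVConfig

from _oracles import bf_balanced_accuracy, bf_kappa


def _labeled_data(n_per_class, p_noise, effect_genes, rng, classes=("A", "B")):
    """Samples x genes matrix with a few informative genes prepended."""
    n = n_per_class * len(classes)
    labels = [c for c in classes for _ in range(n_per_class)]
    X = rng.normal(0.0, 1.0, size=(n, len(effect_genes) + p_noise))
    for j, eff in enumerate(effect_genes):
        for i, lab in enumerate(labels):
            if lab == classes[0]:
                X[i, j] += eff
    ids = [f"s{i}" for i in range(n)]
    genes = [f"inf{j}" for j in range(len(effect_genes))] + [f"g{j}" for j in range(p_noise)]
    perm = rng.permutation(n)
    return (
        ExpressionMatrix(X[perm], [ids[i] for i in perm], genes),
        LabelVector([ids[i] for i in perm], [labels[i] for i in perm]),
    )


class TestStratifiedFolds:
    def test_exact_stratification_two_classes(self):
        lv = LabelVector([f"s{i}" for i in range(100)], ["A"] * 50 + ["B"] * 50)
        fa = fn.stratified_folds(lv, 10, seed=1)
        for f in range(1, 11):
            idx = fa.test_indices(f)
            labs = [lv.labels[i] for i in idx]
            assert labs.count("A") == 5 and labs.count("B") == 5

    def test_folds_partition_samples(self, small_cohort):
        fa = fn.stratified_folds(small_cohort.labels, 4, seed=0)
        all_idx = np.concatenate([fa.test_indices(f) for f in range(1, 5)])
        assert sorted(all_idx) == list(range(small_cohort.n_samples))

    def test_deterministic_given_seed(self, small_cohort):
        a = fn.stratified_folds(small_cohort.labels, 4, seed=3)
        b = fn.stratified_folds(small_cohort.labels, 4, seed=3)
        assert np.array_equal(a.fold, b.fold)

    def test_class_smaller_than_k_errors(self):
        lv = LabelVector(["a", "b", "c", "d"], ["X", "X", "X", "Y"])
        with pytest.raises(ValueError, match="smaller than k"):
            fn.stratified_folds(lv, 3, seed=0)


class TestLassoSelection:
    def test_informative_genes_recovered(self):
        rng = np.random.default_rng(0)
        X, y = _labeled_data(100, 200, [3.0, 3.0], rng)
        res = fn.select_features_lasso(X, y, cv_folds=5, seed=0)
        assert {"inf0", "inf1"} <= set(res.selected_gene_ids)

    def test_pure_noise_selects_few(self):
        hits = []
        for seed in (1, 2, 3):
            rng = np.random.default_rng(seed)
            X, y = _labeled_data(100, 200, [], rng)
            res = fn.select_features_lasso(X, y, cv_folds=5, seed=seed)
            hits.append(len(res.selected_gene_ids) <= 0.05 * X.n_genes)
        assert sum(hits) >= 2  # repeated-seed majority

    def test_deterministic(self):
        rng = np.random.default_rng(4)
        X, y = _labeled_data(30, 40, [2.0], rng)
        a = fn.select_features_lasso(X, y, seed=5).selected_gene_ids
        b = fn.select_features_lasso(X, y, seed=5).selected_gene_ids
        assert a == b


class TestSvmImportanceSelection:
    def test_perfect_separator_has_importance_one(self):
        rng = np.random.default_rng(1)
        X, y = _labeled_data(10, 20, [50.0], rng)
        res = fn.select_features_svm(X, y, total_count=4)
        assert res.per_class_importance.loc["inf0"].max() == pytest.approx(1.0)
        assert "inf0" in res.selected_gene_ids

    def test_uninformative_gene_ranks_last(self):
        rng = np.random.default_rng(2)
        X, y = _labeled_data(10, 5, [10.0], rng)
        X.values[:, -1] = 7.0  # identical across classes
        gid = X.gene_ids[-1]
        res = fn.select_features_svm(X, y, total_count=2)
        assert res.per_class_importance.loc[gid].max() == pytest.approx(0.5)
        assert gid not in res.selected_gene_ids

    def test_dedup_shrinks_achieved_count(self):
        # one dominant gene tops every class list in a 3-class toy
        rng = np.random.default_rng(3)
        n = 30
        labels = ["A"] * 10 + ["B"] * 10 + ["C"] * 10
        X = rng.normal(0, 0.1, size=(n, 4))
        X[:10, 0] += 5.0
        X[10:20, 0] -= 5.0  # gene 0 separates A and B strongly
        M = ExpressionMatrix(X, [f"s{i}" for i in range(n)], list("wxyz"))
        res = fn.select_features_svm(M, LabelVector(M.sample_ids, labels), total_count=3)
        assert len(res.selected_gene_ids) < 3
        assert res.requested_count == 3

    def test_requesting_more_than_p_returns_all_with_warning(self, small_cohort):
        with pytest.warns(UserWarning, match="only"):
            res = fn.select_features_svm(small_cohort.platform_a, small_cohort.labels, 10_000)
        assert res.selected_gene_ids == small_cohort.platform_a.gene_ids


class TestTrainClassifier:
    @pytest.mark.parametrize("model", ["svm_linear", "glmnet"])
    def test_separable_toy_fits_perfectly(self, model):
        rng = np.random.default_rng(5)
        X, y = _labeled_data(10, 5, [20.0], rng)
        clf = fn.train_classifier(X, y, model=model, tuning_folds=3, seed=0)
        pred = clf.predict(X)
        cm = pd.crosstab(y.to_array(), pred).to_numpy()
        assert fn.balanced_accuracy(cm) == pytest.approx(1.0)

    def test_permuted_labels_score_at_chance(self):
        rng = np.random.default_rng(6)
        X, y = _labeled_data(50, 30, [4.0, 4.0], rng, classes=("A", "B", "C", "D"))
        shuffled = list(y.labels)
        rng.shuffle(shuffled)
        y_perm = LabelVector(y.sample_ids, shuffled)
        folds = fn.stratified_folds(y_perm, 5, seed=0)
        bas = []
        for f in range(1, 6):
            tr, te = folds.train_indices(f), folds.test_indices(f)
            clf = fn.train_classifier(X.subset_samples(tr), y_perm.subset(tr), "svm_linear", 3, seed=0)
            pred = clf.predict(X.subset_samples(te))
            truth = y_perm.subset(te).to_array()
            cm = pd.crosstab(
                pd.Categorical(truth, categories=y_perm.classes),
                pd.Categorical(pred, categories=y_perm.classes),
                dropna=False,
            ).to_numpy()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                bas.append(fn.balanced_accuracy(cm))
        # chance level of the (sens+spec)/2 convention is 0.5 regardless of K
        assert abs(np.mean(bas) - 0.5) <= 0.1

    def test_same_seed_same_hyperparameters(self):
        rng = np.random.default_rng(7)
        X, y = _labeled_data(15, 10, [1.0], rng)
        a = fn.train_classifier(X, y, "svm_linear", 3, seed=11).best_params
        b = fn.train_classifier(X, y, "svm_linear", 3, seed=11).best_params
        assert a == b

    def test_single_class_errors(self):
        # a single-class fold cannot even form a valid LabelVector, so the
        # error surfaces at the label-invariant check
        X = ExpressionMatrix(np.random.default_rng(0).normal(size=(6, 3)), [f"s{i}" for i in range(6)], list("abc"))
        y = LabelVector(X.sample_ids, ["A", "A", "A", "A", "A", "B"])
        with pytest.raises(ValueError, match="2 classes"):
            fn.train_classifier(X.subset_samples([0, 1, 2]), y.subset([0, 1, 2]), "svm_linear", 2, 0)


class TestMetrics:
    def test_balanced_accuracy_examples(self):
        assert fn.balanced_accuracy(np.diag([5, 3, 2])) == pytest.approx(1.0)
        assert fn.balanced_accuracy([[50, 0], [50, 0]]) == pytest.approx(0.5)
        cm = [[8, 1, 1], [2, 6, 2], [0, 0, 10]]
        assert fn.balanced_accuracy(cm) == pytest.approx(0.85)
        assert fn.balanced_accuracy(cm) == pytest.approx(bf_balanced_accuracy(cm))

    def test_balanced_accuracy_excludes_empty_class(self):
        with pytest.warns(UserWarning, match="zero true members"):
            v = fn.balanced_accuracy([[4, 0, 0], [0, 0, 0], [1, 0, 3]])
        assert 0.0 <= v <= 1.0

    def test_kappa_examples(self):
        assert fn.cohen_kappa(np.diag([7, 7])) == pytest.approx(1.0)
        assert fn.cohen_kappa([[25, 25], [25, 25]]) == pytest.approx(0.0)
        assert fn.cohen_kappa([[20, 5], [10, 15]]) == pytest.approx(0.4)

    def test_kappa_degenerate_returns_zero(self):
        with pytest.warns(UserWarning, match="kappa"):
            assert fn.cohen_kappa([[5, 0], [0, 0]]) == 0.0

    def test_mase_examples(self, tiny_matrix):
        same = fn.mase(tiny_matrix, tiny_matrix)
        assert np.allclose(same.per_gene, 0.0)
        ref = ExpressionMatrix([[1.0], [2.0], [3.0]], list("abc"), ["g"])
        norm = ExpressionMatrix([[2.0], [3.0], [4.0]], list("abc"), ["g"])
        assert fn.mase(norm, ref).per_gene["g"] == pytest.approx(1.5)

    def test_mase_excludes_constant_reference_gene(self):
        ref = ExpressionMatrix([[1.0, 5.0], [2.0, 5.0]], ["a", "b"], ["g1", "g2"])
        norm = ExpressionMatrix([[1.0, 6.0], [2.0, 6.0]], ["a", "b"], ["g1", "g2"])
        with pytest.warns(UserWarning, match="constant reference"):
            res = fn.mase(norm, ref)
        assert res.excluded_genes == ["g2"]
        assert list(res.per_gene.index) == ["g1"]

    def test_metrics_match_brute_force_on_random_confusions(self):
        rng = np.random.default_rng(12)
        for _ in range(300):
            k = rng.integers(2, 5)
            cm = rng.integers(0, 20, size=(k, k))
            cm[np.arange(k), np.arange(k)] += 1  # every class observed
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                assert fn.balanced_accuracy(cm) == pytest.approx(bf_balanced_accuracy(cm), abs=1e-12)
                assert fn.cohen_kappa(cm) == pytest.approx(bf_kappa(cm), abs=1e-12)


class TestNestedCV:
    def test_record_bookkeeping(self, small_cohort):
        cfg = CVConfig(outer_k=4, inner_k=3, seed=0)
        recs = fn.nested_cv_experiment(small_cohort, "A_trains", "svm_linear", "full", cfg)
        frame = fn.records_to_frame(recs)
        assert len(frame) == 4 * 4  # outer folds x conditions
        assert set(frame.condition) == {"reference", "log2", "fsqn", "fsmvn"}
        assert frame[frame.condition == "reference"].mase.isna().all()
        assert frame[frame.condition != "reference"].mase.notna().all()

    def test_distortion_off_log2_matches_reference(self):
        cfg_sim = fn.SimulationConfig(
            n_samples=60, p_genes=80, k_classes=2, class_proportions=(0.5, 0.5),
            platform_shift_sd=0.0, platform_scale_range=(1.0, 1.0),
            nonlinearity_strength=0.0, platform_b_centering=0.0, seed=13,
        )
        cohort = fn.simulate_paired_cohort(cfg_sim)
        recs = fn.records_to_frame(
            fn.nested_cv_experiment(cohort, "A_trains", "svm_linear", "full", CVConfig(5, 3, 0))
        )
        piv = recs.pivot_table(index="outer_fold", columns="condition", values="balanced_accuracy")
        assert abs((piv["log2"] - piv["reference"]).mean()) < 0.1

    def test_direction_symmetry_under_platform_swap(self, small_cohort):
        cfg = CVConfig(outer_k=3, inner_k=3, seed=1)
        a = fn.records_to_frame(
            fn.nested_cv_experiment(small_cohort, "A_trains", "svm_linear", "full", cfg)
        )
        b = fn.records_to_frame(
            fn.nested_cv_experiment(small_cohort.swapped(), "B_trains", "svm_linear", "full", cfg)
        )
        cols = ["condition", "outer_fold", "balanced_accuracy", "kappa", "mase"]
        pd.testing.assert_frame_equal(
            a[cols].reset_index(drop=True), b[cols].reset_index(drop=True)
        )

    def test_feature_sweep_bookkeeping(self, small_cohort):
        cfg = CVConfig(outer_k=3, inner_k=3, seed=0)
        frame = fn.feature_sweep_experiment(small_cohort, [20, 10], "svm_linear", cfg)
        assert len(frame) == 2 * 3 * 4
        assert (frame.n_features <= frame.requested_count).all()
        with pytest.raises(ValueError, match="descending"):
            fn.feature_sweep_experiment(small_cohort, [10, 20], "svm_linear", cfg)

    def test_mean_lasso_feature_count(self, small_cohort):
        cfg = CVConfig(outer_k=3, inner_k=3, seed=0)
        count = fn.mean_lasso_feature_count(small_cohort, "A_trains", cfg)
        assert 0 <= count <= small_cohort.n_genes
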