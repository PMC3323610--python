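"""One-vs-one SVM, grid searches, wrapper selection, and the k-NN baseline."""

import numpy as np
import pandas as pd
import pytest

from zfpheno.classify import (
    COARSE_C_EXPONENTS,
    COARSE_GAMMA_EXPONENTS,
    SVMConfig,
    TrainedClassifier,
    _fold_indices,
    coarse_grid_search,
    cross_validate,
    knn_classify,
    predict,
    refine_grid_search,
    train_svm,
    wrapper_select,
)
from zfpheno.descriptors import BLOCK_DIMS, BLOCK_ORDER, subset_blocks
from zfpheno.preprocess import Normalizer


class TestTrainSVM:
    def test_three_classes_yield_three_machines(self, blobs3):
        X, y = blobs3
        model = train_svm(X, y, SVMConfig(C=1.0, gamma=1.0))
        assert model.n_machines == 3
        assert set(model.machines) == {
            ("hatched", "unhatched"), ("hatched", "dead"), ("unhatched", "dead"),
        }

    def test_separable_clusters_train_perfectly(self, blobs3):
        X, y = blobs3
        model = train_svm(X, y, SVMConfig(C=10.0, gamma=1.0))
        assert np.mean(predict(model, X) == y) == 1.0

    def test_missing_class_named_in_error(self, blobs3):
        X, y = blobs3
        with pytest.raises(ValueError, match="dead"):
            train_svm(X[:60], y[:60], SVMConfig(), classes=("hatched", "unhatched", "dead"))

    def test_xor_gamma_sensitivity(self, rng):
        # XOR layout is only separable with a narrow kernel
        centers = np.array([[0, 0], [1, 1], [0, 1], [1, 0]], dtype=float)
        X = np.repeat(centers, 20, axis=0) + 0.05 * rng.standard_normal((80, 2))
        y = np.array(["a"] * 40 + ["b"] * 40)
        sharp = train_svm(X, y, SVMConfig(C=10.0, gamma=50.0))
        assert np.mean(predict(sharp, X) == y) == 1.0
        flat = train_svm(X, y, SVMConfig(C=10.0, gamma=1e-7))
        flat_acc = np.mean(predict(flat, X) == y)
        assert flat_acc < 1.0 and flat_acc <= 0.85  # degrades toward majority rate


class TestPredict:
    def test_batch_equals_elementwise(self, blobs3):
        X, y = blobs3
        model = train_svm(X, y, SVMConfig(C=1.0, gamma=0.5))
        batched = predict(model, X)
        looped = np.array([predict(model, row) for row in X])
        np.testing.assert_array_equal(batched, looped)

    def test_vote_tie_resolved_by_summed_margin(self):
        class StubMachine:
            def __init__(self, d):
                self.d = d
                self.n_features_in_ = 2

            def decision_function(self, X):
                return np.full(len(X), self.d)

        # votes cycle a->b->c->a (1 each); summed margins favor "a"
        model = TrainedClassifier(
            kind="svm_ovo",
            classes=("a", "b", "c"),
            machines={
                ("a", "b"): StubMachine(+1.0),   # b wins, margin b+1 a-1
                ("a", "c"): StubMachine(-2.0),   # a wins, margin a+2 c-2
                ("b", "c"): StubMachine(+0.5),   # c wins, margin c+0.5 b-0.5
            },
        )
        assert predict(model, np.zeros(2)) == "a"

    def test_dimension_mismatch_raises(self, blobs3):
        X, y = blobs3
        model = train_svm(X, y, SVMConfig())
        with pytest.raises(ValueError, match="dimension"):
            predict(model, np.zeros(5))


class TestCrossValidate:
    def test_separable_data_scores_100(self, blobs3):
        X, y = blobs3
        res = cross_validate(X, y, SVMConfig(C=10.0, gamma=1.0), folds=10, seed=0)
        assert res.mean == 100.0 and res.sd == 0.0
        assert len(res.fold_accuracies) == 10

    def test_permuted_labels_score_near_chance(self, rng):
        X = rng.standard_normal((150, 12))
        y = np.array(["hatched", "unhatched", "dead"] * 50)
        y = rng.permutation(y)
        res = cross_validate(X, y, SVMConfig(C=8.0, gamma=2.0**-7), folds=10, seed=0)
        assert abs(res.mean - 100.0 / 3.0) < 10.0

    def test_folds_partition_the_index_set(self, blobs3):
        _, y = blobs3
        folds = _fold_indices(y, 10, seed=3)
        test_sets = [set(te) for _, te in folds]
        assert set().union(*test_sets) == set(range(len(y)))
        assert sum(len(s) for s in test_sets) == len(y)  # pairwise disjoint

    def test_small_class_triggers_best_effort_warning(self, rng):
        X = rng.standard_normal((24, 3))
        y = np.array(["hatched"] * 10 + ["unhatched"] * 10 + ["dead"] * 4)
        with pytest.warns(UserWarning, match="best-effort"):
            cross_validate(X, y, SVMConfig(C=1.0, gamma=0.1), folds=10, seed=0)

    def test_normalizer_fit_ignores_held_out_rows(self, blobs3):
        # leakage guard: an extreme outlier in a held-out fold must not
        # move the training-split statistics
        X, y = blobs3
        tr, te = _fold_indices(y, 10, seed=0)[0]
        before = Normalizer.fit(X[tr])
        corrupted = X.copy()
        corrupted[te[0]] += 1e9
        after = Normalizer.fit(corrupted[tr])
        np.testing.assert_array_equal(before.mean, after.mean)
        np.testing.assert_array_equal(before.std, after.std)


class TestGridSearch:
    def test_coarse_grid_has_110_points(self, blobs3):
        X, y = blobs3
        res = coarse_grid_search(X, y, folds=5, seed=0)
        assert res.accuracy.shape == (11, 10)
        assert len(COARSE_C_EXPONENTS) * len(COARSE_GAMMA_EXPONENTS) == 110
        np.testing.assert_allclose(res.c_values, 2.0 ** np.arange(-5, 16, 2))
        np.testing.assert_allclose(res.gamma_values, 2.0 ** np.arange(-15, 4, 2))

    def test_separable_tie_breaks_to_smallest_c_then_gamma(self, blobs3):
        X, y = blobs3
        res = coarse_grid_search(X, y, folds=5, seed=0)
        best = res.accuracy.max()
        ties = np.argwhere(res.accuracy == best)
        i, j = ties[np.lexsort((ties[:, 1], ties[:, 0]))][0]
        assert res.best_c == res.c_values[i]
        assert res.best_gamma == res.gamma_values[j]

    def test_surface_matches_independent_cross_validate(self, blobs3):
        X, y = blobs3
        res = coarse_grid_search(X, y, folds=5, seed=7,
                                 c_exponents=(-1, 3), gamma_exponents=(-5, -1, 3))
        for i, j in [(0, 0), (1, 1), (0, 2)]:
            cv = cross_validate(
                X, y,
                SVMConfig(C=float(res.c_values[i]), gamma=float(res.gamma_values[j])),
                folds=5, seed=7,
            )
            assert res.accuracy[i, j] == pytest.approx(cv.mean, abs=1e-9)

    def test_refined_grid_is_linear_and_contains_reported_optimum(self, blobs3):
        X, y = blobs3
        res = refine_grid_search(X, y, (2.0**3, 2.0**-7), folds=5, seed=0)
        np.testing.assert_allclose(res.c_values, np.arange(2.0, 33.0, 1.0))
        assert 5.0 in res.c_values
        # gamma index 6 recovers the center: 2^-9 + 6*(2^-5 - 2^-9)/30 = 2^-7
        assert res.gamma_values[6] == pytest.approx(2.0**-7)
        assert res.accuracy.shape == (31, 31)

    def test_refined_best_at_least_center_accuracy(self, blobs3):
        X, y = blobs3
        center = (2.0, 2.0**-3)
        cv_center = cross_validate(X, y, SVMConfig(*center), folds=5, seed=1)
        res = refine_grid_search(X, y, center, folds=5, seed=1)
        assert res.best_accuracy >= cv_center.mean - 1e-9


class TestWrapperSelect:
    def test_scores_63_subsets_and_recovers_planted_block(self, rng):
        # only CHD columns carry class signal; all other blocks pure noise
        n = 60
        y = np.array(["hatched", "unhatched", "dead"] * (n // 3))
        cols, data = [], []
        for name in BLOCK_ORDER:
            d = BLOCK_DIMS[name]
            block = rng.standard_normal((n, d))
            if name == "CHD":
                shift = {"hatched": 0.0, "unhatched": 4.0, "dead": -4.0}
                block += np.array([shift[c] for c in y])[:, None]
            cols += [f"{name}_{i}" for i in range(d)]
            data.append(block)
        X = pd.DataFrame(np.hstack(data), columns=cols)
        scores, best = wrapper_select(
            X, y, folds=5, seed=0, c_exponents=(-1, 3, 7), gamma_exponents=(-9, -5, -1)
        )
        assert len(scores) == 63
        assert {s.code for s in scores} == {format(i, "06b") for i in range(1, 64)}
        assert "CHD" in subset_blocks(best)

    def test_rejects_matrix_without_block_columns(self):
        with pytest.raises((TypeError, ValueError)):
            wrapper_select(pd.DataFrame(np.zeros((9, 4))), ["a"] * 9)


class TestKNN:
    def test_duplicate_of_tight_cluster_gets_its_label(self, blobs3):
        X, y = blobs3
        assert knn_classify(X, y, X[0], k=10)[0] == y[0]

    def test_k1_matches_bruteforce_nearest(self, rng):
        Xtr = rng.standard_normal((50, 4))
        ytr = np.array([f"c{i % 3}" for i in range(50)])
        Xte = rng.standard_normal((20, 4))
        got = knn_classify(Xtr, ytr, Xte, k=1)
        want = [ytr[np.argmin(((Xtr - t) ** 2).sum(1))] for t in Xte]
        np.testing.assert_array_equal(got, want)

    def test_balanced_separable_clusters_perfect(self, blobs3):
        X, y = blobs3
        test = X + 0.01
        assert np.mean(knn_classify(X, y, test, k=10) == y) == 1.0

    def test_tie_goes_to_nearest_neighbor(self):
        # k=2 with one neighbor per class: the closer one wins
        Xtr = np.array([[0.0], [1.0]])
        ytr = np.array(["near", "far"])
        assert knn_classify(Xtr, ytr, np.array([[0.2]]), k=2)[0] == "near"

    def test_invalid_k(self, blobs3):
        X, y = blobs3
        with pytest.raises(ValueError, match="k"):
            knn_classify(X, y, X[:1], k=0)
        with pytest.raises(ValueError, match="k"):
            knn_classify(X[:5], y[:5], X[:1], k=10)
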