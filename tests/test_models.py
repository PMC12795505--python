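import numpy as np
import pandas as pd
import pytest

from epiexpr.models import (CNNHyperparams, Dataset, ModelEnsemble, ModelError,
                            PreprocessSpec, SplitSpec, build_dataset, evaluate,
                            predict_ensemble, train_cnn, train_ridge)
from epiexpr.track_io import FeatureWindow, GeneAnnotation


def make_windows(n_genes, n_cts, W=33, n_assays=2, seed=0):
    rng = np.random.default_rng(seed)
    genes = [GeneAnnotation(f"g{i}", f"chr{i % 4 + 1}", 10_000, "+")
             for i in range(n_genes)]
    assays = [f"a{k}" for k in range(n_assays)]
    windows = [FeatureWindow(g.gene_id, f"ct{c}", rng.uniform(0, 5, (W, n_assays)),
                             assays, 25)
               for c in range(n_cts) for g in genes]
    tpm = pd.DataFrame(rng.uniform(0, 50, (n_genes, n_cts)),
                       index=[g.gene_id for g in genes],
                       columns=[f"ct{c}" for c in range(n_cts)])
    return genes, windows, tpm


SPLIT = SplitSpec(val=frozenset({"chr3"}), test=frozenset({"chr4"}))


class TestBuildDataset:
    def test_sample_count_pools_cell_types(self):
        genes, windows, tpm = make_windows(12, 3)
        tr, va, te, pp = build_dataset(windows, tpm, genes, SPLIT)
        assert len(tr) + len(va) + len(te) == 36

    def test_holdout_cell_type_excluded_from_train_and_val(self):
        genes, windows, tpm = make_windows(12, 3)
        tr, va, te, pp = build_dataset(windows, tpm, genes, SPLIT,
                                       holdout_cell_type="ct1")
        assert not (tr.keys.cell_type == "ct1").any()
        assert not (va.keys.cell_type == "ct1").any()
        assert (te.keys.cell_type == "ct1").sum() == 12

    def test_test_chromosome_genes_absent_from_train(self):
        genes, windows, tpm = make_windows(20, 2)
        tr, va, te, pp = build_dataset(windows, tpm, genes, SPLIT)
        test_genes = {g.gene_id for g in genes if g.chrom in SPLIT.test}
        # exhaustive membership scan
        assert not any(g in test_genes for g in tr.keys.gene_id)
        assert not any(g in test_genes for g in va.keys.gene_id)
        assert set(te.keys.gene_id) == test_genes

    def test_missing_tpm_entry_is_error(self):
        genes, windows, tpm = make_windows(8, 2)
        with pytest.raises(ModelError, match="TPM"):
            build_dataset(windows, tpm.drop(index="g0"), genes, SPLIT)

    def test_gene_on_no_split_chromosome_is_error(self):
        genes, windows, tpm = make_windows(8, 1)
        explicit = SplitSpec(val=frozenset({"chr3"}), test=frozenset({"chr4"}),
                             train=frozenset({"chr1"}))   # chr2 unassigned
        with pytest.raises(ModelError, match="chr2"):
            build_dataset(windows, tpm, genes, explicit)

    def test_overlapping_split_sets_rejected(self):
        with pytest.raises(ModelError, match="overlap"):
            SplitSpec(val=frozenset({"chr3"}), test=frozenset({"chr3"}))


def dataset_from(X, y):
    n = len(y)
    keys = pd.DataFrame({"gene_id": [f"g{i}" for i in range(n)],
                         "cell_type": "ct", "chrom": "chr1"})
    return Dataset(X, np.asarray(y, float), keys)


class TestRidge:
    def test_matches_ols_at_vanishing_penalty(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(5, 3))
        y = rng.normal(size=5)
        fitted = train_ridge(dataset_from(X[:, None, :], y), None,
                             penalty_grid=[1e-10])
        # independent OLS oracle via lstsq on the augmented system
        A = np.column_stack([np.ones(5), X])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        np.testing.assert_allclose(fitted.model.intercept_, coef[0], atol=1e-6)
        np.testing.assert_allclose(fitted.model.coef_, coef[1:], atol=1e-6)

    def test_infinite_penalty_shrinks_coefficients_to_zero(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 4))
        y = rng.normal(size=20)
        fitted = train_ridge(dataset_from(X[:, None, :], y), None,
                             penalty_grid=[1e12])
        assert np.max(np.abs(fitted.model.coef_)) < 1e-6

    def test_duplicated_rows_equivalent_with_rescaled_penalty(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 3))
        y = rng.normal(size=10)
        lam = 2.0
        single = train_ridge(dataset_from(X[:, None, :], y), None, [lam])
        doubled = train_ridge(dataset_from(np.tile(X, (2, 1))[:, None, :],
                                           np.tile(y, 2)), None, [2 * lam])
        np.testing.assert_allclose(single.model.coef_, doubled.model.coef_, atol=1e-8)

    def test_penalty_selected_by_validation_mse(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(60, 5))
        w = np.array([2.0, -1.0, 0.5, 0.0, 0.0])
        y = X @ w + rng.normal(0, 0.1, 60)
        tr = dataset_from(X[:40, None, :], y[:40])
        va = dataset_from(X[40:, None, :], y[40:])
        fitted = train_ridge(tr, va, penalty_grid=[1e-3, 1e6])
        assert fitted.penalty == 1e-3

    def test_all_zero_features_rejected(self):
        with pytest.raises(ModelError, match="zero"):
            train_ridge(dataset_from(np.zeros((5, 1, 3)), np.arange(5.0)), None)


HYPER_TINY = CNNHyperparams(lr_schedule=((0.01, 4), (0.005, 2)), batch_size=16)


class TestCNN:
    @staticmethod
    def _coupled_data(n=120, W=33, seed=5):
        rng = np.random.default_rng(seed)
        X = rng.uniform(0, 1, (n, 2, W))
        y = 3 * X[:, 0, W // 2 - 3:W // 2 + 4].mean(axis=1) + rng.normal(0, 0.05, n)
        return dataset_from(X[:100], y[:100]), dataset_from(X[100:], y[100:])

    def test_training_is_deterministic_given_seed(self):
        tr, va = self._coupled_data()
        m1 = train_cnn(tr, va, HYPER_TINY, seed=7)
        m2 = train_cnn(tr, va, HYPER_TINY, seed=7)
        pd.testing.assert_frame_equal(m1.history, m2.history)
        np.testing.assert_array_equal(m1.predict(va.X), m2.predict(va.X))

    def test_different_seeds_differ(self):
        tr, va = self._coupled_data()
        m1 = train_cnn(tr, va, HYPER_TINY, seed=7)
        m2 = train_cnn(tr, va, HYPER_TINY, seed=8)
        assert not np.array_equal(m1.predict(va.X), m2.predict(va.X))

    def test_loss_decreases_and_history_recorded(self):
        tr, va = self._coupled_data()
        m = train_cnn(tr, va, HYPER_TINY, seed=1)
        assert len(m.history) == 6
        assert m.history["train_loss"].iloc[-1] < m.history.attrs["initial_train_loss"]
        assert "val_loss" in m.history

    def test_window_too_small_rejected(self):
        tr, va = self._coupled_data(W=16)
        with pytest.raises(ModelError, match="pool"):
            train_cnn(tr, va, CNNHyperparams(lr_schedule=((0.001, 1),)), seed=0)


class TestEnsemble:
    def test_single_replicate_equals_model(self, constant_model_cls):
        pp = PreprocessSpec(W=9, assay_order=("a",))
        ens = ModelEnsemble("ridge", [constant_model_cls(2.5)], pp)
        X = np.zeros((4, 1, 9))
        np.testing.assert_allclose(predict_ensemble(ens, X), 2.5)

    def test_mean_of_replicates(self, constant_model_cls):
        pp = PreprocessSpec(W=9, assay_order=("a",))
        ens = ModelEnsemble("ridge", [constant_model_cls(1.0), constant_model_cls(3.0)], pp)
        np.testing.assert_allclose(predict_ensemble(ens, np.zeros((2, 1, 9))), 2.0)

    def test_matches_brute_force_loop(self, linear_surrogate_cls):
        rng = np.random.default_rng(6)
        reps = [linear_surrogate_cls(rng.normal(size=(2, 9))) for _ in range(5)]
        pp = PreprocessSpec(W=9, assay_order=("a", "b"))
        ens = ModelEnsemble("ridge", reps, pp)
        X = rng.uniform(0, 1, (7, 2, 9))
        brute = sum(r.predict(X) for r in reps) / 5
        np.testing.assert_allclose(predict_ensemble(ens, X), brute, rtol=1e-12)

    def test_shape_mismatch_rejected(self, constant_model_cls):
        pp = PreprocessSpec(W=9, assay_order=("a",))
        ens = ModelEnsemble("ridge", [constant_model_cls(0.0)], pp)
        with pytest.raises(ModelError, match="match"):
            predict_ensemble(ens, np.zeros((4, 2, 9)))

    def test_ensemble_mse_not_worse_than_worst_replicate(self, linear_surrogate_cls):
        rng = np.random.default_rng(8)
        X = rng.uniform(size=(50, 1, 9))
        y = X[:, 0, 4] * 2
        reps = [linear_surrogate_cls(rng.normal(size=(1, 9))) for _ in range(4)]
        pp = PreprocessSpec(W=9, assay_order=("a",))
        ens = ModelEnsemble("ridge", reps, pp)
        mses = [np.mean((r.predict(X) - y) ** 2) for r in reps]
        ens_mse = np.mean((predict_ensemble(ens, X) - y) ** 2)
        assert ens_mse <= max(mses) + 1e-12


class TestEvaluate:
    def test_perfect_and_inverted_predictions(self):
        y = np.array([1.0, 3, 2, 5, 4])
        assert evaluate(y, y)["spearman"] == pytest.approx(1.0)
        assert evaluate(-y, y)["spearman"] == pytest.approx(-1.0)

    def test_tied_case_matches_hand_computed_average_ranks(self):
        pred = np.array([1.0, 2.0, 2.0, 4.0])
        truth = np.array([10.0, 20.0, 30.0, 40.0])
        # hand ranks: pred [1, 2.5, 2.5, 4], truth [1, 2, 3, 4]
        pr, tr_ = np.array([1, 2.5, 2.5, 4]), np.array([1, 2, 3, 4])
        expected = np.corrcoef(pr, tr_)[0, 1]
        assert evaluate(pred, truth)["spearman"] == pytest.approx(expected)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(9)
        pred, truth = rng.normal(size=30), rng.normal(size=30)
        base = evaluate(pred, truth)["spearman"]
        assert evaluate(np.exp(pred), truth)["spearman"] == pytest.approx(base)
        assert evaluate(2 * pred + 7, truth)["spearman"] == pytest.approx(base)

    def test_per_gene_mode_median_and_exclusions(self, caplog):
        keys = pd.DataFrame({"gene_id": ["a"] * 4 + ["b"] * 4 + ["c"] * 2,
                             "cell_type": list(range(10)), "chrom": "chr1"})
        truth = np.array([1.0, 2, 3, 4] * 2 + [1.0, 2])
        pred = np.concatenate([truth[:4], -truth[4:8], truth[8:]])
        res = evaluate(pred, truth, "per_gene_across_cell_types", keys)
        assert res["per_gene"]["a"] == pytest.approx(1.0)
        assert res["per_gene"]["b"] == pytest.approx(-1.0)
        assert "c" not in res["per_gene"]          # too few cell types
        assert res["median"] == pytest.approx(0.0)

    def test_too_few_points_is_error(self):
        with pytest.raises(ModelError):
            evaluate(np.array([1.0, 2]), np.array([1.0, 2]))
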