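import numpy as np
import pytest

from epiexpr.models import ModelEnsemble, PreprocessSpec
from epiexpr.perturbation import (MNaseVector, PerturbationError,
                                  PerturbationSpec, apply_p300,
                                  grna_bin_for_position, p300_deposit,
                                  predict_fold_change, sweep_parameters)
from epiexpr.track_io import FeatureWindow, GeneAnnotation

W = 21


def mnase(values, normalization="raw"):
    return MNaseVector(np.asarray(values, float), 25, normalization)


def spec(j=10, sigma=500.0, lam=100.0):
    return PerturbationSpec("g", j, sigma, lam)


class TestDeposit:
    def test_zero_occupancy_means_zero_deposit(self):
        d = p300_deposit(mnase(np.zeros(W)), spec())
        np.testing.assert_array_equal(d, 0.0)

    def test_uniform_occupancy_target_bin_value(self):
        # m ≡ 1: deposit at j is λ·e⁻⁵ exactly
        d = p300_deposit(mnase(np.ones(W)), spec(lam=100.0))
        assert d[10] == 100.0 * np.exp(-5.0)

    def test_unoccupied_target_maximal_hindrance_free(self):
        m = np.ones(W)
        m[10] = 0.0
        d = p300_deposit(mnase(m), spec(j=10, sigma=50.0, lam=7.0))
        # at offset k bins: λ·exp(−(25k)²/2σ²), no hindrance since m_j = 0
        for k in (1, 2, 3):
            expected = 7.0 * np.exp(-((25.0 * k) ** 2) / (2 * 50.0 ** 2))
            assert d[10 + k] == pytest.approx(expected, rel=1e-12)
        assert d[10] == 0.0

    def test_support_is_exactly_occupancy_support(self):
        rng = np.random.default_rng(0)
        m = rng.uniform(0, 1, W)
        m[[2, 7, 15]] = 0.0
        d = p300_deposit(mnase(m), spec())
        np.testing.assert_array_equal(d == 0, m == 0)

    def test_symmetric_about_target_under_uniform_occupancy(self):
        d = p300_deposit(mnase(np.full(W, 0.6)), spec(j=10))
        np.testing.assert_allclose(d, d[::-1], rtol=1e-12)

    def test_total_deposit_strictly_decreasing_in_target_occupancy(self):
        totals = []
        for mj in (0.0, 0.25, 0.5, 0.75, 1.0):
            m = np.full(W, 0.5)
            m[10] = mj
            totals.append(p300_deposit(mnase(m), spec()).sum())
        assert np.all(np.diff(totals) < 0)

    def test_target_outside_window_rejected(self):
        with pytest.raises(PerturbationError, match="outside"):
            p300_deposit(mnase(np.ones(W)), spec(j=W))

    def test_window_max_normalization(self):
        v = mnase([0.0, 2.0, 4.0], normalization="window_max")
        np.testing.assert_allclose(v.m, [0, 0.5, 1.0])


class TestApplyP300:
    def _window(self):
        rng = np.random.default_rng(1)
        return FeatureWindow("g", "ct", rng.uniform(0, 5, (W, 2)),
                             ["H3K27ac", "control"], 25)

    def test_zero_deposit_is_identity(self):
        w = self._window()
        out = apply_p300(w, np.zeros(W), "H3K27ac")
        np.testing.assert_array_equal(out.E, w.E)

    def test_difference_equals_deposit_exactly(self):
        w = self._window()
        d = p300_deposit(mnase(np.random.default_rng(2).uniform(0, 1, W)), spec())
        out = apply_p300(w, d, "H3K27ac")
        np.testing.assert_allclose(out.assay_column("H3K27ac") - w.assay_column("H3K27ac"), d)
        np.testing.assert_array_equal(out.assay_column("control"), w.assay_column("control"))

    def test_length_mismatch_rejected(self):
        with pytest.raises(PerturbationError, match="length"):
            apply_p300(self._window(), np.zeros(W - 1), "H3K27ac")


def surrogate_ensemble(linear_surrogate_cls, weight=0.08):
    coef = np.zeros((2, W))
    coef[0, 8:13] = weight           # positive H3K27ac sensitivity near TSS
    pp = PreprocessSpec(W=W, assay_order=("H3K27ac", "control"))
    return ModelEnsemble("ridge", [linear_surrogate_cls(coef)], pp)


class TestFoldChange:
    def _window(self, value=3.0):
        return FeatureWindow("g", "ct", np.full((W, 2), value), ["H3K27ac", "control"], 25)

    def test_zero_lambda_unit_fold_change(self, linear_surrogate_cls):
        ens = surrogate_ensemble(linear_surrogate_cls)
        fc = predict_fold_change(ens, self._window(), mnase(np.ones(W)),
                                 spec(lam=0.0), "H3K27ac")
        assert fc == pytest.approx(1.0)

    def test_monotone_in_lambda_against_closed_form(self, linear_surrogate_cls):
        ens = surrogate_ensemble(linear_surrogate_cls)
        w = self._window()
        m = mnase(np.ones(W))
        fcs, expected = [], []
        for lam in (0.0, 5.0, 20.0, 80.0):
            s = spec(lam=lam)
            fcs.append(predict_fold_change(ens, w, m, s, "H3K27ac", space="tpm"))
            # closed form through the surrogate's known coefficients
            d = p300_deposit(m, s)
            base = 0.08 * np.log1p(w.E[8:13, 0]).sum()
            pert = 0.08 * np.log1p(w.E[8:13, 0] + d[8:13]).sum()
            expected.append(np.expm1(pert) / np.expm1(base))
        np.testing.assert_allclose(fcs, expected, rtol=1e-10)
        assert np.all(np.diff(fcs) >= 0)

    def test_low_denominator_carries_gene_id(self, constant_model_cls):
        pp = PreprocessSpec(W=W, assay_order=("H3K27ac", "control"))
        ens = ModelEnsemble("ridge", [constant_model_cls(np.log1p(0.01))], pp)
        with pytest.raises(PerturbationError, match="g"):
            predict_fold_change(ens, self._window(), mnase(np.ones(W)), spec(),
                                "H3K27ac", space="tpm")


class TestSweep:
    def test_single_cell_grid_equals_direct_call(self, linear_surrogate_cls):
        ens = surrogate_ensemble(linear_surrogate_cls)
        w = FeatureWindow("g", "ct", np.full((W, 2), 3.0), ["H3K27ac", "control"], 25)
        m = mnase(np.ones(W))
        s = spec(lam=10.0, sigma=200.0)
        table = sweep_parameters(ens, [(w, m, s)], [200.0], [10.0])
        assert len(table) == 1
        direct = predict_fold_change(ens, w, m,
                                     PerturbationSpec("g", 10, 200.0, 10.0), "H3K27ac")
        assert table.fold_change.iloc[0] == pytest.approx(direct)

    def test_row_count_is_product_of_grids(self, linear_surrogate_cls):
        ens = surrogate_ensemble(linear_surrogate_cls)
        w = FeatureWindow("g", "ct", np.full((W, 2), 3.0), ["H3K27ac", "control"], 25)
        items = [(w, mnase(np.ones(W)), spec())] * 3
        table = sweep_parameters(ens, items, [100.0, 500.0], [1.0, 5.0, 25.0])
        assert len(table) == 3 * 2 * 3

    def test_fold_changes_finite_across_grid(self, linear_surrogate_cls):
        ens = surrogate_ensemble(linear_surrogate_cls)
        w = FeatureWindow("g", "ct", np.full((W, 2), 3.0), ["H3K27ac", "control"], 25)
        m = mnase(np.random.default_rng(5).uniform(0, 1, W), "window_max")
        table = sweep_parameters(ens, [(w, m, spec())],
                                 [50.0, 250.0, 1000.0], [0.0, 10.0, 1000.0])
        assert np.all(np.isfinite(table.fold_change))
        assert np.all(table.fold_change > 0)

    def test_empty_grid_rejected(self, linear_surrogate_cls):
        ens = surrogate_ensemble(linear_surrogate_cls)
        with pytest.raises(PerturbationError, match="grid"):
            sweep_parameters(ens, [], [], [1.0])


class TestGuideCoordinates:
    def test_plus_strand_midpoint_bin(self):
        g = GeneAnnotation("g", "chr1", 10_000, "+")
        # TSS bin 400; position 10_300 → bin 412 → offset +12
        assert grna_bin_for_position(g, 10_300, 2500, 25) == 50 + 12

    def test_minus_strand_offset_flips(self):
        g = GeneAnnotation("g", "chr1", 10_000, "-")
        assert grna_bin_for_position(g, 10_300, 2500, 25) == 50 - 12

    def test_position_outside_window_rejected(self):
        g = GeneAnnotation("g", "chr1", 10_000, "+")
        with pytest.raises(PerturbationError, match="outside"):
            grna_bin_for_position(g, 50_000, 2500, 25)
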