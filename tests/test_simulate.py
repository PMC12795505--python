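import numpy as np
import pytest
from scipy import stats

from epiexpr.perturbation import PerturbationSpec
from epiexpr.simulate import (AssayConfig, SimulationConfig, SimulationError,
                              apply_batch_distortion, simulate_dataset,
                              simulate_perturbation_truth, write_dataset)
from epiexpr.track_io import read_bedgraph, read_bed6, read_expression


def uncoupled_config(n_genes=500, seed=9):
    assays = tuple(AssayConfig(a.name, a.role, 0.0)
                   for a in SimulationConfig().assays)
    return SimulationConfig(n_genes=n_genes, n_cell_types=1, seed=seed,
                            assays=assays)


class TestSimulateDataset:
    def test_deterministic_given_seed(self, tiny_config, tiny_dataset):
        again = simulate_dataset(tiny_config)
        for key, t in tiny_dataset.tracks.items():
            for chrom in t.data:
                np.testing.assert_array_equal(t.data[chrom],
                                              again.tracks[key].data[chrom])
        np.testing.assert_array_equal(tiny_dataset.expression.to_numpy(),
                                      again.expression.to_numpy())
        for ct in tiny_dataset.mnase:
            for chrom in tiny_dataset.mnase[ct].data:
                np.testing.assert_array_equal(tiny_dataset.mnase[ct].data[chrom],
                                              again.mnase[ct].data[chrom])

    def test_all_signals_nonnegative(self, tiny_dataset):
        for t in list(tiny_dataset.tracks.values()) + list(tiny_dataset.mnase.values()):
            assert all(np.all(v >= 0) for v in t.data.values())
        assert (tiny_dataset.expression.to_numpy() >= 0).all()

    def test_windows_fit_inside_chromosomes(self, tiny_config, tiny_windows):
        # every gene produced a window: none was skipped for overrunning an end
        assert len(tiny_windows) == tiny_config.n_genes * tiny_config.n_cell_types

    def test_latent_activity_drives_tpm(self):
        ds = simulate_dataset(SimulationConfig(seed=3))
        rho = stats.spearmanr(ds.truth.activity.to_numpy().ravel(),
                              ds.expression.to_numpy().ravel()).statistic
        assert rho >= 0.9

    def test_zero_coupling_decouples_tracks_from_expression(self):
        cfg = uncoupled_config()
        ds = simulate_dataset(cfg)
        ct = cfg.cell_types[0]
        order = [a.name for a in cfg.assays]
        from epiexpr.track_io import windows_for_genes
        ws = windows_for_genes(ds.assay_tracks(ct), ds.genes, cfg.context,
                               assay_order=order, cell_type=ct)
        tpm = ds.expression[ct].to_numpy()
        for assay in order:
            means = np.array([w.assay_column(assay).mean() for w in ws])
            assert abs(stats.spearmanr(means, tpm).statistic) < 0.1

    def test_decoy_mark_independent_of_expression(self):
        cfg = SimulationConfig(n_genes=500, n_cell_types=1, seed=4)
        ds = simulate_dataset(cfg)
        ct = cfg.cell_types[0]
        from epiexpr.track_io import windows_for_genes
        ws = windows_for_genes(ds.assay_tracks(ct), ds.genes, cfg.context,
                               assay_order=[a.name for a in cfg.assays],
                               cell_type=ct)
        means = np.array([w.assay_column("control").mean() for w in ws])
        rho = stats.spearmanr(means, ds.expression[ct].to_numpy()).statistic
        assert abs(rho) < 0.1

    def test_quantile_coupling_strictly_increasing(self):
        from epiexpr.evaluation import metagene
        from epiexpr.track_io import windows_for_genes
        cfg = SimulationConfig(n_genes=500, n_cell_types=1, seed=5)
        ds = simulate_dataset(cfg)
        ct = cfg.cell_types[0]
        ws = windows_for_genes(ds.assay_tracks(ct), ds.genes, cfg.context,
                               assay_order=[a.name for a in cfg.assays],
                               cell_type=ct)
        profs = metagene(ws, ds.expression[ct], cfg.tss_assay)
        tss_means = [p.profile[p.profile.size // 2] for p in profs]
        assert np.all(np.diff(tss_means) > 0)

    def test_mnase_has_tss_depletion(self, tiny_config, tiny_dataset):
        from epiexpr.track_io import extract_vector
        cfg = tiny_config
        m = tiny_dataset.mnase[cfg.cell_types[0]]
        vecs = np.stack([extract_vector(m, g, cfg.context)
                         for g in tiny_dataset.genes])
        mean = vecs.mean(axis=0)
        center = mean[mean.size // 2 - 1:mean.size // 2 + 2].mean()
        flanks = np.r_[mean[:5], mean[-5:]].mean()
        assert center < 0.5 * flanks

    def test_body_mark_downstream_only(self, tiny_windows):
        sig = np.stack([w.assay_column("H3K36me3") for w in tiny_windows])
        mean = sig.mean(axis=0)
        c = mean.size // 2
        assert mean[c + 10:].mean() > 3 * mean[:c - 10].mean()

    def test_rejects_oversized_context(self):
        with pytest.raises(SimulationError, match="chromosome"):
            SimulationConfig(context=5000, chromosome_length=4000)

    def test_requires_exactly_one_tss_assay(self):
        bad = (AssayConfig("a", "activating_tss"), AssayConfig("b", "activating_tss"))
        with pytest.raises(SimulationError, match="activating_tss"):
            SimulationConfig(assays=bad)


class TestBatchDistortion:
    def test_identity(self, tiny_dataset):
        t = next(iter(tiny_dataset.tracks.values()))
        out = apply_batch_distortion(t, 1.0, 1.0)
        for chrom in t.data:
            np.testing.assert_allclose(out.data[chrom], t.data[chrom])

    def test_direct_arithmetic(self):
        from epiexpr.track_io import BinnedTrack
        t = BinnedTrack("ct", "a", 25, {"chr1": np.array([1.0, 4.0])})
        out = apply_batch_distortion(t, 2.0, 0.5)
        np.testing.assert_allclose(out.data["chr1"], [2.0, 4.0])

    def test_rank_identical_to_original(self, tiny_dataset):
        t = next(iter(tiny_dataset.tracks.values()))
        out = apply_batch_distortion(t, 0.3, 2.7)
        v0, v1 = t.values_concat(), out.values_concat()
        assert stats.spearmanr(v0, v1).statistic == pytest.approx(1.0)

    @pytest.mark.parametrize("scale,power", [(0.0, 1.0), (1.0, 0.0), (-2.0, 1.0)])
    def test_nonpositive_params_rejected(self, tiny_dataset, scale, power):
        t = next(iter(tiny_dataset.tracks.values()))
        with pytest.raises(SimulationError):
            apply_batch_distortion(t, scale, power)


class TestPerturbationTruth:
    def test_zero_lambda_gives_unit_fold_change(self, tiny_config, tiny_dataset):
        specs = [PerturbationSpec(g.gene_id, tiny_config.W // 2, 500.0, 0.0)
                 for g in tiny_dataset.genes[:5]]
        out = simulate_perturbation_truth(tiny_dataset, specs)
        np.testing.assert_allclose(out.fold_change, 1.0)

    def test_fold_change_monotone_in_lambda(self, tiny_config, tiny_dataset):
        g = tiny_dataset.genes[0]
        specs = [PerturbationSpec(g.gene_id, tiny_config.W // 2, 500.0, lam)
                 for lam in (1.0, 5.0, 20.0)]
        out = simulate_perturbation_truth(tiny_dataset, specs)
        assert np.all(np.diff(out.fold_change) > 0)

    def test_hand_computed_toy_with_flat_mnase(self, tiny_config, tiny_dataset):
        """With MNase ≡ 1 the fold-change equals exp(b1·Δa) with Δa computed
        by hand-evaluating the generator equations."""
        cfg, ds = tiny_config, tiny_dataset
        ct = cfg.cell_types[0]
        flat = ds.mnase[ct].copy()
        for chrom in flat.data:
            flat.data[chrom] = np.ones_like(flat.data[chrom])
        ds_flat = type(ds)(cfg, ds.tracks, {**ds.mnase, ct: flat}, ds.genes,
                           ds.expression, ds.truth)
        j = cfg.W // 2 + 4
        sigma, lam = 25.0, 10.0     # one bin wide
        spec = PerturbationSpec(ds.genes[0].gene_id, j, sigma, lam)
        out = simulate_perturbation_truth(ds_flat, specs=[spec], cell_type=ct)

        # independent hand evaluation of the stated equations
        p = ds.truth.tss_profile
        c = ds.truth.tss_coupling
        deposit = np.array([lam * np.exp(-5.0 * 1.0)
                            * np.exp(-((i - j) * 25.0) ** 2 / (2 * sigma ** 2)) * 1.0
                            for i in range(cfg.W)])
        delta_a = float(p @ deposit) / (c * float(p @ p))
        expected = np.exp(ds.truth.b1 * delta_a)
        assert out.fold_change.iloc[0] == pytest.approx(expected, rel=1e-12)

    def test_unknown_gene_rejected(self, tiny_config, tiny_dataset):
        with pytest.raises(SimulationError, match="unknown gene"):
            simulate_perturbation_truth(
                tiny_dataset,
                [PerturbationSpec("nope", tiny_config.W // 2, 500.0, 1.0)])


def test_write_dataset_roundtrip(tmp_path, tiny_config, tiny_dataset):
    write_dataset(tiny_dataset, tmp_path)
    cfg = SimulationConfig.from_yaml(tmp_path / "config.yaml")
    assert cfg == tiny_config
    genes = read_bed6(tmp_path / "genes.bed")
    assert genes == tiny_dataset.genes
    expr = read_expression(tmp_path / "expression.tsv")
    np.testing.assert_allclose(expr.to_numpy(), tiny_dataset.expression.to_numpy())
    ct, assay = tiny_config.cell_types[0], tiny_config.tss_assay
    back = read_bedgraph(tmp_path / f"{ct}.{assay}.bedGraph", tiny_config.bin_size)
    for chrom, vals in tiny_dataset.tracks[(ct, assay)].data.items():
        np.testing.assert_allclose(back.data[chrom], vals, rtol=1e-4, atol=2e-5)
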