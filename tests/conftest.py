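import numpy as np
import pytest

from epiexpr.simulate import SimulationConfig, simulate_dataset
from epiexpr.track_io import BinnedTrack, GeneAnnotation, windows_for_genes


@pytest.fixture(scope="session")
def tiny_config():
    """Small but complete simulation: 3 cell types, 60 genes, W=41."""
    return SimulationConfig(n_cell_types=3, n_genes=60, n_chromosomes=4,
                            context=1000, seed=42)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return simulate_dataset(tiny_config)


@pytest.fixture(scope="session")
def tiny_windows(tiny_config, tiny_dataset):
    """Per-(gene, cell type) windows from the raw generator tracks."""
    cfg, ds = tiny_config, tiny_dataset
    order = [a.name for a in cfg.assays]
    windows = []
    for ct in cfg.cell_types:
        windows += windows_for_genes(ds.assay_tracks(ct), ds.genes, cfg.context,
                                     assay_order=order, cell_type=ct)
    return windows


@pytest.fixture
def flat_track():
    """A single-chromosome track with known arange values."""
    return BinnedTrack("ct", "H3K27ac", 25, {"chr1": np.arange(400, dtype=float)})


@pytest.fixture
def plus_gene():
    return GeneAnnotation("g_plus", "chr1", 100 * 25, "+")


class ConstantModel:
    """Replicate stub predicting a constant, for ensemble arithmetic tests."""

    def __init__(self, value):
        self.value = value

    def predict(self, X):
        return np.full(X.shape[0], float(self.value))


class LinearSurrogate:
    """Replicate stub that is exactly linear in the transformed features."""

    def __init__(self, coef):
        self.coef = np.asarray(coef, dtype=float)   # shape (A, W)

    def predict(self, X):
        return np.tensordot(X, self.coef, axes=([1, 2], [0, 1]))


@pytest.fixture
def constant_model_cls():
    return ConstantModel


@pytest.fixture
def linear_surrogate_cls():
    return LinearSurrogate
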