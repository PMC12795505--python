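"""In-silico dCas9-p300 editing: local H3K27ac deposition and predicted
fold-changes per gRNA.

The deposition model has three parts, multiplied together:

* steric hindrance — dCas9 binds poorly where a nucleosome sits, so overall
  activity is scaled by exp(−5·m_j) with m_j the nucleosome occupancy
  (MNase signal) at the gRNA target bin j;
* locality — acetylation falls off from the target site as a Gaussian
  kernel exp(−(i−j)²/2σ²) with σ a physical distance in base pairs;
* substrate availability — p300 can only acetylate histones that are
  present, so the deposit at bin i is multiplied point-wise by m_i.

deposit_i = λ · exp(−5·m_j) · exp(−d_ij²/2σ²) · m_i,  d_ij in bp between
bin centers.  The deposit is added to the H3K27ac row of the gene's feature
window on the normalized-track scale, and the fold-change is the ratio of
ensemble-predicted TPM after/before.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .models import ModelEnsemble, fold_change_from_predictions, predict_ensemble
from .track_io import BinnedTrack, FeatureWindow, GeneAnnotation, extract_vector

logger = logging.getLogger(__name__)

DENOM_FLOOR = 0.1   # TPM floor for the fold-change denominator
TPM_EPS = 1e-6      # predictions are clipped to the valid TPM range [ε, ∞)

DEFAULT_SIGMA_GRID = (250.0, 500.0, 1000.0, 2000.0)   # bp
DEFAULT_LAM_GRID = (500.0, 1000.0, 2500.0, 5000.0)    # signal units


class PerturbationError(ValueError):
    pass


@dataclass
class MNaseVector:
    """Nucleosome occupancy aligned to a gene's feature window.

    ``window_max`` normalization rescales to [0, 1] so the hindrance factor
    exp(−5·m_j) spans [e⁻⁵, 1]; ``raw`` keeps coverage units.
    """

    m: np.ndarray
    bin_size: int
    normalization: str = "window_max"

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=float)
        if np.any(self.m < 0) or not np.all(np.isfinite(self.m)):
            raise PerturbationError("MNase vector must be nonnegative and finite")
        if self.normalization not in ("window_max", "raw"):
            raise PerturbationError(f"unknown normalization {self.normalization!r}")
        if self.normalization == "window_max" and self.m.size and self.m.max() > 0:
            self.m = self.m / self.m.max()

    @classmethod
    def from_track(cls, track: BinnedTrack, gene: GeneAnnotation, context: int,
                   normalization: str = "window_max") -> "MNaseVector":
        return cls(extract_vector(track, gene, context), track.bin_size, normalization)


@dataclass(frozen=True)
class PerturbationSpec:
    gene_id: str
    grna_bin: int                  # bin index within the gene's window
    sigma: float                   # Gaussian kernel width, bp
    lam: float                     # overall dCas9-p300 strength, signal units
    hindrance_coeff: float = 5.0

    def __post_init__(self) -> None:
        if self.grna_bin < 0:
            raise PerturbationError("grna_bin must be nonnegative")
        if self.sigma <= 0:
            raise PerturbationError("sigma must be positive")
        if self.lam < 0:
            raise PerturbationError("lam must be nonnegative")


def grna_bin_for_position(gene: GeneAnnotation, position: int, context: int,
                          bin_size: int) -> int:
    """Window bin index of a genomic position (e.g. a protospacer midpoint)."""
    w = context // bin_size + 1
    offset = position // bin_size - gene.tss // bin_size
    if gene.strand == "-":
        offset = -offset
    j = w // 2 + offset
    if not 0 <= j < w:
        raise PerturbationError(
            f"position {position} falls outside the {context} bp window of {gene.gene_id}")
    return j


def p300_deposit(m: MNaseVector, spec: PerturbationSpec) -> np.ndarray:
    """The H3K27ac deposit vector over the window for one gRNA."""
    j = spec.grna_bin
    if j >= m.m.size:
        raise PerturbationError(f"grna_bin {j} outside window of {m.m.size} bins")
    d_bp = (np.arange(m.m.size) - j) * m.bin_size
    hindrance = np.exp(-spec.hindrance_coeff * m.m[j])
    kernel = np.exp(-(d_bp ** 2) / (2.0 * spec.sigma ** 2))
    return spec.lam * hindrance * kernel * m.m


def apply_p300(window: FeatureWindow, deposit: np.ndarray,
               h3k27ac_assay: str) -> FeatureWindow:
    """Add the deposit to the H3K27ac row; all other assays untouched."""
    deposit = np.asarray(deposit, dtype=float)
    if deposit.shape != (window.W,):
        raise PerturbationError(
            f"deposit length {deposit.shape} does not match window W={window.W}")
    out = window.copy()
    out.assay_column(h3k27ac_assay)[:] += deposit
    return out


def predict_fold_change(ensemble: ModelEnsemble, window: FeatureWindow,
                        m: MNaseVector, spec: PerturbationSpec,
                        h3k27ac_assay: str, *, space: str = "pseudocount",
                        denom_floor: float = DENOM_FLOOR) -> float:
    """Predicted expression fold-change for one gRNA: perturbed / endogenous.

    ``pseudocount`` space (default) ratios the predicted (1 + TPM); ``tpm``
    space ratios expm1 predictions and raises when the endogenous predicted
    TPM falls below ``denom_floor``.
    """
    deposit = p300_deposit(m, spec)
    perturbed = apply_p300(window, deposit, h3k27ac_assay)
    preds = predict_ensemble(ensemble, [window, perturbed])
    fc = fold_change_from_predictions(preds[0], preds[1], space, denom_floor)
    if np.isnan(fc):
        endo = float(ensemble.preprocess.inverse_target(preds[0]))
        raise PerturbationError(
            f"{spec.gene_id}: endogenous predicted TPM {endo:.3g} below floor {denom_floor}")
    return float(fc)


def sweep_parameters(ensemble: ModelEnsemble,
                     items: list[tuple[FeatureWindow, MNaseVector, PerturbationSpec]],
                     sigma_grid=DEFAULT_SIGMA_GRID, lam_grid=DEFAULT_LAM_GRID,
                     h3k27ac_assay: str = "H3K27ac",
                     space: str = "pseudocount") -> pd.DataFrame:
    """Fold-change for every (gRNA, σ, λ) combination."""
    if not len(sigma_grid) or not len(lam_grid):
        raise PerturbationError("empty parameter grid")
    rows = []
    for window, m, spec in items:
        for sigma in sigma_grid:
            for lam in lam_grid:
                s = replace(spec, sigma=float(sigma), lam=float(lam))
                fc = predict_fold_change(ensemble, window, m, s, h3k27ac_assay,
                                         space=space)
                rows.append({"gene_id": s.gene_id, "grna_bin": s.grna_bin,
                             "sigma": s.sigma, "lam": s.lam, "fold_change": fc})
    return pd.DataFrame(rows)
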