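"""Cross-cell-type normalization of −log10(p) tracks (adapted S3norm).

A reference cell type is chosen and kept unchanged (up to the shared
add-1/divide rescaling); every other cell type's track for the same assay is
matched to it by a scale-and-power map ``x ↦ α·x^β`` fitted so that mean
signal agrees with the reference separately over *common peaks* (peak bins
in both cell types) and *common background* (background bins in both).

Peaks are called per track: experimental tracks by Benjamini–Hochberg FDR on
the per-bin p-values (genome-wide), imputed tracks as the top-k most
significant bins.  Before fitting, values in the common sets are transformed
as (1 + x) / denom where denom is the minimum observed value over the union
of common peaks and common background for that cell type, floored at a small
ε since −log10(p) minima are typically exactly 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .track_io import IMPUTED, BinnedTrack

logger = logging.getLogger(__name__)

#: floor for the add-1/divide denominator; −log10(p) minima are usually 0
DENOM_FLOOR = 1e-3


class NormalizationError(ValueError):
    pass


@dataclass
class PeakSets:
    """Partition of all bins of a track into peaks and background."""

    peaks: dict[str, np.ndarray]       # sorted bin indices per chromosome
    background: dict[str, np.ndarray]
    method: str                        # "fdr" or "imputed_topk"

    def n_peaks(self) -> int:
        return int(sum(v.size for v in self.peaks.values()))


@dataclass
class NormalizationFit:
    reference_cell_type: str
    target_cell_type: str
    assay: str
    alpha: float
    beta: float
    common_peaks: dict[str, np.ndarray] = field(default_factory=dict)
    common_background: dict[str, np.ndarray] = field(default_factory=dict)
    denominators: tuple[float, float] = (1.0, 1.0)   # (ref_min, tgt_min)
    residual: float = 0.0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise NormalizationError(
                f"alpha/beta must be positive, got ({self.alpha}, {self.beta})")


def identity_fit(cell_type: str, assay: str, denom: float = 1.0) -> NormalizationFit:
    """The pass-through fit used for the reference cell type (α = β = 1)."""
    return NormalizationFit(cell_type, cell_type, assay, 1.0, 1.0,
                            denominators=(denom, denom))


# ---------------------------------------------------------------------------

def call_peaks(track: BinnedTrack, fdr: float = 0.05, top_k: int = 1000) -> PeakSets:
    """Call peak bins on a −log10(p) track.

    Experimental tracks: BH-adjust p = 10^(−value) genome-wide and take
    adjusted p < ``fdr``.  Imputed tracks: take the ``top_k`` bins with the
    largest −log10(p) (smallest p), clipped to the track size with a warning.
    """
    if track.n_bins() == 0:
        raise NormalizationError("cannot call peaks on an empty track")
    chroms = track.chroms
    lengths = [track.data[c].size for c in chroms]
    values = track.values_concat()

    if track.provenance == IMPUTED:
        k = top_k
        if k >= values.size:
            logger.warning("top_k=%d >= %d bins; all bins become peaks", k, values.size)
            k = values.size
        order = np.argsort(values, kind="stable")[::-1]
        flat_peaks = np.zeros(values.size, dtype=bool)
        flat_peaks[order[:k]] = True
        method = "imputed_topk"
    else:
        if not 0 < fdr < 1:
            raise NormalizationError(f"fdr must be in (0, 1), got {fdr}")
        pvals = np.power(10.0, -values)
        padj = stats.false_discovery_control(pvals, method="bh")
        flat_peaks = padj < fdr
        method = "fdr"

    peaks, background = {}, {}
    offset = 0
    for chrom, n in zip(chroms, lengths):
        mask = flat_peaks[offset:offset + n]
        peaks[chrom] = np.flatnonzero(mask)
        background[chrom] = np.flatnonzero(~mask)
        offset += n
    return PeakSets(peaks, background, method)


def common_sets(ref: PeakSets, tgt: PeakSets) -> tuple[dict[str, np.ndarray],
                                                       dict[str, np.ndarray]]:
    """Common peaks (peak in both) and common background (background in both)."""
    chroms = set(ref.peaks) | set(tgt.peaks)
    cp, cb = {}, {}
    for c in sorted(chroms):
        cp[c] = np.intersect1d(ref.peaks.get(c, []), tgt.peaks.get(c, []))
        cb[c] = np.intersect1d(ref.background.get(c, []), tgt.background.get(c, []))
    if sum(v.size for v in cp.values()) == 0:
        raise NormalizationError("no common peaks; normalization fit impossible")
    if sum(v.size for v in cb.values()) == 0:
        raise NormalizationError("no common background; normalization fit impossible")
    return cp, cb


def _gather(track: BinnedTrack, index_sets: dict[str, np.ndarray]) -> np.ndarray:
    parts = [track.data[c][idx] for c, idx in index_sets.items()
             if c in track.data and idx.size]
    return np.concatenate(parts) if parts else np.empty(0)


def transform_values(values: np.ndarray, min_denominator: float,
                     clamp_at_zero: bool = False) -> np.ndarray:
    """The add-1/divide transform: (1 + x) / min_denominator.

    ``clamp_at_zero`` additionally applies max(·, 0), as the background
    equations prescribe (a no-op for nonnegative input, kept for fidelity).
    """
    if min_denominator <= 0:
        raise NormalizationError(f"nonpositive denominator {min_denominator}")
    out = (1.0 + np.asarray(values, dtype=float)) / min_denominator
    if clamp_at_zero:
        out = np.maximum(out, 0.0)
    return out


def fit_s3norm(ref_transformed_peaks: np.ndarray, ref_transformed_bg: np.ndarray,
               tgt_transformed_peaks: np.ndarray, tgt_transformed_bg: np.ndarray,
               *, tol: float = 1e-8, max_expand: int = 60) -> tuple[float, float, float]:
    """Solve the two mean-matching equations for (α, β).

    Given β, α is available in closed form from the peak equation, which it
    then satisfies exactly; β is found by Powell minimization of the squared
    log-residual of the background equation, followed by a Brent root polish
    when a sign change brackets the optimum.  Returns (alpha, beta, residual)
    where residual is the largest absolute log-residual of the two equations.
    """
    for name, v in [("ref peaks", ref_transformed_peaks), ("ref background", ref_transformed_bg),
                    ("tgt peaks", tgt_transformed_peaks), ("tgt background", tgt_transformed_bg)]:
        v = np.asarray(v, dtype=float)
        if v.size == 0:
            raise NormalizationError(f"empty vector for {name}")
        if np.any(v <= 0):
            raise NormalizationError(f"nonpositive transformed values in {name}")

    log_ref_pk = np.log(np.mean(ref_transformed_peaks))
    log_ref_bg = np.log(np.mean(ref_transformed_bg))

    def alpha_of(beta: float) -> float:
        return float(np.exp(log_ref_pk - np.log(np.mean(tgt_transformed_peaks ** beta))))

    def bg_log_residual(beta: float) -> float:
        a = alpha_of(beta)
        return float(np.log(a) + np.log(np.mean(tgt_transformed_bg ** beta)) - log_ref_bg)

    res = optimize.minimize(lambda b: bg_log_residual(b[0]) ** 2, x0=[1.0],
                            method="Powell",
                            options={"xtol": 1e-12, "ftol": 1e-16, "maxiter": 500})
    beta = float(res.x[0])
    if beta <= 0:
        beta = 1e-6

    # polish: bracket a sign change around the Powell optimum and root-find
    r0 = bg_log_residual(beta)
    if abs(r0) > tol:
        step = max(1e-6, abs(beta) * 1e-3)
        lo = hi = beta
        for _ in range(max_expand):
            lo, hi = max(lo - step, 1e-9), hi + step
            rlo, rhi = bg_log_residual(lo), bg_log_residual(hi)
            if np.sign(rlo) != np.sign(rhi):
                beta = float(optimize.brentq(bg_log_residual, lo, hi, xtol=1e-14))
                break
            step *= 2.0

    alpha = alpha_of(beta)
    residual = max(abs(bg_log_residual(beta)), 0.0)  # peak residual is 0 by construction
    if residual > 1e-6:
        raise NormalizationError(
            f"mean-matching failed to converge: background log-residual {residual:.3g}")
    return alpha, beta, residual


def fit_tracks(ref: BinnedTrack, tgt: BinnedTrack, *, fdr: float = 0.05,
               top_k: int = 1000) -> NormalizationFit:
    """End-to-end fit of one target track against the reference track."""
    if ref.assay != tgt.assay:
        raise NormalizationError(f"assay mismatch: {ref.assay} vs {tgt.assay}")
    cp, cb = common_sets(call_peaks(ref, fdr, top_k), call_peaks(tgt, fdr, top_k))

    ref_pk, ref_bg = _gather(ref, cp), _gather(ref, cb)
    tgt_pk, tgt_bg = _gather(tgt, cp), _gather(tgt, cb)
    ref_min = max(float(min(ref_pk.min(), ref_bg.min())), DENOM_FLOOR)
    tgt_min = max(float(min(tgt_pk.min(), tgt_bg.min())), DENOM_FLOOR)

    alpha, beta, residual = fit_s3norm(
        transform_values(ref_pk, ref_min),
        transform_values(ref_bg, ref_min, clamp_at_zero=True),
        transform_values(tgt_pk, tgt_min),
        transform_values(tgt_bg, tgt_min, clamp_at_zero=True),
    )
    return NormalizationFit(ref.cell_type, tgt.cell_type, ref.assay, alpha, beta,
                            common_peaks=cp, common_background=cb,
                            denominators=(ref_min, tgt_min), residual=residual)


def apply_s3norm(fit: NormalizationFit, track: BinnedTrack) -> BinnedTrack:
    """Apply a fit to a full track: (1 + x)/denom, then α·(·)^β.

    The reference cell type is passed through the same add-1/divide transform
    with α = β = 1 (an :func:`identity_fit`) so every cell type ends up on
    one common scale.
    """
    if fit.assay and track.assay and fit.assay != track.assay:
        raise NormalizationError(
            f"fit is for assay {fit.assay!r}, track is {track.assay!r}")
    denom = fit.denominators[1]
    out = track.copy()
    for chrom, vals in out.data.items():
        out.data[chrom] = fit.alpha * transform_values(vals, denom) ** fit.beta
    return out


def normalize_cell_types(tracks: dict[tuple[str, str], BinnedTrack],
                         reference: str, *, fdr: float = 0.05,
                         top_k: int = 1000) -> tuple[dict[tuple[str, str], BinnedTrack],
                                                     list[NormalizationFit]]:
    """Normalize every (cell type, assay) track against the reference cell type.

    Returns the normalized tracks (reference passed through add-1/divide with
    its own denominator) and the list of fits.
    """
    assays = sorted({assay for (_, assay) in tracks})
    cell_types = sorted({ct for (ct, _) in tracks})
    if reference not in cell_types:
        raise NormalizationError(f"reference cell type {reference!r} not present")
    normed: dict[tuple[str, str], BinnedTrack] = {}
    fits: list[NormalizationFit] = []
    for assay in assays:
        ref_track = tracks[(reference, assay)]
        ref_denom = None
        for ct in cell_types:
            if ct == reference:
                continue
            fit = fit_tracks(ref_track, tracks[(ct, assay)], fdr=fdr, top_k=top_k)
            fits.append(fit)
            normed[(ct, assay)] = apply_s3norm(fit, tracks[(ct, assay)])
            if ref_denom is None:   # first pairing fixes the reference scale
                ref_denom = fit.denominators[0]
        if ref_denom is None:   # single cell type: nothing to match against
            ref_denom = 1.0
        normed[(reference, assay)] = apply_s3norm(
            identity_fit(reference, assay, ref_denom), ref_track)
    return normed, fits
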