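"""Synthetic multi-cell-type histone PTM / MNase / expression datasets.

The generator emulates the statistical structure the downstream stages
need, without any read-level simulation:

* a latent activity a_{g,c} per gene × cell type (gene effect + cell-type
  effect + interaction noise, Gaussian, clipped at 0);
* an activating promoter mark (the H3K27ac analog) laid down as
  coupling · a_{g,c} times a TSS-peaked profile with ~200 bp nucleosome-
  period bumps; a gene-body mark elevated only downstream of the TSS; a
  repressive mark that rises as activity falls; and a decoy mark driven by
  an independent latent, so it carries no expression information;
* MNase nucleosome occupancy with ~200 bp periodicity and a nucleosome-
  depleted region (NDR) of randomized depth/width spanning each TSS;
* TPM = max(exp(b0 + b1·a_{g,c} + ε) − offset, 0), so expression is a known
  monotone function of activity with zeros for silent genes;
* truncated-Gaussian (clipped at 0) track noise, keeping every track a
  valid nonnegative −log10(p)-like signal.

Cross-cell-type batch distortion (x ↦ scale·x^power) is *not* applied by
``simulate_dataset``; it is a separate step so the normalization stage can
be tested against a known distortion.

Genes alternate across chromosomes chr1..chrN so held-out-chromosome splits
carry genes from every part of the generative process.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .perturbation import MNaseVector, PerturbationSpec, p300_deposit
from .track_io import (BinnedTrack, GeneAnnotation, window_bins,
                       write_bed6, write_bedgraph, write_expression)

logger = logging.getLogger(__name__)

ASSAY_ROLES = ("activating_tss", "activating_body", "repressive", "decoy")

#: nucleosome repeat length emulated in tracks and MNase signal, bp
NUCLEOSOME_PERIOD = 200


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class AssayConfig:
    name: str
    role: str
    coupling: float = 1.0

    def __post_init__(self) -> None:
        if self.role not in ASSAY_ROLES:
            raise SimulationError(f"unknown assay role {self.role!r}")


def default_assays() -> tuple[AssayConfig, ...]:
    return (AssayConfig("H3K27ac", "activating_tss", 2.5),
            AssayConfig("H3K36me3", "activating_body", 2.0),
            AssayConfig("H3K27me3", "repressive", 2.0),
            AssayConfig("control", "decoy", 2.5))


def default_batch_params(n_cell_types: int) -> dict[str, tuple[float, float]]:
    """Per-cell-type (scale, power) distortions; the reference (cell_type_0)
    is undistorted.  Powers far from 1 reshape metagene profiles enough that
    raw cross-cell-type profile correlations drop well below the normalized
    ones."""
    cycle = [(1.8, 4.5), (0.55, 6.0), (2.40, 8.0), (0.70, 5.0)]
    out = {"cell_type_0": (1.0, 1.0)}
    for i in range(1, n_cell_types):
        out[f"cell_type_{i}"] = cycle[(i - 1) % len(cycle)]
    return out


@dataclass
class SimulationConfig:
    n_cell_types: int = 4
    n_genes: int = 1000
    n_chromosomes: int = 4
    bin_size: int = 25
    context: int = 2500
    assays: tuple[AssayConfig, ...] = field(default_factory=default_assays)
    noise_sd: float = 0.3
    batch_params: dict[str, tuple[float, float]] | None = None
    tpm_link: tuple[float, float] = (-1.0, 1.0)     # (b0, b1)
    tpm_offset: float = 1.0
    gene_gap_bins: int = 20
    chromosome_length: int | None = None            # bp; default derived
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise SimulationError("n_genes must be >= 1")
        if self.n_cell_types < 1 or self.n_chromosomes < 1:
            raise SimulationError("need >= 1 cell type and chromosome")
        if self.context % self.bin_size != 0:
            raise SimulationError(
                f"bin_size {self.bin_size} does not divide context {self.context}")
        roles = [a.role for a in self.assays]
        if roles.count("activating_tss") != 1:
            raise SimulationError(
                "exactly one assay must play the activating_tss (H3K27ac analog) role")
        if self.batch_params is not None:
            for ct, (a, b) in self.batch_params.items():
                if a <= 0 or b <= 0:
                    raise SimulationError(
                        f"batch scale/power for {ct} must be positive, got ({a}, {b})")
        if self.chromosome_length is not None and \
                self.chromosome_length < self.context + 2 * self.bin_size:
            raise SimulationError(
                f"context {self.context} bp does not fit in a "
                f"{self.chromosome_length} bp chromosome")

    @property
    def W(self) -> int:
        return window_bins(self.context, self.bin_size)

    @property
    def cell_types(self) -> list[str]:
        return [f"cell_type_{i}" for i in range(self.n_cell_types)]

    @property
    def tss_assay(self) -> str:
        return next(a.name for a in self.assays if a.role == "activating_tss")

    def resolved_batch_params(self) -> dict[str, tuple[float, float]]:
        if self.batch_params is not None:
            return dict(self.batch_params)
        return default_batch_params(self.n_cell_types)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["assays"] = [asdict(a) for a in self.assays]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["assays"] = tuple(AssayConfig(**a) for a in d.get("assays", []))
        if d.get("batch_params"):
            d["batch_params"] = {k: tuple(v) for k, v in d["batch_params"].items()}
        d["tpm_link"] = tuple(d["tpm_link"])
        return cls(**d)


@dataclass
class GeneratorTruth:
    """The generative quantities downstream stages are evaluated against."""

    activity: pd.DataFrame            # genes × cell types, latent a_{g,c}
    decoy_latent: pd.DataFrame
    b0: float
    b1: float
    tss_coupling: float
    tss_profile: np.ndarray           # length-W noise-free profile p, peak 1
    config: SimulationConfig

    def activity_readout(self, window_signal: np.ndarray) -> float:
        """Matched-filter estimate of activity from an activating_tss window:
        R(x) = Σ pᵢxᵢ / (c·Σ pᵢ²), so R(c·a·p) = a exactly."""
        p = self.tss_profile
        return float(p @ np.asarray(window_signal) / (self.tss_coupling * (p @ p)))

    def delta_activity(self, deposit: np.ndarray) -> float:
        """Activity increment implied by adding ``deposit`` to the track."""
        return self.activity_readout(deposit) if deposit.size else 0.0


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    tracks: dict[tuple[str, str], BinnedTrack]     # (cell type, assay)
    mnase: dict[str, BinnedTrack]                  # cell type
    genes: list[GeneAnnotation]
    expression: pd.DataFrame                       # genes × cell types, TPM
    truth: GeneratorTruth

    def gene(self, gene_id: str) -> GeneAnnotation:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise SimulationError(f"unknown gene {gene_id!r}")

    def assay_tracks(self, cell_type: str) -> dict[str, BinnedTrack]:
        return {assay: t for (ct, assay), t in self.tracks.items() if ct == cell_type}


# ---------------------------------------------------------------------------
# Spatial profiles (length W, oriented: index increases downstream of TSS)
# ---------------------------------------------------------------------------

def _offsets_bp(W: int, bin_size: int) -> np.ndarray:
    return (np.arange(W) - W // 2) * float(bin_size)


def tss_profile(W: int, bin_size: int) -> np.ndarray:
    """Promoter profile: Gaussian envelope with nucleosome-period bumps."""
    d = _offsets_bp(W, bin_size)
    env = np.exp(-d ** 2 / (2 * 400.0 ** 2))
    bumps = 0.75 + 0.25 * np.cos(2 * np.pi * d / NUCLEOSOME_PERIOD)
    return env * bumps


def body_profile(W: int, bin_size: int) -> np.ndarray:
    """Gene-body profile: near zero upstream, plateau downstream of the TSS."""
    d = _offsets_bp(W, bin_size)
    return 0.8 / (1.0 + np.exp(-(d - 200.0) / 100.0))


def broad_profile(W: int, bin_size: int) -> np.ndarray:
    """Broad domain used by the repressive and decoy marks."""
    d = _offsets_bp(W, bin_size)
    return 0.6 * np.exp(-d ** 2 / (2 * 1000.0 ** 2))


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _gene_layout(cfg: SimulationConfig) -> tuple[list[GeneAnnotation], dict[str, int]]:
    """Genes on alternating chromosomes at fixed spacing, windows fully inside."""
    W, half = cfg.W, cfg.W // 2
    pitch = W + cfg.gene_gap_bins
    margin = half + 4
    per_chrom = -(-cfg.n_genes // cfg.n_chromosomes)
    n_bins = margin + per_chrom * pitch + half + 4
    if cfg.chromosome_length is not None:
        avail = cfg.chromosome_length // cfg.bin_size
        if avail < margin + pitch:
            raise SimulationError("context larger than the simulated chromosome allows")
        n_bins = max(n_bins, avail)
    genes = []
    for g in range(cfg.n_genes):
        chrom = f"chr{g % cfg.n_chromosomes + 1}"
        idx = g // cfg.n_chromosomes
        center_bin = margin + idx * pitch
        strand = "+" if g % 2 == 0 else "-"
        genes.append(GeneAnnotation(f"gene_{g:05d}", chrom,
                                    center_bin * cfg.bin_size, strand))
    sizes = {f"chr{i + 1}": n_bins for i in range(cfg.n_chromosomes)}
    return genes, sizes


def _truncated_noise(rng: np.random.Generator, sd: float, shape) -> np.ndarray:
    return np.maximum(rng.normal(0.0, sd, shape), 0.0) if sd > 0 else np.zeros(shape)


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Draw a complete multi-cell-type dataset; deterministic given the seed."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    W, half, bs = cfg.W, cfg.W // 2, cfg.bin_size
    genes, chrom_bins = _gene_layout(cfg)
    cts = cfg.cell_types

    # latent activity: gene effect + cell-type effect + interaction, clipped
    gene_eff = rng.normal(2.0, 1.0, cfg.n_genes)
    cell_eff = rng.normal(0.0, 0.3, cfg.n_cell_types)
    inter = rng.normal(0.0, 0.3, (cfg.n_genes, cfg.n_cell_types))
    activity = np.clip(gene_eff[:, None] + cell_eff[None, :] + inter, 0.0, None)
    decoy_latent = np.clip(rng.normal(2.0, 1.0, (cfg.n_genes, cfg.n_cell_types)), 0.0, None)
    a_high = float(np.quantile(activity, 0.9))

    profiles = {"activating_tss": tss_profile(W, bs),
                "activating_body": body_profile(W, bs),
                "repressive": broad_profile(W, bs),
                "decoy": broad_profile(W, bs)}

    gene_ids = [g.gene_id for g in genes]
    centers = {g.gene_id: g.tss // bs for g in genes}

    tracks: dict[tuple[str, str], BinnedTrack] = {}
    for ci, ct in enumerate(cts):
        for assay in cfg.assays:
            prof = profiles[assay.role]
            data = {c: np.zeros(n) for c, n in chrom_bins.items()}
            for gi, g in enumerate(genes):
                a = activity[gi, ci]
                if assay.role == "activating_tss" or assay.role == "activating_body":
                    amp = assay.coupling * a
                elif assay.role == "repressive":
                    amp = assay.coupling * max(a_high - a, 0.0)
                else:                                   # decoy: independent latent
                    amp = assay.coupling * decoy_latent[gi, ci]
                oriented = prof if g.strand == "+" else prof[::-1]
                c0 = centers[g.gene_id]
                data[g.chrom][c0 - half:c0 + half + 1] += amp * oriented
            for c in data:
                data[c] += _truncated_noise(rng, cfg.noise_sd, data[c].shape)
            tracks[(ct, assay.name)] = BinnedTrack(ct, assay.name, bs, data)

    # MNase: ~200 bp periodic occupancy, per-(cell type, chromosome) phase,
    # with a randomized NDR carved around each TSS
    mnase: dict[str, BinnedTrack] = {}
    for ci, ct in enumerate(cts):
        data = {}
        for chrom, n in chrom_bins.items():
            phase = rng.uniform(0, 2 * np.pi)
            pos = np.arange(n) * bs
            data[chrom] = 0.55 + 0.45 * np.cos(2 * np.pi * pos / NUCLEOSOME_PERIOD + phase)
        for g in genes:
            depth = rng.uniform(0.70, 0.95)
            width = rng.uniform(75.0, 150.0)
            c0 = centers[g.gene_id]
            lo, hi = c0 - half, c0 + half + 1
            d = (np.arange(lo, hi) - c0) * float(bs)
            data[g.chrom][lo:hi] *= 1.0 - depth * np.exp(-d ** 2 / (2 * width ** 2))
        for c in data:
            data[c] = np.maximum(data[c] + rng.normal(0, 0.02, data[c].shape), 0.0)
        mnase[ct] = BinnedTrack(ct, "MNase", bs, data)

    b0, b1 = cfg.tpm_link
    eps = rng.normal(0.0, cfg.noise_sd, activity.shape)
    tpm = np.maximum(np.exp(b0 + b1 * activity + eps) - cfg.tpm_offset, 0.0)
    expression = pd.DataFrame(tpm, index=gene_ids, columns=cts)
    expression.index.name = "gene_id"

    tss_cfg = next(a for a in cfg.assays if a.role == "activating_tss")
    truth = GeneratorTruth(
        activity=pd.DataFrame(activity, index=gene_ids, columns=cts),
        decoy_latent=pd.DataFrame(decoy_latent, index=gene_ids, columns=cts),
        b0=b0, b1=b1, tss_coupling=tss_cfg.coupling,
        tss_profile=profiles["activating_tss"], config=cfg)
    return SyntheticDataset(cfg, tracks, mnase, genes, expression, truth)


# ---------------------------------------------------------------------------
# Batch distortion
# ---------------------------------------------------------------------------

def apply_batch_distortion(track: BinnedTrack, scale: float, power: float) -> BinnedTrack:
    """Distort a track by x ↦ scale·x^power (a monotone, rank-preserving map
    emulating inconsistent sequencing depth / dynamic range across batches)."""
    if scale <= 0 or power <= 0:
        raise SimulationError(
            f"scale and power must be positive, got ({scale}, {power})")
    out = track.copy()
    for chrom, vals in out.data.items():
        out.data[chrom] = scale * np.power(vals, power)
    return out


def distort_dataset(dataset: SyntheticDataset) -> dict[tuple[str, str], BinnedTrack]:
    """Apply each cell type's (scale, power) batch distortion to its PTM tracks."""
    params = dataset.config.resolved_batch_params()
    out = {}
    for (ct, assay), track in dataset.tracks.items():
        scale, power = params.get(ct, (1.0, 1.0))
        out[(ct, assay)] = apply_batch_distortion(track, scale, power)
    return out


# ---------------------------------------------------------------------------
# Ground-truth perturbation fold-changes
# ---------------------------------------------------------------------------

def simulate_perturbation_truth(dataset: SyntheticDataset,
                                specs: Sequence[PerturbationSpec],
                                cell_type: str | None = None,
                                mnase_normalization: str = "window_max",
                                ) -> pd.DataFrame:
    """Generator-truth expression fold-change for each gRNA spec.

    The generator-truth H3K27ac deposit (same deposition model the predictor
    uses, with the generator's own MNase) is added to the activating_tss
    track; the implied activity increment Δa is read out with the
    generator's matched filter and the fold-change on the expression link
    scale is exp(b1·Δa) — the offset-free ratio TPM_perturbed/TPM_endogenous.
    """
    cfg = dataset.config
    ct = cell_type if cell_type is not None else cfg.cell_types[0]
    if ct not in dataset.mnase:
        raise SimulationError(f"unknown cell type {ct!r}")
    truth = dataset.truth
    rows = []
    for spec in specs:
        gene = dataset.gene(spec.gene_id)
        if not 0 <= spec.grna_bin < cfg.W:
            raise SimulationError(
                f"{spec.gene_id}: gRNA bin {spec.grna_bin} outside the window")
        m = MNaseVector.from_track(dataset.mnase[ct], gene, cfg.context,
                                   mnase_normalization)
        deposit = p300_deposit(m, spec)
        delta_a = truth.delta_activity(deposit)
        rows.append({"gene_id": spec.gene_id, "cell_type": ct,
                     "grna_bin": spec.grna_bin, "sigma": spec.sigma,
                     "lam": spec.lam, "delta_activity": delta_a,
                     "fold_change": float(np.exp(truth.b1 * delta_a))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# On-disk representation
# ---------------------------------------------------------------------------

def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> None:
    """Write tracks as bedGraph, genes as BED6, expression as TSV, config as YAML."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for (ct, assay), track in dataset.tracks.items():
        write_bedgraph(track, outdir / f"{ct}.{assay}.bedGraph")
    for ct, track in dataset.mnase.items():
        write_bedgraph(track, outdir / f"{ct}.MNase.bedGraph")
    write_bed6(dataset.genes, outdir / "genes.bed")
    write_expression(dataset.expression, outdir / "expression.tsv")
    dataset.truth.activity.to_csv(outdir / "truth_activity.tsv", sep="\t")
    dataset.config.to_yaml(outdir / "config.yaml")
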