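"""Stage orchestration: simulate → normalize → train → evaluate →
attribute → perturb, with reproducible configuration and provenance.

Each stage reads its inputs from the run directory (written by an earlier
stage), writes its artifacts there, and records a manifest (config hash,
seed, package version, artifact list) so any output can be re-derived.
Stage dependencies are checked before any computation starts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .attribution import AttributionSpec, attribution_profile, sample_genes
from .evaluation import metagene
from .models import (CNNHyperparams, SplitSpec, build_dataset, evaluate,
                     predict_ensemble, train_ensemble)
from .normalization import normalize_cell_types
from .perturbation import (DEFAULT_LAM_GRID, DEFAULT_SIGMA_GRID, MNaseVector,
                           PerturbationSpec, sweep_parameters)
from .simulate import SimulationConfig, distort_dataset, simulate_dataset
from .track_io import windows_for_genes

logger = logging.getLogger(__name__)

STAGES = ("simulate", "normalize", "train", "evaluate", "attribute", "perturb")

#: artifacts each stage needs before it can run
_REQUIRES = {
    "simulate": (),
    "normalize": ("tracks",),
    "train": ("normalized",),
    "evaluate": ("ensemble",),
    "attribute": ("ensemble",),
    "perturb": ("ensemble",),
}


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    out_dir: str = "results/run"
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    reference_cell_type: str = "cell_type_0"
    fdr: float = 0.05
    top_k: int = 1000
    model_kind: str = "cnn"
    n_replicates: int = 3
    val_chroms: tuple[str, ...] = ("chr3",)
    test_chroms: tuple[str, ...] = ("chr4",)
    holdout_cell_type: str | None = None
    lr_schedule: tuple[tuple[float, int], ...] = ((0.001, 10), (0.0005, 5))
    attribution_assay: str = "H3K27ac"
    lambda0: float = 2500.0
    attr_halfwidth: int = 3
    attr_n_genes: int = 200
    sigma_grid: tuple[float, ...] = DEFAULT_SIGMA_GRID
    lam_grid: tuple[float, ...] = DEFAULT_LAM_GRID

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "simulation" in d:
            sim = d["simulation"]
            if "assays" in sim:
                from .simulate import AssayConfig
                sim["assays"] = tuple(AssayConfig(**a) for a in sim["assays"])
            d["simulation"] = SimulationConfig(**sim)
        for key in ("val_chroms", "test_chroms", "sigma_grid", "lam_grid"):
            if key in d:
                d[key] = tuple(d[key])
        if "lr_schedule" in d:
            d["lr_schedule"] = tuple((float(a), int(b)) for a, b in d["lr_schedule"])
        return cls(**d)

    def config_hash(self) -> str:
        d = asdict(self)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _write_manifest(out: Path, stage: str, config: RunConfig, artifacts: list[str]) -> None:
    manifest = {"stage": stage, "config_hash": config.config_hash(),
                "seed": config.seed, "version": __version__,
                "artifacts": sorted(artifacts)}
    with open(out / f"manifest_{stage}.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


class PipelineRun:
    """Holds in-memory state across stages of one run."""

    def __init__(self, config: RunConfig) -> None:
        self.config = config
        self.out = Path(config.out_dir)
        self.dataset = None
        self.normalized = None
        self.ensemble = None
        self.splits = None

    def _have(self, artifact: str) -> bool:
        return getattr(self, {"tracks": "dataset", "normalized": "normalized",
                              "ensemble": "ensemble"}[artifact]) is not None

    def run(self, stages: list[str]) -> None:
        for s in stages:
            if s not in STAGES:
                raise PipelineError(f"unknown stage {s!r}")
        # fail before any computation if a dependency is missing
        planned = set()
        for s in stages:
            for need in _REQUIRES[s]:
                if not self._have(need) and not self._satisfiable(need, planned):
                    raise PipelineError(
                        f"stage {s!r} requires {need!r}; run the producing stage first")
            planned.add(s)
        self.out.mkdir(parents=True, exist_ok=True)
        for s in stages:
            logger.info("running stage %s", s)
            getattr(self, f"stage_{s}")()

    @staticmethod
    def _satisfiable(need: str, planned: set) -> bool:
        producers = {"tracks": "simulate", "normalized": "normalize",
                     "ensemble": "train"}
        return producers[need] in planned

    # -- stages -----------------------------------------------------------

    def stage_simulate(self) -> None:
        from .simulate import write_dataset
        cfg = self.config.simulation
        if cfg.seed != self.config.seed:
            from dataclasses import replace
            cfg = replace(cfg, seed=self.config.seed)
        self.dataset = simulate_dataset(cfg)
        sim_dir = self.out / "simulated"
        write_dataset(self.dataset, sim_dir)
        _write_manifest(self.out, "simulate", self.config,
                        [p.name for p in sim_dir.iterdir()])

    def stage_normalize(self) -> None:
        distorted = distort_dataset(self.dataset)
        self.normalized, fits = normalize_cell_types(
            distorted, self.config.reference_cell_type,
            fdr=self.config.fdr, top_k=self.config.top_k)
        rows = [{"assay": f.assay, "target": f.target_cell_type,
                 "alpha": f.alpha, "beta": f.beta, "residual": f.residual}
                for f in fits]
        pd.DataFrame(rows).to_csv(self.out / "normalization_fits.tsv",
                                  sep="\t", index=False)
        _write_manifest(self.out, "normalize", self.config, ["normalization_fits.tsv"])

    def _windows(self, tracks) -> list:
        cfg = self.config.simulation
        out = []
        for ct in cfg.cell_types:
            per_assay = {assay: t for (c, assay), t in tracks.items() if c == ct}
            out.extend(windows_for_genes(per_assay, self.dataset.genes, cfg.context,
                                         assay_order=[a.name for a in cfg.assays],
                                         cell_type=ct))
        return out

    def stage_train(self) -> None:
        cfg = self.config
        windows = self._windows(self.normalized)
        split = SplitSpec(val=frozenset(cfg.val_chroms), test=frozenset(cfg.test_chroms))
        train, val, test, pp = build_dataset(
            windows, self.dataset.expression, self.dataset.genes, split,
            holdout_cell_type=cfg.holdout_cell_type)
        hyper = CNNHyperparams(lr_schedule=cfg.lr_schedule)
        self.ensemble = train_ensemble(
            cfg.model_kind, train, val, pp, n_replicates=cfg.n_replicates,
            base_seed=cfg.seed, hyper=hyper,
            split_description=f"val={sorted(cfg.val_chroms)} test={sorted(cfg.test_chroms)}")
        self.splits = (train, val, test)
        logger.info("split sizes: train=%d val=%d test=%d", len(train), len(val), len(test))
        pred = predict_ensemble(self.ensemble, test.X)
        res = evaluate(pred, test.y, "pooled")
        pd.DataFrame([{"heldout_spearman": res["spearman"], "n_test": res["n"]}]
                     ).to_csv(self.out / "train_metrics.tsv", sep="\t", index=False)
        _write_manifest(self.out, "train", self.config, ["train_metrics.tsv"])

    def stage_evaluate(self) -> None:
        cfg = self.config
        train, val, test = self.splits
        pred = predict_ensemble(self.ensemble, test.X)
        pooled = evaluate(pred, test.y, "pooled")
        rows = [{"metric": "pooled_spearman", "value": pooled["spearman"]}]
        try:
            per_gene = evaluate(pred, test.y, "per_gene_across_cell_types", test.keys)
            rows.append({"metric": "per_gene_median_spearman", "value": per_gene["median"]})
        except Exception as err:          # too few cell types, e.g.
            logger.warning("per-gene evaluation unavailable: %s", err)
        pd.DataFrame(rows).to_csv(self.out / "evaluation.tsv", sep="\t", index=False)

        # metagene profiles of the activating TSS mark in the reference cell type
        sim = cfg.simulation
        ct = cfg.reference_cell_type
        per_assay = self.dataset.assay_tracks(ct)
        windows = windows_for_genes(per_assay, self.dataset.genes, sim.context,
                                    assay_order=[a.name for a in sim.assays],
                                    cell_type=ct)
        profs = metagene(windows, self.dataset.expression[ct], sim.tss_assay)
        pd.DataFrame({p.quantile: p.profile for p in profs}).to_csv(
            self.out / "metagene.tsv", sep="\t", index_label="bin")
        _write_manifest(self.out, "evaluate", self.config,
                        ["evaluation.tsv", "metagene.tsv"])

    def stage_attribute(self) -> None:
        cfg = self.config
        train, _, _ = self.splits
        windows = self._windows(self.normalized)
        train_keys = set(zip(train.keys.gene_id, train.keys.cell_type))
        pool = [w for w in windows if (w.gene_id, w.cell_type) in train_keys]
        chosen = sample_genes(pool, cfg.attr_n_genes, cfg.seed)
        spec = AttributionSpec(cfg.attribution_assay, cfg.lambda0,
                               cfg.attr_halfwidth, cfg.attr_n_genes)
        prof = attribution_profile(self.ensemble, chosen, spec)
        pd.DataFrame({"offset_bp": prof.offsets_bp,
                      "mean_fold_change": prof.fold_change,
                      "sd": prof.sd}).to_csv(self.out / "attribution.tsv",
                                             sep="\t", index=False)
        _write_manifest(self.out, "attribute", self.config, ["attribution.tsv"])

    def stage_perturb(self) -> None:
        cfg = self.config
        sim = cfg.simulation
        ct = cfg.reference_cell_type
        rng = np.random.default_rng(cfg.seed)
        # editing targets must be measurably expressed: the fold-change
        # denominator is their predicted endogenous TPM
        tpm = self.dataset.expression[ct]
        pool = [g for g in self.dataset.genes if tpm[g.gene_id] >= 1.0]
        if not pool:
            raise PipelineError("no expressed genes to target")
        genes = [pool[i] for i in
                 sorted(rng.choice(len(pool), size=min(8, len(pool)), replace=False))]
        per_assay = {assay: t for (c, assay), t in self.normalized.items() if c == ct}
        items = []
        for g in genes:
            window = windows_for_genes(per_assay, [g], sim.context,
                                       assay_order=[a.name for a in sim.assays],
                                       cell_type=ct)[0]
            m = MNaseVector.from_track(self.dataset.mnase[ct], g, sim.context)
            spec = PerturbationSpec(g.gene_id, sim.W // 2, cfg.sigma_grid[0],
                                    cfg.lam_grid[0])
            items.append((window, m, spec))
        table = sweep_parameters(self.ensemble, items, cfg.sigma_grid, cfg.lam_grid,
                                 h3k27ac_assay=sim.tss_assay)
        table.to_csv(self.out / "perturbation_sweep.tsv", sep="\t", index=False)
        _write_manifest(self.out, "perturb", self.config, ["perturbation_sweep.tsv"])


def run_pipeline(config: RunConfig, stages: list[str] | None = None) -> PipelineRun:
    run = PipelineRun(config)
    run.run(list(stages) if stages else list(STAGES))
    return run
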