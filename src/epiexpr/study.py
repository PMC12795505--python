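"""Desk-scale study protocols: the canonical synthetic experiments the
package's headline properties are measured on.

Each function sets up one experiment — generate data with the generator's
default study conditions, run the relevant pipeline stage, measure — and
returns plain numbers.  The scaled-down study conditions are: W = 101 bins
(2,500 bp context at 25 bp), four cell types, 1,000 genes, two expression-
coupled marks (H3K27ac at the TSS, H3K36me3 over the gene body) plus one
decoy mark, CNN ensembles of 3 replicates trained for 15 epochs
(10 at lr 0.001 + 5 at 0.0005).

Models are trained on *normalized* tracks, as in the real pipeline: even
without batch distortion the tracks pass through peak calling and the
add-1/divide + scale-power matching against the reference cell type.  For
the reference cell type that map is exactly affine, x ↦ (1 + x)/denom, so
generator-scale quantities (the dCas9-p300 deposit in particular) convert
to the normalized feature scale by dividing by the stored reference
denominator.  The uncoupled control study trains on raw tracks instead:
signal-free noise tracks have no peaks, leaving the peak-matching step
undefined — and the control's point is only that no relationship is
recoverable, which no rescaling can change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .attribution import AttributionSpec, attribution_profile, sample_genes
from .evaluation import metagene, rank_eval_across, rank_eval_within
from .models import (CNNHyperparams, Dataset, ModelEnsemble, PreprocessSpec,
                     SplitSpec, build_dataset, evaluate, predict_ensemble,
                     train_ensemble, train_ridge)
from .normalization import fit_s3norm, normalize_cell_types, transform_values
from .perturbation import MNaseVector, PerturbationSpec, predict_fold_change
from .simulate import (AssayConfig, SimulationConfig, distort_dataset,
                       simulate_dataset, simulate_perturbation_truth)
from .track_io import windows_for_genes

STUDY_ASSAYS = (AssayConfig("H3K27ac", "activating_tss", 2.5),
                AssayConfig("H3K36me3", "activating_body", 2.0),
                AssayConfig("control", "decoy", 2.5))

STUDY_SPLIT = SplitSpec(val=frozenset({"chr3"}), test=frozenset({"chr4"}))

STUDY_HYPER = CNNHyperparams(lr_schedule=((0.001, 10), (0.0005, 5)))


@dataclass
class Study:
    """One simulated study: dataset, normalized windows, chromosome splits."""

    config: SimulationConfig
    dataset: object
    windows: list                 # per-(gene, cell type), normalized scale
    train: Dataset
    val: Dataset
    test: Dataset
    preprocess: PreprocessSpec
    ref_denom: float = 1.0        # add-1/divide denominator of the reference
    #                               cell type's activating mark


def make_study(seed: int, *, coupled: bool = True,
               n_genes: int = 1000) -> Study:
    """Simulate the scaled-down study dataset, normalize, and build splits.

    ``coupled=False`` zeroes every assay's coupling, leaving tracks that are
    pure noise with respect to expression (and skips normalization; see the
    module docstring).
    """
    assays = STUDY_ASSAYS if coupled else tuple(
        AssayConfig(a.name, a.role, 0.0) for a in STUDY_ASSAYS)
    cfg = SimulationConfig(seed=seed, assays=assays, n_genes=n_genes)
    ds = simulate_dataset(cfg)
    ref_denom = 1.0
    if coupled:
        tracks, fits = normalize_cell_types(ds.tracks, cfg.cell_types[0])
        ref_denom = next(f.denominators[0] for f in fits if f.assay == cfg.tss_assay)
    else:
        tracks = ds.tracks
    windows = []
    for ct in cfg.cell_types:
        per_assay = {a: t for (c, a), t in tracks.items() if c == ct}
        windows += windows_for_genes(per_assay, ds.genes, cfg.context,
                                     assay_order=[a.name for a in cfg.assays],
                                     cell_type=ct)
    train, val, test, pp = build_dataset(windows, ds.expression, ds.genes,
                                         STUDY_SPLIT)
    return Study(cfg, ds, windows, train, val, test, pp, ref_denom)


#: replicate counts: 3 for the recovery evaluation, a 10-model pool for
#: attribution and editing predictions (scaling down 100-model averaging)
N_REPLICATES_RECOVERY = 3
N_REPLICATES_POOL = 10


def train_study_cnn(study: Study, base_seed: int,
                    n_replicates: int = N_REPLICATES_RECOVERY) -> ModelEnsemble:
    return train_ensemble("cnn", study.train, study.val, study.preprocess,
                          n_replicates=n_replicates, base_seed=base_seed,
                          hyper=STUDY_HYPER,
                          split_description="val={chr3} test={chr4}")


def subset_ensemble(ensemble: ModelEnsemble, n: int) -> ModelEnsemble:
    """The ensemble restricted to its first n replicates."""
    return ModelEnsemble(ensemble.model_kind, ensemble.replicates[:n],
                         ensemble.preprocess, ensemble.split_description)


def heldout_spearman(study: Study, ensemble: ModelEnsemble) -> float:
    pred = predict_ensemble(ensemble, study.test.X)
    return evaluate(pred, study.test.y, "pooled")["spearman"]


# ---------------------------------------------------------------------------
# Normalization checks
# ---------------------------------------------------------------------------

def random_pair_residuals(n_pairs: int, seed: int) -> np.ndarray:
    """Max mean-matching log-residual over ``n_pairs`` random ref/target
    pairs: reference peak/background vectors drawn lognormal with peaks
    above background, target a jittered scale-and-power distortion of the
    reference."""
    rng = np.random.default_rng(seed)
    residuals = np.empty(n_pairs)
    for i in range(n_pairs):
        ref_pk = rng.lognormal(2.0, 0.5, 200) + 2.0
        ref_bg = rng.lognormal(0.0, 0.3, 500)
        scale = rng.uniform(0.3, 3.0)
        power = rng.uniform(0.4, 2.5)
        tgt_pk = scale * ref_pk ** power * rng.lognormal(0.0, 0.05, ref_pk.size)
        tgt_bg = scale * ref_bg ** power * rng.lognormal(0.0, 0.05, ref_bg.size)
        denom_r = float(min(ref_pk.min(), ref_bg.min()))
        denom_t = float(min(tgt_pk.min(), tgt_bg.min()))
        _, _, res = fit_s3norm(transform_values(ref_pk, denom_r),
                               transform_values(ref_bg, denom_r, clamp_at_zero=True),
                               transform_values(tgt_pk, denom_t),
                               transform_values(tgt_bg, denom_t, clamp_at_zero=True))
        residuals[i] = res
    return residuals


def squared_target_fit() -> tuple[float, float]:
    """(α, β) for the constructed target-equals-reference-squared pair;
    the exact solution is (1, 0.5)."""
    alpha, beta, _ = fit_s3norm(np.array([2.0, 4.0]), np.array([1.0, 1.5]),
                                np.array([4.0, 16.0]), np.array([1.0, 2.25]))
    return alpha, beta


def batch_removal_correlations(seed: int) -> pd.DataFrame:
    """Raw vs normalized cross-cell-type metagene profile correlations.

    Each cell type's PTM tracks are distorted with its known (scale, power),
    then normalized back against the reference; the top-expression-quantile
    H3K27ac metagene profile of each non-reference cell type is correlated
    with the reference's.
    """
    cfg = SimulationConfig(seed=seed)
    ds = simulate_dataset(cfg)
    distorted = distort_dataset(ds)
    normed, fits = normalize_cell_types(distorted, "cell_type_0")

    def top_profile(tracks, ct):
        per = {a: t for (c, a), t in tracks.items() if c == ct}
        ws = windows_for_genes(per, ds.genes, cfg.context,
                               assay_order=[a.name for a in cfg.assays],
                               cell_type=ct)
        return metagene(ws, ds.expression[ct], cfg.tss_assay)[3].profile

    ref_raw = top_profile(distorted, "cell_type_0")
    ref_norm = top_profile(normed, "cell_type_0")
    rows = []
    for ct in cfg.cell_types[1:]:
        rows.append({
            "cell_type": ct,
            "raw_corr": float(np.corrcoef(ref_raw, top_profile(distorted, ct))[0, 1]),
            "normalized_corr": float(np.corrcoef(ref_norm, top_profile(normed, ct))[0, 1]),
            "fit_residual": max(f.residual for f in fits if f.target_cell_type == ct),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Ridge oracle
# ---------------------------------------------------------------------------

def ridge_closed_form(X: np.ndarray, y: np.ndarray, lam: float) -> tuple[np.ndarray, float]:
    """Regularized normal equations with unpenalized intercept (centering)."""
    xm, ym = X.mean(axis=0), y.mean()
    Xc, yc = X - xm, y - ym
    w = np.linalg.solve(Xc.T @ Xc + lam * np.eye(X.shape[1]), Xc.T @ yc)
    return w, float(ym - xm @ w)


def ridge_oracle_max_diff(n_instances: int, seed: int) -> float:
    """Largest |coefficient difference| between the fitted ridge and the
    closed-form solution over random small instances."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n, p = int(rng.integers(10, 30)), int(rng.integers(3, 8))
        X = rng.normal(size=(n, p))
        y = rng.normal(size=n)
        lam = float(rng.uniform(0.01, 10.0))
        ds = Dataset(X[:, None, :], y, pd.DataFrame({"gene_id": [str(i) for i in range(n)],
                                                     "cell_type": "ct", "chrom": "chr1"}))
        fitted = train_ridge(ds, None, penalty_grid=[lam])
        w, b = ridge_closed_form(X, y, lam)
        worst = max(worst,
                    float(np.max(np.abs(fitted.model.coef_ - w))),
                    abs(float(fitted.model.intercept_) - b))
    return worst


# ---------------------------------------------------------------------------
# Attribution / perturbation protocols
# ---------------------------------------------------------------------------

def attribution_profiles(study: Study, ensemble: ModelEnsemble, *,
                         n_genes: int = 200, seed: int = 7) -> dict:
    """Activating-mark and decoy-mark fold-change profiles over training genes."""
    train_keys = set(zip(study.train.keys.gene_id, study.train.keys.cell_type))
    pool = [w for w in study.windows if (w.gene_id, w.cell_type) in train_keys]
    chosen = sample_genes(pool, n_genes, seed)
    act = attribution_profile(ensemble, chosen,
                              AttributionSpec("H3K27ac", n_genes=n_genes))
    dec = attribution_profile(ensemble, chosen,
                              AttributionSpec("control", n_genes=n_genes))
    return {"activating": act, "decoy": dec}


#: gRNA offsets from the TSS (bins) used by the editing protocol
E2E_OFFSETS = (-30, -10, 0, 10, 30)
E2E_SIGMA = 500.0     # bp
E2E_LAM = 6.0         # generator signal units; gives few-fold truth changes
E2E_MIN_TPM = 1.0     # target genes must be measurably expressed


def end_to_end_rank_recovery(study: Study, ensemble: ModelEnsemble, *,
                             n_genes: int = 8, seed: int = 5) -> dict:
    """Predicted vs generator-truth fold-changes, 8 genes × 5 gRNAs.

    Target genes are drawn from training chromosomes of the reference cell
    type, restricted to measurably expressed genes (TPM ≥ 1, as editing
    targets would be chosen in practice); each receives one gRNA at each
    offset of :data:`E2E_OFFSETS`.  The overall dCas9-p300 strength λ is
    fixed on the generator's signal scale and converted to the normalized
    feature scale through the reference denominator (the reference cell
    type's normalization map is affine).  Returns the pooled across-gene
    Spearman and the within-gene median.
    """
    cfg, ds = study.config, study.dataset
    ct = cfg.cell_types[0]
    tpm = ds.expression[ct]
    pool = [g for g in ds.genes
            if g.chrom in ("chr1", "chr2") and tpm[g.gene_id] >= E2E_MIN_TPM]
    rng = np.random.default_rng(seed)
    genes = [pool[i] for i in sorted(rng.choice(len(pool), n_genes, replace=False))]

    specs = [PerturbationSpec(g.gene_id, cfg.W // 2 + off, E2E_SIGMA, E2E_LAM)
             for g in genes for off in E2E_OFFSETS]
    truth_tab = simulate_perturbation_truth(ds, specs, ct)
    idx = pd.MultiIndex.from_tuples(
        [(r.gene_id, r.grna_bin) for r in truth_tab.itertuples()])
    truth = pd.Series(truth_tab.fold_change.to_numpy(), index=idx)

    lam_norm = E2E_LAM / study.ref_denom
    window_of = {(w.gene_id, w.cell_type): w for w in study.windows}
    preds = {}
    for g in genes:
        w = window_of[(g.gene_id, ct)]
        m = MNaseVector.from_track(ds.mnase[ct], g, cfg.context)
        for off in E2E_OFFSETS:
            spec = PerturbationSpec(g.gene_id, cfg.W // 2 + off, E2E_SIGMA, lam_norm)
            preds[(g.gene_id, spec.grna_bin)] = predict_fold_change(
                ensemble, w, m, spec, cfg.tss_assay)
    pred = pd.Series(preds)

    across_rho, table = rank_eval_across(pred, truth)
    groups = pd.Series([k[0] for k in pred.index], index=pred.index)
    per_gene, within_median = rank_eval_within(pred, truth, groups)
    return {"across_rho": float(across_rho), "within_median": float(within_median),
            "per_gene": per_gene, "table": table}


def metagene_tss_means(study: Study) -> np.ndarray:
    """TSS-bin mean activating-mark signal per expression quantile (low→high)."""
    cfg, ds = study.config, study.dataset
    ct = cfg.cell_types[0]
    ws = [w for w in study.windows if w.cell_type == ct]
    profs = metagene(ws, ds.expression[ct], cfg.tss_assay)
    return np.array([p.profile[p.profile.size // 2] for p in profs])
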