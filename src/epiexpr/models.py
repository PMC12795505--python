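"""Ridge and CNN models mapping TSS-centered PTM windows to log-expression.

One training sample is a (gene, cell type) pair: the feature is the gene's
W-bin × A-assay window of normalized −log10(p) signal in that cell type,
log(1+x)-transformed; the target is log(1+TPM).  Samples are pooled across
cell types and split into train/validation/test by the gene's chromosome,
so test genes are never seen during training; a whole cell type can
additionally be held out to probe cross-cell-type generalization.

Predictions are ensembled by arithmetic mean over computational replicates
that differ only in their seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Ridge

from . import nn
from .track_io import FeatureWindow, GeneAnnotation

logger = logging.getLogger(__name__)


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class PreprocessSpec:
    """The feature/target transforms a model was trained with.

    Both transforms are log(1+x): strictly monotone and defined at the
    abundant zeros of both −log10(p) tracks and TPM tables.
    """

    W: int
    assay_order: tuple[str, ...]
    feature_transform: str = "log1p"
    target_transform: str = "log1p"

    def features(self, windows: Sequence[FeatureWindow]) -> np.ndarray:
        """Stack windows into a transformed (N, A, W) array."""
        X = np.empty((len(windows), len(self.assay_order), self.W))
        for i, w in enumerate(windows):
            if w.W != self.W or tuple(w.assays) != self.assay_order:
                raise ModelError(
                    f"window {w.gene_id} (W={w.W}, assays={w.assays}) does not "
                    f"match preprocess spec (W={self.W}, assays={list(self.assay_order)})")
            X[i] = w.E.T
        return np.log1p(X)

    def target(self, tpm: np.ndarray) -> np.ndarray:
        return np.log1p(np.asarray(tpm, dtype=float))

    def inverse_target(self, y: np.ndarray) -> np.ndarray:
        return np.expm1(np.asarray(y, dtype=float))


def fold_change_from_predictions(base_pred: np.ndarray, pert_pred: np.ndarray,
                                 space: str = "pseudocount",
                                 denom_floor: float = 0.1,
                                 eps: float = 1e-6) -> np.ndarray:
    """Expression fold-change between two predictions in log(1+TPM) space.

    ``pseudocount`` (default): exp(Δprediction), the ratio of predicted
    (1 + TPM).  This coincides with the TPM ratio for expressed genes and
    stays defined and stable for silent ones.  ``tpm``: the plain ratio of
    expm1(prediction); near-silent genes amplify prediction noise by
    ~1/TPM there, so entries whose endogenous predicted TPM falls below
    ``denom_floor`` are NaN (callers exclude or raise), and numerators are
    clipped to the valid TPM range [eps, ∞).
    """
    base_pred = np.asarray(base_pred, dtype=float)
    pert_pred = np.asarray(pert_pred, dtype=float)
    if space == "pseudocount":
        return np.exp(pert_pred - base_pred)
    if space == "tpm":
        denom = np.expm1(base_pred)
        num = np.maximum(np.expm1(pert_pred), eps)
        out = np.where(denom >= denom_floor, num / np.maximum(denom, eps), np.nan)
        return out
    raise ModelError(f"unknown fold-change space {space!r}")


@dataclass(frozen=True)
class SplitSpec:
    """Held-out chromosome sets; train defaults to every other chromosome."""

    val: frozenset[str] = frozenset({"chr7"})
    test: frozenset[str] = frozenset({"chr8", "chr9"})
    train: frozenset[str] | None = None

    def __post_init__(self) -> None:
        sets = [self.val, self.test] + ([self.train] if self.train is not None else [])
        for i, a in enumerate(sets):
            for b in sets[i + 1:]:
                if a & b:
                    raise ModelError(f"split chromosome sets overlap: {sorted(a & b)}")

    def assign(self, chrom: str) -> str:
        if chrom in self.val:
            return "val"
        if chrom in self.test:
            return "test"
        if self.train is None or chrom in self.train:
            return "train"
        raise ModelError(f"chromosome {chrom} is on no split set")


@dataclass
class Dataset:
    """Preprocessed samples: X (N, A, W), y (N,), and their (gene, cell type) keys."""

    X: np.ndarray
    y: np.ndarray
    keys: pd.DataFrame   # columns: gene_id, cell_type, chrom

    def __len__(self) -> int:
        return self.X.shape[0]


def build_dataset(windows: Sequence[FeatureWindow], tpm: pd.DataFrame,
                  genes: Sequence[GeneAnnotation], split: SplitSpec,
                  *, holdout_cell_type: str | None = None,
                  preprocess: PreprocessSpec | None = None,
                  ) -> tuple[Dataset, Dataset, Dataset, PreprocessSpec]:
    """Assemble train/val/test datasets from per-(gene, cell type) windows.

    Samples land in train/val/test by their gene's chromosome; a held-out
    cell type contributes no train or val samples and is routed to test.
    """
    if not windows:
        raise ModelError("no windows supplied")
    chrom_of = {g.gene_id: g.chrom for g in genes}
    if preprocess is None:
        preprocess = PreprocessSpec(W=windows[0].W, assay_order=tuple(windows[0].assays))

    rows: dict[str, list[int]] = {"train": [], "val": [], "test": []}
    keys = []
    targets = np.empty(len(windows))
    for i, w in enumerate(windows):
        if w.gene_id not in chrom_of:
            raise ModelError(f"window gene {w.gene_id} missing from annotation")
        if w.gene_id not in tpm.index or w.cell_type not in tpm.columns:
            raise ModelError(f"no TPM entry for ({w.gene_id}, {w.cell_type})")
        targets[i] = tpm.at[w.gene_id, w.cell_type]
        part = split.assign(chrom_of[w.gene_id])
        if holdout_cell_type is not None and w.cell_type == holdout_cell_type:
            part = "test"
        rows[part].append(i)
        keys.append((w.gene_id, w.cell_type, chrom_of[w.gene_id]))

    if not rows["train"]:
        raise ModelError("empty training set")
    X = preprocess.features(windows)
    y = preprocess.target(targets)
    key_df = pd.DataFrame(keys, columns=["gene_id", "cell_type", "chrom"])

    def subset(idx: list[int]) -> Dataset:
        idx = np.asarray(idx, dtype=int)
        return Dataset(X[idx], y[idx], key_df.iloc[idx].reset_index(drop=True))

    return subset(rows["train"]), subset(rows["val"]), subset(rows["test"]), preprocess


# ---------------------------------------------------------------------------
# Ridge
# ---------------------------------------------------------------------------

@dataclass
class RidgeModel:
    model: Ridge
    penalty: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict(X.reshape(X.shape[0], -1))


DEFAULT_PENALTY_GRID = tuple(np.logspace(-2, 4, 13))


def train_ridge(train: Dataset, val: Dataset | None = None,
                penalty_grid: Iterable[float] = DEFAULT_PENALTY_GRID) -> RidgeModel:
    """Ridge regression on flattened windows; penalty chosen by validation MSE.

    The intercept is unpenalized (sklearn's convention).  Without a
    validation set the smallest grid penalty is used.
    """
    Xf = train.X.reshape(len(train), -1)
    if len(train) < 2:
        raise ModelError("ridge needs at least 2 training samples")
    if not np.any(Xf):
        raise ModelError("degenerate all-zero feature matrix")
    grid = sorted(penalty_grid)
    if not grid:
        raise ModelError("empty penalty grid")

    best, best_mse = None, np.inf
    for lam in grid:
        m = Ridge(alpha=lam).fit(Xf, train.y)
        if val is None or len(val) == 0:
            best = RidgeModel(m, lam)
            break
        mse = float(np.mean((m.predict(val.X.reshape(len(val), -1)) - val.y) ** 2))
        if mse < best_mse:
            best, best_mse = RidgeModel(m, lam), mse
    logger.info("ridge penalty selected: %g", best.penalty)
    return best


# ---------------------------------------------------------------------------
# CNN
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CNNHyperparams:
    n_blocks: int = 5
    kernels_per_block: int = 32
    kernel_width: int = 5
    dropout: float = 0.1
    pool_type: str = "avg"          # "avg" or "max"
    pool_size: int = 2
    fc_units: int = 16
    lr_schedule: tuple[tuple[float, int], ...] = ((0.001, 50), (0.0005, 50))
    batch_size: int = 64

    def __post_init__(self) -> None:
        if min(self.n_blocks, self.kernels_per_block, self.kernel_width,
               self.pool_size, self.fc_units, self.batch_size) < 1:
            raise ModelError("all CNN hyperparameter counts must be positive")
        if any(n < 1 for _, n in self.lr_schedule):
            raise ModelError("each learning-rate phase needs >= 1 epoch")

    @property
    def epochs(self) -> int:
        return sum(n for _, n in self.lr_schedule)


def _build_cnn(n_assays: int, W: int, hyper: CNNHyperparams,
               init_rng: np.random.Generator,
               dropout_rng: np.random.Generator) -> nn.Sequential:
    if hyper.pool_type == "max":
        pool_cls = nn.MaxPool1D
    elif hyper.pool_type == "avg":
        pool_cls = nn.AvgPool1D
    else:
        raise ModelError(f"unknown pool type {hyper.pool_type!r}")
    layers: list[nn.Layer] = []
    c, w = n_assays, W
    for _ in range(hyper.n_blocks):
        layers += [nn.BatchNorm1D(c), nn.ReLU(),
                   nn.Conv1D(c, hyper.kernels_per_block, hyper.kernel_width, init_rng),
                   nn.Dropout(hyper.dropout, dropout_rng),
                   pool_cls(hyper.pool_size)]
        c = hyper.kernels_per_block
        w = w // hyper.pool_size
        if w < 1:
            raise ModelError(f"W={W} too small for {hyper.n_blocks} pooling stages")
    layers += [nn.Flatten(), nn.Dense(c * w, hyper.fc_units, init_rng), nn.ReLU(),
               nn.Dense(hyper.fc_units, 1, init_rng)]
    return nn.Sequential(layers)


@dataclass
class CNNModel:
    net: nn.Sequential
    hyper: CNNHyperparams
    seed: int
    history: pd.DataFrame = field(default_factory=pd.DataFrame)

    def predict(self, X: np.ndarray, batch_size: int = 512) -> np.ndarray:
        out = [self.net.forward(X[i:i + batch_size], training=False)[:, 0]
               for i in range(0, X.shape[0], batch_size)]
        return np.concatenate(out) if out else np.empty(0)


def train_cnn(train: Dataset, val: Dataset | None, hyper: CNNHyperparams,
              seed: int) -> CNNModel:
    """Train the CNN with MSE/Adam and the two-phase learning-rate schedule.

    Deterministic given the seed: initialization, dropout masks and batch
    shuffling all derive from one generator.
    """
    if hyper.pool_size ** hyper.n_blocks > train.X.shape[2]:
        raise ModelError(f"W={train.X.shape[2]} < pool^blocks="
                         f"{hyper.pool_size ** hyper.n_blocks}")
    init_rng, drop_rng, shuffle_rng = np.random.default_rng(seed).spawn(3)
    net = _build_cnn(train.X.shape[1], train.X.shape[2], hyper, init_rng, drop_rng)
    opt = nn.Adam(net)

    y = train.y[:, None]
    shell = CNNModel(net, hyper, seed)
    initial_loss = float(np.mean((shell.predict(train.X) - train.y) ** 2))
    records = []
    for lr, n_epochs in hyper.lr_schedule:
        opt.lr = lr
        for _ in range(n_epochs):
            order = shuffle_rng.permutation(len(train))
            losses = []
            for i in range(0, len(order), hyper.batch_size):
                idx = order[i:i + hyper.batch_size]
                pred = net.forward(train.X[idx], training=True)
                loss, dpred = nn.mse_loss(pred, y[idx])
                if not np.isfinite(loss):
                    raise ModelError("non-finite training loss")
                net.backward(dpred)
                opt.step()
                losses.append(loss)
            rec = {"lr": lr, "train_loss": float(np.mean(losses))}
            if val is not None and len(val):
                vp = CNNModel(net, hyper, seed).predict(val.X)
                rec["val_loss"] = float(np.mean((vp - val.y) ** 2))
            records.append(rec)
    history = pd.DataFrame(records)
    history.index.name = "epoch"
    history.attrs["initial_train_loss"] = initial_loss
    if history["train_loss"].iloc[-1] >= initial_loss:
        raise ModelError("training did not reduce the loss")
    return CNNModel(net, hyper, seed, history)


# ---------------------------------------------------------------------------
# Ensembling and evaluation
# ---------------------------------------------------------------------------

@dataclass
class ModelEnsemble:
    model_kind: str                      # "ridge" or "cnn"
    replicates: list
    preprocess: PreprocessSpec
    split_description: str = ""

    def __post_init__(self) -> None:
        if not self.replicates:
            raise ModelError("ensemble needs at least one replicate")

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.mean([m.predict(X) for m in self.replicates], axis=0)


def train_ensemble(model_kind: str, train: Dataset, val: Dataset | None,
                   preprocess: PreprocessSpec, *, n_replicates: int = 3,
                   base_seed: int = 0, hyper: CNNHyperparams | None = None,
                   penalty_grid: Iterable[float] = DEFAULT_PENALTY_GRID,
                   split_description: str = "") -> ModelEnsemble:
    """Train ``n_replicates`` models differing only by seed = base_seed + i."""
    reps: list = []
    for i in range(n_replicates):
        if model_kind == "cnn":
            reps.append(train_cnn(train, val, hyper or CNNHyperparams(), base_seed + i))
        elif model_kind == "ridge":
            reps.append(train_ridge(train, val, penalty_grid))
        else:
            raise ModelError(f"unknown model kind {model_kind!r}")
    return ModelEnsemble(model_kind, reps, preprocess, split_description)


def predict_ensemble(ensemble: ModelEnsemble,
                     windows: Sequence[FeatureWindow] | np.ndarray) -> np.ndarray:
    """Ensemble-mean predictions in target-transform (log1p TPM) space.

    Accepts raw windows (transformed here with the ensemble's own
    PreprocessSpec) or an already-transformed (N, A, W) array.
    """
    if isinstance(windows, np.ndarray):
        X = windows
        expected = (len(ensemble.preprocess.assay_order), ensemble.preprocess.W)
        if X.ndim != 3 or X.shape[1:] != expected:
            raise ModelError(f"feature array {X.shape} does not match "
                             f"preprocess spec (N, {expected[0]}, {expected[1]})")
    else:
        X = ensemble.preprocess.features(windows)
    return ensemble.predict(X)


def evaluate(predictions: np.ndarray, truth: np.ndarray,
             mode: str = "pooled", keys: pd.DataFrame | None = None) -> dict:
    """Spearman evaluation of predictions against observed log-expression.

    ``pooled``: one rank correlation over all samples.
    ``per_gene_across_cell_types``: one correlation per gene across its cell
    types (groups with < 3 points are excluded and logged) plus the median.
    """
    predictions = np.asarray(predictions, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if predictions.shape != truth.shape:
        raise ModelError("prediction/truth length mismatch")
    if mode == "pooled":
        if len(truth) < 3:
            raise ModelError("need >= 3 points for a correlation")
        rho = stats.spearmanr(predictions, truth).statistic
        return {"mode": mode, "spearman": float(rho), "n": len(truth)}
    if mode == "per_gene_across_cell_types":
        if keys is None:
            raise ModelError("per-gene mode needs sample keys")
        rhos = {}
        for gene, idx in keys.groupby("gene_id").groups.items():
            idx = np.asarray(idx)
            if len(idx) < 3:
                logger.info("excluding gene %s: only %d cell types", gene, len(idx))
                continue
            t = truth[idx]
            if np.all(t == t[0]) or np.all(predictions[idx] == predictions[idx][0]):
                logger.info("excluding gene %s: constant values", gene)
                continue
            rhos[gene] = float(stats.spearmanr(predictions[idx], t).statistic)
        if not rhos:
            raise ModelError("no gene had enough points for a correlation")
        series = pd.Series(rhos, name="spearman")
        return {"mode": mode, "per_gene": series, "median": float(series.median()),
                "n_genes": len(series)}
    raise ModelError(f"unknown evaluation mode {mode!r}")
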