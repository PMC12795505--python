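"""Metagene quantile profiles and rank-based fold-change evaluations.

Metagene profiles average a mark's TSS-centered signal over genes grouped
into four expression quantiles within one cell type (silent, zero-TPM genes
included — they populate the bottom band).  Rank evaluations use the
convention that rank 1 is the highest numerical value, with average ranks
for ties.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .track_io import FeatureWindow

logger = logging.getLogger(__name__)

QUANTILE_LABELS = ("0-25%", "25-50%", "50-75%", "75-100%")


class EvaluationError(ValueError):
    pass


@dataclass
class MetageneProfile:
    assay: str
    cell_type: str
    quantile: str                  # one of QUANTILE_LABELS
    profile: np.ndarray            # per-bin mean signal, length W
    n_genes: int


def assign_quantiles(tpm: np.ndarray) -> np.ndarray:
    """Quantile index 0..3 per gene; boundary ties go to the lower quantile."""
    tpm = np.asarray(tpm, dtype=float)
    t25, t50, t75 = np.percentile(tpm, [25, 50, 75])
    return (tpm > t25).astype(int) + (tpm > t50) + (tpm > t75)


def metagene(windows: list[FeatureWindow], tpm: pd.Series | np.ndarray,
             assay: str) -> list[MetageneProfile]:
    """Per-bin mean signal of one assay within each expression quantile.

    ``tpm`` gives one value per window (same cell type).  Requires >= 4
    genes; a quantile emptied by extreme ties yields an all-NaN profile with
    a warning.
    """
    if len(windows) < 4:
        raise EvaluationError(f"metagene needs >= 4 genes, got {len(windows)}")
    if isinstance(tpm, pd.Series):
        tpm = tpm.reindex([w.gene_id for w in windows]).to_numpy()
        if np.any(np.isnan(tpm)):
            raise EvaluationError("TPM missing for some windows")
    tpm = np.asarray(tpm, dtype=float)
    if tpm.size != len(windows):
        raise EvaluationError("one TPM value per window required")

    q = assign_quantiles(tpm)
    signal = np.stack([w.assay_column(assay) for w in windows])
    ct = windows[0].cell_type
    out = []
    for qi, label in enumerate(QUANTILE_LABELS):
        mask = q == qi
        if not mask.any():
            logger.warning("quantile %s is empty (heavy ties)", label)
            prof = np.full(signal.shape[1], np.nan)
        else:
            prof = signal[mask].mean(axis=0)
        out.append(MetageneProfile(assay, ct, label, prof, int(mask.sum())))
    return out


def ranks_highest_first(values: np.ndarray) -> np.ndarray:
    """Rank 1 = largest value; average ranks for ties."""
    return stats.rankdata(-np.asarray(values, dtype=float), method="average")


def rank_eval_across(pred: pd.Series, truth: pd.Series) -> tuple[float, pd.DataFrame]:
    """Spearman ρ and the paired rank table over all items.

    ``pred`` and ``truth`` are keyed by item (e.g. (gene, gRNA)); keys are
    aligned by intersection.
    """
    pred, truth = pd.Series(pred), pd.Series(truth)
    common = pred.index.intersection(truth.index)
    if len(common) < 3:
        raise EvaluationError(f"need >= 3 shared items, got {len(common)}")
    p, t = pred.loc[common].to_numpy(float), truth.loc[common].to_numpy(float)
    if np.all(p == p[0]) or np.all(t == t[0]):
        raise EvaluationError("rank correlation undefined for a constant vector")
    rho = float(stats.spearmanr(p, t).statistic)
    table = pd.DataFrame({"pred": p, "truth": t,
                          "pred_rank": ranks_highest_first(p),
                          "truth_rank": ranks_highest_first(t)}, index=common)
    return rho, table


def rank_eval_within(pred: pd.Series, truth: pd.Series,
                     groups: pd.Series) -> tuple[pd.Series, float]:
    """Per-group (per-gene) rank correlation and the median across groups.

    Groups with < 3 items or constant values are excluded and logged; if
    every group is excluded, that is an error.
    """
    pred, truth, groups = pd.Series(pred), pd.Series(truth), pd.Series(groups)
    rhos = {}
    for g, idx in groups.groupby(groups).groups.items():
        try:
            rho, _ = rank_eval_across(pred.loc[idx], truth.loc[idx])
        except EvaluationError as err:
            logger.info("excluding group %s: %s", g, err)
            continue
        rhos[g] = rho
    if not rhos:
        raise EvaluationError("no group admitted a rank correlation")
    series = pd.Series(rhos, name="spearman")
    return series, float(series.median())
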