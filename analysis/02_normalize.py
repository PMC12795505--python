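#!/usr/bin/env python
"""Distort the simulated cell types with known batch effects and undo them.

Each non-reference cell type's PTM tracks are warped by its (scale, power)
batch distortion, then normalized back against the reference by peak/
background mean matching.  Reports the fitted (α, β) per track and the
cross-cell-type metagene profile correlations before and after.
"""

import argparse
from pathlib import Path

import pandas as pd

from epiexpr.study import batch_removal_correlations
from epiexpr.normalization import normalize_cell_types
from epiexpr.simulate import SimulationConfig, distort_dataset, simulate_dataset


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=11)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cfg = SimulationConfig(seed=args.seed)
    ds = simulate_dataset(cfg)
    distorted = distort_dataset(ds)
    _, fits = normalize_cell_types(distorted, "cell_type_0")
    fit_tab = pd.DataFrame([{"assay": f.assay, "target": f.target_cell_type,
                             "alpha": f.alpha, "beta": f.beta,
                             "residual": f.residual} for f in fits])
    fit_tab.to_csv(args.out / "normalization_fits.tsv", sep="\t", index=False)
    print("fitted scale-power maps (mean-matching residual < 1e-6 everywhere):")
    print(fit_tab.to_string(index=False))

    corr = batch_removal_correlations(seed=args.seed)
    corr.to_csv(args.out / "batch_removal.tsv", sep="\t", index=False)
    print("\ncross-cell-type top-quantile metagene correlation, "
          "distorted vs normalized:")
    print(corr.to_string(index=False))
    print(f"\nwrote {args.out}/normalization_fits.tsv and batch_removal.tsv")


if __name__ == "__main__":
    main()
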