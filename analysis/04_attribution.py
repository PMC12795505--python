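#!/usr/bin/env python
"""Where in the window does the model believe each mark acts?

Adds a fixed signal increment (λ0 = 2500 normalized units over ±3 bins,
about one nucleosome) at every position in turn and records the predicted
expression fold-change, averaged over 200 training genes.  The activating
promoter mark should produce a sharp peak at the TSS; the decoy mark, which
carries no expression information by construction, should stay flat at 1.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from epiexpr.study import attribution_profiles, make_study, train_study_cnn


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=11)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    study = make_study(args.seed)
    ensemble = train_study_cnn(study, base_seed=args.seed + 89)
    profs = attribution_profiles(study, ensemble, seed=args.seed + 7)

    act, dec = profs["activating"], profs["decoy"]
    tab = pd.DataFrame({"offset_bp": act.offsets_bp,
                        "H3K27ac_fold_change": act.fold_change,
                        "H3K27ac_sd": act.sd,
                        "decoy_fold_change": dec.fold_change,
                        "decoy_sd": dec.sd})
    tab.to_csv(args.out / "attribution_profiles.tsv", sep="\t", index=False)

    jmax = int(np.argmax(act.fold_change))
    print(f"activating mark: peak fold-change "
          f"{act.fold_change[jmax]:.3f} at {act.offsets_bp[jmax]:+d} bp from TSS")
    print(f"decoy mark: fold-change stays in "
          f"[{dec.fold_change.min():.3f}, {dec.fold_change.max():.3f}]")
    print(f"wrote {args.out}/attribution_profiles.tsv")


if __name__ == "__main__":
    main()
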