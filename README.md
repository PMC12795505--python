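# epiexpr

Predicting gene expression from histone post-translational-modification
(PTM) tracks, and predicting the outcome of dCas9-p300 epigenome editing
*in silico*.

Histone marks around a gene's transcription start site (TSS) — activating
promoter acetylation such as H3K27ac, gene-body H3K36me3, repressive
H3K27me3 — carry enough information to predict that gene's expression.
`epiexpr` implements the full chain needed to exploit that:

1. **Track handling** — genome-wide −log10(p) ChIP-seq signal binned at
   25 bp, TSS-centered strand-oriented feature windows (bedGraph/BED6/TSV
   in and out).
2. **Cross-cell-type normalization** — an adapted S3norm: peak and
   background bins are matched between each cell type and a reference by a
   fitted scale-and-power map α·x^β, so that mean signal agrees on common
   peaks and on common background simultaneously.
3. **Expression models** — ridge regression and a five-block convolutional
   network (batch-norm → ReLU → conv(32, width 5) → dropout → pool; dense
   16 → 1) mapping log(1+signal) windows to log(1+TPM), ensembled over
   seeded replicates, evaluated on held-out chromosomes and held-out cell
   types.
4. **Attribution** — add a fixed increment λ0 to one mark at each position
   in turn and read out the predicted expression fold-change: where does
   the model think the mark acts?
5. **Editing model** — for a gRNA at bin j with nucleosome occupancy m,
   dCas9-p300 deposits H3K27ac as λ·exp(−5·m_j)·exp(−(i−j)²/2σ²)·m_i
   (steric hindrance × Gaussian locality × histone availability); the
   deposit is added to the window and the model re-predicts expression.
6. **Synthetic data** — a generator with known latent structure
   (activity-coupled marks, nucleosome-periodic MNase with a depleted
   region at the TSS, TPM from a known exponential link, per-cell-type
   batch distortions) so every stage is testable without external
   downloads, including ground-truth editing fold-changes.

Everything runs on plain numpy/scipy/pandas/scikit-learn; the CNN,
including reverse-mode gradients and Adam, is implemented in numpy and is
bit-reproducible given a seed.

See `docs/methods.md` for the models, assumptions, and numerical choices.

## Worked example

The numbered scripts under `analysis/` run the study end to end on
synthetic data (about ten minutes total, one CPU; tables land in
`results/`):

```sh
python analysis/01_simulate.py        # generate tracks/expression, summary
python analysis/02_normalize.py       # batch-distort and normalize back
python analysis/03_train_models.py    # ridge + CNN, held-out accuracy
python analysis/04_attribution.py     # per-position fold-change profiles
python analysis/05_perturbation.py    # dCas9-p300 predictions vs truth
```

`01_simulate.py` prints the generative coupling —

```
simulated 1000 genes x 4 cell types (W=101, bin 25 bp)
Spearman(latent activity, TPM) = 0.955; silent genes: 19.9%
quantile  n_genes  tss_mean_signal
   0-25%      250         2.125708
  25-50%      250         4.413234
  50-75%      250         6.083680
 75-100%      250         8.481155
```

— the activating mark's TSS signal rises monotonically across expression
quantiles, as metagene profiles of real promoter acetylation do.

`02_normalize.py` distorts each cell type with a known (scale, power)
batch effect and fits the normalization back against the reference; the
fitted maps satisfy both mean-matching equations to < 1e−6, and the
cross-cell-type metagene correlation returns from < 0.8 (distorted) to
> 0.99 (normalized).

`03_train_models.py` reports held-out-chromosome Spearman ρ ≈ 0.95 for the
CNN on coupled data and |ρ| < 0.1 for the identical recipe on an uncoupled
control, so the recovery is signal, not leakage. `04_attribution.py` shows
the model attributes expression to the activating mark specifically around
the TSS (peak fold-change ≈ 1.12 within ±100 bp) while a decoy mark stays
within ~3% of 1 everywhere. `05_perturbation.py` ranks predicted editing
fold-changes against the generator's ground truth across 8 genes × 5
gRNAs (across-gene ρ ≈ 0.95; the within-gene median is also reported).

A `click` CLI wraps the same stages for file-based runs:

```sh
epiexpr run --seed 11 --out-dir results/run \
    --stages simulate,normalize,train,evaluate,attribute,perturb
```

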