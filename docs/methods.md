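# Methods

`epiexpr` models gene expression as a function of local chromatin state and
uses that model to predict the outcome of targeted epigenome editing. This
note documents the models, the synthetic data they are validated on, and
the numerical choices, in enough detail to re-derive every pipeline stage.

## Signal representation and coordinates

All genome-wide signals are vectors of fixed-width bins (default 25 bp) per
chromosome, 0-based half-open. Histone PTM tracks hold −log10(p) enrichment
values (as produced by a peak caller on ChIP-seq data); MNase tracks hold
read coverage as a nucleosome-occupancy proxy. A gene's feature window is a
W × A matrix: W = context/bin_size + 1 bins centered on the TSS bin
(context 10,000 bp at 25 bp gives W = 401; the desk-scale default here is
2,500 bp, W = 101), by A assays in a fixed order. Minus-strand windows are
reversed so increasing index always means downstream of the TSS — the
orientation that makes gene-body marks (H3K36me3) directional. Genes whose
window would overrun a chromosome end are excluded rather than zero-padded,
to avoid fabricating signal.

## Cross-cell-type normalization

Tracks from different cell types carry batch distortions (inconsistent
depth and dynamic range). One cell type is fixed as reference; every other
cell type's track per assay is matched to it by a scale-and-power map
fitted on two bin sets:

* **Peaks** — experimental tracks: bins whose p = 10^(−value) passes
  Benjamini–Hochberg at FDR < 0.05, computed genome-wide per track;
  imputed tracks: the top-k (default 1000) most significant bins.
* **Common peaks / common background** — bins that are peaks (respectively
  background) in *both* cell types.

Values in the common sets are first transformed as (1 + x)/denom, where
denom is the minimum observed value over the union of common peaks and
common background for that cell type — floored at ε = 10⁻³, since −log10(p)
minima are typically exactly 0 (clipped background noise guarantees zero
bins here). The fit then finds α, β > 0 such that

    mean(T_peaks,ref) = mean(α · T_peaks,tgt^β)
    mean(T_bg,ref)    = mean(α · T_bg,tgt^β)

α is recovered in closed form from the peak equation given β, making that
equation hold exactly; β is found by Powell minimization of the squared log
residual of the background equation, followed by a Brent root polish when a
sign change brackets the optimum. A fit whose background log-residual
exceeds 10⁻⁶ is an error, not a silent degradation. The full target track
is then mapped by x ↦ α·((1+x)/denom)^β; the reference passes through the
same add-1/divide transform with α = β = 1, so all cell types end up on one
scale. Both maps are strictly monotone: within-track rank order is never
changed.

Note the ε floor sets the absolute scale of normalized tracks (values in
the thousands when background minima are 0). This is deliberate: all
downstream perturbation magnitudes (λ0, λ grids) are quoted on this
normalized scale.

## Expression models

One training sample is a (gene, cell type) pair: features are the window
values after log(1+x); the target is log(1+TPM). Samples pool across cell
types and split by the gene's chromosome (default here: validation chr3,
test chr4), so held-out genes are never seen in any cell type; a whole cell
type can additionally be held out to test cross-cell-type transfer.

* **Ridge** on flattened W·A features, penalty chosen by validation MSE
  over a log-spaced grid, intercept unpenalized. A closed-form
  normal-equations solution is kept as an independent cross-check in tests.
* **CNN**: five blocks of [batch-norm → ReLU → conv(32 kernels, width 5,
  same padding) → dropout 0.1 → pooling(2)], then flatten → dense(16,
  ReLU) → dense(1). MSE loss, Adam, learning rate 0.001 then 0.0005 in two
  phases (50 + 50 epochs at full scale; the desk-scale schedule is 10 + 5).
  The network is implemented in numpy with reverse-mode gradients; all
  randomness (He initialization, dropout masks, batch shuffling) flows from
  one seeded generator, so training is bit-reproducible on a fixed BLAS.

Pooling is **average** pooling. The architecture source says only "a
pooling layer"; we found max pooling makes attribution unreliable: under a
large localized feature increment, ReLU + max selection preferentially
propagates positive responses, so even an uninformative (decoy) channel
shows a systematically positive predicted fold-change. With average
pooling the decoy response is symmetric noise around 1 that ensemble
averaging cancels. Batch size (64) and initialization (He normal) are
config-exposed choices the architecture source does not state.

Predictions are ensembled by arithmetic mean over replicates differing only
in seed (base_seed + index). Ensembling in log space before any fold-change
ratio means replicate-specific attribution noise cancels; the mean-squared
error of the ensemble is never worse than the worst replicate (convexity).

## Feature attribution

To ask *where* a model believes a mark acts, a scalar λ0 = 2500 (normalized
units) is added to one assay's values at bins j−3..j+3 (≈150 bp, one
nucleosome) for each focal position j, before the log preprocessing.
Profiles average the fold-change over a seeded sample of training genes
(default 500 at full scale, 200 desk-scale).

**Fold-change space.** Predictions live in log(1+TPM); two ratio
definitions are supported. The default is the *pseudocount* ratio
exp(Δprediction) — the ratio of predicted (1+TPM) — which coincides with
the TPM ratio for expressed genes and is defined and stable for silent
ones. The plain TPM-space ratio expm1(perturbed)/expm1(endogenous) is
available behind `space="tpm"` (genes below a 0.1-TPM denominator floor
excluded, numerators clipped at 10⁻⁶); we found it unsuitable as a
default for gene-averaged profiles because a gene predicted near the floor
amplifies log-space prediction noise by roughly 1/TPM, letting a handful
of near-silent genes dominate the average.

## dCas9-p300 editing model

For a gRNA targeting bin j, the H3K27ac increment at bin i is

    deposit_i = λ · exp(−5·m_j) · exp(−(d_ij)² / 2σ²) · m_i

with m the MNase occupancy aligned to the window and d_ij the distance in
bp between bin centers. The three factors are: steric hindrance of dCas9 by
the nucleosome at the target site; Gaussian spreading of acetylation with
physical width σ; and gating by occupancy — no histone, no acetylation, so
the deposit is zero exactly where m is zero. m is window-max normalized to
[0, 1] by default so exp(−5·m_j) spans [e⁻⁵, 1] (raw-coverage mode is
retained behind config; the occupancy units in the hindrance exponent are
not canonically defined). The deposit is added to the H3K27ac row of the
window in normalized-track space and the fold-change compares the ensemble
prediction after/before (same fold-change spaces as attribution, same
pseudocount default). Default sweep grids: σ ∈ {250, 500,
1000, 2000} bp (acetylation spreading of at least ~1 kb is biologically
expected), λ ∈ {500, 1000, 2500, 5000} normalized units; the absolute λ
scale is not anchored by data, which is why it is swept.

gRNA genomic coordinates map to the window bin containing the protospacer
midpoint, with the offset sign flipped for minus-strand genes.

## Synthetic data generator

The generator replaces external ChIP-seq/RNA-seq inputs with data whose
generative structure is known exactly:

* **Latent activity** a_{g,c} = gene effect N(2, 1) + cell-type effect
  N(0, 0.3) + interaction N(0, 0.3), clipped at 0 — giving both across-gene
  and across-cell-type variation, matching the two evaluation axes.
* **Marks**: the activating TSS mark (H3K27ac analog) is coupling·a times a
  profile peaked at the TSS (Gaussian envelope, sd 400 bp) with ~200 bp
  nucleosome-period bumps; the gene-body mark rises only downstream of the
  TSS; the repressive mark scales with relu(a_high − a); the decoy mark
  uses an independent latent with the same marginal, so it carries no
  expression information. Truncated-Gaussian noise (sd 0.3, clipped at 0)
  keeps tracks valid nonnegative −log10(p)-like signals.
* **MNase**: 0.55 + 0.45·cos(2π·pos/200 bp) occupancy with random phase per
  (cell type, chromosome), a nucleosome-depleted region of randomized depth
  (0.70–0.95) and width (75–150 bp) carved around each TSS, plus small
  clipped noise. The per-gene NDR variation is what differentiates gRNA
  hindrance across genes.
* **Expression**: TPM = max(exp(b0 + b1·a + ε) − 1, 0) with (b0, b1) =
  (−1, 1) and ε ~ N(0, 0.3); the −1 offset produces genuinely silent genes
  (~15%).
* **Layout**: genes alternate across chromosomes chr1..chrN at fixed
  spacing with strands alternating, so held-out-chromosome splits are
  representative and strand handling is exercised everywhere.

**Signal amplitude.** Default mark couplings are 2.5 (H3K27ac), 2.0
(H3K36me3, H3K27me3), 2.5 (decoy), putting peak −log10(p) at roughly 5–12 —
realistic for moderate-depth ChIP-seq and comfortably callable by BH. This
scale was fixed jointly with the attribution constant: for the generator,
the *true* fold-change of a λ0 perturbation at the TSS has the closed form

    FC_true = exp(b1 · λ0·denom · Σ_{|i−j|≤3} p_i / (c · Σ p_i²))

(p the TSS profile, c the coupling, denom the normalization denominator).
With these defaults FC_true ≈ 1.38, i.e. the standard λ0 = 2500 probes the
few-fold regime rather than vanishing into the signal; a much larger
coupling would make the same λ0 undetectable by construction, telling us
nothing about any model.

**Batch distortion** (x ↦ scale·x^power per cell type) is applied as a
separate step so normalization can be tested against known parameters.
Default powers are sharpening (4.5–8 with mixed scales): powers below 1
compress −log10(p) toward 1 and destroy peak calling, which no
normalization could be expected to survive; sharpening powers reshape
metagene profiles strongly (cross-cell-type profile correlation drops below
0.8) while remaining invertible by the scale-power fit.

**Perturbation ground truth.** The generator owns a linear read-out
R(x) = Σ p_i x_i / (c·Σ p_i²) satisfying R(c·a·p) = a, i.e. a matched
filter for the noise-free activating profile. The truth fold-change of a
deposit d is exp(b1·R(d)) — the offset-free ratio of the expression link
before/after, independent of the gene's baseline. Because the reference
cell type's normalization map is affine, generator-scale deposits convert
exactly to the normalized feature scale by dividing by the reference
denominator; the end-to-end evaluation uses λ = 6 generator units
(≈ few-fold truth changes) and σ = 500 bp.

## Metagene and rank evaluations

Metagene profiles average a mark over genes within four expression
quantiles per cell type, zeros included (silent genes populate the bottom
band); boundary ties go to the lower quantile. Rank evaluations use rank 1
= highest value with average ranks for ties; across-item Spearman for
pooled comparisons, and per-gene Spearman with the median across genes for
within-gene comparisons. Fewer than 3 items, or a constant vector, makes a
correlation undefined — excluded and logged in grouped mode, an error when
nothing remains.

## Desk-scale study conditions

The validation study (see `epiexpr.study`) uses 1,000 genes × 4 cell
types, W = 101, two coupled marks + one decoy, CNN ensembles of 3
replicates × 15 epochs, trained on normalized tracks; attribution and
editing predictions average over a 10-replicate pool (scaling down the
100-model averaging used at full scale). The uncoupled control study
(zero couplings) trains on raw tracks: signal-free noise has no BH peaks,
so peak-matching normalization is undefined there — and the control's only
claim is that nothing is recoverable, which rescaling cannot change.

## What the synthetic validation does and does not show

Passing tests show the machinery is correct and self-consistent: the
normalization solves its equations and undoes known monotone distortions;
the models recover a planted monotone relationship between local chromatin
signal and expression and localize it correctly; the editing model's
deposit algebra is exact; and predicted fold-change rankings recover the
generator's truth when the generator's assumptions (local action, known
link) hold. They do not show that real chromatin obeys those assumptions:
real histone-PTM/expression coupling is neither monotone nor univariate,
real dCas9-p300 may act through mechanisms other than local acetylation,
and gRNA efficacy varies in ways the deposit model ignores. Accuracy
figures on synthetic data are therefore upper bounds under ideal
assumptions, not forecasts for ENCODE-scale data.

## Known limitations

* The numpy CNN is CPU-bound and single-threaded beyond BLAS; full-scale
  (W = 401, 13 cell types, 100 epochs × 100 replicates) training is
  feasible but slow — the desk-scale schedule exists for routine use.
* The ε floor on normalization denominators sets an arbitrary global scale;
  λ0 and λ values are only meaningful relative to it.
* Multi-isoform genes are reduced to the single TSS in the annotation.
* The decoy-null attribution check holds for ensemble-averaged profiles;
  individual replicates retain ±10–15% attribution noise on uninformative
  channels.
* Attribution magnitudes are conservative. A localized 7-bin increment is
  off the data manifold (real signal varies coherently across the whole
  profile), so a regression model's response to it is not pinned down by
  training; the desk-scale CNN transmits roughly 60% of the generator's
  true log-response, and in the pseudocount space the gene-averaged
  profile of even a perfect model is capped near 1.2 because silent genes
  contribute fold-changes of 1. Attribution profiles are therefore read
  for *localization* (where the response sits) rather than absolute
  magnitude.
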