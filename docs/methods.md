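# Methods

## The problem

Sequencing the cytoplasmic and nuclear RNA of one cell as two libraries
yields two TPM profiles that are each normalized to one million and so carry
no information about the compartment split. All downstream questions here —
does a gene's nuclear variation reach the cytoplasm, are cell-cycle
oscillations synchronized between compartments, which introns stay nuclear,
which compartment leads a differentiation response — require either restoring
the split (normalization) or comparing the compartments directly
(correlation analyses). This note records the models, parameter choices and
numerical conventions the package uses, and what its validation does and
does not establish.

## In silico normalization

For marker gene A, 2^ΔCt (ΔCt = Ct_nuc,A − Ct_cyt,A, assuming equal
amplification efficiency) measures the *absolute* cytoplasmic/nuclear
abundance ratio of A, while the raw TPM ratio TPM*_cyt,A/TPM*_nuc,A measures
its *relative* within-library abundance. Their quotient is the ratio of
total transcript content of the two compartments, hence

α = 2^ΔCt / (TPM*_cyt,A/TPM*_nuc,A + 2^ΔCt)

is the cytoplasmic transcript fraction and β = 1 − α the nuclear one.
Implementation details:

* Per-marker α values are averaged per cell (not per-marker ΔCt values);
  replicate ΔCt measurements of the same marker are averaged first.
* The HBG marker uses the sum of the HBG1 and HBG2 rows as its raw TPM.
* A marker with zero nuclear TPM makes the ratio undefined; it is skipped
  with a warning rather than imputed (markers are high-expressed genes, so
  this path is degenerate). A cell with no usable marker is an error.
* Raw-TPM column sums are checked against 10⁶ at 10⁻³ relative tolerance as
  a warning, not an error; the α/β-scaled sub-matrices intentionally sum to
  α·10⁶ and β·10⁶ and are exempt.

α is strictly increasing in ΔCt and strictly decreasing in the TPM ratio,
with α = ½ exactly when 2^ΔCt equals the ratio; the test suite asserts both.

## Correlation landscape

"Cross-correlation" between compartments is Pearson correlation at zero lag
on log₁₀(TPM+1) across cells (Spearman available by config). P-values use
the t-approximation t = r·√((n−2)/(1−r²)); genes enter the landscape only if
expressed (TPM > 1) in ≥ 5 cells in both compartments — without this filter
zero-inflated genes produce degenerate r. Constant genes carry r = NaN and
are excluded from ranking. BH adjustment is reported alongside raw p.
Whether the landscape runs on raw or α/β-scaled matrices is configurable;
per-gene Pearson r is invariant to the per-cell scaling, so the choice only
affects which cells/genes pass the expression filter.

## Differential expression

`nb_de_test` is a two-sample exact conditional test assuming
negative-binomial counts, in the style of MATLAB's `nbintest` / the classic
DESeq exact test:

1. library sizes are column sums; size factors s_j = libsize_j / mean
   libsize; normalized counts K/s_j;
2. per-gene dispersion by method of moments, pooled across the two groups
   (within-group variance minus the Poisson term, truncated at zero,
   averaged), floored at 10⁻⁸;
3. if the floor is hit, the Poisson limit applies: conditional on the total
   count, the group-A sum is Binomial(total, S_A/(S_A+S_B)) and an exact
   two-sided binomial test (minimum-likelihood tie rule) is used;
4. otherwise the two group sums are approximated by NB laws matched in mean
   and variance to the sum of per-cell NBs, and the exact conditional
   two-sided p sums all outcomes no more likely than the observed one
   (a 1+10⁻⁷ relative slack includes ties).
5. log₂ fold change uses normalized group means with pseudo-count 1;
   significance is p < 0.001 and |log₂FC| > 1.

On NB-simulated nulls (500 genes, 20+20 cells, dispersion 0.3) the empirical
type-I error at nominal 0.05 is ≈ 0.06–0.07; the Poisson-limit branch matches
a brute-force binomial oracle to < 10⁻⁹.

## Cell-cycle structure

The G1/G2 gene lists are an input (two-column TSV); the algorithms are
list-agnostic, and the synthetic generator emits matching planted sets.
Within-compartment matrices are symmetric with unit diagonal,
cross-compartment matrices need not be; both are asserted. The per-cell
phase score is the mean z-scored (per gene, across cells) log expression of
G2 genes minus that of G1 genes — a deliberately simple surrogate for
published phase-scoring schemes, sufficient to order cells along the planted
oscillation (Spearman > 0.8 against the planted phase in the tests).
Compartment comparison uses a two-sided Mann–Whitney U on the off-diagonal
block values.

## Intron retention

Classification is per (intron, cell, compartment) with the thresholds in
the README; all boundary conventions are explicit and tested: the gene
floor is strict (`< 2 TPM` discards), the retained ratio and coverage are
inclusive (≥ 0.10, ≥ 0.95), the spliced ratio is strict (< 0.01) and its
exon coverage inclusive (≥ 0.50). The expression ratio compares intron FPKM
to gene expression on the same per-kilobase-per-million scale (identical
scales in the synthetic data, where gene length is 1). "Coverage" is read
as breadth. Retention probability divides by assessable (retained +
spliced) cells only — discarded cells carry no information; all-discarded
introns are NaN. The NRI/CRI gap threshold 0.25 is inclusive. Unique
filtering is greedy by length (ties: leftmost start, then id) over half-open
intervals on the same chromosome and strand, and is order-independent.
Intron annotation follows the BED convention (0-based half-open); introns
of length ≤ 50 nt are dropped on read.

Splice-site strength is a position-weight-matrix log₂-odds score against a
uniform background with pseudocount 0.5 per base per position, trained on
the fully spliced introns, over the 9-mer 5′ window (exonic 3 + intronic 6,
GT core) and the 23-mer 3′ window (intronic 20 + exonic 3, AG core). This
is a simpler surrogate for maximum-entropy splice models; it is used only
comparatively (one-sided U test, retained lower), never as an absolute
strength.

## L-PCA and dynamics

L-PCA stacks the cytoplasmic and nuclear log₁₀(TPM+1) rows of the selected
genes into a 2n×m matrix, centers each feature across cells (no unit-variance
scaling by default, matching the convention of standard PCA routines;
scaling is a config switch), and takes components by SVD. Constant features
are dropped with a warning. Two identities pin the implementation down:
duplicating one compartment reproduces conventional PCA scores scaled by √2,
and orthogonal one-dimensional signals placed in the two compartments are
both captured by the first two components.

The fallback pseudotime is the rank of cells along conventional PC1,
sign-oriented so a designated reference group sits at the origin; an
externally supplied ordering always takes precedence. Cells are binned into
k = 5 contiguous equal-size pseudotime groups (remainder cells to the last
bins). Corner asymmetry compares the single extreme off-diagonal k×k blocks
(late-nucleus×early-cytoplasm vs early-nucleus×late-cytoplasm) with a
two-sided cell-resampling bootstrap (1000 resamples, seeded) on the
difference. The decline statistic is the Spearman trend of the within-bin
same-cell nuc↔cyt correlation against bin index. DEG selection for these
analyses takes the union of per-compartment significant genes.

## Synthetic data: what it emulates and what it does not

The generator is the package's test bed; the real assay defines no
generative model, so every distribution here is an artifact choice,
documented in `sincflow.synthetic`. Defaults (units in parentheses):

| parameter | default | meaning |
|---|---|---|
| n_genes / n_cells | 2000 / 60 | matrix size; presets: 60 unperturbed, 41 perturbed |
| reads_per_compartment | 2×10⁵ | multinomial library depth L |
| log_mean_loc/scale | 1.0 / 1.0 | per-gene log₁₀ mean expression ~ N(1,1) |
| sigma_t | 0.5 (dex) | cell-to-cell latent sd (biological variability) |
| sigma_eps | 0.05 (dex) | technical lognormal noise |
| cyt_fraction (± sd) | 0.84 ± 0.02 | true cytoplasmic transcript fraction |
| sigma_ct | 0.1 (cycles) | qPCR ΔCt noise |
| n_cellcycle, amplitude | 60, 0.5 (dex) | G1/G2 antiphase cosine oscillation |
| n_deg, deg_effect | 0 / 100, 1.0 (dex) | trajectory responders (perturbed preset) |
| deg_lag | 0.4 | cytoplasm tracks the nucleus at τ·(1−lag) |
| n_nri / background | 100 / 200 | planted NRIs (gap ≥ 0.25+0.15) vs equal-probability introns |

Key mechanisms:

* The qPCR ΔCt is defined on *absolute* marker abundance, which makes the
  α estimator consistent for the planted fraction — the property the
  normalization formula implicitly assumes.
* Negative coupling negates the centered nuclear latent before mixing, so
  the landscape has planted anticorrelated genes; 15% of generic genes get
  coupling exactly 0 as a planted null class for false-positive
  calibration.
* Trajectory genes respond in both compartments (60%), cytoplasm only
  (25%), or nucleus only (15%) — a shared-only effect cannot produce the
  same-cell correlation decline because the growing shared signal outweighs
  a constant lag divergence. Cells are sampled on 5 discrete days, matching
  a perturbation time course and aligning the analysis bins with days. The
  lag (0.4) and effect size (1.0 dex ≈ 10-fold over the course, typical of
  strong differentiation markers) are set so the planted lead-lag is
  recoverable from a single 41-cell experiment.
* NRI retention in the nucleus is tilted by the gene's nuclear expression
  z-score with strength ∝ p_nuc, producing the positive retention↔expression
  correlation in the nucleus and none in the cytoplasm.

The generator does **not** emulate: UMIs or sequencing error, gene length
variation (TPM uses unit length — no downstream formula here depends on
length), dropout beyond multinomial sampling, doublets, batch effects, or
mechanistic export kinetics. Tests passing on this generator show the
algorithms recover the structures they target under controlled noise; they
do not show robustness to the full noise anatomy of real libraries.

## Problem sizes and determinism

The test and acceptance runs use the preset sizes above (≤ 2000 genes,
41–60 cells, 20 replicate experiments for the α recovery, 5 pooled
experiments for the landscape rates); all stages run in seconds on one CPU.
Every stochastic component (generator, bootstrap) takes an explicit seed;
identical seeds give bitwise-identical outputs, asserted in the suite.

## Known limitations

* The NB variance-matching of group sums is exact only for equal size
  factors; with very unequal libraries the conditional test is approximate.
* The t-approximation p for Pearson r assumes bivariate normality of the
  log values; at n ≈ 60 it is adequate but not exact.
* The phase score and the PWM splice score are simplified surrogates (see
  above) — adequate for ordering and for group comparisons, not for
  absolute calibration against published scores.
* The corner-asymmetry bootstrap resamples cells within the extreme bins
  only, so its p-value is conditional on the binning.
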