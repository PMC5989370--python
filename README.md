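# sincflow

Analysis pipeline for **paired nuclear/cytoplasmic single-cell RNA-seq** —
experiments in which the cytoplasmic RNA (cytRNA) and the nuclear RNA
(nucRNA) of the *same* single cell are sequenced as two separate libraries.
Separate libraries are each normalized to transcripts-per-million on their
own, which destroys the information about how much RNA sat in each
compartment; `sincflow` restores it and then asks how the two compartments
covary, gene by gene, cell by cell, and along a differentiation trajectory.

The package is aimed at computational biologists who have (or simulate)
paired compartment TPM matrices, per-cell qPCR marker records, and per-intron
quantifications, and want a tested, reproducible implementation of:

* **In silico single-cell normalization.** With raw TPM (written `TPM*`) per
  compartment library and a marker gene *A* measured by qPCR in both
  compartment cDNAs (ΔCt = Ct_nuc,A − Ct_cyt,A), the per-cell cytoplasmic
  fraction is

  α = 2^ΔCt / (TPM*_cyt,A / TPM*_nuc,A + 2^ΔCt),  β = 1 − α,

  and the whole-cell profile is TPM_insilico = α·TPM*_cyt + β·TPM*_nuc,
  which again sums to 10⁶ per cell. α averages over markers (GAPDH and the
  summed γ-globins HBG1+HBG2 by default) and directly estimates the fraction
  of the cell's transcripts in the cytoplasm.
* **Correlation landscape.** Per-gene Pearson r across cells between
  log₁₀(TPM+1) nuclear and cytoplasmic expression, ranked and tested
  (t-approximation, BH-adjusted).
* **Cell-cycle structure.** In-phase vs out-of-phase correlation blocks of
  G1/G2 gene sets within each compartment and in the nucleus×cytoplasm cross
  matrix, with a Mann–Whitney U compartment comparison and a per-cell phase
  score.
* **Intron retention.** Per (intron, cell, compartment) classification —
  retained (intron FPKM ≥ 10% of the gene, ≥ 95% intronic coverage, expressed
  adjacent exon), fully spliced (< 1% and ≥ 50% exon coverage), or discarded
  (including any intron on a gene < 2 TPM); retention probability = retained
  fraction of assessable cells; nuclear-retained introns (NRIs) at a ≥ 0.25
  probability gap, longest-unique overlap filtering, retention↔expression
  correlation, and PWM log-odds splice-site scoring (5′ 9-mer, 3′ 23-mer).
* **L-PCA and dynamics.** Localization-embedded PCA on the stacked 2n×m
  matrix that treats each gene's cytoplasmic and nuclear expression as
  distinct features; pseudotime-ordered cell×cell nuc↔cyt cross-correlation
  with five-group binning, same-cell correlation decline, and corner
  asymmetry (which compartment leads the divergence).
* **Synthetic experiments.** A generator that plants every recoverable
  target — the compartment split, per-gene coupling, cell-cycle phases,
  NRIs with weakened splice sites, and a lead-lag differentiation
  trajectory — so each stage can be validated end to end.

## Worked example

```python
import sincflow as sf

exp = sf.simulate_experiment(sf.unperturbed_config(), seed=1)
res = sf.normalize(exp.cyt, exp.nuc, exp.qpcr)
summary = sf.cytoplasmic_abundance_summary(res)
print(f"{summary.mean_percent_cytoplasmic:.1f}%")
```

prints `84.2%` — the mean estimated cytoplasmic transcript fraction across
60 simulated cells, recovering the planted 84%/16% cytoplasm/nucleus split
from the simulated qPCR ΔCt records alone. Running
`python examples/05_lpca_dynamics.py` prints, among others,

```
corner means: top-right 0.501 vs bottom-left 0.652 (difference -0.151, bootstrap p = 0.001)
decline trend: Spearman rho = -1.00, p = 1.4e-24
```

— the late-nucleus/early-cytoplasm corner of the pseudotime-binned
cross-correlation grid is lower than its mirror image, the signature that
the nucleus drives the expression divergence, and the same-cell correlation
of trajectory-responsive genes declines monotonically along pseudotime.
The other `examples/*.py` scripts cover the landscape, the cell-cycle
blocks, and the NRI caller the same way.

A thin CLI mirrors the library (`sincflow simulate | insilico | correlate |
cellcycle | introns | lpca | dynamics`); each stage's output files are valid
inputs of the next.

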