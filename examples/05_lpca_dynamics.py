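"""Localization-embedded PCA and lead-lag dynamics along pseudotime.

In the perturbation preset the nucleus responds to the trajectory first and
the cytoplasm follows. The cell-by-cell nuclear-vs-cytoplasmic correlation
matrix, binned into five pseudotime groups, then shows (1) a same-cell
correlation decline for trajectory-responsive genes (DEGs), and (2) corner
asymmetry: late-nucleus/early-cytoplasm pairs correlate less than
early-nucleus/late-cytoplasm pairs.
"""

import sincflow as sf

exp = sf.simulate_experiment(sf.perturbed_config(), seed=7)
degs = exp.truth.deg_genes["gene_id"].tolist()

lp = sf.lpca(exp.cyt, exp.nuc, degs)
evr = lp.explained_variance_ratio
print(f"L-PCA on {len(degs)} DEGs x {exp.cyt.shape[1]} cells: "
      f"PC1 {100 * evr[0]:.1f}%, PC2 {100 * evr[1]:.1f}% of variance")

ccm = sf.cell_cross_correlation(exp.nuc, exp.cyt, degs, exp.pseudotime)
asym = sf.corner_asymmetry(ccm, k=5, n_boot=1000, seed=0)
print(f"corner means: top-right {asym.mean_topright:.3f} "
      f"vs bottom-left {asym.mean_bottomleft:.3f} "
      f"(difference {asym.difference:+.3f}, bootstrap p = {asym.p_value:.3g})")

trend = sf.correlation_decline(ccm, k=5)
print(f"same-cell DEG correlation per bin: "
      f"{[round(v, 3) for v in trend.per_bin]}")
print(f"decline trend: Spearman rho = {trend.rho:.2f}, p = {trend.p_value:.3g}")
# A negative difference means the late nuclear state is not yet visible in
# the early cytoplasm: the nucleus drives the divergence.
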