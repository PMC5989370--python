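"""Cross-compartment correlation landscape and differential expression.

The landscape asks, gene by gene, whether a cell with more of transcript g in
the nucleus also has more of it in the cytoplasm: Pearson correlation across
cells between log10(TPM+1) nuclear and cytoplasmic expression, ranked by r.

Differential expression between two cell groups uses a negative-binomial
two-sample test on counts (library-size-normalized, per-gene method-of-moments
dispersion pooled across groups). When the dispersion estimate collapses to
the floor, the test reduces to the exact conditional Poisson test — a
binomial test of the group-A count sum against the library-size split;
otherwise an exact conditional NB test on the two group sums is used.
Significance follows the rule p < 0.001 and |log2 fold change| > 1.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import CompartmentMatrix

logger = logging.getLogger("sincflow")


def log_transform(values: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Elementwise log10(x + 1)."""
    return np.log10(values + 1.0)


def pearson_p_from_r(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for Pearson r via the t statistic r*sqrt((n-2)/(1-r^2))."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
    return p


def gene_landscape(cyt: CompartmentMatrix, nuc: CompartmentMatrix,
                   min_cells_expressed: int = 5,
                   detection_tpm: float = 1.0,
                   method: str = "pearson") -> pd.DataFrame:
    """Per-gene nucleus<->cytoplasm correlation table, sorted by r.

    Genes enter the landscape when expressed (TPM > ``detection_tpm``) in at
    least ``min_cells_expressed`` cells in *both* compartments. Columns:
    gene, r, p, q (BH), rank, quantile. Genes with zero variance in either
    compartment carry r = NaN and are excluded from ranking.
    """
    if not cyt.cells.equals(nuc.cells):
        raise ValueError("matrices must share the cell ordering")
    n = len(cyt.cells)
    if n < 3:
        raise ValueError(f"need >= 3 shared cells, got {n}")
    genes = cyt.genes.intersection(nuc.genes, sort=False)
    cvals = cyt.values.loc[genes]
    nvals = nuc.values.loc[genes]
    expressed = (((cvals > detection_tpm).sum(axis=1) >= min_cells_expressed)
                 & ((nvals > detection_tpm).sum(axis=1) >= min_cells_expressed))
    genes = genes[expressed.to_numpy()]
    logger.info("landscape: %d/%d genes pass the >= %d expressed-cells filter",
                len(genes), len(expressed), min_cells_expressed)
    x = np.asarray(log_transform(cvals.loc[genes].to_numpy()))
    y = np.asarray(log_transform(nvals.loc[genes].to_numpy()))
    if method == "spearman":
        x = stats.rankdata(x, axis=1)
        y = stats.rankdata(y, axis=1)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    sx = np.sqrt((xc ** 2).sum(axis=1))
    sy = np.sqrt((yc ** 2).sum(axis=1))
    # a constant row is zero-variance regardless of centering round-off
    flat = (np.ptp(x, axis=1) == 0) | (np.ptp(y, axis=1) == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc * yc).sum(axis=1) / (sx * sy)
    r = np.where(flat | (sx == 0) | (sy == 0), np.nan, r)
    p = np.where(np.isnan(r), np.nan, pearson_p_from_r(np.nan_to_num(r), n))
    table = pd.DataFrame({"gene": genes, "r": r, "p": p})
    valid = table["r"].notna()
    q = np.full(len(table), np.nan)
    if valid.any():
        q[valid.to_numpy()] = multipletests(table.loc[valid, "p"], method="fdr_bh")[1]
    table["q"] = q
    table = table.sort_values("r", na_position="last", kind="mergesort",
                              ignore_index=True)
    nv = int(valid.sum())
    table["rank"] = np.where(table["r"].notna(), np.arange(len(table)), np.nan)
    table["quantile"] = table["rank"] / max(nv - 1, 1)
    npos = int(((table["r"] > 0) & (table["p"] < 0.05)).sum())
    nneg = int(((table["r"] < 0) & (table["p"] < 0.05)).sum())
    logger.info("landscape: %d positively / %d negatively correlated genes "
                "at p < 0.05", npos, nneg)
    table.attrs["n_positive_p05"] = npos
    table.attrs["n_negative_p05"] = nneg
    return table


def sample_correlation(profile_a: np.ndarray | pd.Series,
                       profile_b: np.ndarray | pd.Series) -> float:
    """Pearson r over genes between two log-transformed expression profiles."""
    a = np.asarray(log_transform(np.asarray(profile_a, dtype=float)))
    b = np.asarray(log_transform(np.asarray(profile_b, dtype=float)))
    if a.shape != b.shape:
        raise ValueError("profiles differ in length")
    return float(stats.pearsonr(a, b).statistic)


# ---------------------------------------------------------------------------
# negative-binomial two-sample differential expression
# ---------------------------------------------------------------------------

def _nb_params_for_sum(mu_cell: float, size_factors: np.ndarray,
                       dispersion: float) -> tuple[float, float]:
    """(n, p) of the NB law approximating a sum of per-cell NB counts.

    Cell j has mean mu_cell * s_j and variance mu*s_j + dispersion*(mu*s_j)^2;
    the group sum is matched by mean and variance (exact when all size
    factors are equal).
    """
    mean = mu_cell * size_factors.sum()
    var = mean + dispersion * (mu_cell ** 2) * (size_factors ** 2).sum()
    if var <= mean:
        var = mean * (1 + 1e-12)
    n = mean ** 2 / (var - mean)
    p = mean / var
    return n, p


def _nb_exact_conditional_p(ka: int, kb: int, mu: float,
                            sf_a: np.ndarray, sf_b: np.ndarray,
                            dispersion: float) -> float:
    """Exact conditional two-sided p: P(outcomes as or less likely than obs).

    Conditions on the total ka+kb and enumerates the joint pmf of the two
    group sums under the null of a common per-cell mean.
    """
    total = ka + kb
    na, pa = _nb_params_for_sum(mu, sf_a, dispersion)
    nb_, pb = _nb_params_for_sum(mu, sf_b, dispersion)
    a = np.arange(total + 1)
    with np.errstate(divide="ignore"):
        logp = (stats.nbinom.logpmf(a, na, pa)
                + stats.nbinom.logpmf(total - a, nb_, pb))
    logp -= logp.max()
    probs = np.exp(logp)
    denom = probs.sum()
    if denom == 0 or not np.isfinite(denom):
        return 1.0
    obs = probs[ka]
    # small relative slack so ties with the observed outcome are included
    return float(probs[probs <= obs * (1 + 1e-7)].sum() / denom)


def nb_de_test(counts_a: pd.DataFrame, counts_b: pd.DataFrame,
               p_threshold: float = 1e-3, lfc_threshold: float = 1.0,
               dispersion_floor: float = 1e-8) -> pd.DataFrame:
    """Per-gene negative-binomial two-sample test between cell groups.

    Inputs are gene x cell count (or rescaled pseudo-count) matrices sharing
    the gene index. Returns a DataFrame with gene, log2fc (A over B,
    pseudo-count 1 on normalized means), p, q (BH), significant.
    """
    if not counts_a.index.equals(counts_b.index):
        raise ValueError("count matrices must share the gene index")
    if counts_a.shape[1] < 2 or counts_b.shape[1] < 2:
        raise ValueError("each group needs >= 2 cells")
    a = np.round(counts_a.to_numpy(float))
    b = np.round(counts_b.to_numpy(float))
    lib_a = a.sum(axis=0)
    lib_b = b.sum(axis=0)
    if (lib_a == 0).any() or (lib_b == 0).any():
        raise ValueError("a cell has zero library size")
    mean_lib = np.concatenate([lib_a, lib_b]).mean()
    sf_a = lib_a / mean_lib
    sf_b = lib_b / mean_lib
    norm_a = a / sf_a
    norm_b = b / sf_b

    # pooled method-of-moments dispersion: average within-group excess variance
    disp = np.zeros(a.shape[0])
    denom = np.zeros(a.shape[0])
    for norm, sf in ((norm_a, sf_a), (norm_b, sf_b)):
        m = norm.mean(axis=1)
        v = norm.var(axis=1, ddof=1)
        # Var(K/s) = mu/s + disp*mu^2 per cell; average over cells
        base = m * np.mean(1.0 / sf)
        with np.errstate(divide="ignore", invalid="ignore"):
            d = (v - base) / m ** 2
        ok = m > 0
        disp[ok] += np.where(np.isfinite(d[ok]), np.maximum(d[ok], 0.0), 0.0)
        denom[ok] += 1
    with np.errstate(invalid="ignore"):
        disp = np.where(denom > 0, disp / np.maximum(denom, 1), 0.0)
    disp = np.maximum(disp, dispersion_floor)

    p_split = sf_a.sum() / (sf_a.sum() + sf_b.sum())
    mu_all = (a.sum(axis=1) + b.sum(axis=1)) / (sf_a.sum() + sf_b.sum())
    pvals = np.ones(a.shape[0])
    ka_all = a.sum(axis=1).astype(int)
    kb_all = b.sum(axis=1).astype(int)
    for g in range(a.shape[0]):
        total = ka_all[g] + kb_all[g]
        if total == 0:
            pvals[g] = 1.0
            continue
        if disp[g] <= dispersion_floor * (1 + 1e-12):
            # Poisson limit: conditional on the total, K_A ~ Binomial
            pvals[g] = stats.binomtest(ka_all[g], total, p_split).pvalue
        else:
            pvals[g] = _nb_exact_conditional_p(
                ka_all[g], kb_all[g], mu_all[g], sf_a, sf_b, disp[g])
    pvals = np.clip(pvals, 0.0, 1.0)
    log2fc = np.log2((norm_a.mean(axis=1) + 1.0) / (norm_b.mean(axis=1) + 1.0))
    qvals = multipletests(pvals, method="fdr_bh")[1]
    out = pd.DataFrame({
        "gene": counts_a.index, "log2fc": log2fc, "p": pvals, "q": qvals,
        "significant": (pvals < p_threshold) & (np.abs(log2fc) > lfc_threshold),
    })
    logger.info("nb_de_test: %d/%d genes significant at p < %g, |log2fc| > %g",
                int(out["significant"].sum()), len(out), p_threshold,
                lfc_threshold)
    return out
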