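"""Localization-embedded PCA and pseudotime cross-correlation dynamics.

L-PCA treats each gene's cytoplasmic and nuclear expression as distinct
features: the n cytoplasmic rows and the n nuclear rows of the same genes are
stacked into a 2n x m matrix (log10(TPM+1)), features are centered across
cells, and principal components are taken by SVD. Conventional PCA applies
the same contract to the n x m whole-cell (in silico) matrix.

The dynamics analysis orders cells along pseudotime, computes the m x m
matrix of correlations between every nuclear profile and every cytoplasmic
profile over a gene set, bins cells into k contiguous pseudotime groups, and
compares the extreme off-diagonal corners: if the nucleus leads the
cytoplasm, late-nucleus/early-cytoplasm pairs correlate less than
early-nucleus/late-cytoplasm pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CompartmentMatrix, PseudotimeOrdering
from .correlation import log_transform

logger = logging.getLogger("sincflow")


@dataclass
class PcaResult:
    scores: pd.DataFrame            # cells x components
    explained_variance_ratio: np.ndarray
    components: np.ndarray          # components x features
    feature_names: list[str]


def _pca_on_features(x: np.ndarray, feature_names: list[str],
                     cells: pd.Index, scale: bool = False) -> PcaResult:
    """Center features (rows) across cells, optional unit variance, SVD."""
    sd = x.std(axis=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all features are constant across cells")
    if (~keep).any():
        logger.warning("dropping %d constant features before PCA",
                       int((~keep).sum()))
    x = x[keep]
    names = [n for n, k in zip(feature_names, keep) if k]
    xc = x - x.mean(axis=1, keepdims=True)
    if scale:
        xc = xc / xc.std(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    var = s ** 2
    evr = var / var.sum()
    scores = pd.DataFrame((vt.T * s),
                          index=cells,
                          columns=[f"PC{i+1}" for i in range(len(s))])
    return PcaResult(scores=scores, explained_variance_ratio=evr,
                     components=u.T, feature_names=names)


def _selected_log(matrix: CompartmentMatrix, genes: list[str]) -> np.ndarray:
    missing = [g for g in genes if g not in matrix.genes]
    if missing:
        raise KeyError(f"genes absent from matrix: {missing[:5]}")
    return np.asarray(log_transform(matrix.values.loc[genes].to_numpy()))


def lpca(cyt: CompartmentMatrix, nuc: CompartmentMatrix, genes: list[str],
         scale: bool = False) -> PcaResult:
    """Localization-embedded PCA on the stacked 2n x m feature matrix."""
    if len(genes) < 2:
        raise ValueError("need >= 2 genes")
    if not cyt.cells.equals(nuc.cells):
        raise ValueError("matrices must share the cell ordering")
    if len(cyt.cells) < 3:
        raise ValueError("need >= 3 cells")
    stacked = np.vstack([_selected_log(cyt, genes), _selected_log(nuc, genes)])
    names = [f"{g}|cyt" for g in genes] + [f"{g}|nuc" for g in genes]
    return _pca_on_features(stacked, names, cyt.cells, scale=scale)


def conventional_pca(matrix: CompartmentMatrix | pd.DataFrame,
                     genes: list[str], scale: bool = False) -> PcaResult:
    """PCA with the same centering/SVD contract on an n x m matrix."""
    values = matrix.values if isinstance(matrix, CompartmentMatrix) else matrix
    if len(genes) < 2:
        raise ValueError("need >= 2 genes")
    if values.shape[1] < 3:
        raise ValueError("need >= 3 cells")
    missing = [g for g in genes if g not in values.index]
    if missing:
        raise KeyError(f"genes absent from matrix: {missing[:5]}")
    x = np.asarray(log_transform(values.loc[genes].to_numpy()))
    return _pca_on_features(x, list(genes), values.columns, scale=scale)


def fallback_pseudotime(matrix: CompartmentMatrix | pd.DataFrame,
                        genes: list[str], reference_cells: list[str] | None = None,
                        reverse: bool = False) -> PseudotimeOrdering:
    """Pseudotime surrogate: rank of cell scores along conventional PC1.

    The sign is oriented so the designated reference cells (default: the
    first cell) sit near the origin; ``reverse`` flips the ordering.
    """
    res = conventional_pca(matrix, genes)
    pc1 = res.scores["PC1"]
    refs = reference_cells if reference_cells else [pc1.index[0]]
    missing = [c for c in refs if c not in pc1.index]
    if missing:
        raise KeyError(f"reference cells absent: {missing}")
    if pc1.loc[refs].mean() > pc1.mean():
        pc1 = -pc1
    if reverse:
        pc1 = -pc1
    tau = pc1.rank(method="first").to_numpy() - 1.0
    return PseudotimeOrdering(cells=list(pc1.index), pseudotime=tau)


@dataclass
class CrossCorrMatrix:
    """m x m nuclear-cell x cytoplasmic-cell correlation, pseudotime order."""

    matrix: pd.DataFrame
    ordering: PseudotimeOrdering


def cell_cross_correlation(nuc: CompartmentMatrix, cyt: CompartmentMatrix,
                           genes: list[str],
                           ordering: PseudotimeOrdering) -> CrossCorrMatrix:
    """Entry (i, j): Pearson r over genes between nuclear profile of cell i
    and cytoplasmic profile of cell j, cells sorted by pseudotime."""
    if len(genes) < 3:
        raise ValueError("need >= 3 genes")
    if not cyt.cells.equals(nuc.cells):
        raise ValueError("matrices must share the cell ordering")
    cells = ordering.ordered_cells()
    missing = [c for c in cells if c not in cyt.cells]
    if missing:
        raise KeyError(f"ordering cells absent from matrices: {missing[:5]}")
    xn = _selected_log(nuc, genes)[:, [list(nuc.cells).index(c) for c in cells]]
    xc = _selected_log(cyt, genes)[:, [list(cyt.cells).index(c) for c in cells]]
    xn_c = xn - xn.mean(axis=0, keepdims=True)
    xc_c = xc - xc.mean(axis=0, keepdims=True)
    sn = np.sqrt((xn_c ** 2).sum(axis=0))
    sc = np.sqrt((xc_c ** 2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (xn_c.T @ xc_c) / np.outer(sn, sc)
    return CrossCorrMatrix(
        matrix=pd.DataFrame(corr, index=cells, columns=cells),
        ordering=ordering)


def bin_edges(m: int, k: int) -> list[tuple[int, int]]:
    """Contiguous equal-size bins; remainder cells go to the last bins."""
    if k < 1 or k > m:
        raise ValueError(f"cannot split {m} cells into {k} bins")
    base = m // k
    rem = m % k
    sizes = [base] * (k - rem) + [base + 1] * rem
    edges = []
    start = 0
    for s in sizes:
        edges.append((start, start + s))
        start += s
    return edges


def bin_and_summarize(ccm: CrossCorrMatrix, k: int = 5
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """k x k grid of within-block mean correlation and per-block SD."""
    m = ccm.matrix.shape[0]
    edges = bin_edges(m, k)
    grid = np.empty((k, k))
    disp = np.empty((k, k))
    arr = ccm.matrix.to_numpy()
    for i, (r0, r1) in enumerate(edges):
        for j, (c0, c1) in enumerate(edges):
            block = arr[r0:r1, c0:c1]
            grid[i, j] = np.nanmean(block)
            disp[i, j] = np.nanstd(block)
    labels = [f"bin{i+1}" for i in range(k)]
    return (pd.DataFrame(grid, index=labels, columns=labels),
            pd.DataFrame(disp, index=labels, columns=labels))


@dataclass
class CornerAsymmetry:
    mean_topright: float      # late nucleus vs early cytoplasm
    mean_bottomleft: float    # early nucleus vs late cytoplasm
    difference: float         # topright - bottomleft
    p_value: float


def corner_asymmetry(ccm: CrossCorrMatrix, k: int = 5,
                     n_boot: int = 1000, seed: int = 0) -> CornerAsymmetry:
    """Compare the two extreme off-diagonal pseudotime blocks.

    Top-right: last nuclear bin x first cytoplasmic bin; bottom-left: first
    nuclear bin x last cytoplasmic bin. The p-value is a two-sided
    cell-resampling bootstrap of the difference (cells resampled within each
    extreme bin).
    """
    if k < 2:
        raise ValueError("corner asymmetry needs k >= 2 bins")
    m = ccm.matrix.shape[0]
    edges = bin_edges(m, k)
    first = np.arange(*edges[0])
    last = np.arange(*edges[-1])
    arr = ccm.matrix.to_numpy()
    tr = float(np.nanmean(arr[np.ix_(last, first)]))
    bl = float(np.nanmean(arr[np.ix_(first, last)]))
    diff = tr - bl
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        f = rng.choice(first, size=len(first), replace=True)
        l = rng.choice(last, size=len(last), replace=True)
        boots[b] = (np.nanmean(arr[np.ix_(l, f)])
                    - np.nanmean(arr[np.ix_(f, l)]))
    # two-sided bootstrap p: does the CI of the difference exclude zero?
    p = 2.0 * min((boots <= 0).mean(), (boots >= 0).mean())
    p = min(max(p, 1.0 / n_boot), 1.0)
    return CornerAsymmetry(mean_topright=tr, mean_bottomleft=bl,
                           difference=diff, p_value=float(p))


@dataclass
class DeclineTrend:
    rho: float
    p_value: float
    per_bin: pd.Series


def correlation_decline(ccm: CrossCorrMatrix, k: int = 5) -> DeclineTrend:
    """Spearman trend of within-bin same-cell nuc<->cyt correlation vs bin.

    Uses the diagonal blocks of the binned grid (each cell's nuclear profile
    against its own cytoplasmic profile, averaged per pseudotime bin).
    """
    if k < 3:
        raise ValueError("trend needs >= 3 bins")
    m = ccm.matrix.shape[0]
    edges = bin_edges(m, k)
    arr = ccm.matrix.to_numpy()
    per_bin = []
    for (r0, r1) in edges:
        per_bin.append(float(np.nanmean(np.diag(arr)[r0:r1])))
    res = stats.spearmanr(np.arange(k), per_bin)
    return DeclineTrend(rho=float(res.statistic), p_value=float(res.pvalue),
                        per_bin=pd.Series(per_bin,
                                          index=[f"bin{i+1}" for i in range(k)]))
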