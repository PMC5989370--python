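"""Correlation structure of cell-cycle genes within and across compartments.

Cycling transcription makes genes of the same phase (G1 with G1, G2 with G2)
covary positively across cells and genes of opposite phases covary
negatively. Those signatures survive, per compartment, in both the nuclear
and the cytoplasmic libraries of the same cells, and the nucleus-by-cytoplasm
cross matrix shows the same block structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CompartmentMatrix
from .correlation import log_transform

logger = logging.getLogger("sincflow")


@dataclass
class PhaseGeneSets:
    """Disjoint G1 and G2 gene-id sets."""

    g1_genes: list[str]
    g2_genes: list[str]

    def __post_init__(self):
        overlap = set(self.g1_genes) & set(self.g2_genes)
        if overlap:
            raise ValueError(f"G1 and G2 sets overlap: {sorted(overlap)}")

    def restrict_to(self, genes: pd.Index) -> "PhaseGeneSets":
        """Drop genes absent from an expression matrix, with a warning."""
        g1 = [g for g in self.g1_genes if g in genes]
        g2 = [g for g in self.g2_genes if g in genes]
        missing = (len(self.g1_genes) - len(g1)) + (len(self.g2_genes) - len(g2))
        if missing:
            logger.warning("%d cell-cycle genes absent from matrix; dropped",
                           missing)
        return PhaseGeneSets(g1, g2)


def _log_expression(matrix: CompartmentMatrix | pd.DataFrame,
                    genes: list[str]) -> pd.DataFrame:
    values = matrix.values if isinstance(matrix, CompartmentMatrix) else matrix
    missing = [g for g in genes if g not in values.index]
    if missing:
        raise KeyError(f"genes absent from matrix: {missing[:5]}")
    return pd.DataFrame(np.asarray(log_transform(values.loc[genes].to_numpy())),
                        index=genes, columns=values.columns)


@dataclass
class PhaseCorrelation:
    matrix: pd.DataFrame            # gene x gene Pearson r, NaN for constants
    phase: pd.Series                # gene -> "G1"/"G2"
    mean_in_phase: float
    mean_out_of_phase: float

    def offdiag_values(self, which: str) -> np.ndarray:
        """Off-diagonal correlation values: 'in_phase' or 'out_of_phase'."""
        return _block_values(self.matrix, self.phase, which)


def _block_values(matrix: pd.DataFrame, phase: pd.Series, which: str) -> np.ndarray:
    labels = phase.loc[matrix.index].to_numpy()
    same = labels[:, None] == labels[None, :]
    offdiag = ~np.eye(len(labels), dtype=bool)
    mask = (same if which == "in_phase" else ~same) & offdiag
    vals = matrix.to_numpy()[mask]
    return vals[~np.isnan(vals)]


def phase_correlation_matrix(matrix: CompartmentMatrix | pd.DataFrame,
                             sets: PhaseGeneSets) -> PhaseCorrelation:
    """Gene-gene Pearson correlation (log10(TPM+1) across cells) in G1 u G2.

    Constant genes get NaN rows/columns and are excluded from the in-phase /
    out-of-phase summary means.
    """
    values = matrix.values if isinstance(matrix, CompartmentMatrix) else matrix
    sets = sets.restrict_to(values.index)
    if len(sets.g1_genes) < 2 or len(sets.g2_genes) < 2:
        raise ValueError("each phase set needs >= 2 genes present in the matrix")
    if values.shape[1] < 3:
        raise ValueError("need >= 3 cells")
    genes = sets.g1_genes + sets.g2_genes
    x = _log_expression(matrix, genes).to_numpy()
    flat = np.ptp(x, axis=1) == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.corrcoef(x)
    corr[flat, :] = np.nan
    corr[:, flat] = np.nan
    cm = pd.DataFrame(corr, index=genes, columns=genes)
    phase = pd.Series(["G1"] * len(sets.g1_genes) + ["G2"] * len(sets.g2_genes),
                      index=genes)
    mean_in = float(np.mean(_block_values(cm, phase, "in_phase")))
    mean_out = float(np.mean(_block_values(cm, phase, "out_of_phase")))
    return PhaseCorrelation(matrix=cm, phase=phase, mean_in_phase=mean_in,
                            mean_out_of_phase=mean_out)


def compare_compartments(corr_cyt: PhaseCorrelation, corr_nuc: PhaseCorrelation,
                         which: str = "out_of_phase") -> tuple[float, float]:
    """Two-sided Mann-Whitney U comparing off-diagonal correlations.

    Returns (U, p) for cytoplasm vs nucleus on the chosen block
    ('out_of_phase' or 'in_phase').
    """
    x = corr_cyt.offdiag_values(which)
    y = corr_nuc.offdiag_values(which)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty correlation block")
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def cross_compartment_cellcycle_matrix(cyt: CompartmentMatrix,
                                       nuc: CompartmentMatrix,
                                       sets: PhaseGeneSets) -> PhaseCorrelation:
    """Nucleus-gene x cytoplasm-gene correlation matrix over the same cells.

    Entry (i, j) is the Pearson r across cells between nuclear expression of
    gene i and cytoplasmic expression of gene j; generally not symmetric.
    """
    if not cyt.cells.equals(nuc.cells):
        raise ValueError("matrices must share the cell ordering")
    if len(cyt.cells) < 3:
        raise ValueError("need >= 3 cells")
    sets = PhaseGeneSets(
        [g for g in sets.g1_genes if g in cyt.genes and g in nuc.genes],
        [g for g in sets.g2_genes if g in cyt.genes and g in nuc.genes])
    if len(sets.g1_genes) < 2 or len(sets.g2_genes) < 2:
        raise ValueError("each phase set needs >= 2 genes present in both matrices")
    genes = sets.g1_genes + sets.g2_genes
    xn = _log_expression(nuc, genes).to_numpy()
    xc = _log_expression(cyt, genes).to_numpy()
    xn_c = xn - xn.mean(axis=1, keepdims=True)
    xc_c = xc - xc.mean(axis=1, keepdims=True)
    sn = xn_c.std(axis=1) * np.sqrt(xn.shape[1])
    sc = xc_c.std(axis=1) * np.sqrt(xc.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (xn_c @ xc_c.T) / np.outer(sn, sc)
    corr[sn == 0, :] = np.nan
    corr[:, sc == 0] = np.nan
    cm = pd.DataFrame(corr, index=genes, columns=genes)
    phase = pd.Series(["G1"] * len(sets.g1_genes) + ["G2"] * len(sets.g2_genes),
                      index=genes)
    mean_in = float(np.mean(_block_values(cm, phase, "in_phase")))
    mean_out = float(np.mean(_block_values(cm, phase, "out_of_phase")))
    return PhaseCorrelation(matrix=cm, phase=phase, mean_in_phase=mean_in,
                            mean_out_of_phase=mean_out)


def phase_scores(matrix: CompartmentMatrix | pd.DataFrame,
                 sets: PhaseGeneSets) -> pd.Series:
    """Per-cell cycle position score: mean z-scored G2 minus mean z-scored G1.

    Expression is log10(TPM+1), z-scored per gene across cells; a cell at the
    G1 pole of the cycle scores negative, at the G2 pole positive.
    """
    values = matrix.values if isinstance(matrix, CompartmentMatrix) else matrix
    sets = sets.restrict_to(values.index)
    genes = sets.g1_genes + sets.g2_genes
    x = _log_expression(matrix, genes)
    sd = x.std(axis=1, ddof=0)
    keep = sd > 0
    z = x.loc[keep].sub(x.loc[keep].mean(axis=1), axis=0).div(sd[keep], axis=0)
    g1 = [g for g in sets.g1_genes if keep.get(g, False)]
    g2 = [g for g in sets.g2_genes if keep.get(g, False)]
    if not g1 or not g2:
        raise ValueError("phase score needs variable genes in both sets")
    return score_from_z(z, g1, g2)


def score_from_z(z: pd.DataFrame, g1: list[str], g2: list[str]) -> pd.Series:
    """G2-minus-G1 mean of an already z-scored gene x cell matrix.

    A per-cell additive offset on ``z`` cancels exactly in the difference.
    """
    return z.loc[g2].mean(axis=0) - z.loc[g1].mean(axis=0)
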