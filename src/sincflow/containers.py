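"""Core in-memory containers for paired nuclear/cytoplasmic expression data.

Expression matrices are plain pandas DataFrames (genes in rows, cells in
columns) wrapped in :class:`CompartmentMatrix`, which carries the compartment
label and enforces the invariants every downstream stage relies on:
non-negative values, unique identifiers, and (for raw TPM input) per-cell
column sums near one million.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd

logger = logging.getLogger("sincflow")

Compartment = Literal["cyt", "nuc"]

#: Relative tolerance on the per-cell TPM column sum (1e6) before a warning.
TPM_SUM_RTOL = 1e-3


class CompartmentMatrix:
    """Gene x cell expression matrix (TPM) for one subcellular compartment.

    Parameters
    ----------
    values
        DataFrame with gene identifiers as the index and cell identifiers as
        the columns. All entries must be finite and non-negative.
    compartment
        ``"cyt"`` or ``"nuc"``.
    check_tpm_sum
        When True (raw TPM input), warn if any column sum deviates from 1e6
        by more than ``TPM_SUM_RTOL`` relative. Scaled sub-matrices produced
        by the in silico normalization intentionally sum to alpha*1e6 or
        beta*1e6, so they are constructed with ``check_tpm_sum=False``.
    """

    def __init__(self, values: pd.DataFrame, compartment: Compartment,
                 check_tpm_sum: bool = True):
        if compartment not in ("cyt", "nuc"):
            raise ValueError(f"compartment must be 'cyt' or 'nuc', got {compartment!r}")
        if values.index.has_duplicates:
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dups}")
        if values.columns.has_duplicates:
            dups = values.columns[values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate cell identifiers: {dups}")
        arr = values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("expression matrix contains non-numeric values")
        if not np.isfinite(arr).all():
            raise ValueError("expression matrix contains non-finite values")
        if (arr < 0).any():
            bad = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative expression at gene {values.index[bad[0]]!r}, "
                f"cell {values.columns[bad[1]]!r}")
        self.values = values.astype(float)
        self.compartment: Compartment = compartment
        if check_tpm_sum:
            sums = arr.sum(axis=0)
            off = np.abs(sums - 1e6) > TPM_SUM_RTOL * 1e6
            if off.any():
                logger.warning(
                    "%d/%d cells in %s matrix have TPM column sums outside "
                    "1e6 (1 +/- %g); first offender %s sums to %.1f",
                    int(off.sum()), len(sums), compartment, TPM_SUM_RTOL,
                    values.columns[int(np.argmax(off))], float(sums[np.argmax(off)]))

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def cells(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def __repr__(self) -> str:  # pragma: no cover
        g, c = self.shape
        return f"CompartmentMatrix({self.compartment}, {g} genes x {c} cells)"


@dataclass(frozen=True)
class IntronAnnotation:
    """One intron interval in BED convention (0-based, half-open)."""

    intron_id: str
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(
                f"intron {self.intron_id}: start {self.start} >= end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"intron {self.intron_id}: bad strand {self.strand!r}")

    @property
    def length_nt(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class QpcrRecord:
    """Per-cell qPCR record: delta Ct = Ct_nuc - Ct_cyt for one marker gene."""

    cell: str
    marker_gene: str
    delta_ct: float

    def __post_init__(self):
        if not math.isfinite(self.delta_ct):
            raise ValueError(
                f"non-finite delta Ct for cell {self.cell}, marker {self.marker_gene}")


@dataclass
class PseudotimeOrdering:
    """One-dimensional ordering of cells along an inferred trajectory."""

    cells: list[str]
    pseudotime: np.ndarray

    def __post_init__(self):
        self.pseudotime = np.asarray(self.pseudotime, dtype=float)
        if len(self.cells) != len(self.pseudotime):
            raise ValueError("cells and pseudotime lengths differ")
        if len(set(self.cells)) != len(self.cells):
            raise ValueError("duplicate cell identifiers in pseudotime ordering")

    @property
    def ranks(self) -> np.ndarray:
        """Integer ranks 0..M-1 of each cell along pseudotime (stable ties)."""
        order = np.argsort(self.pseudotime, kind="stable")
        ranks = np.empty(len(order), dtype=int)
        ranks[order] = np.arange(len(order))
        return ranks

    def ordered_cells(self) -> list[str]:
        order = np.argsort(self.pseudotime, kind="stable")
        return [self.cells[i] for i in order]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cell_id": self.cells, "pseudotime": self.pseudotime,
             "rank": self.ranks})


@dataclass
class InSilicoResult:
    """Output of the in silico single-cell normalization.

    ``alpha`` is the per-cell cytoplasmic fraction, ``beta = 1 - alpha``;
    ``tpm_insilico = tpm_cyt_scaled + tpm_nuc_scaled`` elementwise and each
    column sums to one million.
    """

    alpha: pd.Series
    tpm_insilico: pd.DataFrame
    tpm_cyt_scaled: pd.DataFrame
    tpm_nuc_scaled: pd.DataFrame

    @property
    def beta(self) -> pd.Series:
        return 1.0 - self.alpha


@dataclass
class GroundTruth:
    """Planted truth emitted by the synthetic generator, for recovery tests."""

    cytoplasmic_fraction: pd.Series        # per cell, in (0, 1)
    coupling: pd.Series                    # per gene, rho in [-1, 1]
    g1_genes: list[str] = field(default_factory=list)
    g2_genes: list[str] = field(default_factory=list)
    phase: pd.Series | None = None         # per cell, theta in [0, 2*pi)
    nri_introns: pd.DataFrame | None = None  # intron_id, p_nuc, p_cyt
    background_introns: pd.DataFrame | None = None
    deg_genes: pd.DataFrame | None = None  # gene_id, effect size per compartment
    pseudotime: pd.Series | None = None    # per cell tau in [0, 1]

    def __post_init__(self):
        fc = self.cytoplasmic_fraction
        if ((fc <= 0) | (fc >= 1)).any():
            raise ValueError("true cytoplasmic fractions must lie strictly in (0, 1)")
        if set(self.g1_genes) & set(self.g2_genes):
            raise ValueError("G1 and G2 gene sets overlap")
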