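"""In silico single-cell normalization of paired compartment RNA-seq.

A cell sequenced as two libraries (cytoplasmic and nuclear) yields two raw
TPM profiles that each sum to one million and therefore carry no information
about the relative transcript amounts in the two compartments. The
normalization recombines them into a whole-cell ("in silico single cell")
profile by weighting with the per-cell cytoplasmic fraction alpha and nuclear
fraction beta = 1 - alpha:

    TPM_insilico = alpha * TPM*_cyt + (1 - alpha) * TPM*_nuc

alpha is estimated from qPCR of marker genes (GAPDH and the gamma-globin pair
HBG1+HBG2 in the original protocol): with dCt = Ct_nuc - Ct_cyt for marker A,

    alpha = 2^dCt / (TPM*_cyt,A / TPM*_nuc,A + 2^dCt)

The 2^dCt term measures the absolute cyt/nuc abundance ratio of the marker
while the raw TPM ratio measures its relative within-library abundance; their
quotient is the ratio of total transcript amounts, which is what alpha
captures. Per-marker alphas are averaged per cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CompartmentMatrix, InSilicoResult, QpcrRecord

logger = logging.getLogger("sincflow")

#: Marker groups: table name -> gene rows summed to form the marker TPM.
DEFAULT_MARKER_GROUPS: dict[str, tuple[str, ...]] = {
    "GAPDH": ("GAPDH",),
    "HBG": ("HBG1", "HBG2"),
}


def alpha_for_marker(delta_ct: float, raw_tpm_cyt_marker: float,
                     raw_tpm_nuc_marker: float) -> float:
    """Cytoplasmic fraction alpha from one marker gene.

    ``delta_ct`` is Ct_nuc - Ct_cyt (cycles); the TPM arguments are the
    marker's raw TPM in each compartment library. Requires a detected nuclear
    marker (raw_tpm_nuc_marker > 0).
    """
    if raw_tpm_nuc_marker <= 0:
        raise ValueError("marker unusable: raw nuclear TPM must be > 0")
    if raw_tpm_cyt_marker < 0:
        raise ValueError("raw cytoplasmic TPM must be >= 0")
    ratio = raw_tpm_cyt_marker / raw_tpm_nuc_marker
    pow2 = 2.0 ** float(delta_ct)
    return pow2 / (ratio + pow2)


def _marker_tpm(matrix: CompartmentMatrix, genes: tuple[str, ...],
                cell: str) -> float:
    present = [g for g in genes if g in matrix.genes]
    if not present:
        return float("nan")
    return float(matrix.values.loc[list(present), cell].sum())


def cell_alpha(records: list[QpcrRecord], cyt: CompartmentMatrix,
               nuc: CompartmentMatrix,
               marker_groups: dict[str, tuple[str, ...]] | None = None) -> float:
    """Mean per-marker alpha for one cell.

    ``records`` are the qPCR rows of a single cell; each marker's raw TPM is
    the sum over its gene group (e.g. HBG = HBG1 + HBG2). Markers whose
    nuclear TPM is zero (ratio undefined) are skipped with a warning; at
    least one usable marker is required.
    """
    if not records:
        raise ValueError("no qPCR records supplied")
    cells = {r.cell for r in records}
    if len(cells) != 1:
        raise ValueError(f"records span multiple cells: {sorted(cells)}")
    cell = records[0].cell
    if cell not in cyt.cells or cell not in nuc.cells:
        raise ValueError(f"cell {cell!r} absent from expression matrices")
    groups = DEFAULT_MARKER_GROUPS if marker_groups is None else marker_groups
    # average replicate delta-Ct per marker first
    by_marker: dict[str, list[float]] = {}
    for r in records:
        by_marker.setdefault(r.marker_gene, []).append(r.delta_ct)
    alphas = []
    for marker, dcts in by_marker.items():
        genes = groups.get(marker, (marker,))
        tpm_c = _marker_tpm(cyt, genes, cell)
        tpm_n = _marker_tpm(nuc, genes, cell)
        if not np.isfinite(tpm_n) or tpm_n <= 0:
            logger.warning("cell %s: marker %s unusable (nuclear TPM %s); skipped",
                           cell, marker, tpm_n)
            continue
        alphas.append(alpha_for_marker(float(np.mean(dcts)), tpm_c, tpm_n))
    if not alphas:
        raise ValueError(f"cell {cell!r}: no usable qPCR marker")
    return float(np.mean(alphas))


def combine(raw_cyt_column: np.ndarray, raw_nuc_column: np.ndarray,
            alpha: float) -> np.ndarray:
    """Weighted recombination of one cell's raw compartment profiles.

    Both inputs are raw TPM vectors summing to 1e6, so the output
    ``alpha*cyt + (1-alpha)*nuc`` also sums to 1e6.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    c = np.asarray(raw_cyt_column, dtype=float)
    n = np.asarray(raw_nuc_column, dtype=float)
    if c.shape != n.shape:
        raise ValueError("compartment columns differ in length")
    return alpha * c + (1.0 - alpha) * n


def normalize(cyt: CompartmentMatrix, nuc: CompartmentMatrix,
              qpcr: list[QpcrRecord],
              marker_groups: dict[str, tuple[str, ...]] | None = None
              ) -> InSilicoResult:
    """Full in silico normalization over all shared cells.

    Genes are aligned on the union of the two indices (missing rows are
    zero); cells must match between the matrices and the qPCR records.
    """
    if not cyt.cells.equals(nuc.cells):
        shared = cyt.cells.intersection(nuc.cells)
        if len(shared) == 0:
            raise ValueError("matrices share no cells")
        logger.warning("matrices share %d/%d cells; restricting", len(shared),
                       max(len(cyt.cells), len(nuc.cells)))
    cells = cyt.cells.intersection(nuc.cells)
    genes = cyt.genes.union(nuc.genes, sort=False)
    cvals = cyt.values.reindex(index=genes, columns=cells, fill_value=0.0)
    nvals = nuc.values.reindex(index=genes, columns=cells, fill_value=0.0)

    by_cell: dict[str, list[QpcrRecord]] = {}
    for r in qpcr:
        by_cell.setdefault(r.cell, []).append(r)
    alphas = {}
    for cell in cells:
        if cell not in by_cell:
            raise ValueError(f"cell {cell!r}: no qPCR records")
        alphas[cell] = cell_alpha(by_cell[cell], cyt, nuc, marker_groups)
    alpha = pd.Series(alphas, name="alpha").loc[cells]

    cyt_scaled = cvals * alpha.values
    nuc_scaled = nvals * (1.0 - alpha.values)
    insilico = cyt_scaled + nuc_scaled
    logger.info("in silico normalization: %d cells, mean alpha %.3f",
                len(cells), float(alpha.mean()))
    return InSilicoResult(alpha=alpha, tpm_insilico=insilico,
                          tpm_cyt_scaled=cyt_scaled, tpm_nuc_scaled=nuc_scaled)


@dataclass
class AbundanceSummary:
    mean_alpha: float
    sd_alpha: float
    per_cell: pd.Series

    @property
    def mean_percent_cytoplasmic(self) -> float:
        return 100.0 * self.mean_alpha

    @property
    def mean_percent_nuclear(self) -> float:
        return 100.0 * (1.0 - self.mean_alpha)


def cytoplasmic_abundance_summary(result: InSilicoResult) -> AbundanceSummary:
    """Distribution of the per-cell cytoplasmic transcript fraction."""
    alpha = result.alpha
    if len(alpha) == 0:
        raise ValueError("empty in silico result")
    return AbundanceSummary(mean_alpha=float(alpha.mean()),
                            sd_alpha=float(alpha.std(ddof=1)) if len(alpha) > 1 else 0.0,
                            per_cell=alpha.copy())


def count_detected(matrix: pd.DataFrame | CompartmentMatrix,
                   threshold: float = 1.0) -> pd.Series:
    """Genes detected per cell at TPM strictly greater than ``threshold``."""
    values = matrix.values if isinstance(matrix, CompartmentMatrix) else matrix
    return (values > threshold).sum(axis=0)


def detection_venn(cyt: CompartmentMatrix, nuc: CompartmentMatrix,
                   threshold: float = 1.0) -> tuple[int, int, int]:
    """Detected-gene overlap between compartments: (cyt only, nuc only, both).

    A gene counts as detected in a compartment when its mean TPM across cells
    exceeds ``threshold``.
    """
    genes = cyt.genes.union(nuc.genes, sort=False)
    c = cyt.values.reindex(genes, fill_value=0.0).mean(axis=1) > threshold
    n = nuc.values.reindex(genes, fill_value=0.0).mean(axis=1) > threshold
    both = int((c & n).sum())
    return int((c & ~n).sum()), int((~c & n).sum()), both
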