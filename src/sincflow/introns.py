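"""Intron retention: per-cell RI calling, NRI/CRI probabilities, splice sites.

Within each cell and compartment an intron is called *retained* when it is
expressed at >= 10% of its gene, covered over >= 95% of its length, and the
adjacent exon is expressed; *fully spliced* when it is expressed at < 1% of
the gene and the adjacent exon is covered over >= 50%; anything else — or any
intron on a gene below 2 TPM in that cell/compartment — is discarded. The
retention probability of an intron in a compartment is the fraction of
assessable (non-discarded) cells in which it is retained. An intron whose
retention probability is at least 0.25 higher in the nucleus than in the
cytoplasm is a nuclear-retained intron (NRI); the mirror-image call is a
cytoplasmic one (CRI). Overlapping NRIs are reduced to the longest per
overlap chain. Splice-site strength is scored with a position-weight matrix
trained on the fully spliced introns (log2-odds against a uniform
background) on the 9-mer 5' window (exonic 3 + intronic 6) and the 23-mer 3'
window (intronic 20 + exonic 3).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CompartmentMatrix, IntronAnnotation
from .correlation import pearson_p_from_r

logger = logging.getLogger("sincflow")

BASES = "ACGT"


def intron_fpkm(fragment_count: float, length_nt: int,
                total_mapped_fragments: float) -> float:
    """Fragments per kilobase of intron per million mapped fragments."""
    if length_nt <= 0 or total_mapped_fragments <= 0:
        raise ValueError("length and total mapped fragments must be positive")
    return fragment_count / ((length_nt / 1e3) * (total_mapped_fragments / 1e6))


def classify(fpkm: float, intron_cov_frac: float, adj_exon_expr: float,
             adj_exon_cov_frac: float, gene_expression: float,
             min_gene_tpm: float = 2.0, ri_min_ratio: float = 0.10,
             ri_min_intron_cov: float = 0.95, spliced_max_ratio: float = 0.01,
             spliced_min_exon_cov: float = 0.50) -> str:
    """Classify one (intron, cell, compartment) as retained/spliced/discarded.

    ``gene_expression`` is the host gene's expression in the same cell and
    compartment on the same per-kilobase-per-million scale as the intron
    FPKM; genes below ``min_gene_tpm`` are discarded outright.
    """
    if not np.isfinite(gene_expression):
        raise ValueError("gene expression missing")
    if gene_expression < min_gene_tpm:
        return "discarded"
    ratio = fpkm / gene_expression
    if ratio >= ri_min_ratio and intron_cov_frac >= ri_min_intron_cov \
            and adj_exon_expr > 0:
        return "retained"
    if ratio < spliced_max_ratio and adj_exon_cov_frac >= spliced_min_exon_cov:
        return "spliced"
    return "discarded"


def classify_table(quant: pd.DataFrame, gene_tpm: dict[str, CompartmentMatrix],
                   **thresholds) -> pd.DataFrame:
    """Vector version of :func:`classify` over a long-format quant table.

    ``gene_tpm`` maps compartment -> CompartmentMatrix used to look up the
    host gene's expression. Adds a ``state`` column.
    """
    states = []
    for row in quant.itertuples():
        mat = gene_tpm[row.compartment]
        if row.gene_id not in mat.genes:
            raise KeyError(f"gene {row.gene_id!r} missing from {row.compartment} "
                           "matrix")
        expr = float(mat.values.at[row.gene_id, row.cell_id])
        states.append(classify(row.fpkm, row.intron_cov_frac, row.adj_exon_expr,
                               row.adj_exon_cov_frac, expr, **thresholds))
    out = quant.copy()
    out["state"] = states
    return out


def retention_probability(states: pd.Series | list[str]) -> float:
    """Fraction of assessable cells with the retained call; NaN if none."""
    s = pd.Series(states)
    assessable = s.isin(["retained", "spliced"])
    if assessable.sum() == 0:
        return float("nan")
    return float((s == "retained").sum() / assessable.sum())


def call_nri_cri(p_nuc: float, p_cyt: float, delta: float = 0.25) -> str:
    """NRI when p_nuc - p_cyt >= delta, CRI when <= -delta, else neither."""
    if np.isnan(p_nuc) or np.isnan(p_cyt):
        return "neither"
    gap = p_nuc - p_cyt
    if gap >= delta:
        return "NRI"
    if gap <= -delta:
        return "CRI"
    return "neither"


def nri_table(calls: pd.DataFrame, delta: float = 0.25) -> pd.DataFrame:
    """Per-intron retention probabilities and NRI/CRI class.

    ``calls`` must carry intron_id, gene_id, cell_id, compartment, state.
    """
    rows = []
    for (intron_id, gene_id), grp in calls.groupby(["intron_id", "gene_id"],
                                                   sort=True):
        p_nuc = retention_probability(grp.loc[grp.compartment == "nuc", "state"])
        p_cyt = retention_probability(grp.loc[grp.compartment == "cyt", "state"])
        rows.append({"intron_id": intron_id, "gene_id": gene_id,
                     "p_nuc": p_nuc, "p_cyt": p_cyt,
                     "delta": p_nuc - p_cyt,
                     "class": call_nri_cri(p_nuc, p_cyt, delta)})
    return pd.DataFrame(rows)


def filter_unique(nris: pd.DataFrame,
                  annotations: dict[str, IntronAnnotation]) -> pd.DataFrame:
    """Greedy longest-first resolution of overlapping NRIs.

    Among NRIs on the same chromosome and strand whose half-open intervals
    overlap, only the longest is flagged unique (ties: leftmost start, then
    lexicographic id). The result is independent of the input row order.
    """
    out = nris.copy()
    out["unique"] = False
    cand = out[out["class"] == "NRI"]
    anns = []
    for iid in cand["intron_id"]:
        if iid not in annotations:
            raise KeyError(f"NRI {iid!r} lacks an annotation")
        anns.append(annotations[iid])
    order = sorted(
        anns, key=lambda a: (-(a.length_nt), a.start, a.intron_id))
    kept: dict[tuple[str, str], list[IntronAnnotation]] = {}
    unique_ids = set()
    for a in order:
        key = (a.chrom, a.strand)
        clash = any(a.start < b.end and b.start < a.end
                    for b in kept.get(key, []))
        if not clash:
            kept.setdefault(key, []).append(a)
            unique_ids.add(a.intron_id)
    out.loc[out["intron_id"].isin(unique_ids), "unique"] = True
    logger.info("filter_unique: %d/%d NRIs unique", len(unique_ids), len(cand))
    return out


def nri_expression_correlation(calls: pd.DataFrame, expression: CompartmentMatrix,
                               nris: pd.DataFrame, compartment: str,
                               min_cells_per_group: int = 2
                               ) -> tuple[float, float, pd.DataFrame]:
    """Relate NRI probability to the retained-vs-spliced expression shift.

    For each NRI gene, the log2 fold change (pseudo-count 1) of mean gene
    expression between cells where the intron is retained and cells where it
    is spliced, within ``compartment``; then the Pearson r (with
    t-approximation p) between the retention probability and that fold
    change across introns. Introns with fewer than ``min_cells_per_group``
    cells in either group are excluded and logged.
    """
    pcol = "p_nuc" if compartment == "nuc" else "p_cyt"
    sub = calls[calls["compartment"] == compartment]
    rows = []
    dropped = 0
    for row in nris[nris["class"] == "NRI"].itertuples():
        grp = sub[sub["intron_id"] == row.intron_id]
        ret_cells = grp.loc[grp.state == "retained", "cell_id"]
        spl_cells = grp.loc[grp.state == "spliced", "cell_id"]
        if len(ret_cells) < min_cells_per_group or len(spl_cells) < min_cells_per_group:
            dropped += 1
            continue
        expr = expression.values.loc[row.gene_id]
        fc = np.log2((expr[ret_cells].mean() + 1.0) / (expr[spl_cells].mean() + 1.0))
        rows.append({"intron_id": row.intron_id, "gene_id": row.gene_id,
                     "p_retention": getattr(row, pcol), "log2fc": fc})
    if dropped:
        logger.info("nri_expression_correlation: %d introns excluded "
                    "(< %d cells in a group)", dropped, min_cells_per_group)
    table = pd.DataFrame(rows)
    if len(table) < 2:
        raise ValueError("correlation undefined with fewer than 2 NRI genes")
    r = float(stats.pearsonr(table["p_retention"], table["log2fc"]).statistic)
    p = float(pearson_p_from_r(np.array([r]), len(table))[0])
    return r, p, table


# ---------------------------------------------------------------------------
# splice-site position-weight-matrix scoring
# ---------------------------------------------------------------------------

@dataclass
class SpliceSitePwm:
    """Log2-odds PWM against a uniform background, one per window length."""

    log_odds: np.ndarray  # (length, 4) in A, C, G, T order

    @property
    def length(self) -> int:
        return self.log_odds.shape[0]

    def score(self, seq: str) -> float:
        seq = seq.upper()
        if len(seq) != self.length:
            raise ValueError(
                f"sequence length {len(seq)} does not match PWM length "
                f"{self.length}")
        total = 0.0
        for pos, base in enumerate(seq):
            idx = BASES.find(base)
            if idx < 0:
                raise ValueError(f"non-ACGT base {base!r} at position {pos}")
            total += self.log_odds[pos, idx]
        return total


def train_pwm(sequences: list[str], pseudocount: float = 0.5) -> SpliceSitePwm:
    """Train a PWM from equal-length training sequences.

    Base frequencies per position get ``pseudocount`` added per base; scores
    are log2(freq / 0.25).
    """
    if not sequences:
        raise ValueError("empty training set")
    length = len(sequences[0])
    if any(len(s) != length for s in sequences):
        raise ValueError("training sequences differ in length")
    counts = np.full((length, 4), pseudocount, dtype=float)
    for seq in sequences:
        for pos, base in enumerate(seq.upper()):
            idx = BASES.find(base)
            if idx < 0:
                raise ValueError(f"non-ACGT base {base!r} in training sequence")
            counts[pos, idx] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)
    return SpliceSitePwm(log_odds=np.log2(freqs / 0.25))


def splice_site_scores(five: dict[str, str], three: dict[str, str],
                       training_ids: list[str],
                       pseudocount: float = 0.5) -> pd.DataFrame:
    """Score every intron's 5' 9-mer and 3' 23-mer against spliced-intron PWMs.

    ``training_ids`` are the fully spliced introns whose sequences define the
    PWMs. Returns a table (intron_id, score5, score3).
    """
    train5 = [five[i] for i in training_ids if i in five]
    train3 = [three[i] for i in training_ids if i in three]
    if not train5 or not train3:
        raise ValueError("training set has no sequences")
    pwm5 = train_pwm(train5, pseudocount)
    pwm3 = train_pwm(train3, pseudocount)
    ids = sorted(set(five) & set(three))
    return pd.DataFrame({
        "intron_id": ids,
        "score5": [pwm5.score(five[i]) for i in ids],
        "score3": [pwm3.score(three[i]) for i in ids],
    })


def compare_splice_scores(scores: pd.DataFrame, ri_ids: set[str],
                          spliced_ids: set[str],
                          which: str = "score5") -> tuple[float, float]:
    """One-sided Mann-Whitney U: are retained-intron scores lower?

    Returns (U, p) for the alternative that the RI group's splice-site
    scores are stochastically smaller than the fully spliced group's.
    """
    ri = scores.loc[scores["intron_id"].isin(ri_ids), which]
    spl = scores.loc[scores["intron_id"].isin(spliced_ids), which]
    if len(ri) == 0 or len(spl) == 0:
        raise ValueError("empty group in splice-score comparison")
    res = stats.mannwhitneyu(ri, spl, alternative="less")
    return float(res.statistic), float(res.pvalue)
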