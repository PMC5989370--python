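"""Synthetic paired nuclear/cytoplasmic single-cell experiments.

The generator emits everything the pipeline consumes — paired compartment
TPM matrices, per-cell qPCR delta-Ct records for the marker genes, a
per-intron quantification table, splice-site sequences, and a pseudotime
ordering — together with the planted ground truth each stage should recover.

Generative model (all distributions are artifact choices; the original assay
defines no generative model):

1. per-gene log10 mean expression mu_g ~ Normal(1, 1); the qPCR markers
   (GAPDH, HBG1, HBG2) get fixed high means as in real cells;
2. latent nuclear transcription t_gc = mu_g + a_g cos(theta_c [+ pi for G2])
   for cell-cycle genes + b_g tau_c for trajectory genes + Normal(0, sigma_t);
3. cytoplasmic log abundance mixes the nuclear latent with an independent
   one of the same marginal through the planted coupling rho_g (negative
   coupling negates the centered latent); for trajectory genes the cytoplasm
   tracks the nucleus at the earlier pseudotime tau_c * (1 - lag), so the
   nucleus leads and the compartment divergence grows along the trajectory;
4. per-cell cytoplasmic abundances are rescaled so the true cytoplasmic
   transcript fraction equals f_c, and reads are drawn multinomially (L per
   compartment per cell) from the abundance simplex; TPM = count / L * 1e6
   (unit gene length), so generated TPM columns sum to exactly 1e6;
5. marker delta-Ct = log2(absolute cyt marker abundance / absolute nuc
   marker abundance) + Normal(0, sigma_ct) — defined on absolute abundance so
   the qPCR-based alpha is a consistent estimator of f_c;
6. introns: planted nuclear-retained introns draw their per-cell retained
   state with probability p_nuc (tilted by the gene's nuclear expression) in
   the nucleus and p_cyt in the cytoplasm, with p_nuc - p_cyt >= 0.25 +
   margin; background introns share one retention probability between
   compartments. Retained introns get ~10-50% of gene expression and >= 95%
   intronic coverage; spliced introns < 1% and well-covered adjacent exons;
7. splice-site 9-mers/23-mers are sampled from a strong consensus
   position-probability model (GT..AG cores) for spliced introns and from a
   weakened model for the planted NRIs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .config import SimConfig
from .containers import (CompartmentMatrix, GroundTruth, IntronAnnotation,
                         PseudotimeOrdering, QpcrRecord)

logger = logging.getLogger("sincflow")

MARKER_GENES = ("GAPDH", "HBG1", "HBG2")
MARKER_LOG_MEANS = {"GAPDH": 3.0, "HBG1": 2.5, "HBG2": 2.5}

BASES = np.array(list("ACGT"))

# 5' window: exonic 3-mer + intronic 6-mer; intron starts with GT.
FIVE_PRIME_CONSENSUS = "CAG" + "GTAAGT"
# 3' window: intronic 20-mer (polypyrimidine tract ending in AG) + exonic 3-mer.
THREE_PRIME_CONSENSUS = "TTTTTTTTTTTTTTTCTCAG" + "GTG"


@dataclass
class SyntheticExperiment:
    cyt: CompartmentMatrix
    nuc: CompartmentMatrix
    qpcr: list[QpcrRecord]
    intron_quant: pd.DataFrame
    intron_annotations: list[IntronAnnotation]
    splice_5p: dict[str, str]
    splice_3p: dict[str, str]
    pseudotime: PseudotimeOrdering
    truth: GroundTruth


def _site_probs(consensus: str, core: slice, core_p: float, flank_p: float,
                flatten: float = 0.0) -> np.ndarray:
    """Per-position base probabilities around a consensus string.

    ``flatten`` mixes toward uniform (0 = full strength, 1 = uniform).
    """
    probs = np.empty((len(consensus), 4))
    core_idx = set(range(*core.indices(len(consensus))))
    for pos, base in enumerate(consensus):
        p = core_p if pos in core_idx else flank_p
        row = np.full(4, (1 - p) / 3)
        row[list("ACGT").index(base)] = p
        probs[pos] = (1 - flatten) * row + flatten * 0.25
    return probs


def strong_site_probs() -> tuple[np.ndarray, np.ndarray]:
    five = _site_probs(FIVE_PRIME_CONSENSUS, slice(3, 5), 0.99, 0.70)
    three = _site_probs(THREE_PRIME_CONSENSUS, slice(18, 20), 0.99, 0.55)
    return five, three


def weak_site_probs() -> tuple[np.ndarray, np.ndarray]:
    five = _site_probs(FIVE_PRIME_CONSENSUS, slice(3, 5), 0.70, 0.70,
                       flatten=0.55)
    three = _site_probs(THREE_PRIME_CONSENSUS, slice(18, 20), 0.70, 0.55,
                        flatten=0.55)
    return five, three


def _sample_site(probs: np.ndarray, rng: np.random.Generator) -> str:
    return "".join(BASES[rng.choice(4, p=row)] for row in probs)


def simulate_experiment(sim: SimConfig | None = None,
                        seed: int = 0) -> SyntheticExperiment:
    """Generate one paired-compartment experiment with planted ground truth."""
    sim = sim or SimConfig()
    rng = np.random.default_rng(seed)
    G, M = sim.n_genes, sim.n_cells
    if G < len(MARKER_GENES) + sim.n_cellcycle + sim.n_deg:
        raise ValueError("n_genes too small for the requested gene classes")

    genes = list(MARKER_GENES) + [f"gene{i:05d}" for i in range(G - 3)]
    cells = [f"cell{i:03d}" for i in range(M)]

    mu = rng.normal(sim.log_mean_loc, sim.log_mean_scale, size=G)
    for g, m in MARKER_LOG_MEANS.items():
        mu[genes.index(g)] = m

    # gene classes (disjoint): cell-cycle G1/G2, trajectory DEGs
    assignable = rng.permutation(np.arange(3, G))
    n_half = sim.n_cellcycle // 2
    g1_idx = assignable[:n_half]
    g2_idx = assignable[n_half:2 * n_half]
    deg_idx = assignable[2 * n_half:2 * n_half + sim.n_deg]

    # planted coupling: cycle/DEG/marker genes strongly coupled; the rest
    # span the whole range, with 15% exact-zero couplings as a planted null
    # class for false-positive calibration
    rho = rng.uniform(-1.0, 1.0, size=G)
    rho[rng.random(G) < 0.15] = 0.0
    rho[:3] = 0.95
    rho[g1_idx] = 0.95
    rho[g2_idx] = 0.95
    rho[deg_idx] = 0.9

    theta = rng.uniform(0, 2 * np.pi, size=M)
    if sim.n_deg:
        # sampling-day design: cells collected on n_days discrete days with
        # small within-day spread, as in a perturbation time course
        days = rng.permutation(np.arange(M) % sim.n_days)
        tau = np.clip(days / (sim.n_days - 1)
                      + rng.normal(0, 0.04, size=M), 0.0, 1.0)
    else:
        tau = rng.uniform(0, 1, size=M)
    if sim.cyt_fraction_sd > 0:
        f_c = np.clip(rng.normal(sim.cyt_fraction, sim.cyt_fraction_sd, size=M),
                      0.05, 0.95)
    else:
        f_c = np.full(M, sim.cyt_fraction)
    if ((f_c <= 0) | (f_c >= 1)).any():
        raise ValueError("cytoplasmic fractions must lie in (0, 1)")

    osc = np.zeros((G, M))
    osc[g1_idx] = sim.oscillation_amplitude * np.cos(theta)
    osc[g2_idx] = sim.oscillation_amplitude * np.cos(theta + np.pi)

    # compartment-specific trajectory responses: DEGs respond in both
    # compartments, only the cytoplasm, or only the nucleus (the original
    # assay saw far more cytoplasmic than nuclear DEGs), so the profiles
    # genuinely diverge along the trajectory
    b_nuc = np.zeros(G)
    b_cyt = np.zeros(G)
    if sim.n_deg:
        sign = rng.choice([-1.0, 1.0], size=sim.n_deg) * sim.deg_effect
        pattern = rng.choice(3, size=sim.n_deg, p=[0.6, 0.25, 0.15])
        b_nuc[deg_idx] = np.where(pattern != 1, sign, 0.0)   # both or nuc-only
        b_cyt[deg_idx] = np.where(pattern != 2, sign, 0.0)   # both or cyt-only
    traj_nuc = b_nuc[:, None] * tau[None, :]
    # cytoplasm tracks the nucleus at the earlier pseudotime tau*(1 - lag):
    # the nucleus leads, and the compartment divergence grows along tau
    traj_cyt = b_cyt[:, None] * (tau[None, :] * (1.0 - sim.deg_lag))

    delta = rng.normal(0, sim.sigma_t, size=(G, M))
    u = rng.normal(0, sim.sigma_t, size=(G, M))
    w = np.abs(rho)[:, None]
    s = np.sign(rho)[:, None]

    log_nuc = mu[:, None] + osc + traj_nuc + delta \
        + rng.normal(0, sim.sigma_eps, size=(G, M))
    log_cyt = mu[:, None] + osc + traj_cyt + s * w * delta + (1 - w) * u \
        + rng.normal(0, sim.sigma_eps, size=(G, M))

    nuc_abs = 10.0 ** log_nuc
    cyt_abs = 10.0 ** log_cyt
    kappa = (f_c / (1 - f_c)) * nuc_abs.sum(axis=0) / cyt_abs.sum(axis=0)
    cyt_abs = cyt_abs * kappa[None, :]

    L = int(sim.reads_per_compartment)
    cyt_counts = np.empty((G, M))
    nuc_counts = np.empty((G, M))
    for j in range(M):
        cyt_counts[:, j] = rng.multinomial(L, cyt_abs[:, j] / cyt_abs[:, j].sum())
        nuc_counts[:, j] = rng.multinomial(L, nuc_abs[:, j] / nuc_abs[:, j].sum())
    cyt_tpm = cyt_counts / L * 1e6
    nuc_tpm = nuc_counts / L * 1e6

    cyt = CompartmentMatrix(pd.DataFrame(cyt_tpm, index=genes, columns=cells),
                            "cyt")
    nuc = CompartmentMatrix(pd.DataFrame(nuc_tpm, index=genes, columns=cells),
                            "nuc")

    # qPCR on absolute marker abundance
    qpcr: list[QpcrRecord] = []
    marker_rows = {"GAPDH": [genes.index("GAPDH")],
                   "HBG": [genes.index("HBG1"), genes.index("HBG2")]}
    for j, cell in enumerate(cells):
        for marker, rows in marker_rows.items():
            dct = float(np.log2(cyt_abs[rows, j].sum() / nuc_abs[rows, j].sum())
                        + rng.normal(0, sim.sigma_ct))
            qpcr.append(QpcrRecord(cell=cell, marker_gene=marker, delta_ct=dct))

    introns = _simulate_introns(sim, rng, genes, cells, mu, log_nuc,
                                cyt, nuc)
    quant, annotations, five, three, nri_truth, bg_truth = introns

    truth = GroundTruth(
        cytoplasmic_fraction=pd.Series(f_c, index=cells),
        coupling=pd.Series(rho, index=genes),
        g1_genes=[genes[i] for i in g1_idx],
        g2_genes=[genes[i] for i in g2_idx],
        phase=pd.Series(theta, index=cells),
        nri_introns=nri_truth,
        background_introns=bg_truth,
        deg_genes=pd.DataFrame({"gene_id": [genes[i] for i in deg_idx],
                                "effect_cyt": b_cyt[deg_idx],
                                "effect_nuc": b_nuc[deg_idx]}),
        pseudotime=pd.Series(tau, index=cells),
    )
    return SyntheticExperiment(
        cyt=cyt, nuc=nuc, qpcr=qpcr, intron_quant=quant,
        intron_annotations=annotations, splice_5p=five, splice_3p=three,
        pseudotime=PseudotimeOrdering(cells=list(cells), pseudotime=tau),
        truth=truth)


def _simulate_introns(sim: SimConfig, rng: np.random.Generator,
                      genes: list[str], cells: list[str], mu: np.ndarray,
                      log_nuc: np.ndarray, cyt: CompartmentMatrix,
                      nuc: CompartmentMatrix):
    """Plant NRI and background introns on well-expressed host genes."""
    n_introns = sim.n_nri + sim.n_background_introns
    if n_introns == 0:
        empty = pd.DataFrame(columns=sio.INTRON_QUANT_COLUMNS)
        return empty, [], {}, {}, None, None
    # host genes: well-expressed non-marker genes so the 2-TPM floor rarely bites
    candidates = [i for i in np.argsort(mu)[::-1]
                  if genes[i] not in MARKER_GENES][:max(n_introns, 1)]
    if len(candidates) < n_introns:
        raise ValueError("not enough genes to host the requested introns")
    hosts = rng.permutation(np.array(candidates))[:n_introns]

    strong5, strong3 = strong_site_probs()
    weak5, weak3 = weak_site_probs()

    annotations: list[IntronAnnotation] = []
    five: dict[str, str] = {}
    three: dict[str, str] = {}
    rows = []
    nri_rows = []
    bg_rows = []
    M = len(cells)
    for k, gidx in enumerate(hosts):
        is_nri = k < sim.n_nri
        intron_id = f"intr{k:05d}"
        gene_id = genes[gidx]
        start = 10_000 * k + int(rng.integers(0, 2_000))
        length = int(rng.integers(200, 2_000))
        annotations.append(IntronAnnotation(
            intron_id=intron_id, gene_id=gene_id, chrom="chr1",
            start=start, end=start + length,
            strand="+" if rng.random() < 0.5 else "-"))
        if is_nri:
            p_nuc = float(rng.uniform(0.65, 0.95))
            gap = 0.25 + sim.nri_gap_margin + float(rng.uniform(0, 0.15))
            p_cyt = p_nuc - gap
            five[intron_id] = _sample_site(weak5, rng)
            three[intron_id] = _sample_site(weak3, rng)
            nri_rows.append({"intron_id": intron_id, "gene_id": gene_id,
                             "p_nuc": p_nuc, "p_cyt": p_cyt})
        else:
            p_nuc = p_cyt = float(rng.uniform(0.05, 0.5))
            five[intron_id] = _sample_site(strong5, rng)
            three[intron_id] = _sample_site(strong3, rng)
            bg_rows.append({"intron_id": intron_id, "gene_id": gene_id,
                            "p_nuc": p_nuc, "p_cyt": p_cyt})

        # expression tilt: stronger NRIs are retained preferentially in cells
        # with high nuclear expression of the host gene
        z = log_nuc[gidx] - log_nuc[gidx].mean()
        sd = z.std()
        z = z / sd if sd > 0 else z
        gamma = sim.nri_expression_coupling * p_nuc if is_nri else 0.0
        for comp, mat, p_base in (("nuc", nuc, p_nuc), ("cyt", cyt, p_cyt)):
            p_cells = np.clip(p_base + (gamma * z if comp == "nuc" else 0.0),
                              0.02, 0.98)
            retained = rng.random(M) < p_cells
            gene_tpm = mat.values.iloc[gidx].to_numpy()
            for j, cell in enumerate(cells):
                gt = gene_tpm[j]
                if retained[j]:
                    fpkm = float(rng.uniform(0.10, 0.5)) * gt
                    icov = float(rng.uniform(0.95, 1.0))
                    ecov = float(rng.uniform(0.5, 1.0))
                else:
                    fpkm = float(rng.uniform(0.0, 0.01)) * gt
                    icov = float(rng.uniform(0.0, 0.5))
                    ecov = float(rng.uniform(0.5, 1.0))
                rows.append((intron_id, gene_id, cell, comp, fpkm, icov,
                             gt, ecov))
    quant = pd.DataFrame(rows, columns=sio.INTRON_QUANT_COLUMNS)
    return (quant, annotations, five, three,
            pd.DataFrame(nri_rows) if nri_rows else None,
            pd.DataFrame(bg_rows) if bg_rows else None)


def unperturbed_config(**overrides) -> SimConfig:
    """Standard-culture conditions: oscillation and introns, no trajectory."""
    return dataclasses.replace(SimConfig(), n_deg=0, **overrides)


def perturbed_config(**overrides) -> SimConfig:
    """Differentiation conditions: 41 cells with compartment-divergent DEGs.

    The divergence analyses do not consume introns, so none are planted.
    """
    defaults = dict(n_cells=41, n_deg=100, n_nri=0, n_background_introns=0)
    defaults.update(overrides)
    return dataclasses.replace(SimConfig(), **defaults)


def write_experiment(exp: SyntheticExperiment, outdir: str | Path) -> None:
    """Serialize every generated artifact in the pipeline's on-disk formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sio.write_compartment_matrix(exp.cyt, outdir / "cyt_tpm.tsv")
    sio.write_compartment_matrix(exp.nuc, outdir / "nuc_tpm.tsv")
    sio.write_qpcr(exp.qpcr, outdir / "qpcr.tsv")
    sio.write_pseudotime(exp.pseudotime, outdir / "pseudotime.tsv")
    if len(exp.intron_quant):
        sio.write_intron_quant(exp.intron_quant, outdir / "intron_quant.tsv")
        sio.write_intron_annotation(exp.intron_annotations,
                                    outdir / "introns.bed")
        sio.write_splice_sites(exp.splice_5p, exp.splice_3p,
                               outdir / "splice_sites.fa")
    sio.write_gene_sets(exp.truth.g1_genes, exp.truth.g2_genes,
                        outdir / "cellcycle_sets.tsv")
    truth_dir = outdir / "truth"
    truth_dir.mkdir(exist_ok=True)
    exp.truth.cytoplasmic_fraction.rename("f_cyt").to_csv(
        truth_dir / "cyt_fraction.tsv", sep="\t", index_label="cell_id")
    exp.truth.coupling.rename("rho").to_csv(
        truth_dir / "coupling.tsv", sep="\t", index_label="gene_id")
    if exp.truth.nri_introns is not None:
        exp.truth.nri_introns.to_csv(truth_dir / "nri.tsv", sep="\t",
                                     index=False)
    if exp.truth.deg_genes is not None and len(exp.truth.deg_genes):
        exp.truth.deg_genes.to_csv(truth_dir / "degs.tsv", sep="\t",
                                   index=False)
    meta = {"g1_genes": exp.truth.g1_genes, "g2_genes": exp.truth.g2_genes}
    (truth_dir / "gene_sets.json").write_text(json.dumps(meta, indent=1))
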