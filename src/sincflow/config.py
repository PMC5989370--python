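"""Run configuration: every pipeline threshold in one dataclass, YAML-backed.

All randomness in the package flows from ``RunConfig.seed``; CLI runs log it.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

logger = logging.getLogger("sincflow")

DEFAULT_SEED = 1729


@dataclass
class SimConfig:
    """Synthetic-experiment parameters (the planted study conditions)."""

    n_genes: int = 2000
    n_cells: int = 60
    reads_per_compartment: int = 200_000
    log_mean_loc: float = 1.0          # per-gene log10 mean expression
    log_mean_scale: float = 1.0
    sigma_t: float = 0.5               # cell-to-cell latent sd, log10 dex
    sigma_eps: float = 0.05            # technical lognormal noise, log10 dex
    cyt_fraction: float = 0.84         # true cytoplasmic transcript fraction
    cyt_fraction_sd: float = 0.02
    sigma_ct: float = 0.1              # qPCR delta-Ct noise, cycles
    n_cellcycle: int = 60              # split evenly into G1 and G2 sets
    oscillation_amplitude: float = 0.5 # a_g, log10 dex
    n_deg: int = 0                     # trajectory-responsive genes
    deg_effect: float = 1.0            # |b_g|, log10 dex over unit pseudotime
    deg_lag: float = 0.4               # cytoplasmic lag, fraction of pseudotime
    n_days: int = 5                    # sampling days of the perturbation course
    n_nri: int = 100                   # planted nuclear-retained introns
    n_background_introns: int = 200
    nri_gap_margin: float = 0.15       # planted p_nuc - p_cyt >= 0.25 + margin
    nri_expression_coupling: float = 0.2


@dataclass
class RunConfig:
    """Thresholds and switches for every analysis stage."""

    seed: int = DEFAULT_SEED
    detection_tpm: float = 1.0         # detected iff TPM > detection_tpm
    min_gene_tpm: float = 2.0          # intron reads on genes below are discarded
    ri_min_ratio: float = 0.10         # intron/gene expression for a retained call
    ri_min_intron_cov: float = 0.95
    spliced_max_ratio: float = 0.01
    spliced_min_exon_cov: float = 0.50
    nri_delta: float = 0.25            # retention-probability gap for NRI/CRI
    min_intron_length: int = 50        # keep introns strictly longer than this
    landscape_min_cells: int = 5       # TPM>1 in >= this many cells, both compartments
    correlation_method: str = "pearson"  # or "spearman"
    de_p_threshold: float = 1e-3
    de_lfc_threshold: float = 1.0
    dispersion_floor: float = 1e-8
    pwm_pseudocount: float = 0.5
    n_pseudotime_bins: int = 5
    bootstrap_resamples: int = 1000
    pca_scale_unit_variance: bool = False
    pseudotime_reverse: bool = False
    sim: SimConfig = field(default_factory=SimConfig)


def _fields(cls) -> set[str]:
    return {f.name for f in dataclasses.fields(cls)}


def read_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from YAML; unknown keys raise with the valid key list."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    sim_raw = raw.pop("sim", {}) or {}
    unknown = set(raw) - _fields(RunConfig)
    if unknown:
        raise ValueError(
            f"unknown config keys {sorted(unknown)}; "
            f"valid keys: {sorted(_fields(RunConfig))}")
    unknown_sim = set(sim_raw) - _fields(SimConfig)
    if unknown_sim:
        raise ValueError(
            f"unknown sim config keys {sorted(unknown_sim)}; "
            f"valid keys: {sorted(_fields(SimConfig))}")
    cfg = RunConfig(sim=SimConfig(**sim_raw), **raw)
    if "seed" not in raw:
        logger.info("config omits seed; using default seed %d", cfg.seed)
    return cfg


def write_config(cfg: RunConfig, path: str | Path) -> None:
    data = dataclasses.asdict(cfg)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
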