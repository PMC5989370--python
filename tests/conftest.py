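import numpy as np
import pandas as pd
import pytest

import sincflow as sf


@pytest.fixture(scope="session")
def unperturbed_exp() -> sf.SyntheticExperiment:
    """Standard-culture synthetic experiment: oscillation + planted introns."""
    return sf.simulate_experiment(sf.unperturbed_config(), seed=11)


@pytest.fixture(scope="session")
def perturbed_exp() -> sf.SyntheticExperiment:
    """Perturbation time-course experiment with compartment-divergent DEGs."""
    return sf.simulate_experiment(sf.perturbed_config(), seed=7)


@pytest.fixture(scope="session")
def unperturbed_calls(unperturbed_exp) -> pd.DataFrame:
    exp = unperturbed_exp
    return sf.classify_table(exp.intron_quant,
                             {"cyt": exp.cyt, "nuc": exp.nuc})


def make_matrix(values, genes, cells, compartment="cyt", check=False):
    return sf.CompartmentMatrix(
        pd.DataFrame(np.asarray(values, dtype=float), index=genes,
                     columns=cells),
        compartment, check_tpm_sum=check)


# shared hand-built fixtures -------------------------------------------------

# (fpkm, intron_cov, exon_expr, exon_cov, gene_tpm) -> expected state
CLASSIFY_CASES = [
    ((1.5, 0.96, 5.0, 0.8, 10.0), "retained"),    # 15% ratio, covered
    ((0.05, 0.3, 5.0, 0.6, 10.0), "spliced"),     # 0.5% ratio, exon covered
    ((1.5, 0.96, 5.0, 0.8, 1.5), "discarded"),    # gene below 2 TPM
    ((1.0, 0.96, 5.0, 0.8, 10.0), "retained"),    # ratio exactly 10%
    ((0.99, 0.96, 5.0, 0.8, 10.0), "discarded"),  # ratio just under 10%
    ((1.5, 0.94, 5.0, 0.8, 10.0), "discarded"),   # intron coverage < 95%
    ((1.5, 0.95, 5.0, 0.8, 10.0), "retained"),    # coverage exactly 95%
    ((1.5, 0.96, 0.0, 0.8, 10.0), "discarded"),   # adjacent exon silent
    ((0.1, 0.3, 5.0, 0.6, 10.0), "discarded"),    # 1% ratio not < 1%
    ((0.05, 0.3, 5.0, 0.49, 10.0), "discarded"),  # exon coverage < 50%
    ((0.05, 0.3, 5.0, 0.50, 10.0), "spliced"),    # exon coverage at 50%
    ((0.5, 0.5, 5.0, 0.8, 10.0), "discarded"),    # between the two rules
]


def make_annotation(iid, start, end, chrom="chr1", strand="+"):
    return sf.IntronAnnotation(intron_id=iid, gene_id="g", chrom=chrom,
                               start=start, end=end, strand=strand)


def make_nri_frame(ids):
    return pd.DataFrame({"intron_id": ids, "gene_id": ["g"] * len(ids),
                         "p_nuc": [0.9] * len(ids), "p_cyt": [0.1] * len(ids),
                         "delta": [0.8] * len(ids), "class": ["NRI"] * len(ids)})
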