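import numpy as np
import pandas as pd
import pytest
from scipy import stats

import sincflow as sf
from sincflow.trajectory import bin_edges
from .conftest import make_matrix


def _align_signs(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Flip columns of b so each aligns with a (PCs have arbitrary sign)."""
    signs = np.sign(np.einsum("ij,ij->j", a, b))
    signs[signs == 0] = 1
    return b * signs


class TestLpca:
    def test_duplicated_compartment_is_scaled_conventional_pca(self):
        rng = np.random.default_rng(0)
        vals = pd.DataFrame(rng.lognormal(2, 1, (20, 10)),
                            index=[f"g{i}" for i in range(20)],
                            columns=[f"c{i}" for i in range(10)])
        cyt = sf.CompartmentMatrix(vals, "cyt", check_tpm_sum=False)
        nuc = sf.CompartmentMatrix(vals.copy(), "nuc", check_tpm_sum=False)
        lp = sf.lpca(cyt, nuc, list(vals.index))
        cp = sf.conventional_pca(cyt, list(vals.index))
        k = min(lp.scores.shape[1], cp.scores.shape[1])
        expected = _align_signs(lp.scores.to_numpy()[:, :k],
                                cp.scores.to_numpy()[:, :k] * np.sqrt(2))
        np.testing.assert_allclose(lp.scores.to_numpy()[:, :k], expected,
                                   atol=1e-8)

    def test_orthogonal_compartment_signals_both_captured(self):
        rng = np.random.default_rng(1)
        m, n = 12, 30
        t1 = np.cos(2 * np.pi * np.arange(m) / m)
        t2 = np.sin(2 * np.pi * np.arange(m) / m)  # orthogonal to t1
        base = rng.normal(3, 0.2, (n, 1)) * np.ones((m,))
        w1 = rng.normal(0, 0.5, n)
        w2 = rng.normal(0, 0.5, n)
        log_c = base + np.outer(w1, t1)
        log_n = base + np.outer(w2, t2)
        genes = [f"g{i}" for i in range(n)]
        cells = [f"c{i}" for i in range(m)]
        cyt = make_matrix(10.0 ** log_c - 1, genes, cells, "cyt")
        nuc = make_matrix(10.0 ** log_n - 1, genes, cells, "nuc")
        res = sf.lpca(cyt, nuc, genes)
        pcs = res.scores.to_numpy()[:, :2]
        for sig in (t1, t2):
            best = max(abs(np.corrcoef(pcs[:, j], sig)[0, 1]) for j in (0, 1))
            assert best > 0.95

    def test_constant_input_rejected(self):
        vals = pd.DataFrame(np.full((4, 5), 7.0),
                            index=list("abcd"), columns=[f"c{i}" for i in range(5)])
        cyt = sf.CompartmentMatrix(vals, "cyt", check_tpm_sum=False)
        nuc = sf.CompartmentMatrix(vals.copy(), "nuc", check_tpm_sum=False)
        with pytest.raises(ValueError, match="constant"):
            sf.lpca(cyt, nuc, list("abcd"))

    def test_explained_variance_ratios(self, perturbed_exp):
        exp = perturbed_exp
        genes = exp.truth.deg_genes["gene_id"].tolist()
        res = sf.lpca(exp.cyt, exp.nuc, genes)
        evr = res.explained_variance_ratio
        assert evr.sum() == pytest.approx(1.0)
        assert np.all(np.diff(evr) <= 1e-12)


class TestConventionalPca:
    def test_matches_covariance_eigendecomposition(self):
        rng = np.random.default_rng(2)
        vals = pd.DataFrame(rng.lognormal(2, 1, (15, 8)),
                            index=[f"g{i}" for i in range(15)],
                            columns=[f"c{i}" for i in range(8)])
        res = sf.conventional_pca(
            sf.CompartmentMatrix(vals, "cyt", check_tpm_sum=False),
            list(vals.index))
        x = np.log10(vals.to_numpy() + 1)
        xc = x - x.mean(axis=1, keepdims=True)
        cov = xc.T @ xc  # cell-space Gram matrix shares nonzero eigenvalues
        evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        var = res.explained_variance_ratio * evals.sum()
        np.testing.assert_allclose(var[: len(evals) - 1],
                                   evals[: len(evals) - 1], atol=1e-8)

    def test_too_few_cells_rejected(self):
        vals = pd.DataFrame(np.arange(8.0).reshape(4, 2),
                            index=list("abcd"), columns=["c1", "c2"])
        with pytest.raises(ValueError, match="cells"):
            sf.conventional_pca(
                sf.CompartmentMatrix(vals, "cyt", check_tpm_sum=False),
                list("abcd"))


class TestFallbackPseudotime:
    def test_planted_trajectory_recovered(self, perturbed_exp):
        exp = perturbed_exp
        res = sf.normalize(exp.cyt, exp.nuc, exp.qpcr)
        degs = exp.truth.deg_genes["gene_id"].tolist()
        refs = list(exp.truth.pseudotime.nsmallest(8).index)
        ordering = sf.fallback_pseudotime(res.tpm_insilico, degs,
                                          reference_cells=refs)
        rho = stats.spearmanr(
            ordering.pseudotime,
            exp.truth.pseudotime.loc[ordering.cells]).statistic
        assert rho >= 0.8

    def test_reverse_flips_ordering(self, perturbed_exp):
        exp = perturbed_exp
        res = sf.normalize(exp.cyt, exp.nuc, exp.qpcr)
        degs = exp.truth.deg_genes["gene_id"].tolist()
        fwd = sf.fallback_pseudotime(res.tpm_insilico, degs)
        rev = sf.fallback_pseudotime(res.tpm_insilico, degs, reverse=True)
        m = len(fwd.cells)
        np.testing.assert_array_equal(fwd.ranks, (m - 1) - rev.ranks)

    def test_external_ordering_preferred_over_fallback(self, tmp_path,
                                                       perturbed_exp):
        # plumbing: a supplied ordering file is read back verbatim
        from sincflow import io as sio
        out = tmp_path / "pt.tsv"
        sio.write_pseudotime(perturbed_exp.pseudotime, out)
        again = sio.read_pseudotime(out)
        assert again.ordered_cells() == perturbed_exp.pseudotime.ordered_cells()


class TestCellCrossCorrelation:
    def test_identical_matrices_have_unit_diagonal(self, perturbed_exp):
        exp = perturbed_exp
        genes = exp.truth.deg_genes["gene_id"].tolist()
        dup = sf.CompartmentMatrix(exp.nuc.values.copy(), "cyt",
                                   check_tpm_sum=False)
        ccm = sf.cell_cross_correlation(exp.nuc, dup, genes, exp.pseudotime)
        np.testing.assert_allclose(np.diag(ccm.matrix.to_numpy()), 1.0,
                                   atol=1e-12)

    def test_three_cell_toy_matches_hand_oracle(self):
        genes = ["a", "b", "c", "d"]
        cells = ["c1", "c2", "c3"]
        xn = np.array([[1.0, 5.0, 2.0], [9.0, 3.0, 8.0],
                       [4.0, 7.0, 1.0], [2.0, 2.0, 9.0]])
        xc = np.array([[3.0, 1.0, 6.0], [5.0, 9.0, 2.0],
                       [8.0, 4.0, 4.0], [1.0, 6.0, 7.0]])
        nuc = make_matrix(xn, genes, cells, "nuc")
        cyt = make_matrix(xc, genes, cells, "cyt")
        ordering = sf.PseudotimeOrdering(cells=cells,
                                         pseudotime=np.array([0.0, 1.0, 2.0]))
        ccm = sf.cell_cross_correlation(nuc, cyt, genes, ordering)
        ln, lc = np.log10(xn + 1), np.log10(xc + 1)
        for i in range(3):
            for j in range(3):
                expected = stats.pearsonr(ln[:, i], lc[:, j]).statistic
                assert ccm.matrix.iloc[i, j] == pytest.approx(expected,
                                                              abs=1e-12)

    def test_too_few_genes_rejected(self, perturbed_exp):
        exp = perturbed_exp
        with pytest.raises(ValueError, match="genes"):
            sf.cell_cross_correlation(exp.nuc, exp.cyt,
                                      ["GAPDH", "HBG1"], exp.pseudotime)

    def test_permutation_equivariance(self, perturbed_exp):
        exp = perturbed_exp
        genes = exp.truth.deg_genes["gene_id"].tolist()[:20]
        ccm = sf.cell_cross_correlation(exp.nuc, exp.cyt, genes,
                                        exp.pseudotime)
        rng = np.random.default_rng(3)
        # reassign pseudotimes at random: rows/columns must permute with the
        # cells, leaving every labelled entry unchanged
        shuffled = sf.PseudotimeOrdering(
            cells=exp.pseudotime.cells,
            pseudotime=rng.permutation(exp.pseudotime.pseudotime))
        ccm2 = sf.cell_cross_correlation(exp.nuc, exp.cyt, genes, shuffled)
        common = ccm.matrix.index
        pd.testing.assert_frame_equal(
            ccm2.matrix.loc[common, common], ccm.matrix,
            check_exact=False, atol=1e-9)


class TestBinning:
    def test_even_split(self):
        assert bin_edges(10, 5) == [(0, 2), (2, 4), (4, 6), (6, 8), (8, 10)]

    def test_remainder_goes_to_last_bins(self):
        edges = bin_edges(11, 5)
        sizes = [b - a for a, b in edges]
        assert sizes == [2, 2, 2, 2, 3]

    def test_constant_matrix_gives_equal_blocks(self):
        cells = [f"c{i}" for i in range(10)]
        mat = pd.DataFrame(np.full((10, 10), 0.5), index=cells, columns=cells)
        ccm = sf.trajectory.CrossCorrMatrix(
            matrix=mat, ordering=sf.PseudotimeOrdering(
                cells=cells, pseudotime=np.arange(10.0)))
        grid, disp = sf.bin_and_summarize(ccm, k=5)
        np.testing.assert_allclose(grid.to_numpy(), 0.5)
        np.testing.assert_allclose(disp.to_numpy(), 0.0)


class TestCornerAsymmetry:
    def _ccm_from(self, arr):
        cells = [f"c{i}" for i in range(arr.shape[0])]
        return sf.trajectory.CrossCorrMatrix(
            matrix=pd.DataFrame(arr, index=cells, columns=cells),
            ordering=sf.PseudotimeOrdering(cells=cells,
                                           pseudotime=np.arange(float(len(cells)))))

    def test_symmetric_matrix_has_zero_difference(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(-1, 1, (10, 10))
        sym = (a + a.T) / 2
        res = sf.corner_asymmetry(self._ccm_from(sym), k=5, n_boot=200, seed=0)
        assert res.difference == pytest.approx(0.0, abs=1e-12)

    def test_single_bin_rejected(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ValueError, match="k >= 2"):
            sf.corner_asymmetry(self._ccm_from(rng.uniform(size=(6, 6))), k=1)

    def test_bootstrap_reproducible_under_seed(self, perturbed_exp):
        exp = perturbed_exp
        genes = exp.truth.deg_genes["gene_id"].tolist()
        ccm = sf.cell_cross_correlation(exp.nuc, exp.cyt, genes, exp.pseudotime)
        a = sf.corner_asymmetry(ccm, k=5, n_boot=300, seed=9)
        b = sf.corner_asymmetry(ccm, k=5, n_boot=300, seed=9)
        assert a == b


class TestDynamicsRecovery:
    def test_lead_lag_produces_corner_asymmetry(self, perturbed_exp):
        exp = perturbed_exp
        genes = exp.truth.deg_genes["gene_id"].tolist()
        ccm = sf.cell_cross_correlation(exp.nuc, exp.cyt, genes, exp.pseudotime)
        res = sf.corner_asymmetry(ccm, k=5, n_boot=1000, seed=0)
        assert res.mean_topright < res.mean_bottomleft
        assert res.p_value < 0.05

    def test_deg_correlation_declines_but_null_does_not(self, perturbed_exp):
        exp = perturbed_exp
        degs = exp.truth.deg_genes["gene_id"].tolist()
        ccm = sf.cell_cross_correlation(exp.nuc, exp.cyt, degs, exp.pseudotime)
        trend = sf.correlation_decline(ccm, k=5)
        assert trend.rho < 0
        # planted-null control: no trajectory effect at all
        null_exp = sf.simulate_experiment(sf.perturbed_config(n_deg=0), seed=21)
        genes = [g for g in null_exp.cyt.genes
                 if g not in ("GAPDH", "HBG1", "HBG2")][:100]
        ccm0 = sf.cell_cross_correlation(null_exp.nuc, null_exp.cyt, genes,
                                         null_exp.pseudotime)
        trend0 = sf.correlation_decline(ccm0, k=5)
        assert trend0.p_value > 0.05

    def test_too_few_bins_rejected(self, perturbed_exp):
        exp = perturbed_exp
        genes = exp.truth.deg_genes["gene_id"].tolist()
        ccm = sf.cell_cross_correlation(exp.nuc, exp.cyt, genes, exp.pseudotime)
        with pytest.raises(ValueError, match="3 bins"):
            sf.correlation_decline(ccm, k=2)
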