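import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import sincflow as sf
from sincflow.introns import train_pwm
from .conftest import CLASSIFY_CASES, make_annotation as _ann, \
    make_nri_frame as _nri_frame


class TestIntronFpkm:
    @pytest.mark.parametrize("count,length,total,expected", [
        (10, 1000, 1e6, 10.0),
        (0, 700, 3e6, 0.0),
        (5, 500, 2e6, 5.0),
    ])
    def test_values(self, count, length, total, expected):
        assert sf.intron_fpkm(count, length, total) == pytest.approx(expected)

    def test_bad_length_rejected(self):
        with pytest.raises(ValueError):
            sf.intron_fpkm(1, 0, 1e6)


class TestClassify:
    @pytest.mark.parametrize("args,expected", CLASSIFY_CASES)
    def test_rule_table(self, args, expected):
        fpkm, icov, eexpr, ecov, gene = args
        assert sf.classify(fpkm, icov, eexpr, ecov, gene) == expected

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.floats(0, 5), st.floats(0, 5), st.floats(0, 1), st.floats(0, 1),
           st.floats(0, 1), st.floats(2, 50))
    def test_monotone_in_intron_expression(self, f1, f2, icov, eexpr_frac,
                                           ecov, gene):
        """Raising intron FPKM never moves a call from retained to spliced."""
        lo, hi = sorted([f1, f2])
        eexpr = eexpr_frac * gene
        state_lo = sf.classify(lo, icov, eexpr, ecov, gene)
        state_hi = sf.classify(hi, icov, eexpr, ecov, gene)
        assert not (state_lo == "retained" and state_hi == "spliced")

    def test_missing_gene_expression_rejected(self):
        with pytest.raises(ValueError):
            sf.classify(1.0, 0.96, 5.0, 0.8, float("nan"))


class TestRetentionProbability:
    def test_simple_proportion(self):
        states = ["retained"] * 6 + ["spliced"] * 4
        assert sf.retention_probability(states) == pytest.approx(0.6)

    def test_all_discarded_is_nan(self):
        assert np.isnan(sf.retention_probability(["discarded"] * 5))

    def test_discarded_cells_carry_no_information(self):
        states = ["retained"] * 3 + ["spliced"] * 2 + ["discarded"] * 5
        assert sf.retention_probability(states) == pytest.approx(0.6)


class TestCallNriCri:
    @pytest.mark.parametrize("p_nuc,p_cyt,expected", [
        (0.8, 0.4, "NRI"),
        (0.5, 0.4, "neither"),
        (0.65, 0.40, "NRI"),      # boundary gap of exactly 0.25 is inclusive
        (0.2, 0.6, "CRI"),
        (float("nan"), 0.4, "neither"),
    ])
    def test_threshold_rule(self, p_nuc, p_cyt, expected):
        assert sf.call_nri_cri(p_nuc, p_cyt) == expected


class TestFilterUnique:
    def test_nested_overlap_keeps_longest(self):
        anns = {"long": _ann("long", 100, 500), "short": _ann("short", 150, 300)}
        out = sf.filter_unique(_nri_frame(["long", "short"]), anns)
        assert out.set_index("intron_id")["unique"].to_dict() == {
            "long": True, "short": False}

    def test_non_overlapping_both_unique(self):
        anns = {"a": _ann("a", 100, 300), "b": _ann("b", 400, 900)}
        out = sf.filter_unique(_nri_frame(["a", "b"]), anns)
        assert out["unique"].all()

    def test_different_strand_or_chrom_do_not_clash(self):
        anns = {"a": _ann("a", 100, 500, strand="+"),
                "b": _ann("b", 150, 450, strand="-"),
                "c": _ann("c", 120, 480, chrom="chr2")}
        out = sf.filter_unique(_nri_frame(["a", "b", "c"]), anns)
        assert out["unique"].all()

    def test_transitive_chain_resolved_greedily(self):
        # A overlaps B, B overlaps C, A and C disjoint; A and C outlast B
        anns = {"A": _ann("A", 0, 400), "B": _ann("B", 350, 650),
                "C": _ann("C", 600, 950)}
        out = sf.filter_unique(_nri_frame(["A", "B", "C"]), anns)
        assert out.set_index("intron_id")["unique"].to_dict() == {
            "A": True, "B": False, "C": True}

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        anns = {}
        ids = []
        for i in range(30):
            start = int(rng.integers(0, 3000))
            anns[f"i{i}"] = _ann(f"i{i}", start, start + int(rng.integers(60, 800)))
            ids.append(f"i{i}")
        ref = sf.filter_unique(_nri_frame(ids), anns)
        ref = ref.set_index("intron_id")["unique"].to_dict()
        for _ in range(5):
            perm = list(rng.permutation(ids))
            out = sf.filter_unique(_nri_frame(perm), anns)
            assert out.set_index("intron_id")["unique"].to_dict() == ref


class TestNriRecovery:
    def test_planted_nris_recovered(self, unperturbed_exp, unperturbed_calls):
        nris = sf.nri_table(unperturbed_calls)
        planted = set(unperturbed_exp.truth.nri_introns["intron_id"])
        called = set(nris.loc[nris["class"] == "NRI", "intron_id"])
        tp = len(planted & called)
        assert tp / len(planted) >= 0.85          # sensitivity
        assert tp / max(len(called), 1) >= 0.85   # precision

    def test_empirical_gap_concentrates_near_planted(self, unperturbed_exp,
                                                     unperturbed_calls):
        nris = sf.nri_table(unperturbed_calls).set_index("intron_id")
        truth = unperturbed_exp.truth.nri_introns.set_index("intron_id")
        joint = nris.join(truth, rsuffix="_true").dropna()
        planted_gap = joint["p_nuc_true"] - joint["p_cyt_true"]
        assert (joint["delta"] - planted_gap).abs().mean() < 0.1

    def test_expression_coupling_in_nucleus_only(self, unperturbed_exp,
                                                 unperturbed_calls):
        exp = unperturbed_exp
        nris = sf.nri_table(unperturbed_calls)
        r_nuc, p_nuc, _ = sf.nri_expression_correlation(
            unperturbed_calls, exp.nuc, nris, "nuc")
        r_cyt, p_cyt, _ = sf.nri_expression_correlation(
            unperturbed_calls, exp.cyt, nris, "cyt")
        assert r_nuc > 0 and p_nuc < 0.05
        assert abs(r_cyt) < abs(r_nuc) and p_cyt > 0.05

    def test_single_gene_correlation_undefined(self, unperturbed_exp,
                                               unperturbed_calls):
        nris = sf.nri_table(unperturbed_calls)
        one = nris[nris["class"] == "NRI"].head(1)
        with pytest.raises(ValueError, match="fewer than 2"):
            sf.nri_expression_correlation(unperturbed_calls,
                                          unperturbed_exp.nuc, one, "nuc")


class TestSpliceSites:
    def test_consensus_sequence_scores_near_maximum(self):
        rng = np.random.default_rng(1)
        from sincflow.synthetic import (FIVE_PRIME_CONSENSUS, _sample_site,
                                        strong_site_probs)
        probs5, _ = strong_site_probs()
        seqs = [_sample_site(probs5, rng) for _ in range(300)]
        pwm = train_pwm(seqs)
        consensus_score = pwm.score(FIVE_PRIME_CONSENSUS)
        others = [pwm.score(s) for s in seqs[:50]]
        assert consensus_score >= max(others) - 1e-9

    def test_weak_sites_score_lower(self, unperturbed_exp):
        exp = unperturbed_exp
        nri = set(exp.truth.nri_introns["intron_id"])
        bg = set(exp.truth.background_introns["intron_id"])
        scores = sf.splice_site_scores(exp.splice_5p, exp.splice_3p, sorted(bg))
        for col in ("score5", "score3"):
            _, p = sf.compare_splice_scores(scores, nri, bg, col)
            assert p < 0.05

    def test_wrong_length_training_rejected(self):
        with pytest.raises(ValueError):
            train_pwm(["ACGTACGTA", "ACGT"])

    def test_wrong_length_query_rejected(self):
        pwm = train_pwm(["ACGTACGTA"] * 3)
        with pytest.raises(ValueError, match="length"):
            pwm.score("ACGTACGT")
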