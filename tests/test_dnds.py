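"""Opportunity counting, the dN/dS estimator and the resampling null."""

import numpy as np
import pandas as pd
import pytest

from immunocycle import build_opportunities, dnds_ratio, resampling_null
from immunocycle.dnds import (
    CONTEXTS_96,
    OpportunityTable,
    codon_substitution_classes,
    collapse_context,
)

STANDARD_CODE = {  # independent oracle: plain dict of the standard genetic code
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def brute_codon_table(codon):
    """Exhaustive 9-case classification against the plain code dict."""
    out = {"synonymous": 0, "missense": 0, "nonsense": 0}
    for pos in range(3):
        for alt in "ACGT":
            if alt == codon[pos]:
                continue
            mut = codon[:pos] + alt + codon[pos + 1:]
            if STANDARD_CODE[mut] == STANDARD_CODE[codon]:
                out["synonymous"] += 1
            elif STANDARD_CODE[mut] == "*":
                out["nonsense"] += 1
            else:
                out["missense"] += 1
    return out


class TestOpportunities:
    @pytest.mark.parametrize("codon", ["ATG", "TTT", "TGG", "CAA", "GGG", "AGA"])
    def test_codon_enumeration_matches_code_table(self, codon):
        got = {"synonymous": 0, "missense": 0, "nonsense": 0}
        classes = codon_substitution_classes(codon)
        assert len(classes) == 9
        for _, _, impact in classes:
            got[impact] += 1
        assert got == brute_codon_table(codon)

    def test_atg_has_no_single_step_nonsense(self):
        # every single-base change of ATG is missense (exhaustive enumeration)
        counts = brute_codon_table("ATG")
        assert counts == {"synonymous": 0, "missense": 9, "nonsense": 0}

    def test_ttt_single_synonymous_change(self):
        assert brute_codon_table("TTT")["synonymous"] == 1  # TTT -> TTC

    def test_class_totals_additive_under_concatenation(self, tiny_cds):
        a, b = tiny_cds["GENE1"], tiny_cds["GENE2"]
        sep = build_opportunities({"A": a, "B": b})
        cat = build_opportunities({"AB": a + b})
        np.testing.assert_allclose(
            cat.aggregate(["AB"]).sum(axis=0),
            sep.aggregate(["A", "B"]).sum(axis=0))

    def test_total_count_is_three_per_base(self, tiny_cds):
        opp = build_opportunities({"GENE1": tiny_cds["GENE1"]})
        assert opp.aggregate(["GENE1"]).sum() == 3 * len(tiny_cds["GENE1"])

    def test_non_acgt_raises_naming_gene(self):
        with pytest.raises(ValueError, match="BADGENE"):
            build_opportunities({"BADGENE": "ATGNNN"})

    def test_terminal_stop_trimmed_and_internal_stop_warns(self):
        opp = build_opportunities({"G": "ATGAAATAA"})
        assert opp.aggregate(["G"]).sum() == 3 * 6  # stop codon dropped
        with pytest.warns(UserWarning, match="internal stop"):
            opp2 = build_opportunities({"G": "ATGTTTTAAAAAAAA"})
        assert opp2.aggregate(["G"]).sum() == 3 * 6


class TestCollapse:
    def test_pyrimidine_center_unchanged(self):
        assert collapse_context("ACA", "T") == ("ACA", "T")

    def test_purine_center_reverse_complemented(self):
        assert collapse_context("TGT", "A") == ("ACA", "T")

    def test_context_universe_has_96_classes(self):
        assert len(CONTEXTS_96) == 96
        assert len(set(CONTEXTS_96)) == 96


def _single_context_table(L_syn, L_mis, L_non=0.0):
    arr = np.zeros((96, 3))
    arr[0] = [L_syn, L_mis, L_non]
    return OpportunityTable({"g": arr}), CONTEXTS_96[0]


def _records(context, impacts):
    tri, alt = context.split(">")
    return pd.DataFrame({
        "sample_id": "s1", "gene": "g", "impact": impacts,
        "ref_tri": tri, "alt": alt, "vaf": 0.3,
    })


class TestDnDsRatio:
    def test_analytically_forced_single_context(self):
        opp, ctx = _single_context_table(100, 300)
        cat = _records(ctx, ["synonymous"] * 2 + ["missense"] * 6)
        est = dnds_ratio(cat, ["g"], opp, "missense")
        assert est.e_exp == pytest.approx(6.0)
        assert est.ratio == pytest.approx(1.0)
        assert est.ci_low <= 1.0 <= est.ci_high

    @pytest.mark.parametrize("n_mis,n_syn,L_syn,L_mis", [
        (6, 2, 100, 300), (1, 5, 50, 100), (12, 3, 80, 240), (0, 4, 10, 30),
    ])
    def test_matches_hand_formula_single_context(self, n_mis, n_syn, L_syn, L_mis):
        opp, ctx = _single_context_table(L_syn, L_mis)
        cat = _records(ctx, ["synonymous"] * n_syn + ["missense"] * n_mis)
        est = dnds_ratio(cat, ["g"], opp, "missense")
        expected = (n_mis / L_mis) / (n_syn / L_syn)
        assert est.ratio == pytest.approx(expected, rel=1e-12)

    def test_zero_observed_gives_zero_with_upper_bound(self):
        opp, ctx = _single_context_table(100, 300)
        cat = _records(ctx, ["synonymous"] * 10)
        est = dnds_ratio(cat, ["g"], opp, "missense")
        assert est.ratio == 0.0
        assert est.ci_low == 0.0
        assert est.ci_high > 0.0

    def test_nonsyn_counts_add_up(self, small_opportunities, toy_catalog):
        _, opp = small_opportunities
        arr = np.stack([opp.aggregate([g]) for g in opp.genes]).sum(axis=0)
        table = OpportunityTable({g: arr / len(opp.genes) for g in ["G1", "G2"]})
        alln = dnds_ratio(toy_catalog, ["G1", "G2"], table, "all_nonsynonymous")
        mis = dnds_ratio(toy_catalog, ["G1", "G2"], table, "missense")
        non = dnds_ratio(toy_catalog, ["G1", "G2"], table, "nonsense")
        assert alln.n_obs == mis.n_obs + non.n_obs

    def test_no_synonymous_observation_raises_with_guidance(self):
        opp, ctx = _single_context_table(100, 300)
        cat = _records(ctx, ["missense"] * 5)
        with pytest.raises(ValueError, match="pool strata"):
            dnds_ratio(cat, ["g"], opp, "missense")


class TestResamplingNull:
    def _catalog_and_opp(self, seed=0, n=400):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(20)]
        arr = np.zeros((96, 3))
        arr[0] = [30, 90, 6]
        opp = OpportunityTable({g: arr for g in genes})
        tri, alt = CONTEXTS_96[0].split(">")
        cat = pd.DataFrame({
            "sample_id": "s",
            "gene": rng.choice(genes, n),
            "impact": rng.choice(["synonymous", "missense"], n, p=[0.4, 0.6]),
            "ref_tri": tri, "alt": alt, "vaf": 0.3,
        })
        return cat, opp, genes

    def test_deterministic_under_seed(self):
        cat, opp, genes = self._catalog_and_opp()
        a = resampling_null(cat, genes, genes[:8], opp, iterations=10, seed=5)
        b = resampling_null(cat, genes, genes[:8], opp, iterations=10, seed=5)
        np.testing.assert_array_equal(a.null_ratios, b.null_ratios)
        assert a.empirical_p == b.empirical_p

    def test_single_iteration_p_values(self):
        cat, opp, genes = self._catalog_and_opp()
        res = resampling_null(cat, genes, genes[:8], opp, iterations=1, seed=2)
        assert res.empirical_p in (0.5, 1.0)

    def test_uniform_rates_give_centered_p(self):
        # under gene-exchangeable rates the empirical p is ~uniform, so its
        # mean over replicate catalogs is ~0.5
        ps = []
        for seed in range(30):
            cat, opp, genes = self._catalog_and_opp(seed=seed)
            res = resampling_null(cat, genes, genes[:10], opp,
                                  iterations=20, seed=seed)
            ps.append(res.empirical_p)
        assert abs(np.mean(ps) - 0.5) < 0.15

    def test_target_outside_universe_raises(self):
        cat, opp, genes = self._catalog_and_opp()
        with pytest.raises(ValueError, match="not contained"):
            resampling_null(cat, genes[:5], ["nope"], opp)
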