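"""Synthetic cohort generator: determinism, planted structure, validation."""

import numpy as np
import pandas as pd
import pytest

import immunocycle as ic


def _small_config(**kw):
    defaults = dict(n_samples=24, n_genes=280, genes_per_set=10,
                    n_mut_genes=6, cds_codons=80, mutations_per_sample=30,
                    seed=1)
    defaults.update(kw)
    return ic.SyntheticConfig(**defaults)


class TestConfigValidation:
    def test_too_few_genes_raises(self):
        with pytest.raises(ValueError, match="n_genes"):
            _small_config(n_genes=30, genes_per_set=10)

    def test_wrong_template_length_raises(self):
        with pytest.raises(ValueError, match="8 axis levels"):
            _small_config(archetypes={"a": [0.1] * 7, "b": [0.1] * 8})

    def test_single_archetype_raises(self):
        with pytest.raises(ValueError, match="at least 2"):
            _small_config(archetypes={"only": [0.0] * 8})

    def test_negative_omega_raises(self):
        with pytest.raises(ValueError, match="omega"):
            _small_config(omega_by_subtype={"I": -1.0})

    def test_censoring_rate_bounds(self):
        with pytest.raises(ValueError, match="censoring"):
            _small_config(censoring_rate=1.0)


class TestExpression:
    def test_bitwise_deterministic(self):
        a, _, _ = ic.generate_expression(_small_config())
        b, _, _ = ic.generate_expression(_small_config())
        pd.testing.assert_frame_equal(a, b)

    def test_nonnegative_values(self):
        expr, _, _ = ic.generate_expression(_small_config())
        assert (expr.to_numpy() >= 0).all()

    def test_zero_noise_same_archetype_identical_member_genes(self):
        cfg = _small_config(axis_noise_sd=0.0, n_samples=40)
        expr, sets, truth = ic.generate_expression(cfg)
        labels = truth.true_labels
        for name in labels.unique():
            cols = labels.index[labels == name]
            member_genes = sets.sets["IGS1"]
            block = expr.loc[member_genes, cols]
            assert (block.nunique(axis=1) == 1).all()

    def test_gene_sets_disjoint(self):
        _, sets, _ = ic.generate_expression(_small_config())
        seen = set()
        for members in sets.axis_sets().values():
            assert not (seen & set(members))
            seen |= set(members)

    def test_template_level_monotone_in_enrichment(self):
        # raising one axis level strictly raises that axis's mean score
        base_arch = ic.default_archetypes()
        lo = {k: list(v) for k, v in base_arch.items()}
        hi = {k: list(v) for k, v in base_arch.items()}
        lo["I"][0], hi["I"][0] = -0.5, 0.9
        out = {}
        for name, arch in [("lo", lo), ("hi", hi)]:
            cfg = _small_config(archetypes=arch, axis_noise_sd=0.0, n_samples=60)
            expr, sets, truth = ic.generate_expression(cfg)
            scores = ic.enrichment_scores(expr, sets.axis_sets())
            mask = truth.true_labels == "I"
            out[name] = scores.loc[mask.to_numpy(), "IGS1"].mean()
        assert out["hi"] > out["lo"]


class TestMutations:
    def test_empty_catalog_when_rate_zero(self, small_opportunities):
        _, opp = small_opportunities
        cfg = _small_config(mutations_per_sample=0)
        _, _, truth = ic.generate_expression(cfg)
        md = ic.generate_mutations(cfg, truth, opp)
        assert md.catalog.empty
        assert (md.neoantigens == 0).all()

    def test_deterministic(self, small_opportunities):
        _, opp = small_opportunities
        cfg = _small_config()
        _, _, truth = ic.generate_expression(cfg)
        a = ic.generate_mutations(cfg, truth, opp)
        b = ic.generate_mutations(cfg, truth, opp)
        pd.testing.assert_frame_equal(a.catalog, b.catalog)
        pd.testing.assert_series_equal(a.neoantigens, b.neoantigens)

    def test_vafs_valid_and_impacts_closed(self, small_opportunities):
        _, opp = small_opportunities
        cfg = _small_config()
        _, _, truth = ic.generate_expression(cfg)
        md = ic.generate_mutations(cfg, truth, opp)
        assert md.catalog["vaf"].between(0, 1, inclusive="right").all()
        assert set(md.catalog["impact"]) <= {"synonymous", "missense", "nonsense"}

    def test_neutral_limit_mean_ratio_one(self, small_opportunities):
        _, opp = small_opportunities
        ratios = []
        for seed in range(40):
            cfg = _small_config(
                seed=seed, n_samples=10, mutations_per_sample=300,
                omega_by_subtype={k: 1.0 for k in "I II III IV".split()})
            _, _, truth = ic.generate_expression(cfg)
            md = ic.generate_mutations(cfg, truth, opp)
            ratios.append(ic.dnds_ratio(md.catalog, opp.genes, opp).ratio)
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.05)

    def test_planted_selection_ordering(self, small_opportunities):
        _, opp = small_opportunities
        wins = 0
        for seed in range(20):
            cfg = _small_config(
                seed=seed, n_samples=16, mutations_per_sample=250,
                omega_by_subtype={"I": 1.0, "II": 3.0, "III": 1.0, "IV": 1.0})
            _, _, truth = ic.generate_expression(cfg)
            md = ic.generate_mutations(cfg, truth, opp)
            labels = truth.true_labels
            est = {}
            for sub in ("II", "IV"):
                sids = labels.index[labels == sub]
                est[sub] = ic.dnds_ratio(md.catalog, opp.genes, opp,
                                         samples=list(sids)).ratio
            wins += est["II"] > est["IV"]
        assert wins >= 19  # planted omega ordering recovered in >=95%


class TestClinical:
    def test_deterministic(self):
        cfg = _small_config()
        _, _, truth = ic.generate_expression(cfg)
        a = ic.generate_clinical(truth, cfg)
        b = ic.generate_clinical(truth, cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_schema_and_positivity(self):
        cfg = _small_config(n_samples=50)
        _, _, truth = ic.generate_expression(cfg)
        clin = ic.generate_clinical(truth, cfg)
        assert (clin["os_time"] > 0).all()
        assert clin["os_event"].isin([0, 1]).all()
        assert clin["stage"].isin(["I", "II", "III", "IV"]).all()

    def test_hazard_ordering_dominates_km(self):
        cfg = _small_config(
            n_samples=600, n_genes=280,
            hazard_by_subtype={"I": 0.5, "II": 2.0, "III": 1.0, "IV": 1.0},
            censoring_rate=0.0, seed=3)
        _, _, truth = ic.generate_expression(cfg)
        clin = ic.generate_clinical(truth, cfg)
        med = clin.groupby("subtype")["os_time"].median()
        assert med["I"] > med["II"]

    def test_censoring_fraction_close_to_target(self):
        cfg = _small_config(n_samples=2000, censoring_rate=0.3,
                            hazard_by_subtype={k: 1.0 for k in "I II III IV".split()})
        _, _, truth = ic.generate_expression(cfg)
        clin = ic.generate_clinical(truth, cfg)
        assert (1 - clin["os_event"]).mean() == pytest.approx(0.3, abs=0.05)
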