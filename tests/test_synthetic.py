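"""Generator tests: determinism, conservation laws, planted-effect fidelity."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit
from scipy.stats import spearmanr

from transgen_meth.errors import ConfigurationError
from transgen_meth.methylome import dmc_test, filter_sites
from transgen_meth.synthetic import (
    BehaviorSimConfig,
    MethylSimConfig,
    simulate_behavior_cohort,
    simulate_de_table,
    simulate_gene_model,
    simulate_methyl_matrix,
)


class TestBehaviorSim:
    def test_no_effect_cohort_centred_on_base_mean(self):
        cfg = BehaviorSimConfig(
            n_animals=100, motivation_sd=0.0,
            motivation_effect_fr5=0.0, motivation_effect_bp=0.0, seed=11,
        )
        sessions, _ = simulate_behavior_cohort(cfg)
        fr5 = sessions[sessions.schedule == "FR5"]["active_presses"]
        se = fr5.std(ddof=1) / np.sqrt(len(fr5))
        assert abs(fr5.mean() - cfg.base_fr5_mean) < 3 * se

    def test_deterministic_given_seed(self):
        cfg = BehaviorSimConfig(n_animals=20, seed=5)
        s1, l1 = simulate_behavior_cohort(cfg)
        s2, l2 = simulate_behavior_cohort(cfg)
        assert s1.to_csv() == s2.to_csv()
        assert l1.to_csv() == l2.to_csv()

    def test_motivation_drives_fr5_pressing(self):
        cfg = BehaviorSimConfig(n_animals=200, seed=3)
        sessions, latent = simulate_behavior_cohort(cfg)
        fr5 = (
            sessions[sessions.schedule == "FR5"]
            .groupby("animal_id")["active_presses"].mean()
        )
        rho, p = spearmanr(latent.set_index("animal_id")["motivation"].loc[fr5.index], fr5)
        assert rho > 0 and p < 0.01

    def test_session_structure(self):
        cfg = BehaviorSimConfig(n_animals=3, seed=0)
        sessions, _ = simulate_behavior_cohort(cfg)
        per_animal = sessions.groupby("animal_id")["schedule"].value_counts().unstack()
        assert (per_animal["FR1"] == 5).all()
        assert (per_animal["FR3"] == 2).all()
        assert (per_animal["FR5"] == 5).all()
        assert (per_animal["PR"] == 1).all()

    def test_invalid_config_names_field(self):
        with pytest.raises(ConfigurationError, match="base_fr5_mean"):
            BehaviorSimConfig(base_fr5_mean=-1.0).validate()
        with pytest.raises(ConfigurationError, match="n_animals"):
            BehaviorSimConfig(n_animals=2).validate()


class TestMethylSim:
    def test_deterministic_given_seed(self):
        cfg = MethylSimConfig(n_sites=300, n_planted_dmcs=10, seed=9)
        m1, t1 = simulate_methyl_matrix(cfg)
        m2, t2 = simulate_methyl_matrix(cfg)
        assert np.array_equal(m1.meth, m2.meth)
        assert np.array_equal(m1.total, m2.total)
        assert t1.planted_site_ids == t2.planted_site_ids

    def test_counts_conserved_and_sorted(self):
        m, _ = simulate_methyl_matrix(MethylSimConfig(n_sites=500, seed=2))
        assert (m.meth <= m.total).all()
        assert (m.meth >= 0).all()
        key = list(zip(m.sites.chrom, m.sites.pos))
        assert key == sorted(key)

    def test_group_design(self):
        m, _ = simulate_methyl_matrix(MethylSimConfig(n_sites=50, n_planted_dmcs=5, seed=0))
        counts = m.samples.groupby(["phenotype", "generation"]).size()
        assert counts[("Saline", "F0")] == 3
        assert counts[("Non-addict", "F1")] == 4
        assert len(m.samples) == 16

    def test_missing_group_rejected(self):
        cfg = MethylSimConfig(samples_per_group={"Saline-F0": 3})
        with pytest.raises(ConfigurationError, match="samples_per_group"):
            cfg.validate()

    def test_null_effect_differences_centred_at_zero(self):
        cfg = MethylSimConfig(n_sites=4000, planted_effect=0.0, seed=4)
        m, _ = simulate_methyl_matrix(cfg)
        out = dmc_test(filter_sites(m), "F0")
        diffs = out["diff"].to_numpy()
        se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean()) < 2 * se + 1e-3

    def test_null_binomial_sampling_is_calibrated(self):
        # pooled Fisher is exact for binomial counts: with no planted effect
        # and no extra-binomial variation, FDR control leaves ~no discoveries
        for seed in range(3):
            cfg = MethylSimConfig(
                n_sites=5000, planted_effect=0.0, overdispersion=0.0, seed=seed
            )
            m, _ = simulate_methyl_matrix(cfg)
            out = dmc_test(filter_sites(m), "F0")
            assert out["significant"].sum() <= 0.001 * len(out)

    def test_high_coverage_converges_to_baseline(self):
        cfg = MethylSimConfig(
            n_sites=200, n_planted_dmcs=0, overdispersion=0.0,
            coverage_mean=5000.0, global_demethylation_shift=0.0, seed=6,
        )
        m, _ = simulate_methyl_matrix(cfg)
        # Saline-F0 samples carry no shift: their levels estimate the baseline
        sal = m.sample_mask(phenotype="Saline")
        lv = m.levels()[:, sal]
        spread = np.nanmax(lv, axis=1) - np.nanmin(lv, axis=1)
        assert np.nanmax(spread) < 0.06

    def test_planted_difference_matches_logit_shift(self):
        cfg = MethylSimConfig(seed=8)  # 10,000 sites, 200 planted, effect 1.5
        m, truth = simulate_methyl_matrix(cfg)
        out = dmc_test(filter_sites(m), "F0")
        out["sid"] = out["chrom"] + ":" + out["pos"].astype(str)
        planted = out[out["sid"].isin(truth.planted_site_ids)]
        obs = planted["diff"].to_numpy()
        signs = np.array([truth.signs[s] for s in planted["sid"]])
        base = np.array([truth.baseline[s] for s in planted["sid"]])
        analytic = expit(logit(base) + signs * cfg.planted_effect) - expit(logit(base))
        # the F0 global shift applies to both groups, so it nearly cancels in
        # the Addict - Non-addict contrast; compare means over planted sites
        assert abs(obs.mean() - analytic.mean()) < 0.05

    def test_maintained_subset_of_planted(self):
        _, truth = simulate_methyl_matrix(MethylSimConfig(n_sites=400, seed=1))
        assert truth.maintained_site_ids <= truth.planted_site_ids

    def test_ground_truth_frame_roundtrip(self):
        from transgen_meth.synthetic import GroundTruth

        _, truth = simulate_methyl_matrix(
            MethylSimConfig(n_sites=200, n_planted_dmcs=20, seed=3)
        )
        again = GroundTruth.from_frame(truth.to_frame())
        assert again.planted_site_ids == truth.planted_site_ids
        assert again.maintained_site_ids == truth.maintained_site_ids
        assert again.signs == truth.signs


class TestGeneModelAndDe:
    def test_gene_model_well_formed(self):
        gm = simulate_gene_model(seed=0)
        g = gm.genes
        assert (g["end"] > g["start"]).all()
        for r in g.itertuples():
            assert r.exon_starts[0] == r.start
            assert r.exon_ends[-1] == r.end
            assert all(e > s for s, e in zip(r.exon_starts, r.exon_ends))

    def test_promoter_placement_enrichment(self):
        from transgen_meth.methylome import annotate_sites

        gm = simulate_gene_model(seed=0)
        cfg = MethylSimConfig(
            n_sites=2000, n_planted_dmcs=200, seed=0,
            planted_promoter_fraction=0.8, background_promoter_fraction=0.35,
        )
        m, truth = simulate_methyl_matrix(cfg, gene_model=gm)
        ann = annotate_sites(m.sites, gm)
        sid = m.site_ids
        planted = sid.isin(truth.planted_site_ids).to_numpy()
        prom = (ann["element"] == "promoter").to_numpy()
        assert prom[planted].mean() > prom[~planted].mean()

    def test_de_table_enrichment_structure(self):
        genes = [f"G{i:04d}" for i in range(200)]
        de = simulate_de_table(genes, enriched_genes=set(genes[:20]), seed=0)
        assert (de["fold_change"] > 0).all()
        hit = (de["fold_change"] >= 2) & (de["p_value"] < 0.05)
        assert hit[:20].mean() > hit[20:].mean()
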