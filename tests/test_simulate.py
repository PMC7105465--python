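"""Simulator contracts: replicate structure, ground truth, noise model."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from mitodep import (SimulationConfig, evidence_table, generate_design,
                     generate_gene_sets, generate_peptide_intensities,
                     generate_truth, score_proteins)
from mitodep.config import DEFAULT_SCHEME
from mitodep.errors import ConfigError, InputError


class TestDesign:
    def test_study_replicate_structure(self):
        """2 conditions x 3 biological x 3 technical -> 18 runs, 6 bio reps."""
        design = generate_design(SimulationConfig(
            n_conditions=2, n_bio_reps=3, n_tech_reps=3))
        assert len(design) == 18
        assert design["run_id"].is_unique
        bio = design.groupby(["condition", "bio_rep"])
        assert len(bio) == 6
        assert (bio.size() == 3).all()
        assert set(design["condition"]) == {"Ctrl", "KO1"}

    def test_single_tech_rep_degenerate(self):
        design = generate_design(SimulationConfig(n_tech_reps=1))
        assert len(design) == 2 * 3

    @pytest.mark.parametrize("field,value", [
        ("n_conditions", 1), ("n_bio_reps", 1), ("frac_mito", 1.5),
        ("planted_fc", 1.0), ("missing_rate", -0.1), ("min_peptides", 0),
    ])
    def test_invalid_config_names_field(self, field, value):
        with pytest.raises(ConfigError, match=field):
            SimulationConfig(**{field: value})


class TestTruth:
    def test_planted_counts_follow_config(self):
        truth = generate_truth(SimulationConfig(
            n_proteins=1000, frac_mito=0.3, frac_dep=0.2, seed=1))
        assert truth["is_mito"].sum() == 300
        assert truth["is_dep"].sum() == 60
        assert (truth.loc[truth["is_dep"], "is_mito"]).all()

    def test_down_up_split_preset(self):
        """frac_down = 46/62 with 62 planted effects -> 46 down, 16 up."""
        truth = generate_truth(SimulationConfig(
            n_proteins=1000, frac_mito=0.3, frac_dep=62 / 300,
            frac_down=46 / 62, seed=5))
        assert truth["is_dep"].sum() == 62
        assert (truth["direction"] == "down").sum() == 46
        assert (truth["direction"] == "up").sum() == 16

    def test_null_simulation_has_unit_fold_changes(self):
        truth = generate_truth(SimulationConfig(frac_dep=0.0, seed=2))
        assert (truth["true_fc"] == 1.0).all()
        assert (truth["direction"] == "none").all()

    def test_truth_invariants(self):
        truth = generate_truth(SimulationConfig(seed=11))
        dep = truth["is_dep"]
        assert (truth.loc[dep, "true_fc"] >= 2.0).all()
        assert truth.loc[dep, "direction"].isin(["up", "down"]).all()
        assert (truth.loc[~dep, "true_fc"] == 1.0).all()
        assert (truth.loc[~dep, "direction"] == "none").all()
        assert (truth["base_abundance"] > 0).all()

    def test_evidence_separates_classes_without_contamination(self):
        cfg = SimulationConfig(n_proteins=400, contamination_rate=0.0, seed=4)
        truth = generate_truth(cfg)
        scores = score_proteins(evidence_table(truth), DEFAULT_SCHEME)
        merged = truth.merge(scores, on="protein_id")
        mito = merged["is_mito"]
        assert (merged.loc[mito, "total_score"] >= 3).all()
        assert (merged.loc[~mito, "total_score"] < 3).all()

    def test_contamination_misannotates_at_roughly_stated_rate(self):
        cfg = SimulationConfig(n_proteins=3000, contamination_rate=0.1,
                               seed=9)
        truth = generate_truth(cfg)
        scores = score_proteins(evidence_table(truth), DEFAULT_SCHEME)
        merged = truth.merge(scores, on="protein_id")
        wrong = ((merged["total_score"] >= 3) != merged["is_mito"]).mean()
        lo, hi = scipy.stats.binom.interval(0.999, 3000, 0.1)
        assert lo / 3000 <= wrong <= hi / 3000


class TestPeptideIntensities:
    def test_determinism_same_seed_identical_tables(self, small_config):
        a_truth = generate_truth(small_config)
        b_truth = generate_truth(small_config)
        pd.testing.assert_frame_equal(a_truth, b_truth)
        design = generate_design(small_config)
        a = generate_peptide_intensities(a_truth, design, small_config)
        b = generate_peptide_intensities(b_truth, design, small_config)
        pd.testing.assert_frame_equal(a, b)

    def test_noiseless_intensities_equal_expected_means(self, noiseless_config):
        """With zero CV and no missingness, KO/Ctrl intensity ratios are
        exactly the planted direction-signed fold change."""
        truth = generate_truth(noiseless_config)
        design = generate_design(noiseless_config)
        pep = generate_peptide_intensities(truth, design, noiseless_config)
        assert pep["intensity"].notna().all()
        merged = pep.merge(design, on="run_id").merge(
            truth[["protein_id", "true_fc", "direction"]], on="protein_id")
        wide = merged.pivot_table(index="peptide_id", columns="condition",
                                  values="intensity", aggfunc="mean")
        info = merged.drop_duplicates("peptide_id").set_index("peptide_id")
        ratio = (wide["KO1"] / wide["Ctrl"]).reindex(info.index)
        expected = info["true_fc"] ** np.where(info["direction"] == "down",
                                               -1.0, 1.0)
        np.testing.assert_allclose(ratio, expected, rtol=1e-12)

    def test_empirical_cv_matches_configured_cv(self):
        """Across 100 replicate draws of one peptide the sample CV sits
        within +-0.05 of the configured 0.2 (oracle: sample CV)."""
        cfg = SimulationConfig(n_proteins=1, frac_mito=1.0, frac_dep=0.0,
                               peptides_per_protein=1.0, min_peptides=1,
                               noise_cv=0.2, tech_cv_ratio=0.0,
                               missing_rate=0.0, n_conditions=2,
                               n_bio_reps=50, n_tech_reps=1, seed=21)
        truth = generate_truth(cfg)
        design = generate_design(cfg)
        pep = generate_peptide_intensities(truth, design, cfg)
        one = pep[pep["peptide_id"] == pep["peptide_id"].iloc[0]]
        assert len(one) == 100
        cv = one["intensity"].std() / one["intensity"].mean()
        assert abs(cv - 0.2) < 0.05

    def test_missing_rate_within_binomial_interval(self):
        cfg = SimulationConfig(n_proteins=200, peptides_per_protein=3.0,
                               missing_rate=0.1, seed=13)
        truth = generate_truth(cfg)
        design = generate_design(cfg)
        pep = generate_peptide_intensities(truth, design, cfg)
        n = len(pep)
        assert n >= 10_000
        miss = int(pep["intensity"].isna().sum())
        lo, hi = scipy.stats.binom.interval(0.99, n, 0.1)
        assert lo <= miss <= hi
        assert (pep["intensity"].dropna() > 0).all()

    def test_empty_inputs_rejected(self, small_config):
        truth = generate_truth(small_config)
        design = generate_design(small_config)
        with pytest.raises(InputError):
            generate_peptide_intensities(truth.iloc[:0], design, small_config)
        with pytest.raises(InputError):
            generate_peptide_intensities(truth, design.iloc[:0], small_config)

    def test_min_peptides_floor_is_respected(self):
        cfg = SimulationConfig(n_proteins=100, peptides_per_protein=2.0,
                               min_peptides=2, seed=17)
        pep = generate_peptide_intensities(generate_truth(cfg),
                                           generate_design(cfg), cfg)
        per_protein = pep.groupby("protein_id")["peptide_id"].nunique()
        assert (per_protein >= 2).all()


class TestGeneSets:
    def test_synthetic_sets_cover_planted_pathway(self, small_config):
        truth = generate_truth(small_config)
        sets = generate_gene_sets(truth, small_config, n_sets=5, set_size=10)
        assert "planted_pathway" in sets
        assert len(sets) == 5
        mito = set(truth.loc[truth["is_mito"], "protein_id"])
        for members in sets.values():
            assert set(members) <= mito
            assert len(members) > 0
        dep = set(truth.loc[truth["is_dep"], "protein_id"])
        assert len(set(sets["planted_pathway"]) & dep) > 0
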