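"""Technical-replicate averaging, fold change, ANOVA and Filter 2."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from mitodep import (FilterConfig, SimulationConfig, anova_pvalue,
                     average_technical_replicates, build_dep_table,
                     evidence_table, fold_change, filter_mito,
                     generate_design, generate_peptide_intensities,
                     generate_truth, normalize_runs, rollup_proteins,
                     score_proteins, select_mtdeps)
from mitodep.errors import InputError


def design_frame(conditions=("Ctrl", "KO1"), n_bio=3, n_tech=3):
    rows = []
    for c in conditions:
        for b in range(1, n_bio + 1):
            for t in range(1, n_tech + 1):
                rows.append((f"{c}_b{b}_t{t}", c, f"b{b}", f"t{t}"))
    return pd.DataFrame(rows, columns=["run_id", "condition", "bio_rep",
                                       "tech_rep"])


def quant_frame(values, design, n_unique=3):
    """values: protein -> {run_id: abundance}; unlisted runs are missing."""
    rows = []
    for prot, per_run in values.items():
        for run in design["run_id"]:
            rows.append((prot, run, per_run.get(run, np.nan), n_unique))
    return pd.DataFrame(rows, columns=["protein_id", "run_id", "abundance",
                                       "n_unique_peptides"])


def matrix_from_groups(groups):
    """groups: condition -> list of bio-rep values, one protein."""
    cols = pd.MultiIndex.from_tuples(
        [(c, f"b{i}") for c, vals in groups.items()
         for i in range(len(vals))], names=["condition", "bio_rep"])
    data = [v for vals in groups.values() for v in vals]
    return pd.DataFrame([data], index=pd.Index(["P1"], name="protein_id"),
                        columns=cols)


class TestAveraging:
    def test_mean_of_technical_replicates(self):
        design = design_frame(n_bio=1, n_tech=3)
        quant = quant_frame({"P1": {"Ctrl_b1_t1": 10, "Ctrl_b1_t2": 20,
                                    "Ctrl_b1_t3": 30,
                                    "KO1_b1_t1": 5, "KO1_b1_t2": 5,
                                    "KO1_b1_t3": 5}}, design)
        mat = average_technical_replicates(quant, design)
        assert mat.loc["P1", ("Ctrl", "b1")] == 20.0

    def test_mean_of_observed_when_one_tech_rep_missing(self):
        design = design_frame(n_bio=1, n_tech=3)
        quant = quant_frame({"P1": {"Ctrl_b1_t1": 10.0, "Ctrl_b1_t3": 30.0,
                                    "KO1_b1_t1": 1.0}}, design)
        mat = average_technical_replicates(quant, design)
        assert mat.loc["P1", ("Ctrl", "b1")] == 20.0

    def test_single_tech_rep_passthrough(self):
        design = design_frame(n_bio=2, n_tech=1)
        quant = quant_frame({"P1": {r: i + 1.0 for i, r in
                                    enumerate(design["run_id"])}}, design)
        mat = average_technical_replicates(quant, design)
        assert mat.shape == (1, 4)
        assert mat.loc["P1"].tolist() == [1.0, 2.0, 3.0, 4.0]

    def test_unknown_run_raises_naming_run(self):
        design = design_frame()
        quant = quant_frame({"P1": {"mystery_run": 1.0}}, design)
        quant.loc[len(quant)] = ("P1", "mystery_run", 1.0, 3)
        with pytest.raises(InputError, match="mystery_run"):
            average_technical_replicates(quant, design)


class TestFoldChange:
    def test_magnitude_and_direction(self):
        mat = matrix_from_groups({"Ctrl": [150, 150, 150],
                                  "KO1": [100, 100, 100]})
        fc = fold_change(mat, "Ctrl", "KO1")
        assert fc.loc["P1", "fc"] == pytest.approx(1.5)
        assert fc.loc["P1", "direction"] == "down"
        assert fc.loc["P1", "log2fc"] == pytest.approx(-np.log2(1.5))

    def test_equal_means_give_unit_fc_no_direction(self):
        mat = matrix_from_groups({"Ctrl": [100, 100], "KO1": [100, 100]})
        fc = fold_change(mat, "Ctrl", "KO1")
        assert fc.loc["P1", "fc"] == 1.0
        assert fc.loc["P1", "direction"] == "none"

    def test_zero_group_mean_gives_infinite_fc(self, caplog):
        mat = matrix_from_groups({"Ctrl": [0.0, 0.0], "KO1": [10.0, 10.0]})
        fc = fold_change(mat, "Ctrl", "KO1")
        assert np.isinf(fc.loc["P1", "fc"])
        assert fc.loc["P1", "direction"] == "up"
        assert any("infinite" in r.message for r in caplog.records)

    def test_noiseless_simulation_recovers_planted_fc_exactly(self):
        cfg = SimulationConfig(n_proteins=40, frac_mito=1.0, frac_dep=0.5,
                               planted_fc=2.0, min_peptides=2,
                               frac_unique_peptides=1.0, noise_cv=0.0,
                               missing_rate=0.0, contamination_rate=0.0,
                               seed=19)
        truth = generate_truth(cfg)
        design = generate_design(cfg)
        pep = generate_peptide_intensities(truth, design, cfg)
        quant = rollup_proteins(normalize_runs(pep)[0])
        mat = average_technical_replicates(quant, design)
        fc = fold_change(mat, "Ctrl", "KO1")
        tr = truth.set_index("protein_id").reindex(fc.index)
        dep = tr["is_dep"]
        np.testing.assert_allclose(fc.loc[dep, "fc"], 2.0, rtol=1e-9)
        assert (fc.loc[dep, "direction"] == tr.loc[dep, "direction"]).all()
        np.testing.assert_allclose(fc.loc[~dep, "fc"], 1.0, rtol=1e-9)


class TestAnova:
    def test_identical_groups_give_p_one(self):
        mat = matrix_from_groups({"Ctrl": [1, 2, 3], "KO1": [1, 2, 3]})
        # identical value *sets* -> equal means; with spread, F is exactly 0
        p = anova_pvalue(mat, log_transform=False)
        assert p["P1"] == 1.0

    def test_matches_t_test_via_f_t2_identity(self):
        mat = matrix_from_groups({"Ctrl": [1, 2, 3], "KO1": [4, 5, 6]})
        p = anova_pvalue(mat, log_transform=False)
        t = scipy.stats.ttest_ind([1, 2, 3], [4, 5, 6], equal_var=True)
        assert p["P1"] == pytest.approx(t.pvalue, abs=1e-12)

    def test_zero_variance_unequal_means_gives_tiny_p(self):
        mat = matrix_from_groups({"Ctrl": [5, 5, 5], "KO1": [9, 9, 9]})
        p = anova_pvalue(mat, log_transform=False)
        assert 0 < p["P1"] < 1e-300

    def test_insufficient_observations_give_missing_p(self):
        mat = matrix_from_groups({"Ctrl": [1.0, np.nan, np.nan],
                                  "KO1": [2.0, 3.0, 4.0]})
        p = anova_pvalue(mat, log_transform=False)
        assert np.isnan(p["P1"])

    def test_three_groups_match_scipy_f_oneway(self):
        rng = np.random.default_rng(5)
        groups = {c: list(rng.normal(10, 2, 4)) for c in
                  ("Ctrl", "KO1", "KO2")}
        mat = matrix_from_groups(groups)
        p = anova_pvalue(mat, log_transform=False)
        ref = scipy.stats.f_oneway(*groups.values())
        assert p["P1"] == pytest.approx(ref.pvalue, abs=1e-12)


class TestFilter2:
    TOY = pd.DataFrame({
        "protein_id": ["A", "B", "C", "D", "E", "F"],
        "fc": [3.0, 1.5, 1.4, 2.0, 2.0, np.nan],
        "direction": ["up", "down", "up", "down", "up", "none"],
        "p_value": [0.001, 0.05, 0.001, 0.2, 0.01, np.nan],
        "n_unique_peptides": [1, 2, 5, 3, 2, 4],
    })

    def test_toy_table_pass_fail_pattern(self):
        """Row-by-row boolean predicate: A fails on unique peptides, B passes
        at both boundaries, C fails FC, D fails p, E passes, F fails on
        missing values."""
        cfg = FilterConfig(fc_threshold=1.5, p_threshold=0.05,
                           min_unique_peptides=2)
        out, summary = select_mtdeps(self.TOY, cfg)
        assert out["passes_filter2"].tolist() == [False, True, False, False,
                                                  True, False]
        assert summary == {"total": 2, "up": 1, "down": 1}

    def test_count_conservation(self):
        _, summary = select_mtdeps(self.TOY, FilterConfig())
        assert summary["total"] == summary["up"] + summary["down"]

    def test_strict_fc_boundary_excludes_equality(self):
        cfg = FilterConfig(fc_threshold=1.5, fc_inclusive=False)
        out, _ = select_mtdeps(self.TOY, cfg)
        assert not out.loc[out["protein_id"] == "B", "passes_filter2"].iloc[0]

    def test_threshold_monotonicity(self):
        """Raising the FC threshold or lowering the p threshold never adds a
        differential protein."""
        base, _ = select_mtdeps(self.TOY, FilterConfig(fc_threshold=1.5,
                                                       p_threshold=0.05))
        base_set = set(base.loc[base["passes_filter2"], "protein_id"])
        for fc_t, p_t in [(2.0, 0.05), (1.5, 0.01), (3.0, 0.001)]:
            out, _ = select_mtdeps(self.TOY, FilterConfig(
                fc_threshold=fc_t, p_threshold=p_t))
            sel = set(out.loc[out["passes_filter2"], "protein_id"])
            assert sel <= base_set

    def test_bh_mode_is_more_conservative_here(self):
        out, _ = select_mtdeps(self.TOY, FilterConfig(use_bh=True))
        assert "q_value" in out.columns
        raw, _ = select_mtdeps(self.TOY, FilterConfig())
        assert set(out.loc[out["passes_filter2"], "protein_id"]) <= \
            set(raw.loc[raw["passes_filter2"], "protein_id"])


class TestFilterCommutativity:
    def test_filter1_then_filter2_equals_filter2_then_filter1(self):
        cfg = SimulationConfig(n_proteins=80, frac_mito=0.5, frac_dep=0.4,
                               min_peptides=2, frac_unique_peptides=1.0,
                               noise_cv=0.1, missing_rate=0.0, seed=23)
        truth = generate_truth(cfg)
        design = generate_design(cfg)
        pep = generate_peptide_intensities(truth, design, cfg)
        quant = rollup_proteins(normalize_runs(pep)[0])
        scores = score_proteins(evidence_table(truth))
        fcfg = FilterConfig()

        # Filter 1 first
        f1, _ = filter_mito(quant, scores)
        mat1 = average_technical_replicates(f1, design)
        rec1 = build_dep_table(mat1, f1, "Ctrl", ["KO1"])
        out1, _ = select_mtdeps(rec1, fcfg)
        set1 = set(out1.loc[out1["passes_filter2"], "protein_id"])

        # Filter 2 first
        mat2 = average_technical_replicates(quant, design)
        rec2 = build_dep_table(mat2, quant, "Ctrl", ["KO1"])
        out2, _ = select_mtdeps(rec2, fcfg)
        passed2 = out2.loc[out2["passes_filter2"], "protein_id"]
        f2, _ = filter_mito(quant[quant["protein_id"].isin(passed2)], scores)
        set2 = set(f2["protein_id"])

        assert set1 == set2
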