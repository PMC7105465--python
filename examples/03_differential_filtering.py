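"""Filter 2: fold change + unique peptides + one-way ANOVA.

Technical replicates are averaged into biological replicates, fold change is
the KO/Ctrl ratio of condition means (magnitude >= 1 plus direction), and
significance comes from a one-way between-subject ANOVA.  A protein passes
with FC >= 1.5, >= 2 unique peptides and p <= 0.05.
"""

from mitodep import (FilterConfig, SimulationConfig,
                     average_technical_replicates, build_dep_table,
                     evidence_table, filter_mito, generate_design,
                     generate_peptide_intensities, generate_truth,
                     normalize_runs, rollup_proteins, score_proteins,
                     select_mtdeps)

config = SimulationConfig(n_proteins=500, frac_dep=0.2, planted_fc=2.0,
                          min_peptides=2, frac_unique_peptides=1.0, seed=1)
design = generate_design(config)
truth = generate_truth(config)
quant = rollup_proteins(normalize_runs(
    generate_peptide_intensities(truth, design, config))[0])
scores = score_proteins(evidence_table(truth))
filtered, _ = filter_mito(quant, scores)

matrix = average_technical_replicates(filtered, design)
records = build_dep_table(matrix, filtered, control="Ctrl", test=["KO1"],
                          scores=scores)
dep, summary = select_mtdeps(records, FilterConfig(fc_threshold=1.5))
print(f"mtDEPs: {summary}")

planted = set(truth.loc[truth["is_dep"], "protein_id"])
selected = set(dep.loc[dep["passes_filter2"], "protein_id"])
print(f"planted effects recovered: {len(selected & planted)}/{len(planted)}"
      f" (false positives: {len(selected - planted)})")
# 'total' counts proteins passing both filters; up + down = total always.
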