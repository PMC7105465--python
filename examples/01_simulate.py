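"""Generate a synthetic knock-out vs control proteomics experiment.

Builds the study-style design (2 conditions x 3 biological x 3 technical
replicates), plants two-fold changes on a fraction of mitochondrial
proteins, and draws noisy peptide intensities with missing values.
"""

from mitodep import (SimulationConfig, generate_design,
                     generate_peptide_intensities, generate_truth)

config = SimulationConfig(n_proteins=500, frac_mito=0.3, frac_dep=0.2,
                          planted_fc=2.0, noise_cv=0.15, missing_rate=0.05,
                          seed=1)
design = generate_design(config)
truth = generate_truth(config)
peptides = generate_peptide_intensities(truth, design, config)

print(f"runs: {len(design)} "
      f"({design['condition'].nunique()} conditions x "
      f"{design['bio_rep'].nunique()} bio x "
      f"{design['tech_rep'].nunique()} tech)")
print(f"proteins: {len(truth)}, mitochondrial: {truth['is_mito'].sum()}, "
      f"planted DEPs: {truth['is_dep'].sum()} "
      f"({(truth['direction'] == 'down').sum()} down / "
      f"{(truth['direction'] == 'up').sum()} up)")
print(f"peptide measurements: {len(peptides)}, "
      f"missing: {peptides['intensity'].isna().mean():.1%}")
# The truth table is the ground truth downstream stages are judged against:
# every planted DEP has true_fc = 2 in the stated direction, all others 1.
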