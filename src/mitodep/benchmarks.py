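"""Reference benchmark runs of the pipeline on its packaged presets.

These helpers execute the full method on the packaged study-condition
presets and return measured quantities (DEP counts, p-value calibration,
planted-effect recovery).  They exist so the documentation, the test suite
and reproduction scripts all run the identical computation.
"""

from __future__ import annotations

import pandas as pd

from .differential import (average_technical_replicates, build_dep_table,
                           select_mtdeps)
from .presets import cell_scenario, null_calibration, recovery_benchmark
from .quantify import normalize_runs, rollup_proteins
from .scoring import filter_mito, score_proteins
from .simulate import (evidence_table, generate_design,
                       generate_peptide_intensities, generate_truth)

__all__ = ["run_filtering", "scenario_counts", "null_pvalues",
           "recovery_stats"]


def run_filtering(config, seed: int | None = None):
    """Simulate -> quantify -> Filter 1 -> Filter 2 under one config.

    Returns ``(dep_table, summary, truth)`` where ``summary`` is the
    total/up/down count dict over proteins passing both filters.
    """
    sim = config.simulation
    if seed is not None:
        import dataclasses
        sim = dataclasses.replace(sim, seed=int(seed))
    design = generate_design(sim)
    truth = generate_truth(sim, config.scoring)
    peptides = generate_peptide_intensities(truth, design, sim)
    if config.quant.normalization == "median-ratio":
        peptides, _ = normalize_runs(peptides)
    quant = rollup_proteins(peptides, statistic=config.quant.rollup)
    scores = score_proteins(evidence_table(truth, config.scoring),
                            config.scoring)
    filtered, _ = filter_mito(quant, scores)
    matrix = average_technical_replicates(filtered, design)
    test = sorted(c for c in design["condition"].unique() if c != "Ctrl")
    records = build_dep_table(matrix, filtered, control="Ctrl", test=test,
                              scores=scores)
    dep, summary = select_mtdeps(records, config.filter)
    return dep, summary, truth


def scenario_counts(seed: int = 0) -> dict[str, int]:
    """Noiseless cell-scenario replay: expected {total 62, down 46, up 16}."""
    _, summary, _ = run_filtering(cell_scenario(seed=seed))
    return summary


def null_pvalues(seed: int, n_proteins: int = 2000) -> pd.Series:
    """ANOVA p-values of one no-effect simulation (2 cond x 3 bio x 3 tech)."""
    from .differential import anova_pvalue

    cfg = null_calibration(seed=seed, n_proteins=n_proteins)
    sim = cfg.simulation
    design = generate_design(sim)
    truth = generate_truth(sim, cfg.scoring)
    peptides, _ = normalize_runs(
        generate_peptide_intensities(truth, design, sim))
    quant = rollup_proteins(peptides)
    matrix = average_technical_replicates(quant, design)
    return anova_pvalue(matrix).dropna()


def recovery_stats(seed: int, noise_cv: float = 0.15,
                   n_proteins: int = 300) -> dict[str, float]:
    """Planted-effect recovery under the benchmark noise conditions.

    Returns sensitivity (recovered / planted) and the false-positive count.
    """
    cfg = recovery_benchmark(seed=seed, noise_cv=noise_cv,
                             n_proteins=n_proteins)
    dep, _, truth = run_filtering(cfg)
    selected = set(dep.loc[dep["passes_filter2"], "protein_id"])
    planted = set(truth.loc[truth["is_dep"], "protein_id"])
    return {
        "sensitivity": len(selected & planted) / len(planted),
        "false_positives": len(selected - planted),
        "n_planted": len(planted),
    }
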