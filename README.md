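# mitodep

Mitochondria-focused differential proteomics, as a tested, reusable Python
pipeline. `mitodep` implements the two-stage filtering strategy used in
organelle-enriched label-free (DIA) proteomics of knock-out vs control
models:

1. **Quantitation** — peptide MS1 precursor intensities are normalized
   across runs (median log-ratio to a reference run) and rolled up to
   protein abundances using **only unique, non-conflicting peptides**, with
   per-protein unique-peptide counts retained.
2. **Filter 1 — mitochondrial confidence.** Each protein carries integer
   evidence points from several annotation sources (curated catalog 0–3, GO
   cellular-component 0–2, experimental proteomics evidence 0–2, predicted
   targeting sequence 0–1). The total score *S* classifies the protein:
   High Confidence for *S* ∈ [6, 8], Medium for *S* ∈ [3, 5], discarded for
   *S* < 3. HC and MC proteins proceed.
3. **Filter 2 — differential selection.** Technical replicates are averaged
   into biological replicates; per protein, the fold change
   FC = max(m̄_Ctrl, m̄_KO) / min(m̄_Ctrl, m̄_KO) (with an up/down direction)
   and a one-way between-subject ANOVA p-value are computed. A protein is a
   **mtDEP** when FC ≥ 1.5 (cell preset; 1.3 for mouse tissue), it has ≥ 2
   unique peptides, and p ≤ 0.05.
4. **Enrichment** — hypergeometric over-representation of mtDEPs in
   user-supplied GMT gene sets (BH-adjusted), plus cross-model DEP/pathway
   overlap reports.

Because real organelle-proteomics deposits require commercial quantitation
software to reproduce, the package ships a **ground-truth simulator**: it
generates the full replicate structure (2+ conditions × 3 biological × 3
technical replicates), plants fold changes on a chosen fraction of
mitochondrial proteins, fabricates graded annotation evidence, and adds
log-normal intensity noise and missing values — so every stage is testable
against known truth.

## Worked example

```bash
mitodep run-all --preset cell-scenario --seed 1 --out-dir out/
```

prints

```
{"down": 46, "total": 62, "up": 16}
manifest: seed=1 config_hash=60a71010c599
```

The `cell-scenario` preset plants 62 two-fold changes (46 down, 16 up) among
300 mitochondrial proteins with zero noise; the pipeline recovers exactly
those counts — total mtDEPs, down- and up-regulated — demonstrating the
chain is lossless in the noiseless limit. `out/` contains every intermediate
table (`peptides.tsv`, `quant.tsv`, `scores.tsv`, `dep.tsv`, volcano-plot
coordinates, enrichment results) plus `summary.json` and a `manifest.json`
whose checksums are byte-identical across re-runs with the same seed.

From Python (see `examples/` for one script per capability):

```python
from mitodep.benchmarks import recovery_stats
stats = recovery_stats(seed=1)          # planted fc=2, CV 0.15, 3x3 design
print(stats)                            # {'sensitivity': 1.0, 'false_positives': 0, 'n_planted': 45}
```

Under realistic noise (CV 0.15) the pipeline recovers ~98% of planted
effects with essentially no false positives; with no planted effects the
ANOVA p-values are uniform (≈5% fall below 0.05).

## Layout

- `src/mitodep/` — library (`simulate`, `quantify`, `scoring`,
  `differential`, `enrichment`, `tableio`, `pipeline`, `cli`)
- `examples/` — five narrative scripts, one per capability
- `tests/` — pytest suite, including property tests and oracle checks
- `docs/methods.md` — model, assumptions, parameter choices, limitations
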