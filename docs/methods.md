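# Methods

## The analysis model

`mitodep` models the downstream half of an organelle-enriched, label-free
(DIA) quantitative proteomics experiment comparing knock-out (KO) genotypes
with a control cell line or tissue. The raw-spectra stages (acquisition,
database search, FDR control) are out of scope; the pipeline starts at
quantified peptide precursor intensities.

**Quantitation.** Runs are placed on a common intensity scale by a single
multiplicative factor per run, chosen so the *median log-ratio* of peptides
shared with a reference run is zero. The reference is the run with the most
observed peptides (ties broken lexicographically by run id). Median-ratio
normalization is the standard open equivalent of the "standardized
expression profiles" step of commercial packages; it is exactly scale
equivariant and rank preserving within a run. Protein abundance per run is
the **sum** of observed unique-peptide intensities (a mean is available);
shared peptides contribute nothing, mirroring quantitation restricted to
non-conflicting identifications. Missing peptide measurements are treated
as unobserved, never as zero: a protein's abundance is missing only when no
contributing peptide was observed in that run. The unique-peptide count is
experiment-wide (a unique peptide observed in ≥ 1 run counts once); whether
the original commercial analysis counted per comparison instead is not
recoverable, so the experiment-wide convention is fixed and documented here.

**Filter 1 (mitochondrial confidence).** Evidence points from each
annotation source are summed; the bands are High Confidence 6–8, Medium
3–5, discard < 3. The published per-source point table lives in
supplementary material that is not openly reproduced, so the default
scheme — catalog 0–3, GO cellular-component 0–2, experimental evidence 0–2,
targeting-sequence prediction 0–1, summing to 8 — is a documented stand-in;
the entire scheme (sources, maxima, bands) is configuration data and can be
replaced verbatim when the original table is available. The Medium band "3
and 5" is read as the inclusive interval [3, 5]; any other reading leaves
score 4 unclassified, contradicting the three-way partition.

**Filter 2 (differential selection).** Technical replicates are averaged
into their biological replicate *before* statistics, making the biological
replicate the experimental unit (the conservative resolution of technical
pseudo-replication; whether the original software tested technical runs
directly is not recoverable from public descriptions). Fold change is the
ratio of condition means of the averaged, normalized abundances, reported as
a magnitude ≥ 1 plus a direction; multiple KO conditions may be pooled into
one test group via the design, which is data, not code. Significance is a
one-way fixed-effects ANOVA across condition groups. The filter is
FC ≥ `fc_threshold` (1.5 cell preset, 1.3 mouse preset) ∧ unique peptides ≥ 2
∧ p ≤ 0.05. Some descriptions state the fold-change cut as strict (">")
and others as inclusive ("≥"); the default is inclusive with a
`fc_inclusive` switch. Raw p-values reproduce the published selection rule;
an optional Benjamini–Hochberg mode (`use_bh`) is provided but off by
default.

**Enrichment.** Over-representation of mtDEPs in GMT gene sets uses the
upper-tail hypergeometric probability P(X ≥ k) with BH adjustment across
sets. This is an open methodological stand-in for proprietary
pathway-categorization products, not a reproduction of their algorithms.
The default background universe is the Filter-1 survivors (HC+MC),
switchable to all quantified proteins.

## Numerical choices

- **ANOVA operates on log2 abundances by default.** Intensity noise is
  multiplicative, so the log transform is variance-stabilizing and makes
  the null F-statistic's assumptions hold; with `log_transform=False` the
  test runs on linear abundances. The F = t² identity with the two-group
  t-test holds on whatever scale both are given.
- **Degenerate variance.** Zero within-group variance with equal group
  means gives p = 1; with unequal means, the smallest positive double
  (both logged). Sums of squares are compared against a relative floor
  (~1e-20 of the squared data scale) so that bit-identical noiseless
  replicates are recognized as zero-variance despite float rounding.
- **Missing data.** A protein is tested only when *every* condition group
  has ≥ 2 observed biological values; otherwise p is missing and the
  protein cannot pass Filter 2 (it is logged, not dropped silently). Fold
  change needs ≥ 1 observed value per group. A zero group mean against a
  positive one yields an infinite FC with a warning; two zero means yield a
  missing FC.
- **Ties and ordering.** Enrichment results sort by p ascending with set
  name as tie-break; the normalization reference rule is deterministic; all
  table writers emit fixed column orders, making full runs byte-identical
  under a fixed seed.

## The simulator

The generator emulates the modelled study's structure: the first condition
is `Ctrl`, the rest `KO1`, `KO2`, …, each condition with `n_bio_reps`
biological replicates analysed in `n_tech_reps` technical replicates
(default 2 × 3 × 3 = 18 runs). Ground truth plants `frac_dep` of the
mitochondrial proteins with a fold change of exactly `planted_fc`, split
`frac_down` down / rest up (default 46/62, the down/up split of the
cell-model preset), applied in all KO conditions relative to control.

Choices the underlying study does not constrain, fixed here once:

- **Noise model:** multiplicative log-normal, with σ chosen so the
  *linear-scale* CV equals `noise_cv` (default 0.15, a typical label-free
  between-replicate CV); drawn per (peptide, biological replicate). A
  smaller technical component (CV = `tech_cv_ratio` × `noise_cv`, default
  half) is drawn per run, making technical-replicate averaging meaningful.
- **Peptides per protein:** `min_peptides + Poisson(mean − min_peptides)`
  with mean 4; `min_peptides` defaults to 1. Benchmark presets that assert
  exact noiseless recovery use `min_peptides=2, frac_unique_peptides=1` so
  the ≥ 2-unique-peptide criterion is structurally satisfiable for every
  planted effect rather than seed-dependent.
- **Ionization efficiency:** per-peptide log-normal factor (σ = 0.8),
  constant across runs — peptides of one protein span the usual order of
  magnitude in MS1 response.
- **Base abundance:** log-normal around 10⁶ (σ = 1), giving a realistic
  dynamic range.
- **Missingness:** completely at random at `missing_rate` (default 5%);
  intensity-dependent missingness is deliberately out of scope.
- **Annotation evidence:** drawn per class (high per-source success
  probabilities for mitochondrial proteins, low otherwise) and clamped to
  the correct side of the Medium-Confidence floor, so misannotation occurs
  *only* through the explicit `contamination_rate` flag (default 2%). This
  makes Filter-1 behaviour on simulated data exact and auditable.

**What the simulator does not emulate** — and hence what passing tests do
not show about real data: correlated peptide noise within a protein,
intensity-dependent missingness, retention-time or batch drift, shared
peptide reassignment (razor peptides), interference between co-eluting
precursors, and annotation databases whose errors are structured rather
than random. Sensitivity measured here (≈98% at fc = 2, CV 0.15, n = 3) is
an upper bound on what equivalent real data would give.

## Benchmark presets and problem sizes

- `cell-scenario`: 1000 proteins (300 mitochondrial), 62 planted effects
  (46 down / 16 up), fc 2, zero noise/missingness/contamination. The
  pipeline must report exactly total 62 / down 46 / up 16 for any seed.
- `recovery`: 300 proteins, fc 2, CV 0.15, 3 × 3 design; sensitivity is
  averaged over 20 seeds.
- `null`: 2000 proteins, no planted effects; the ANOVA p-value distribution
  is checked for uniformity (binomial interval on the fraction ≤ 0.05, and
  Kolmogorov–Smirnov) per seed over 5 seeds.

These sizes keep a full verification run in seconds while leaving the
binomial/KS checks well-powered; all are parameters, not constants.

## Known limitations

- The default scoring scheme is a stand-in with the correct band structure,
  not the published per-source table.
- The hypergeometric ORA is not a reproduction of proprietary pathway
  analysis; pathway-level conclusions on real data depend on the gene-set
  collection supplied.
- No moderated (empirical-Bayes) variance shrinkage: with n = 3 biological
  replicates the plain ANOVA is noticeably noisier than limma-style tests;
  this mirrors the modelled analysis rather than best current practice.
- Identifiers are opaque strings; no accession-format validation or mapping
  between protein and gene namespaces is attempted.
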