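"""Configuration objects for every pipeline stage.

All tunables live here as frozen-ish dataclasses with eager validation: a bad
value raises :class:`~mitodep.errors.ConfigError` naming the offending field,
so a pipeline never starts with a silently nonsensical setting.  Thresholds
are data, not code: the scoring bands and the differential filter cut-offs are
fields of :class:`ScoringScheme` and :class:`FilterConfig` and can be loaded
from a YAML/JSON file (see :func:`load_pipeline_config`).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from .errors import ConfigError

__all__ = [
    "SimulationConfig",
    "ScoringScheme",
    "FilterConfig",
    "EnrichmentConfig",
    "QuantConfig",
    "PipelineConfig",
    "DEFAULT_SCHEME",
    "FILTER_PRESETS",
    "load_pipeline_config",
]


def _require(cond: bool, field_name: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"{field_name}: {msg}")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic label-free proteomics experiment.

    Defaults emulate the study design this package models: two conditions
    (control vs knock-out), three biological replicates each analysed in
    technical triplicates, ~30% mitochondrial proteins, planted two-fold
    changes with the down/up split observed in the cell model, log-normal
    multiplicative intensity noise and a small completely-at-random
    missingness rate.

    Parameters
    ----------
    n_proteins
        Number of simulated proteins.
    frac_mito
        Fraction of proteins that are truly mitochondrial.
    frac_dep
        Fraction of *mitochondrial* proteins carrying a planted fold change.
    planted_fc
        Magnitude (>1) of every planted fold change.
    frac_down
        Fraction of planted changes that are down-regulated in the test
        condition (default 46/62, the split of the cell-model preset).
    peptides_per_protein
        Mean peptide count per protein; counts are drawn as
        ``min_peptides + Poisson(peptides_per_protein - min_peptides)``.
    min_peptides
        Structural lower bound on peptides per protein (>=1).
    frac_unique_peptides
        Probability that a peptide maps uniquely to its protein.
    noise_cv
        Linear-scale coefficient of variation of the biological
        (per biological replicate) multiplicative log-normal noise.
    tech_cv_ratio
        Technical-replicate CV as a fraction of ``noise_cv`` (default 0.5).
    missing_rate
        Probability that any peptide/run cell is missing (MCAR).
    contamination_rate
        Probability that a protein's annotation evidence is drawn from the
        *wrong* localisation class (misannotation).
    n_conditions, n_bio_reps, n_tech_reps
        Replicate structure; the first condition is labelled ``Ctrl`` and the
        others ``KO1``, ``KO2``, ...
    seed
        Seed for all randomness in the simulator.
    """

    n_proteins: int = 1000
    frac_mito: float = 0.30
    frac_dep: float = 0.20
    planted_fc: float = 2.0
    frac_down: float = 46 / 62
    peptides_per_protein: float = 4.0
    min_peptides: int = 1
    frac_unique_peptides: float = 0.8
    noise_cv: float = 0.15
    tech_cv_ratio: float = 0.5
    missing_rate: float = 0.05
    contamination_rate: float = 0.02
    n_conditions: int = 2
    n_bio_reps: int = 3
    n_tech_reps: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_proteins >= 1, "n_proteins", "must be >= 1")
        for name in ("frac_mito", "frac_dep", "frac_down",
                     "frac_unique_peptides", "missing_rate",
                     "contamination_rate"):
            v = getattr(self, name)
            _require(0.0 <= v <= 1.0, name, f"must be in [0, 1], got {v}")
        _require(self.planted_fc > 1.0, "planted_fc",
                 f"must be > 1, got {self.planted_fc}")
        _require(self.min_peptides >= 1, "min_peptides", "must be >= 1")
        _require(self.peptides_per_protein >= self.min_peptides,
                 "peptides_per_protein",
                 f"must be >= min_peptides ({self.min_peptides})")
        _require(self.noise_cv >= 0.0, "noise_cv", "must be >= 0")
        _require(self.tech_cv_ratio >= 0.0, "tech_cv_ratio", "must be >= 0")
        _require(self.n_conditions >= 2, "n_conditions", "must be >= 2")
        _require(self.n_bio_reps >= 2, "n_bio_reps", "must be >= 2")
        _require(self.n_tech_reps >= 1, "n_tech_reps", "must be >= 1")
        _require(int(self.seed) == self.seed, "seed", "must be an integer")


@dataclass
class ScoringScheme:
    """Mitochondrial-confidence scoring scheme.

    ``sources`` is an ordered list of ``(source_name, max_points)``; a
    protein's total score is the sum of its per-source evidence values.
    ``hc_range`` / ``mc_range`` are inclusive integer bands for High and
    Medium confidence; totals outside both bands are discarded.
    """

    sources: Sequence[tuple[str, int]] = (
        ("mito_catalog", 3),       # curated mitochondrial catalog membership
        ("go_cc_mito", 2),         # cellular-component "mitochondrion" annotation
        ("experimental", 2),       # experimental mitochondrial-proteomics evidence
        ("targeting_signal", 1),   # predicted mitochondrial targeting sequence
    )
    hc_range: tuple[int, int] = (6, 8)
    mc_range: tuple[int, int] = (3, 5)

    def __post_init__(self) -> None:
        self.sources = tuple((str(n), int(m)) for n, m in self.sources)
        names = [n for n, _ in self.sources]
        _require(len(names) == len(set(names)), "sources",
                 "source names must be unique")
        _require(all(m >= 0 for _, m in self.sources), "sources",
                 "max points must be >= 0")
        hc_lo, hc_hi = self.hc_range
        mc_lo, mc_hi = self.mc_range
        _require(hc_lo <= hc_hi, "hc_range", "lower bound exceeds upper")
        _require(mc_lo <= mc_hi, "mc_range", "lower bound exceeds upper")
        _require(mc_hi < hc_lo, "hc_range",
                 "hc_range must lie strictly above mc_range")
        _require(self.max_total >= hc_hi, "sources",
                 "sum of max points must cover the top of hc_range")

    @property
    def max_total(self) -> int:
        return sum(m for _, m in self.sources)

    @property
    def source_names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.sources)


DEFAULT_SCHEME = ScoringScheme()


@dataclass
class FilterConfig:
    """Differential-selection thresholds (Filter 2).

    ``fc_threshold`` defaults to the cell-line preset (1.5); the mouse-tissue
    preset uses 1.3.  The fold-change comparison is inclusive (>=) by default;
    set ``fc_inclusive=False`` for a strict ``>``.  ``use_bh`` switches the
    p-value criterion to Benjamini-Hochberg-adjusted q-values (off by default,
    matching raw ``p <= 0.05`` selection).
    """

    fc_threshold: float = 1.5
    p_threshold: float = 0.05
    min_unique_peptides: int = 2
    fc_inclusive: bool = True
    use_bh: bool = False

    def __post_init__(self) -> None:
        _require(self.fc_threshold > 1.0, "fc_threshold", "must be > 1")
        _require(0.0 < self.p_threshold < 1.0, "p_threshold",
                 "must be in (0, 1)")
        _require(self.min_unique_peptides >= 0, "min_unique_peptides",
                 "must be >= 0")


FILTER_PRESETS = {
    "cell": FilterConfig(fc_threshold=1.5),
    "mouse": FilterConfig(fc_threshold=1.3),
}


@dataclass
class QuantConfig:
    """Peptide-to-protein quantitation options."""

    normalization: str = "median-ratio"   # or "none"
    rollup: str = "sum"                   # or "mean"

    def __post_init__(self) -> None:
        _require(self.normalization in ("median-ratio", "none"),
                 "normalization", f"unknown method {self.normalization!r}")
        _require(self.rollup in ("sum", "mean"), "rollup",
                 f"unknown statistic {self.rollup!r}")


@dataclass
class EnrichmentConfig:
    """Over-representation analysis options."""

    gmt_path: str | None = None       # None -> simulator-generated sets
    background: str = "filter1"       # "filter1" (HC+MC) or "all"
    q_threshold: float = 0.05
    n_synthetic_sets: int = 20
    synthetic_set_size: int = 30

    def __post_init__(self) -> None:
        _require(self.background in ("filter1", "all"), "background",
                 f"unknown universe {self.background!r}")
        _require(0.0 < self.q_threshold < 1.0, "q_threshold",
                 "must be in (0, 1)")
        _require(self.n_synthetic_sets >= 1, "n_synthetic_sets", "must be >= 1")
        _require(self.synthetic_set_size >= 1, "synthetic_set_size",
                 "must be >= 1")


@dataclass
class PipelineConfig:
    """Everything an end-to-end run needs, in one nested object."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    quant: QuantConfig = field(default_factory=QuantConfig)
    scoring: ScoringScheme = field(default_factory=ScoringScheme)
    filter: FilterConfig = field(default_factory=FilterConfig)
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scoring"]["sources"] = [list(s) for s in self.scoring.sources]
        return d

    def config_hash_payload(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)


_SECTION_TYPES = {
    "simulation": SimulationConfig,
    "quant": QuantConfig,
    "scoring": ScoringScheme,
    "filter": FilterConfig,
    "enrichment": EnrichmentConfig,
}


def _build_section(cls, name: str, data: dict):
    if not isinstance(data, dict):
        raise ConfigError(f"section {name!r} must be a mapping")
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(
            f"unknown key(s) in section {name!r}: {sorted(unknown)}")
    if cls is ScoringScheme and "sources" in data:
        data = dict(data)
        data["sources"] = [tuple(s) for s in data["sources"]]
    if cls is ScoringScheme:
        data = dict(data)
        for rng in ("hc_range", "mc_range"):
            if rng in data:
                data[rng] = tuple(data[rng])
    return cls(**data)


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a YAML or JSON file.

    Unknown sections or keys are rejected with a :class:`ConfigError` rather
    than silently ignored.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text)  # YAML is a superset of JSON
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("top-level config must be a mapping")
    unknown = set(data) - set(_SECTION_TYPES)
    if unknown:
        raise ConfigError(f"unknown config section(s): {sorted(unknown)}")
    kwargs = {
        name: _build_section(cls, name, data[name])
        for name, cls in _SECTION_TYPES.items() if name in data
    }
    return PipelineConfig(**kwargs)
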