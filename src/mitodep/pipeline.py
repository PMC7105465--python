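"""End-to-end pipeline: simulate -> quantify -> score -> dep -> enrich.

``run_all`` chains every stage under one configuration and one seed, writes
all intermediate and final tables as TSV plus a JSON summary, and records a
manifest (config hash, seed, file checksums, stage timings, version) so that
re-running with identical config + seed provably reproduces identical
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .differential import (average_technical_replicates, build_dep_table,
                           select_mtdeps)
from .enrichment import enrich, read_gmt, write_gmt
from .errors import MitodepError
from .quantify import normalize_runs, rollup_proteins
from .scoring import filter_mito, score_proteins
from .simulate import (CONTROL_CONDITION, condition_labels, evidence_table,
                       generate_design, generate_gene_sets,
                       generate_peptide_intensities, generate_truth)
from .tableio import write_table

__all__ = ["run_all", "RunManifest"]

log = logging.getLogger(__name__)


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    checksums: dict[str, str] = field(default_factory=dict)
    timings_s: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: PipelineConfig, seed: int | None = None,
            out_dir: str | Path = ".") -> RunManifest:
    """Execute the full pipeline and write all outputs under ``out_dir``.

    ``seed`` overrides ``config.simulation.seed`` when given.  Any stage
    error aborts the run with the failing stage named.  Returns the manifest
    (also written as ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        config = dataclasses.replace(
            config,
            simulation=dataclasses.replace(config.simulation, seed=int(seed)))
    sim = config.simulation
    log.info("run-all: seed=%d thresholds: fc>=%s p<=%s min_unique=%s "
             "hc=%s mc=%s norm=%s rollup=%s",
             sim.seed, config.filter.fc_threshold, config.filter.p_threshold,
             config.filter.min_unique_peptides, config.scoring.hc_range,
             config.scoring.mc_range, config.quant.normalization,
             config.quant.rollup)

    manifest = RunManifest(
        config_hash=hashlib.sha256(
            config.config_hash_payload().encode()).hexdigest(),
        seed=sim.seed, version=__version__)
    written: list[Path] = []

    def _stage(name: str, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except MitodepError as exc:
            raise MitodepError(f"stage {name!r} failed: {exc}") from exc
        manifest.timings_s[name] = round(time.perf_counter() - t0, 4)
        return result

    def _write(df: pd.DataFrame, fname: str) -> None:
        path = out / fname
        write_table(df, path)
        written.append(path)

    # --- simulate ---------------------------------------------------------
    def sim_stage():
        design = generate_design(sim)
        truth = generate_truth(sim, config.scoring)
        peptides = generate_peptide_intensities(truth, design, sim)
        return design, truth, peptides

    design, truth, peptides = _stage("simulate", sim_stage)
    _write(design, "design.tsv")
    _write(truth, "truth.tsv")
    _write(peptides, "peptides.tsv")

    # --- quantify ---------------------------------------------------------
    def quant_stage():
        if config.quant.normalization == "median-ratio":
            normalized, factors = normalize_runs(peptides)
        else:
            normalized, factors = peptides, None
        quant = rollup_proteins(normalized, statistic=config.quant.rollup)
        return quant, factors

    quant, factors = _stage("quantify", quant_stage)
    _write(quant, "quant.tsv")
    if factors is not None:
        _write(factors.rename_axis("run_id").reset_index(),
               "scaling_factors.tsv")

    # --- score (Filter 1) -------------------------------------------------
    def score_stage():
        evidence = evidence_table(truth, config.scoring)
        scores = score_proteins(evidence, config.scoring)
        filtered, class_counts = filter_mito(quant, scores)
        return evidence, scores, filtered, class_counts

    evidence, scores, filtered_quant, class_counts = _stage("score",
                                                            score_stage)
    _write(evidence, "evidence.tsv")
    _write(scores, "scores.tsv")

    # --- differential (Filter 2) ------------------------------------------
    def dep_stage():
        matrix = average_technical_replicates(filtered_quant, design)
        test = [c for c in condition_labels(sim.n_conditions)
                if c != CONTROL_CONDITION]
        records = build_dep_table(matrix, filtered_quant,
                                  control=CONTROL_CONDITION, test=test,
                                  scores=scores)
        dep, summary = select_mtdeps(records, config.filter)
        return dep, summary

    dep, dep_summary = _stage("dep", dep_stage)
    _write(dep, "dep.tsv")
    volcano = dep[["protein_id", "log2fc", "p_value"]].copy()
    with np.errstate(divide="ignore"):
        volcano["neg_log10_p"] = -np.log10(dep["p_value"])
    _write(volcano, "volcano.tsv")

    # --- enrichment -------------------------------------------------------
    def enrich_stage():
        if config.enrichment.gmt_path:
            sets = read_gmt(config.enrichment.gmt_path)
        else:
            sets = generate_gene_sets(
                truth, sim, n_sets=config.enrichment.n_synthetic_sets,
                set_size=config.enrichment.synthetic_set_size)
            write_gmt(sets, out / "gene_sets.gmt")
            written.append(out / "gene_sets.gmt")
        if config.enrichment.background == "filter1":
            background = filtered_quant["protein_id"].unique()
        else:
            background = quant["protein_id"].unique()
        dep_ids = dep.loc[dep["passes_filter2"], "protein_id"]
        dep_ids = [d for d in dep_ids if d in set(background)]
        return enrich(dep_ids, background, sets)

    enrichment_result = _stage("enrich", enrich_stage)
    _write(enrichment_result, "enrichment.tsv")

    # --- summary + manifest -----------------------------------------------
    summary = {
        "mtdeps": dep_summary,
        "confidence_classes": class_counts,
        "n_proteins_quantified": int(quant["protein_id"].nunique()),
        "n_enriched_sets_tested": int(len(enrichment_result)),
        "thresholds": {
            "fc_threshold": config.filter.fc_threshold,
            "p_threshold": config.filter.p_threshold,
            "min_unique_peptides": config.filter.min_unique_peptides,
            "fc_inclusive": config.filter.fc_inclusive,
            "hc_range": list(config.scoring.hc_range),
            "mc_range": list(config.scoring.mc_range),
        },
    }
    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True)
                            + "\n")
    written.append(summary_path)

    for path in written:
        manifest.checksums[path.name] = _sha256(path)
    (out / "manifest.json").write_text(manifest.to_json() + "\n")
    log.info("run-all complete: %s", dep_summary)
    return manifest
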