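"""Synthetic label-free proteomics experiments with known ground truth.

The simulator starts where a DIA quantitation pipeline ends: quantified
peptide precursor intensities.  It emulates the replicate structure of the
modelled study (control vs knock-out conditions, biological replicates each
run in technical replicates), plants fold changes on a chosen fraction of
mitochondrial proteins, fabricates graded per-database localisation evidence,
and injects multiplicative log-normal noise plus completely-at-random missing
values.  Every draw flows from ``config.seed``, so identical configurations
give bit-identical tables.

Tables are plain :class:`pandas.DataFrame` objects with fixed column names:

* design:   ``run_id, condition, bio_rep, tech_rep``
* truth:    ``protein_id, is_mito, is_dep, true_fc, direction,
  base_abundance`` plus one integer evidence column per scoring source
* peptides: ``peptide_id, protein_id, is_unique, run_id, intensity``
  (missing cells carry NaN intensity; the (peptide_id, run_id) grid is full)
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import DEFAULT_SCHEME, ScoringScheme, SimulationConfig
from .errors import InputError

__all__ = [
    "generate_design",
    "generate_truth",
    "generate_peptide_intensities",
    "generate_gene_sets",
    "evidence_table",
    "CONTROL_CONDITION",
]

CONTROL_CONDITION = "Ctrl"

# Spread of per-peptide ionization efficiencies (log-normal sigma): peptides
# of one protein routinely span an order of magnitude in MS1 response.
_ION_SIGMA = 0.8
# Dynamic range of protein base abundances (log-normal around 1e6 counts).
_BASE_LOG_MEAN = np.log(1e6)
_BASE_LOG_SIGMA = 1.0


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    # One independent stream per stage so adding draws to one operation does
    # not reshuffle the others.
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(config.seed), spawn_key=(stage,)))


def condition_labels(n_conditions: int) -> list[str]:
    """``Ctrl`` first, then ``KO1``, ``KO2``, ..."""
    return [CONTROL_CONDITION] + [f"KO{i}" for i in range(1, n_conditions)]


def generate_design(config: SimulationConfig) -> pd.DataFrame:
    """One row per MS run: condition x biological x technical replicate."""
    rows = []
    for cond in condition_labels(config.n_conditions):
        for b in range(1, config.n_bio_reps + 1):
            for t in range(1, config.n_tech_reps + 1):
                rows.append({
                    "run_id": f"{cond}_b{b}_t{t}",
                    "condition": cond,
                    "bio_rep": f"b{b}",
                    "tech_rep": f"t{t}",
                })
    return pd.DataFrame(rows, columns=["run_id", "condition", "bio_rep",
                                       "tech_rep"])


def _lognormal_sigma(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv * cv)))


def _draw_profile(rng: np.random.Generator, n: int, scheme: ScoringScheme,
                  mito: bool) -> np.ndarray:
    """Per-source evidence for ``n`` proteins of one localisation class.

    Mitochondrial proteins draw high per-source success probabilities and are
    clamped to a total at or above the Medium-Confidence floor of ``scheme``;
    non-mitochondrial proteins draw low probabilities and are clamped below
    it.  The clamp makes class membership decide the score band exactly;
    misannotation enters only through the explicit contamination flag of
    :func:`generate_truth`.
    """
    floor = scheme.mc_range[0]
    if mito:
        probs = {"default": 0.65, 0: 0.80}  # first source is the catalog
    else:
        probs = {"default": 0.05, 0: 0.03}
    cols = []
    for j, (_, max_pts) in enumerate(scheme.sources):
        p = probs.get(j, probs["default"])
        cols.append(rng.binomial(max_pts, p, size=n))
    ev = np.stack(cols, axis=1)
    total = ev.sum(axis=1)
    if mito:
        # lift sub-threshold totals by topping up the first source
        short = total < floor
        if short.any():
            need = floor - total[short]
            first_max = scheme.sources[0][1]
            ev[short, 0] = np.minimum(ev[short, 0] + need, first_max)
            # if the first source cannot absorb it, spill into the next ones
            total = ev.sum(axis=1)
            still = total < floor
            for j in range(1, ev.shape[1]):
                if not still.any():
                    break
                cap = scheme.sources[j][1]
                add = np.minimum(floor - total, cap - ev[:, j])
                ev[still, j] += np.maximum(add[still], 0)
                total = ev.sum(axis=1)
                still = total < floor
    else:
        over = total >= floor
        if over.any():
            # strip points source-by-source until the total sits below floor
            for j in range(ev.shape[1]):
                excess = ev.sum(axis=1) - (floor - 1)
                take = np.minimum(ev[:, j], np.maximum(excess, 0))
                ev[over, j] -= take[over]
    return ev


def generate_truth(config: SimulationConfig,
                   scheme: ScoringScheme = DEFAULT_SCHEME) -> pd.DataFrame:
    """Ground-truth table: localisation, planted effects, evidence profile."""
    rng = _rng(config, stage=1)
    n = config.n_proteins
    ids = np.array([f"P{i:05d}" for i in range(1, n + 1)])

    n_mito = int(round(n * config.frac_mito))
    mito_idx = rng.choice(n, size=n_mito, replace=False)
    is_mito = np.zeros(n, dtype=bool)
    is_mito[mito_idx] = True

    n_dep = int(round(n_mito * config.frac_dep))
    dep_idx = rng.choice(mito_idx, size=n_dep, replace=False)
    is_dep = np.zeros(n, dtype=bool)
    is_dep[dep_idx] = True

    n_down = int(round(n_dep * config.frac_down))
    down_idx = rng.choice(dep_idx, size=n_down, replace=False)
    direction = np.full(n, "none", dtype=object)
    direction[dep_idx] = "up"
    direction[down_idx] = "down"

    true_fc = np.ones(n)
    true_fc[is_dep] = config.planted_fc

    base = np.exp(rng.normal(_BASE_LOG_MEAN, _BASE_LOG_SIGMA, size=n))

    contaminated = rng.random(n) < config.contamination_rate
    # evidence class = true localisation XOR contamination
    ev_class_mito = is_mito ^ contaminated
    ev = np.zeros((n, len(scheme.sources)), dtype=int)
    for cls in (True, False):
        mask = ev_class_mito == cls
        if mask.any():
            ev[mask] = _draw_profile(rng, int(mask.sum()), scheme, mito=cls)

    truth = pd.DataFrame({
        "protein_id": ids,
        "is_mito": is_mito,
        "is_dep": is_dep,
        "true_fc": true_fc,
        "direction": direction,
        "base_abundance": base,
    })
    for j, name in enumerate(scheme.source_names):
        truth[name] = ev[:, j]
    return truth


def evidence_table(truth: pd.DataFrame,
                   scheme: ScoringScheme = DEFAULT_SCHEME) -> pd.DataFrame:
    """Extract the annotation-evidence columns from a truth table."""
    cols = ["protein_id", *scheme.source_names]
    missing = [c for c in cols if c not in truth.columns]
    if missing:
        raise InputError(f"truth table lacks evidence column(s) {missing}")
    return truth[cols].copy()


def generate_peptide_intensities(truth: pd.DataFrame, design: pd.DataFrame,
                                 config: SimulationConfig) -> pd.DataFrame:
    """Long-form peptide intensity table over the full peptide x run grid.

    Expected intensity of peptide p of protein i in run r is
    ``base_abundance_i * ionization_p * effect_i(condition_r)`` where the
    condition effect applies ``true_fc`` (direction-signed) in non-control
    conditions.  Biological noise (CV ``noise_cv``) is drawn per
    (peptide, condition, bio_rep); a smaller technical component
    (CV ``tech_cv_ratio * noise_cv``) per (peptide, run).  Cells go missing
    completely at random at ``missing_rate``.
    """
    if len(truth) == 0:
        raise InputError("truth table is empty")
    if len(design) == 0:
        raise InputError("design table is empty")
    rng = _rng(config, stage=2)

    n = len(truth)
    n_pep = config.min_peptides + rng.poisson(
        config.peptides_per_protein - config.min_peptides, size=n)
    total_pep = int(n_pep.sum())

    protein_of_pep = np.repeat(np.arange(n), n_pep)
    pep_rank = np.concatenate([np.arange(1, k + 1) for k in n_pep])
    pep_ids = np.array([
        f"{truth['protein_id'].iloc[i]}_pep{j}"
        for i, j in zip(protein_of_pep, pep_rank)
    ])
    is_unique = rng.random(total_pep) < config.frac_unique_peptides
    ion = np.exp(rng.normal(0.0, _ION_SIGMA, size=total_pep))

    conditions = design["condition"].to_numpy()
    run_ids = design["run_id"].to_numpy()
    n_runs = len(design)
    bio_key = pd.factorize(
        design["condition"].astype(str) + "|" + design["bio_rep"].astype(str)
    )[0]
    n_bio = int(bio_key.max()) + 1

    # condition effect per protein per run
    fc = truth["true_fc"].to_numpy(dtype=float)
    sign = np.where(truth["direction"].to_numpy() == "down", -1.0, 1.0)
    effect_ko = fc ** sign                       # applied in KO conditions
    is_ctrl_run = conditions == CONTROL_CONDITION
    # (protein, run) effect matrix built lazily per peptide via indexing
    effect = np.where(is_ctrl_run[None, :], 1.0,
                      effect_ko[protein_of_pep][:, None])

    base = truth["base_abundance"].to_numpy()[protein_of_pep]
    expected = base[:, None] * ion[:, None] * effect

    sigma_b = _lognormal_sigma(config.noise_cv)
    sigma_t = _lognormal_sigma(config.noise_cv * config.tech_cv_ratio)
    bio_noise = np.exp(rng.normal(-0.5 * sigma_b ** 2, sigma_b,
                                  size=(total_pep, n_bio)))
    tech_noise = np.exp(rng.normal(-0.5 * sigma_t ** 2, sigma_t,
                                   size=(total_pep, n_runs)))
    intensity = expected * bio_noise[:, bio_key] * tech_noise

    if config.missing_rate > 0:
        miss = rng.random((total_pep, n_runs)) < config.missing_rate
        intensity = np.where(miss, np.nan, intensity)

    out = pd.DataFrame({
        "peptide_id": np.repeat(pep_ids, n_runs),
        "protein_id": truth["protein_id"].to_numpy()[
            np.repeat(protein_of_pep, n_runs)],
        "is_unique": np.repeat(is_unique, n_runs),
        "run_id": np.tile(run_ids, total_pep),
        "intensity": intensity.ravel(),
    })
    return out


def generate_gene_sets(truth: pd.DataFrame, config: SimulationConfig,
                       n_sets: int = 20, set_size: int = 30,
                       ) -> dict[str, list[str]]:
    """Synthetic gene-set collection over the mitochondrial universe.

    One set (``planted_pathway``) is enriched in planted differential
    proteins; the rest are random draws from the mitochondrial proteins, so
    over-representation analysis on simulated data has both a signal and a
    calibrated null.
    """
    rng = _rng(config, stage=3)
    mito_ids = truth.loc[truth["is_mito"], "protein_id"].to_numpy()
    dep_ids = truth.loc[truth["is_dep"], "protein_id"].to_numpy()
    if len(mito_ids) == 0:
        raise InputError("truth table contains no mitochondrial proteins")
    set_size = min(set_size, len(mito_ids))
    sets: dict[str, list[str]] = {}
    n_dep_in = min(len(dep_ids), max(1, set_size // 2))
    if n_dep_in:
        members = list(rng.choice(dep_ids, size=n_dep_in, replace=False))
        fill_pool = np.setdiff1d(mito_ids, members)
        n_fill = min(set_size - n_dep_in, len(fill_pool))
        members += list(rng.choice(fill_pool, size=n_fill, replace=False))
        sets["planted_pathway"] = sorted(members)
    for i in range(1, n_sets):
        members = rng.choice(mito_ids, size=set_size, replace=False)
        sets[f"random_set_{i:02d}"] = sorted(members)
    return sets
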