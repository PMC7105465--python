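"""Run normalization and peptide-to-protein roll-up.

Quantitation is performed entirely on non-conflicting evidence: only peptides
mapping to a single protein (``is_unique``) contribute to protein abundance.
Run-to-run intensity scale differences are removed by median-log-ratio
normalization against a reference run, the standard open equivalent of the
"standardized expression profiles" step of commercial label-free packages.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import InputError, NormalizationError

__all__ = ["select_reference_run", "normalize_runs", "rollup_proteins"]

log = logging.getLogger(__name__)

PEPTIDE_COLUMNS = ["peptide_id", "protein_id", "is_unique", "run_id",
                   "intensity"]


def _check_peptides(peptides: pd.DataFrame) -> None:
    missing = [c for c in PEPTIDE_COLUMNS if c not in peptides.columns]
    if missing:
        raise InputError(f"peptide table lacks column(s) {missing}")


def select_reference_run(peptides: pd.DataFrame) -> str:
    """Run with the most observed (non-missing) peptides; ties lexicographic."""
    _check_peptides(peptides)
    obs = peptides.dropna(subset=["intensity"])
    if obs.empty:
        raise InputError("no observed intensities in peptide table")
    counts = obs.groupby("run_id").size()
    best = counts.max()
    return sorted(counts.index[counts == best])[0]


def normalize_runs(peptides: pd.DataFrame, reference: str | None = None,
                   ) -> tuple[pd.DataFrame, pd.Series]:
    """Scale every run so its median log-ratio to the reference is zero.

    Parameters
    ----------
    peptides
        Long-form peptide table (missing intensities as NaN).
    reference
        Reference run id; defaults to :func:`select_reference_run`.

    Returns
    -------
    (normalized, factors)
        A copy of the table with scaled intensities, and the per-run scalar
        factors applied (reference factor is exactly 1.0).

    Raises
    ------
    NormalizationError
        If a run shares no observed peptide with the reference.
    """
    _check_peptides(peptides)
    runs = sorted(peptides["run_id"].unique())
    if len(runs) < 2:
        raise InputError("normalization needs >= 2 runs")
    if reference is None:
        reference = select_reference_run(peptides)
    if reference not in runs:
        raise InputError(f"reference run {reference!r} not in table")

    obs = peptides.dropna(subset=["intensity"])
    wide = obs.pivot_table(index="peptide_id", columns="run_id",
                           values="intensity", aggfunc="first")
    if reference not in wide.columns:
        raise NormalizationError(
            f"reference run {reference!r} has no observed peptides")
    ref_col = wide[reference]

    factors = {}
    for run in runs:
        if run == reference:
            factors[run] = 1.0
            continue
        shared = wide[run].notna() & ref_col.notna()
        if not shared.any():
            raise NormalizationError(
                f"run {run!r} shares no observed peptides with reference "
                f"{reference!r}")
        med = np.median(np.log(wide.loc[shared, run] / ref_col[shared]))
        factors[run] = float(np.exp(-med))
    factors = pd.Series(factors, name="scaling_factor").sort_index()
    log.info("normalization reference=%s factors=%s", reference,
             factors.round(4).to_dict())

    out = peptides.copy()
    out["intensity"] = out["intensity"] * out["run_id"].map(factors)
    return out, factors


def rollup_proteins(peptides: pd.DataFrame, statistic: str = "sum",
                    ) -> pd.DataFrame:
    """Per-protein abundance per run from unique-peptide evidence only.

    ``abundance(protein, run)`` is the sum (or mean) of the observed
    intensities of that protein's unique peptides in that run; missing when
    no contributing peptide was observed.  Shared peptides contribute
    nothing.  ``n_unique_peptides`` counts, experiment-wide, the distinct
    unique peptides of the protein observed in at least one run.  Proteins
    with zero unique peptides are retained with all-missing abundances so the
    downstream filter rejects them visibly rather than silently.
    """
    _check_peptides(peptides)
    if statistic not in ("sum", "mean"):
        raise InputError(f"unknown rollup statistic {statistic!r}")
    dup = peptides.duplicated(subset=["peptide_id", "run_id"])
    if dup.any():
        raise InputError(
            f"duplicate (peptide_id, run_id) pairs, e.g. "
            f"{peptides.loc[dup, ['peptide_id', 'run_id']].iloc[0].tolist()}")

    proteins = np.sort(peptides["protein_id"].unique())
    runs = np.sort(peptides["run_id"].unique())

    uniq = peptides[peptides["is_unique"].astype(bool)]
    uniq_obs = uniq.dropna(subset=["intensity"])

    agg = getattr(uniq_obs.groupby(["protein_id", "run_id"])["intensity"],
                  statistic)()
    grid = pd.MultiIndex.from_product([proteins, runs],
                                      names=["protein_id", "run_id"])
    abundance = agg.reindex(grid)

    n_unique = (uniq_obs.groupby("protein_id")["peptide_id"].nunique()
                .reindex(proteins, fill_value=0))

    out = abundance.rename("abundance").reset_index()
    out["n_unique_peptides"] = out["protein_id"].map(n_unique).astype(int)
    n_zero = int((n_unique == 0).sum())
    if n_zero:
        log.warning("%d protein(s) have no observed unique peptides "
                    "(abundances missing)", n_zero)
    return out
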