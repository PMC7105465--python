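"""Mitochondrial-confidence scoring and Filter 1.

Each protein carries non-negative integer evidence points from several
annotation sources (curated catalog membership, GO cellular-component
annotation, experimental proteomics evidence, predicted targeting sequence by
default).  The total score classifies the protein: High Confidence inside
``hc_range`` (default 6-8), Medium Confidence inside ``mc_range`` (default
3-5), discarded otherwise.  Filter 1 retains the HC and MC proteins.
"""

from __future__ import annotations

import logging

import pandas as pd

from .config import DEFAULT_SCHEME, ScoringScheme
from .errors import InputError, ValidationError

__all__ = ["classify_score", "score_proteins", "filter_mito"]

log = logging.getLogger(__name__)

HC, MC, DISCARD = "HC", "MC", "DISCARD"


def classify_score(total: int, scheme: ScoringScheme = DEFAULT_SCHEME) -> str:
    """HC/MC/DISCARD class of one integer total score."""
    if scheme.hc_range[0] <= total <= scheme.hc_range[1]:
        return HC
    if scheme.mc_range[0] <= total <= scheme.mc_range[1]:
        return MC
    return DISCARD


def score_proteins(evidence: pd.DataFrame,
                   scheme: ScoringScheme = DEFAULT_SCHEME) -> pd.DataFrame:
    """Score every protein in an evidence table.

    Parameters
    ----------
    evidence
        One row per protein: ``protein_id`` plus one integer column per
        scoring source.

    Returns
    -------
    DataFrame with ``protein_id``, ``total_score``, ``confidence_class``.

    Raises
    ------
    ValidationError
        If an evidence value is negative, non-integer, or exceeds its
        source's configured maximum (names source and protein).
    """
    missing = [s for s in scheme.source_names if s not in evidence.columns]
    if missing:
        raise InputError(f"evidence table lacks source column(s) {missing}")
    if evidence["protein_id"].duplicated().any():
        dup = evidence.loc[evidence["protein_id"].duplicated(), "protein_id"]
        raise InputError(f"duplicate protein_id in evidence: {dup.iloc[0]!r}")

    evidence = evidence.copy()
    for name, max_pts in scheme.sources:
        col = evidence[name]
        vals = pd.to_numeric(col, errors="coerce")
        bad = vals.isna() | (vals != vals.round()) | (vals < 0) | (vals > max_pts)
        if bad.any():
            pid = evidence.loc[bad, "protein_id"].iloc[0]
            raise ValidationError(
                f"evidence value {col[bad].iloc[0]!r} for source {name!r} of "
                f"protein {pid!r} outside [0, {max_pts}]")
        evidence[name] = vals.astype(int)

    total = evidence[list(scheme.source_names)].sum(axis=1).astype(int)
    out = pd.DataFrame({
        "protein_id": evidence["protein_id"].to_numpy(),
        "total_score": total.to_numpy(),
    })
    out["confidence_class"] = [classify_score(t, scheme) for t in
                               out["total_score"]]
    return out


def filter_mito(quant: pd.DataFrame, scores: pd.DataFrame,
                ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Filter 1: keep quantified proteins of High or Medium confidence.

    Unscored proteins are treated as DISCARD and logged as a warning, not an
    error.  Returns the filtered quantitation table (same columns, subset of
    rows) and the per-class protein counts ``{"HC": ..., "MC": ...,
    "DISCARD": ...}`` over the proteins present in ``quant``.
    """
    if "protein_id" not in quant.columns:
        raise InputError("quant table lacks 'protein_id'")
    cls = scores.set_index("protein_id")["confidence_class"]
    proteins = pd.Index(quant["protein_id"].unique())
    assigned = cls.reindex(proteins)
    n_unscored = int(assigned.isna().sum())
    if n_unscored:
        log.warning("%d quantified protein(s) without a confidence score; "
                    "treated as DISCARD", n_unscored)
    assigned = assigned.fillna(DISCARD)
    counts = {c: int((assigned == c).sum()) for c in (HC, MC, DISCARD)}
    keep = set(assigned.index[assigned.isin([HC, MC])])
    out = quant[quant["protein_id"].isin(keep)].reset_index(drop=True)
    log.info("Filter 1: HC=%d MC=%d DISCARD=%d -> %d proteins retained",
             counts[HC], counts[MC], counts[DISCARD], len(keep))
    return out, counts
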