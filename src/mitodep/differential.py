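"""Differential selection (Filter 2): fold change, ANOVA, thresholds.

Technical replicates are averaged into their biological replicate before any
statistics, so the experimental unit is the biological replicate (a
between-subject design).  Fold change is the ratio of condition means of the
averaged, normalized protein abundances, expressed as a magnitude >= 1 plus a
direction (test relative to control).  Significance comes from a one-way
fixed-effects ANOVA across condition groups, computed on log2 abundances by
default (variance-stabilising for multiplicative intensity noise).  A protein
passes Filter 2 when fold change, unique-peptide count and ANOVA p-value all
meet their thresholds.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .config import FilterConfig
from .errors import InputError

__all__ = [
    "average_technical_replicates",
    "fold_change",
    "anova_pvalue",
    "build_dep_table",
    "select_mtdeps",
]

log = logging.getLogger(__name__)

_TINY_P = float(np.nextafter(0, 1))  # 0-limit convention for zero variance


def average_technical_replicates(quant: pd.DataFrame, design: pd.DataFrame,
                                 ) -> pd.DataFrame:
    """Mean abundance per (protein, condition, bio_rep) over technical reps.

    Returns a wide matrix: index ``protein_id``, columns a MultiIndex
    ``(condition, bio_rep)``.  A cell is the mean of its *observed* technical
    replicates, missing when none was observed.
    """
    known = set(design["run_id"])
    unknown = set(quant["run_id"]) - known
    if unknown:
        raise InputError(
            f"run(s) in quantitation table absent from design: "
            f"{sorted(unknown)[:3]}")
    merged = quant.merge(design[["run_id", "condition", "bio_rep"]],
                         on="run_id", how="left")
    matrix = merged.pivot_table(index="protein_id",
                                columns=["condition", "bio_rep"],
                                values="abundance", aggfunc="mean")
    # keep every protein, even all-missing ones
    all_proteins = pd.Index(np.sort(quant["protein_id"].unique()),
                            name="protein_id")
    return matrix.reindex(all_proteins)


def _as_condition_list(test) -> list[str]:
    return [test] if isinstance(test, str) else list(test)


def fold_change(matrix: pd.DataFrame, control: str, test) -> pd.DataFrame:
    """Per-protein fold-change magnitude and direction, test vs control.

    ``test`` may be one condition label or a list of labels to pool (e.g.
    several knock-out clones treated as one group).  With group means ``m_c``
    and ``m_t``: ``fc = max(m_c, m_t) / min(m_c, m_t)``; direction is ``up``
    when the test mean exceeds the control mean, ``down`` when below,
    ``none`` when equal.  A zero mean against a positive one yields an
    infinite fc (logged); fc is missing when either group has no observed
    value or both means are zero.
    """
    conds = matrix.columns.get_level_values(0)
    test_labels = _as_condition_list(test)
    for lbl in [control, *test_labels]:
        if lbl not in set(conds):
            raise InputError(f"condition {lbl!r} not present in matrix")
    m_c = matrix.loc[:, conds == control].mean(axis=1)
    m_t = matrix.loc[:, conds.isin(test_labels)].mean(axis=1)

    hi = np.maximum(m_c, m_t)
    lo = np.minimum(m_c, m_t)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = hi / lo
    both_zero = (hi == 0) & (lo == 0)
    fc = fc.where(~both_zero, np.nan)
    n_inf = int(np.isinf(fc).sum())
    if n_inf:
        log.warning("%d protein(s) with a zero group mean -> infinite fold "
                    "change", n_inf)
    direction = np.where(m_t > m_c, "up",
                         np.where(m_t < m_c, "down", "none"))
    direction = np.where(fc.isna(), "none", direction)
    with np.errstate(divide="ignore"):
        log2fc = np.where(m_t > m_c, np.log2(fc), -np.log2(fc))
    return pd.DataFrame({"fc": fc, "direction": direction,
                         "log2fc": log2fc}, index=matrix.index)


def anova_pvalue(matrix: pd.DataFrame, log_transform: bool = True,
                 ) -> pd.Series:
    """One-way fixed-effects ANOVA p-value per protein.

    Groups are the condition level of the matrix columns; values are the
    technical-replicate-averaged biological abundances (log2-transformed by
    default).  A protein needs every condition group to have >= 2 observed
    values, and >= 2 groups, else its p is missing.  Degenerate variance is
    handled by convention: zero within-group variance with equal means gives
    p = 1; with unequal means, the smallest positive float (both logged).
    """
    conds = matrix.columns.get_level_values(0)
    groups = pd.unique(conds)
    if len(groups) < 2:
        raise InputError("ANOVA needs >= 2 condition groups")
    X = matrix.to_numpy(dtype=float)
    if log_transform:
        with np.errstate(divide="ignore", invalid="ignore"):
            X = np.log2(X)
        X[~np.isfinite(X)] = np.nan

    n_prot = X.shape[0]
    k = len(groups)
    counts = np.zeros((n_prot, k))
    means = np.zeros((n_prot, k))
    ssw = np.zeros(n_prot)
    for j, g in enumerate(groups):
        sub = X[:, conds == g]
        counts[:, j] = np.sum(~np.isnan(sub), axis=1)
        with np.errstate(invalid="ignore"):
            means[:, j] = np.nanmean(sub, axis=1)
        dev = sub - means[:, j][:, None]
        ssw += np.nansum(dev * dev, axis=1)

    valid = (counts >= 2).all(axis=1)
    N = counts.sum(axis=1)
    with np.errstate(invalid="ignore"):
        grand = np.nansum(means * counts, axis=1) / N
    dev_b = means - grand[:, None]
    ssb = np.nansum(counts * dev_b * dev_b, axis=1)

    p = np.full(n_prot, np.nan)
    df1, df2 = k - 1, N - k
    # numerical floor: treat sums of squares as zero relative to the data scale
    scale = (np.max(np.abs(np.nan_to_num(X)), axis=1) if X.size
             else np.zeros(n_prot))
    tol = (scale + 1.0) ** 2 * 1e-20

    zero_w = ssw <= tol
    zero_b = ssb <= tol
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / df1) / (ssw / df2)
    ordinary = valid & ~zero_w
    p[ordinary] = scipy.stats.f.sf(F[ordinary], df1, df2[ordinary])
    p[valid & zero_w & zero_b] = 1.0
    p[valid & zero_w & ~zero_b] = _TINY_P
    n_degen = int((valid & zero_w).sum())
    if n_degen:
        log.info("%d protein(s) with zero within-group variance; p set by "
                 "convention", n_degen)
    return pd.Series(p, index=matrix.index, name="p_value")


def build_dep_table(matrix: pd.DataFrame, quant: pd.DataFrame,
                    control: str, test, scores: pd.DataFrame | None = None,
                    log_transform: bool = True) -> pd.DataFrame:
    """Assemble per-protein differential records (one row per protein).

    Columns: ``protein_id, fc, log2fc, direction, p_value,
    n_unique_peptides`` and, when ``scores`` is given, ``mito_class``.
    """
    fc = fold_change(matrix, control, test)
    p = anova_pvalue(matrix, log_transform=log_transform)
    n_unique = (quant.groupby("protein_id")["n_unique_peptides"].first()
                .reindex(matrix.index, fill_value=0))
    out = fc.assign(p_value=p, n_unique_peptides=n_unique.astype(int))
    if scores is not None:
        cls = scores.set_index("protein_id")["confidence_class"]
        out["mito_class"] = cls.reindex(matrix.index).fillna("DISCARD")
    return out.reset_index()


def select_mtdeps(records: pd.DataFrame, filter_config: FilterConfig,
                  ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Filter 2: fold change, unique-peptide count and p-value thresholds.

    Adds a boolean ``passes_filter2`` column.  Records with missing fc or p
    fail the filter (logged).  Returns the annotated table plus summary
    counts ``{"total": ..., "up": ..., "down": ...}`` over passing records;
    ``total == up + down`` always (an fc passing the >1 threshold cannot
    have direction ``none``).
    """
    req = {"fc", "direction", "p_value", "n_unique_peptides"}
    missing = req - set(records.columns)
    if missing:
        raise InputError(f"records lack column(s) {sorted(missing)}")
    out = records.copy()
    fc = out["fc"]
    p = out["p_value"]
    if filter_config.use_bh:
        obs = p.notna()
        q = pd.Series(np.nan, index=out.index)
        if obs.any():
            q[obs] = multipletests(p[obs], method="fdr_bh")[1]
        p = q
        out["q_value"] = q
    n_missing = int((fc.isna() | p.isna()).sum())
    if n_missing:
        log.info("%d record(s) with missing fc or p fail Filter 2", n_missing)
    if filter_config.fc_inclusive:
        fc_ok = fc >= filter_config.fc_threshold
    else:
        fc_ok = fc > filter_config.fc_threshold
    passes = (fc_ok.fillna(False)
              & (out["n_unique_peptides"] >= filter_config.min_unique_peptides)
              & (p <= filter_config.p_threshold).fillna(False))
    out["passes_filter2"] = passes.astype(bool)
    sel = out[out["passes_filter2"]]
    summary = {
        "total": int(len(sel)),
        "up": int((sel["direction"] == "up").sum()),
        "down": int((sel["direction"] == "down").sum()),
    }
    log.info("Filter 2: total=%d up=%d down=%d", summary["total"],
             summary["up"], summary["down"])
    return out, summary
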