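"""Hypergeometric over-representation analysis and cross-model comparison.

An open stand-in for proprietary pathway categorization: for each gene set,
the probability of drawing at least ``k`` set members when ``n`` differential
proteins are sampled without replacement from a background of ``N`` proteins
of which ``K`` belong to the set (upper-tail hypergeometric), followed by
Benjamini-Hochberg adjustment across the tested sets.  ``compare_models``
intersects differential-protein sets and significant pathway names across
named disease models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError

__all__ = ["read_gmt", "write_gmt", "enrich", "compare_models",
           "ModelComparison"]

log = logging.getLogger(__name__)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>members...``."""
    sets: dict[str, list[str]] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise InputError(
                f"{path}:{ln}: GMT line needs name, description and >= 1 "
                f"member")
        name, members = parts[0], [m for m in parts[2:] if m]
        if name in sets:
            raise InputError(f"{path}:{ln}: duplicate set name {name!r}")
        if not members:
            raise InputError(f"{path}:{ln}: set {name!r} is empty")
        sets[name] = members
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> None:
    lines = []
    for name, members in sets.items():
        desc = (descriptions or {}).get(name, "na")
        lines.append("\t".join([name, desc, *members]))
    Path(path).write_text("\n".join(lines) + "\n")


def enrich(dep_ids: Iterable[str], background_ids: Iterable[str],
           sets: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """Over-representation of ``dep_ids`` in each gene set.

    Sets are intersected with the background before testing; sets with an
    empty intersection are skipped (logged).  Returns one row per tested set
    with columns ``set_name, k, K, n, N, p_value, q_value``, sorted by
    p-value ascending, ties broken by set name.  An empty DEP list yields an
    empty, well-formed result.
    """
    background = set(background_ids)
    deps = set(dep_ids)
    if not deps <= background:
        raise InputError(
            f"{len(deps - background)} DEP id(s) absent from the background")
    N, n = len(background), len(deps)
    if n == 0:
        log.info("empty DEP list: enrichment result is empty")
        return pd.DataFrame(columns=["set_name", "k", "K", "n", "N",
                                     "p_value", "q_value"])
    rows = []
    for name, members in sets.items():
        in_bg = set(members) & background
        K = len(in_bg)
        if K == 0:
            log.info("set %r has no members in the background; skipped", name)
            continue
        k = len(in_bg & deps)
        # P(X >= k) for X ~ Hypergeom(N, K, n); sf is P(X > k-1)
        p = float(scipy.stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"set_name": name, "k": k, "K": K, "n": n, "N": N,
                     "p_value": min(p, 1.0)})
    out = pd.DataFrame(rows)
    if out.empty:
        return pd.DataFrame(columns=["set_name", "k", "K", "n", "N",
                                     "p_value", "q_value"])
    out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out = out.sort_values(["p_value", "set_name"], kind="mergesort")
    return out.reset_index(drop=True)


@dataclass
class ModelComparison:
    """Pairwise and global overlap of DEP sets and significant pathways."""

    models: list[str]
    dep_overlap: pd.DataFrame            # pairwise |intersection| matrix
    pathway_overlap: pd.DataFrame
    common_deps: list[str] = field(default_factory=list)
    common_pathways: list[str] = field(default_factory=list)
    pairwise_deps: dict[tuple[str, str], list[str]] = field(
        default_factory=dict)
    pairwise_pathways: dict[tuple[str, str], list[str]] = field(
        default_factory=dict)


def _overlap_matrix(named_sets: dict[str, set]) -> pd.DataFrame:
    names = list(named_sets)
    mat = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for a in names:
        for b in names:
            mat.loc[a, b] = len(named_sets[a] & named_sets[b])
    return mat


def compare_models(dep_tables: Mapping[str, Iterable[str]],
                   enrichments: Mapping[str, pd.DataFrame] | None = None,
                   q_threshold: float = 0.05) -> ModelComparison:
    """Cross-model overlap report.

    Parameters
    ----------
    dep_tables
        Mapping model name -> iterable of differential protein ids.
    enrichments
        Optional mapping model name -> enrichment result table; a pathway is
        "significant" when ``q_value <= q_threshold``.
    """
    if len(dep_tables) < 2:
        raise InputError("model comparison needs >= 2 named models")
    deps = {m: set(ids) for m, ids in dep_tables.items()}
    models = list(deps)
    paths: dict[str, set] = {m: set() for m in models}
    if enrichments:
        for m, table in enrichments.items():
            if m in paths and len(table):
                sig = table[table["q_value"] <= q_threshold]
                paths[m] = set(sig["set_name"])

    comparison = ModelComparison(
        models=models,
        dep_overlap=_overlap_matrix(deps),
        pathway_overlap=_overlap_matrix(paths),
        common_deps=sorted(set.intersection(*deps.values())),
        common_pathways=sorted(set.intersection(*paths.values()))
        if paths else [],
    )
    for i, a in enumerate(models):
        for b in models[i + 1:]:
            comparison.pairwise_deps[(a, b)] = sorted(deps[a] & deps[b])
            comparison.pairwise_pathways[(a, b)] = sorted(paths[a] & paths[b])
    return comparison
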