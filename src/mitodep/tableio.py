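"""Schema-validated TSV readers/writers for every pipeline table.

All on-disk tables are tab-separated with a single header row and fixed,
documented column names.  Missing values are empty fields.  ``read_table``
validates column presence, dtypes and key uniqueness and raises
:class:`~mitodep.errors.SchemaError` naming the problem.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError

__all__ = ["TableSchema", "SCHEMAS", "read_table", "write_table"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TableSchema:
    name: str
    columns: tuple[str, ...]          # required, in any order
    key: tuple[str, ...]              # column set that must be unique
    bool_columns: tuple[str, ...] = ()
    float_columns: tuple[str, ...] = ()
    int_columns: tuple[str, ...] = ()
    extra_ok: bool = False            # tolerate extra columns (evidence sources)


SCHEMAS = {
    "peptides": TableSchema(
        name="peptides",
        columns=("peptide_id", "protein_id", "is_unique", "run_id",
                 "intensity"),
        key=("peptide_id", "run_id"),
        bool_columns=("is_unique",),
        float_columns=("intensity",),
    ),
    "design": TableSchema(
        name="design",
        columns=("run_id", "condition", "bio_rep", "tech_rep"),
        key=("run_id",),
    ),
    "truth": TableSchema(
        name="truth",
        columns=("protein_id", "is_mito", "is_dep", "true_fc", "direction",
                 "base_abundance"),
        key=("protein_id",),
        bool_columns=("is_mito", "is_dep"),
        float_columns=("true_fc", "base_abundance"),
        extra_ok=True,                 # evidence source columns
    ),
    "quant": TableSchema(
        name="quant",
        columns=("protein_id", "run_id", "abundance", "n_unique_peptides"),
        key=("protein_id", "run_id"),
        float_columns=("abundance",),
        int_columns=("n_unique_peptides",),
    ),
    "evidence": TableSchema(
        name="evidence",
        columns=("protein_id",),
        key=("protein_id",),
        extra_ok=True,                 # one integer column per source
    ),
    "scores": TableSchema(
        name="scores",
        columns=("protein_id", "total_score", "confidence_class"),
        key=("protein_id",),
        int_columns=("total_score",),
    ),
    "dep": TableSchema(
        name="dep",
        columns=("protein_id", "fc", "log2fc", "direction", "p_value",
                 "n_unique_peptides", "passes_filter2"),
        key=("protein_id",),
        bool_columns=("passes_filter2",),
        float_columns=("fc", "log2fc", "p_value"),
        int_columns=("n_unique_peptides",),
        extra_ok=True,                 # mito_class / q_value when present
    ),
}

_BOOL_MAP = {"true": True, "false": False, "1": True, "0": False}


def read_table(path: str | Path, schema: str | TableSchema) -> pd.DataFrame:
    """Read and validate one TSV table against its schema."""
    if isinstance(schema, str):
        schema = SCHEMAS[schema]
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                     na_values=[""])
    missing = [c for c in schema.columns if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing column(s) {missing} for table "
            f"{schema.name!r} (line 1)")
    if not schema.extra_ok:
        extra = [c for c in df.columns if c not in schema.columns]
        if extra:
            raise SchemaError(
                f"{path}: unexpected column(s) {extra} for table "
                f"{schema.name!r} (line 1)")
    for col in schema.bool_columns:
        vals = df[col].str.lower().map(_BOOL_MAP)
        bad = vals.isna() & df[col].notna()
        if bad.any():
            ln = int(bad.idxmax()) + 2
            raise SchemaError(
                f"{path}:{ln}: column {col!r} is not boolean "
                f"({df.loc[bad, col].iloc[0]!r})")
        df[col] = vals.astype(bool)
    for col in schema.float_columns:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise SchemaError(
                f"{path}: column {col!r} is not numeric: {exc}") from exc
    for col in schema.int_columns:
        nums = pd.to_numeric(df[col], errors="coerce")
        bad = nums.isna() | (nums != nums.round())
        if bad.any():
            ln = int(bad.idxmax()) + 2
            raise SchemaError(
                f"{path}:{ln}: column {col!r} is not an integer "
                f"({df.loc[bad, col].iloc[0]!r})")
        df[col] = nums.astype(int)
    if schema.key:
        dup = df.duplicated(subset=list(schema.key))
        if dup.any():
            ln = int(np.flatnonzero(dup.to_numpy())[0]) + 2
            raise SchemaError(
                f"{path}:{ln}: duplicate key {tuple(schema.key)} "
                f"{df.loc[dup, list(schema.key)].iloc[0].tolist()}")
    log.info("read %s: %d rows from %s", schema.name, len(df), path)
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a table as TSV (missing values as empty fields)."""
    df.to_csv(path, sep="\t", index=False, na_rep="")
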