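"""Readers and writers for the pipeline's tab-delimited formats.

Formats: GMT gene-set files (MSigDB dialect), genes x samples expression
matrices, sample metadata, long-format cytokine panels, and the
signature -> category annotation maps (columns ``level``, ``category``,
``signature_name``). All tables are UTF-8, tab-delimited, with headers.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    AnnotationMap,
    GeneSetCollection,
    GROUPS,
    ModulePartition,
    STIMULATIONS,
)

logger = logging.getLogger(__name__)

METADATA_COLUMNS = ["sample_id", "subject_id", "group", "stimulation", "gender", "batch"]
CYTOKINE_COLUMNS = ["subject_id", "group", "cytokine", "condition", "concentration"]


class FormatError(ValueError):
    """Malformed input file."""


def read_gmt(path, name: str | None = None, source: str = "") -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name TAB description TAB gene...``.

    Duplicate members are deduplicated (logged); a line with fewer than
    three fields is an error naming the line number.
    """
    path = Path(path)
    sets: dict = {}
    n_dups = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            set_name, _desc, *members = fields
            members = [m for m in members if m]
            unique = list(dict.fromkeys(members))
            n_dups += len(members) - len(unique)
            sets[set_name] = unique
    if not sets:
        logger.warning("GMT file %s contains no gene sets", path)
    if n_dups:
        logger.info("deduplicated %d repeated members in %s", n_dups, path)
    return GeneSetCollection(name=name or path.stem, sets=sets, source=source)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for set_name, members in collection.sets.items():
            fh.write("\t".join([set_name, collection.source or "na", *members]) + "\n")


def read_expression(path) -> pd.DataFrame:
    """Genes x samples log2 expression matrix, gene ids in the first column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate gene ids in {path}: {dups[:5]}")
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        if converted.isna().any() and not df[col].isna().any():
            row = df.index[converted.isna().argmax()]
            raise FormatError(f"non-numeric value in {path} at gene {row!r}, sample {col!r}")
        df[col] = converted
    if not np.isfinite(df.to_numpy(dtype=float)).all():
        raise FormatError(f"non-finite values in expression matrix {path}")
    return df


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id")


def _normalize_token(value: str, allowed, what: str, path) -> str:
    token = str(value).strip().upper()
    for a in allowed:
        if token == a.upper():
            return a
    raise FormatError(f"unknown {what} token {value!r} in {path}")


def read_metadata(path) -> pd.DataFrame:
    """Sample metadata; group and stimulation tokens are matched
    case-insensitively; duplicate (subject, stimulation) pairs are an
    error."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"metadata {path} missing columns: {missing}")
    df = df[METADATA_COLUMNS].copy()
    df["group"] = [_normalize_token(v, GROUPS, "group", path) for v in df["group"]]
    df["stimulation"] = [
        _normalize_token(v, STIMULATIONS, "stimulation", path) for v in df["stimulation"]
    ]
    df["gender"] = [_normalize_token(v, ("F", "M"), "gender", path) for v in df["gender"]]
    dup = df.duplicated(subset=["subject_id", "stimulation"])
    if dup.any():
        raise FormatError(
            f"duplicate (subject, stimulation) pairs in {path}: "
            f"{df.loc[dup, ['subject_id', 'stimulation']].values.tolist()[:5]}"
        )
    if df["sample_id"].duplicated().any():
        raise FormatError(f"duplicate sample ids in {path}")
    return df


def read_cytokines(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CYTOKINE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"cytokine table {path} missing columns: {missing}")
    df = df[CYTOKINE_COLUMNS].copy()
    df["group"] = [_normalize_token(v, GROUPS, "group", path) for v in df["group"]]
    df["condition"] = [
        _normalize_token(v, STIMULATIONS, "condition", path) for v in df["condition"]
    ]
    df["concentration"] = pd.to_numeric(df["concentration"], errors="raise")
    if (df["concentration"] < 0).any():
        raise FormatError(f"negative concentrations in {path}")
    if df.duplicated(subset=["subject_id", "cytokine", "condition"]).any():
        raise FormatError(f"duplicate (subject, cytokine, condition) rows in {path}")
    return df


def read_annotation(path) -> dict:
    """Annotation maps keyed by level; file columns ``level``,
    ``category``, ``signature_name``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("level", "category", "signature_name") if c not in df.columns]
    if missing:
        raise FormatError(f"annotation {path} missing columns: {missing}")
    maps = {}
    for level, sub in df.groupby(df["level"].astype(int)):
        if sub["signature_name"].duplicated().any():
            raise FormatError(f"signature assigned to multiple categories at level {level}")
        maps[int(level)] = AnnotationMap(
            level=int(level),
            assignments=dict(zip(sub["signature_name"], sub["category"])),
        )
    return maps


def write_annotation(maps: dict, path) -> None:
    rows = []
    for level in sorted(maps):
        for sig, cat in maps[level].assignments.items():
            rows.append({"level": level, "category": cat, "signature_name": sig})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_partition(partition: ModulePartition, path) -> None:
    partition.assignment.rename("module_label").to_csv(
        path, sep="\t", index_label="gene_id"
    )


def read_partition(path) -> ModulePartition:
    s = pd.read_csv(path, sep="\t", index_col=0)["module_label"].astype(int)
    return ModulePartition(assignment=s)
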