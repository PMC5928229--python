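"""Readers and writers for the screen's file formats.

All artifacts are plain text: the library manifest and result tables are
TSV, Cq measurements are long-format CSV (one well per row, censoring as an
explicit boolean column), pool plans are JSON, and configuration is
YAML/JSON.  Every reader validates the declared schema and names the file
and offending row/column in its error message; write→read round-trips are
lossless.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .design import LibraryEntry, PoolPlan, Role
from .errors import DataError
from .simulate import COMPARTMENTS, DNA_REF, ScreenTruth

__all__ = [
    "read_manifest",
    "write_manifest",
    "read_pools",
    "write_pools",
    "read_cq",
    "write_cq",
    "read_enrichment",
    "write_enrichment",
    "read_hits",
    "write_hits",
    "write_truth",
    "read_truth",
    "read_config_file",
]

MANIFEST_COLUMNS = ["orf_id", "gene_symbol", "role", "barcode"]
CQ_DTYPES = {
    "sample_id": str,
    "mouse_id": str,
    "pool_id": str,
    "compartment": str,
    "probe": str,
}
ENRICHMENT_COLUMNS = [
    "orf_id",
    "n_pairs",
    "mean_fc_mfp",
    "mean_lung_vs_mfp",
    "log2_lung_vs_mfp",
    "included",
]
HITS_COLUMNS = [
    "rank",
    "orf_id",
    "gene_symbol",
    "enrichment_score",
    "mean_fc_mfp",
    "quadrant",
    "n_pairs",
    "is_hit",
]


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing column(s) {', '.join(missing)}")


def read_manifest(path) -> list[LibraryEntry]:
    """Read a library manifest TSV (barcode column optional)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, MANIFEST_COLUMNS[:3], path)
    if "barcode" not in df.columns:
        df["barcode"] = ""
    entries = []
    for i, row in df.iterrows():
        if row["role"] not in Role.ALL:
            raise DataError(
                f"{path}: line {i + 2}, column 'role': unknown role {row['role']!r}"
            )
        entries.append(
            LibraryEntry(
                orf_id=row["orf_id"],
                gene_symbol=row["gene_symbol"],
                role=row["role"],
                barcode=row["barcode"],
            )
        )
    ids = [e.orf_id for e in entries]
    if len(set(ids)) != len(ids):
        dup = next(x for x in ids if ids.count(x) > 1)
        raise DataError(f"{path}: duplicate orf_id {dup!r}")
    return entries


def write_manifest(path, entries: Sequence[LibraryEntry]) -> None:
    df = pd.DataFrame(
        [(e.orf_id, e.gene_symbol, e.role, e.barcode) for e in entries],
        columns=MANIFEST_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_pools(path) -> list[PoolPlan]:
    """Read a pool plan from JSON: a list of {pool_id, member_orf_ids}."""
    path = Path(path)
    with open(path) as fh:
        raw = json.load(fh)
    if not isinstance(raw, list):
        raise DataError(f"{path}: expected a JSON array of pool objects")
    pools = []
    for i, obj in enumerate(raw):
        try:
            pools.append(
                PoolPlan(pool_id=obj["pool_id"], member_orf_ids=tuple(obj["member_orf_ids"]))
            )
        except (KeyError, TypeError) as exc:
            raise DataError(f"{path}: pool entry {i}: {exc}") from exc
    return pools


def write_pools(path, pools: Sequence[PoolPlan]) -> None:
    payload = [
        {"pool_id": p.pool_id, "member_orf_ids": list(p.member_orf_ids)} for p in pools
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def read_cq(path) -> pd.DataFrame:
    """Read a long-format Cq CSV; empty ``mouse_id`` (reference rows) → NA."""
    path = Path(path)
    df = pd.read_csv(path, dtype=CQ_DTYPES)
    _require_columns(
        df,
        ["sample_id", "mouse_id", "pool_id", "compartment", "probe", "replicate", "cq", "censored"],
        path,
    )
    bad = ~df["compartment"].isin(COMPARTMENTS)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise DataError(
            f"{path}: line {i + 2}, column 'compartment': unknown token "
            f"{df['compartment'].iloc[i]!r}"
        )
    if not pd.api.types.is_numeric_dtype(df["cq"]):
        raise DataError(f"{path}: column 'cq' must be numeric")
    df["replicate"] = df["replicate"].astype(int)
    if df["censored"].dtype != bool:
        df["censored"] = (
            df["censored"].astype(str).str.strip().str.lower().map(
                {"true": True, "false": False, "1": True, "0": False}
            )
        )
        if df["censored"].isna().any():
            i = int(np.flatnonzero(df["censored"].isna())[0])
            raise DataError(f"{path}: line {i + 2}, column 'censored': not a boolean")
        df["censored"] = df["censored"].astype(bool)
    df.loc[df["mouse_id"] == "", "mouse_id"] = pd.NA
    return df


def write_cq(path, cq: pd.DataFrame) -> None:
    out = cq.copy()
    out["mouse_id"] = out["mouse_id"].fillna("")
    out.to_csv(path, index=False, float_format="%.6f")


def write_enrichment(path, enrichment: pd.DataFrame) -> None:
    cols = ENRICHMENT_COLUMNS + [c for c in ("pool_id",) if c in enrichment.columns]
    enrichment[cols].to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_enrichment(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ENRICHMENT_COLUMNS, path)
    df["included"] = df["included"].astype(bool)
    return df


def write_hits(path, hits: pd.DataFrame, hits_only: bool = False) -> None:
    """Write the ranked hit table (rank empty for non-hits)."""
    out = hits if not hits_only else hits[hits["is_hit"]]
    cols = HITS_COLUMNS + [c for c in ("mfp_status", "included", "role", "pool_id") if c in out.columns]
    out[cols].to_csv(path, sep="\t", index=False, float_format="%.10g", na_rep="")


def read_hits(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, [c for c in HITS_COLUMNS if c != "rank"], path)
    df["rank"] = df["rank"].astype("Int64") if "rank" in df.columns else pd.NA
    df["is_hit"] = df["is_hit"].astype(bool)
    return df


def write_truth(effects_path, proportions_path, truth: ScreenTruth) -> None:
    """Write ground truth: effects TSV (orf_id, g, m) and a wide per-mouse
    proportion matrix (rows = orf_id, columns = sample compartments)."""
    truth.effects.to_csv(effects_path, sep="\t", index=False, float_format="%.10g")
    wide = truth.proportions.copy()
    wide["mouse_id"] = wide["mouse_id"].fillna("")
    wide["column"] = (
        wide["pool_id"] + ":" + wide["compartment"] + ":" + wide["mouse_id"]
    ).str.rstrip(":")
    mat = wide.pivot_table(
        index="orf_id", columns="column", values="proportion", aggfunc="first"
    )
    mat.to_csv(proportions_path, sep="\t", float_format="%.10g")


def read_truth(effects_path) -> pd.DataFrame:
    return pd.read_csv(effects_path, sep="\t")


def read_config_file(path) -> dict:
    """Read a YAML or JSON configuration file into a plain dict."""
    path = Path(path)
    with open(path) as fh:
        if path.suffix.lower() == ".json":
            data = json.load(fh)
        else:
            data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise DataError(f"{path}: configuration must be a mapping")
    return data
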