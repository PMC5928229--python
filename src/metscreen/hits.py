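"""Empirical-control hit calling and ranking.

The hit threshold is anchored to the screen's internal negative control: the
GFP construct rides along in every pool, so its mean lung enrichment score
measures how far a construct can drift through the metastatic bottleneck with
no true metastasis advantage.  Constructs whose enrichment score reaches that
empirical-control level (≈5 under the default screen format, which is also
the configured fallback when no control rows are available) are called hits.

Two published hit definitions coexist and cannot be reconciled without
guessing: the main rule (lung enrichment at or above the control cutoff) and
an alternative that requires at least two-fold depletion in the mammary
relative to the reference pool.  Both are implemented; ``hit_mode`` selects
``"lung"`` (default), ``"mfp_depletion"``, or the conjunction ``"both"``.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError

__all__ = [
    "QUADRANTS",
    "control_cutoff",
    "classify_quadrant",
    "mammary_depletion_filter",
    "call_and_rank",
    "is_lung_hit",
]

logger = logging.getLogger("metscreen.hits")

QUADRANTS = ("lung_and_mfp", "mfp_only", "lung_only", "neither")
HIT_MODES = ("lung", "mfp_depletion", "both")


def control_cutoff(
    enrichment: pd.DataFrame,
    control_orf_ids: Sequence[str],
    fallback: float = 5.0,
    warn: bool = True,
) -> float:
    """Hit cutoff from the negative control's enrichment scores.

    Returns the mean enrichment score of the control construct(s) over the
    pools where they pass the minimum-pair rule.  With no eligible control
    rows the configured fallback (default 5, the published control level) is
    returned with a warning.
    """
    if fallback < 0:
        raise ConfigError("fallback cutoff must be non-negative")
    controls = enrichment[
        enrichment["orf_id"].isin(control_orf_ids) & enrichment["included"]
    ]
    if controls.empty:
        if warn:
            logger.warning(
                "hits: no eligible control rows; falling back to cutoff %.3g", fallback
            )
        return float(fallback)
    return float(controls["mean_lung_vs_mfp"].mean())


def classify_quadrant(
    enrichment_score: float | np.ndarray | pd.Series,
    mean_fc_mfp: float | np.ndarray | pd.Series,
    lung_cutoff: float,
    mfp_threshold: float = 1.0,
) -> np.ndarray | str:
    """Joint lung/MFP status of a construct.

    The lung axis compares the enrichment score against ``lung_cutoff``; the
    MFP axis compares the mean MFP-vs-reference fold change against
    ``mfp_threshold`` (default 1: any enrichment over the input pool).  Ties
    classify as enriched.
    """
    if lung_cutoff <= 0 or mfp_threshold <= 0:
        raise ConfigError("quadrant thresholds must be positive")
    lung_up = np.asarray(enrichment_score) >= lung_cutoff
    mfp_up = np.asarray(mean_fc_mfp) >= mfp_threshold
    out = np.select(
        [lung_up & mfp_up, ~lung_up & mfp_up, lung_up & ~mfp_up],
        ["lung_and_mfp", "mfp_only", "lung_only"],
        default="neither",
    )
    return out.item() if out.ndim == 0 else out


def mammary_depletion_filter(
    mean_fc_mfp: float | np.ndarray | pd.Series, fold_threshold: float = 2.0
):
    """True when a construct is depleted at least ``fold_threshold``-fold in
    the mammary tumor relative to the reference pool (fc ≤ 1/threshold)."""
    if fold_threshold < 1:
        raise ConfigError("fold_threshold must be at least 1")
    out = np.asarray(mean_fc_mfp) <= 1.0 / fold_threshold
    return bool(out) if out.ndim == 0 else out


def _mfp_status(fc: np.ndarray, enrich_fold: float, deplete_fold: float) -> np.ndarray:
    return np.select(
        [fc >= enrich_fold, fc <= 1.0 / deplete_fold],
        ["enriched", "depleted"],
        default="neutral",
    )


def is_lung_hit(enrichment: pd.DataFrame, orf_id: str, cutoff: float) -> bool:
    """Whether one construct passes the lung-enrichment hit rule."""
    row = enrichment[enrichment["orf_id"] == orf_id]
    if row.empty:
        return False
    row = row.iloc[0]
    return bool(row["included"] and row["mean_lung_vs_mfp"] >= cutoff)


def call_and_rank(
    enrichment: pd.DataFrame,
    cutoff: float,
    roles: Mapping[str, str] | None = None,
    gene_symbols: Mapping[str, str] | None = None,
    hit_mode: str = "lung",
    mfp_threshold: float = 1.0,
    depletion_fold: float = 2.0,
    mfp_enrich_fold: float = 2.0,
) -> pd.DataFrame:
    """Call hits against ``cutoff`` and rank them in descending score order.

    A hit must pass the minimum-pair rule, carry the ``candidate`` role, and
    satisfy the selected criterion: enrichment score ≥ cutoff (``"lung"``),
    ≥ ``depletion_fold``-fold mammary depletion (``"mfp_depletion"``), or both.
    Control constructs are never ranked.  Ranks are dense (1 = best); ties at
    equal score break lexicographically by orf_id so output is byte-stable.
    Non-hits are retained with an empty rank.
    """
    if cutoff <= 0:
        raise ConfigError("cutoff must be positive")
    if hit_mode not in HIT_MODES:
        raise ConfigError(f"unknown hit_mode {hit_mode!r}")
    roles = roles or {}
    gene_symbols = gene_symbols or {}

    out = enrichment.copy()
    out["role"] = out["orf_id"].map(lambda o: roles.get(o, "candidate"))
    out["gene_symbol"] = out["orf_id"].map(lambda o: gene_symbols.get(o, o))
    score = out["mean_lung_vs_mfp"].to_numpy(dtype=float)
    fc_mfp = out["mean_fc_mfp"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        out["quadrant"] = classify_quadrant(score, fc_mfp, cutoff, mfp_threshold)
        out.loc[out["n_pairs"] == 0, "quadrant"] = "neither"
        out["mfp_status"] = _mfp_status(fc_mfp, mfp_enrich_fold, depletion_fold)
        lung_rule = score >= cutoff
        depletion_rule = mammary_depletion_filter(fc_mfp, depletion_fold)
    criterion = {
        "lung": lung_rule,
        "mfp_depletion": depletion_rule,
        "both": lung_rule & depletion_rule,
    }[hit_mode]
    out["is_hit"] = (
        out["included"].to_numpy()
        & (out["role"] == "candidate").to_numpy()
        & np.nan_to_num(criterion, nan=False).astype(bool)
    )

    out = out.sort_values(
        ["is_hit", "mean_lung_vs_mfp", "orf_id"], ascending=[False, False, True]
    ).reset_index(drop=True)
    out["rank"] = pd.array([None] * len(out), dtype="Int64")
    n_hits = int(out["is_hit"].sum())
    if n_hits:
        out.loc[: n_hits - 1, "rank"] = np.arange(1, n_hits + 1)
    logger.info("hits: %d of %d ranked constructs at cutoff %.3g", n_hits, len(out), cutoff)
    cols = [
        "rank",
        "orf_id",
        "gene_symbol",
        "enrichment_score",
        "mean_fc_mfp",
        "quadrant",
        "mfp_status",
        "n_pairs",
        "is_hit",
        "included",
        "role",
        "pool_id",
    ]
    out = out.rename(columns={"mean_lung_vs_mfp": "enrichment_score"})
    return out[[c for c in cols if c in out.columns]]
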