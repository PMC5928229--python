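"""ΔΔCt barcode deconvolution.

The read-out of the screen is a long-format table of qPCR quantification
cycles (Cq).  Quantification proceeds in four steps, each a function here:

1. technical replicates are collapsed to one Cq per sample × probe;
2. each barcode Cq is normalized to total DNA by subtracting the sample's
   ``DNA_REF`` probe Cq (ΔCt), which makes every downstream quantity
   invariant to sample-wide Cq shifts (template amount, plate effects);
3. each tumor sample's ΔCt is converted to a fold change relative to the
   pool's reference-pellet sample, ``2**-(ΔCt_sample - ΔCt_reference)``
   (ΔΔCt at assumed 100% amplification efficiency);
4. for every mouse with both an MFP tumor and a lung lesion, the
   lung-over-MFP ratio is formed per construct (a matched pair), and pairs
   are averaged per construct into the enrichment score, subject to the
   minimum-pair rule (default: at least 3 matched pairs, otherwise the
   construct is excluded from ranking).

Censored ("undetermined") wells carry an explicit flag.  Their Cq is imputed
at the detection limit in the ΔCt table — a conservative lower bound on
abundance — but by default a censored measurement does not form a matched
pair: an undetermined lung well means the barcode was absent from the lesion,
not that its abundance was measured.  Set ``pair_policy="imputed"`` to treat
the detection-limit bound as a measurement instead.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .simulate import DNA_REF

__all__ = [
    "collapse_replicates",
    "normalize_to_dna",
    "fold_change",
    "fold_change_vs_reference",
    "matched_pairs",
    "aggregate_genes",
    "quantify_pool",
]

logger = logging.getLogger("metscreen.quantify")

_SAMPLE_KEYS = ["sample_id", "mouse_id", "pool_id", "compartment"]


def collapse_replicates(cq: pd.DataFrame, policy: str = "mean") -> pd.DataFrame:
    """Collapse technical replicates to one row per sample × probe.

    The default policy averages the uncensored replicate Cq values
    (arithmetic mean; ``"median"`` is also accepted).  A (sample, probe) whose
    replicates are all censored stays censored with ``n_replicates_used = 0``
    and Cq at the detection limit carried by the censored rows.
    """
    if policy not in ("mean", "median"):
        raise ConfigError(f"unknown replicate-collapsing policy {policy!r}")

    keys = _SAMPLE_KEYS + ["probe"]
    work = cq.copy()
    na_mouse = work["mouse_id"].isna()
    work["mouse_id"] = work["mouse_id"].fillna("")

    ok = (
        work.loc[~work["censored"]]
        .groupby(keys, sort=False, as_index=False)
        .agg(cq=("cq", policy), n_replicates_used=("cq", "size"))
    )
    ok["censored"] = False

    seen = set(map(tuple, ok[keys].itertuples(index=False)))
    cens_rows = work.loc[work["censored"]]
    cens = (
        cens_rows.groupby(keys, sort=False, as_index=False)
        .agg(cq=("cq", "max"))
    )
    cens = cens[[tuple(t) not in seen for t in cens[keys].itertuples(index=False)]].copy()
    cens["n_replicates_used"] = 0
    cens["censored"] = True

    out = pd.concat([ok, cens], ignore_index=True)
    out["n_replicates_used"] = out["n_replicates_used"].astype(int)
    out.loc[out["mouse_id"] == "", "mouse_id"] = pd.NA
    return out[keys + ["cq", "censored", "n_replicates_used"]]


def normalize_to_dna(collapsed: pd.DataFrame) -> pd.DataFrame:
    """Normalize barcode Cq to total DNA: ΔCt = Cq_barcode − Cq_DNA_REF.

    Every sample must carry a ``DNA_REF`` row; a sample without one is a hard
    error naming the sample.  Censored barcodes keep their flag; their ΔCt is
    the conservative detection-limit bound.
    """
    is_ref = collapsed["probe"] == DNA_REF
    dna = collapsed.loc[is_ref, ["sample_id", "cq"]].rename(columns={"cq": "cq_dna"})
    if dna["sample_id"].duplicated().any():
        dup = dna.loc[dna["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise DataError(f"sample {dup!r} has multiple {DNA_REF} rows after collapsing")
    barcodes = collapsed.loc[~is_ref].copy()
    missing = set(barcodes["sample_id"]) - set(dna["sample_id"])
    if missing:
        raise DataError(f"sample {sorted(missing)[0]!r} has no {DNA_REF} probe")
    out = barcodes.merge(dna, on="sample_id", how="left")
    out["delta_ct"] = out["cq"] - out["cq_dna"]
    out = out.rename(columns={"probe": "orf_id"})
    return out[_SAMPLE_KEYS + ["orf_id", "delta_ct", "censored", "n_replicates_used"]]


def fold_change(delta_ct_sample: float, delta_ct_reference: float) -> float:
    """ΔΔCt fold change: ``2**-(ΔCt_sample − ΔCt_reference)``."""
    return float(2.0 ** -(delta_ct_sample - delta_ct_reference))


def fold_change_vs_reference(norm: pd.DataFrame) -> pd.DataFrame:
    """Fold change of every tumor sample vs its pool's reference pellet.

    Rows of the ``reference`` compartment provide the per-pool baseline ΔCt;
    every other row becomes ``2**-(ΔCt − ΔCt_ref)``.  The reference sample
    itself is kept (fold change exactly 1 when compared to itself).  A pool
    without a reference sample is an error.
    """
    is_ref = norm["compartment"] == "reference"
    ref = norm.loc[is_ref, ["pool_id", "orf_id", "delta_ct", "censored"]].rename(
        columns={"delta_ct": "delta_ct_ref", "censored": "censored_ref"}
    )
    if ref.duplicated(subset=["pool_id", "orf_id"]).any():
        raise DataError("multiple reference rows for one (pool, orf)")
    missing = set(norm["pool_id"]) - set(ref["pool_id"])
    if missing:
        raise DataError(f"pool {sorted(missing)[0]!r} has no reference sample")
    out = norm.merge(ref, on=["pool_id", "orf_id"], how="left", validate="m:1")
    if out["delta_ct_ref"].isna().any():
        bad = out.loc[out["delta_ct_ref"].isna()].iloc[0]
        raise DataError(
            f"no reference measurement for orf {bad['orf_id']!r} in pool {bad['pool_id']!r}"
        )
    out["fold_change"] = 2.0 ** -(out["delta_ct"] - out["delta_ct_ref"])
    return out[
        _SAMPLE_KEYS + ["orf_id", "fold_change", "censored", "censored_ref"]
    ]


def matched_pairs(fc: pd.DataFrame, pair_policy: str = "detected") -> pd.DataFrame:
    """Per-mouse lung-versus-mammary enrichment for every construct.

    A matched pair exists for (mouse, orf) when the mouse contributed both an
    MFP tumor and a lung lesion measurement for that construct;
    ``lung_vs_mfp = fc_lung / fc_mfp`` (the ΔΔCt of lung vs mammary on the
    linear scale).  Mice without lung lesions contribute no pairs.  Under the
    default ``"detected"`` policy a censored well is not a measurement and
    voids the pair; ``"imputed"`` keeps censored values at their
    detection-limit bound.
    """
    if pair_policy not in ("detected", "imputed"):
        raise ConfigError(f"unknown pair policy {pair_policy!r}")
    tumors = fc[fc["compartment"].isin(["mfp", "lung"])].copy()
    if tumors.duplicated(subset=["mouse_id", "compartment", "orf_id"]).any():
        bad = tumors[tumors.duplicated(subset=["mouse_id", "compartment", "orf_id"])].iloc[0]
        raise DataError(
            f"duplicate measurement for mouse {bad['mouse_id']!r}, "
            f"compartment {bad['compartment']!r}, orf {bad['orf_id']!r}"
        )
    if pair_policy == "detected":
        tumors = tumors[~tumors["censored"]]
    wide = tumors.pivot_table(
        index=["pool_id", "mouse_id", "orf_id"],
        columns="compartment",
        values="fold_change",
        aggfunc="first",
    ).reset_index()
    for comp in ("mfp", "lung"):
        if comp not in wide.columns:
            wide[comp] = np.nan
    pairs = wide.dropna(subset=["mfp", "lung"]).rename(
        columns={"mfp": "fc_mfp", "lung": "fc_lung"}
    )
    pairs = pairs[["pool_id", "mouse_id", "orf_id", "fc_mfp", "fc_lung"]].copy()
    pairs["lung_vs_mfp"] = pairs["fc_lung"] / pairs["fc_mfp"]
    return pairs.reset_index(drop=True)


def aggregate_genes(
    pairs: pd.DataFrame,
    min_pairs: int = 3,
    mean_type: str = "arithmetic",
    all_orfs: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Average matched pairs into one enrichment record per construct.

    ``mean_lung_vs_mfp`` is the enrichment score.  Constructs with fewer than
    ``min_pairs`` matched pairs are retained but marked ``included=False``
    (the minimum-data rule; default 3 pairs).  ``all_orfs`` — a DataFrame with
    ``orf_id`` and ``pool_id`` columns — adds zero-pair constructs to the
    output.  Aggregation is per (orf, pool) so that a control construct
    present in several pools yields one score per pool.
    """
    if min_pairs < 1:
        raise ConfigError("min_pairs must be at least 1")
    if mean_type not in ("arithmetic", "geometric"):
        raise ConfigError(f"unknown mean type {mean_type!r}")

    if len(pairs):
        if mean_type == "arithmetic":
            agg = pairs.groupby(["orf_id", "pool_id"], sort=False).agg(
                n_pairs=("lung_vs_mfp", "size"),
                mean_fc_mfp=("fc_mfp", "mean"),
                mean_lung_vs_mfp=("lung_vs_mfp", "mean"),
            )
        else:
            logmean = lambda s: float(np.exp(np.log(s).mean()))
            agg = pairs.groupby(["orf_id", "pool_id"], sort=False).agg(
                n_pairs=("lung_vs_mfp", "size"),
                mean_fc_mfp=("fc_mfp", logmean),
                mean_lung_vs_mfp=("lung_vs_mfp", logmean),
            )
        agg = agg.reset_index()
    else:
        agg = pd.DataFrame(
            columns=["orf_id", "pool_id", "n_pairs", "mean_fc_mfp", "mean_lung_vs_mfp"]
        )

    if all_orfs is not None:
        universe = all_orfs[["orf_id", "pool_id"]].drop_duplicates()
        agg = universe.merge(agg, on=["orf_id", "pool_id"], how="left")
        agg["n_pairs"] = agg["n_pairs"].fillna(0)

    agg["n_pairs"] = agg["n_pairs"].astype(int)
    with np.errstate(divide="ignore", invalid="ignore"):
        agg["log2_lung_vs_mfp"] = np.log2(agg["mean_lung_vs_mfp"].astype(float))
    agg["included"] = agg["n_pairs"] >= min_pairs
    return agg.sort_values(["pool_id", "orf_id"]).reset_index(drop=True)


def quantify_pool(
    cq: pd.DataFrame,
    min_pairs: int = 3,
    pair_policy: str = "detected",
    mean_type: str = "arithmetic",
    replicate_policy: str = "mean",
    detection_limit: float | None = None,
) -> pd.DataFrame:
    """Run the full ΔΔCt chain on one Cq table and return gene enrichments.

    ``detection_limit`` fills in the Cq of censored rows imported with a
    missing value (tables written by the simulator already carry the limit).
    """
    cq = cq.copy()
    if detection_limit is not None:
        cq.loc[cq["censored"] & cq["cq"].isna(), "cq"] = float(detection_limit)
    collapsed = collapse_replicates(cq, policy=replicate_policy)
    norm = normalize_to_dna(collapsed)
    fc = fold_change_vs_reference(norm)
    pairs = matched_pairs(fc, pair_policy=pair_policy)
    universe = fc[fc["compartment"] != "reference"][["orf_id", "pool_id"]].drop_duplicates()
    if universe.empty:
        universe = fc[["orf_id", "pool_id"]].drop_duplicates()
    enrichment = aggregate_genes(
        pairs, min_pairs=min_pairs, mean_type=mean_type, all_orfs=universe
    )
    logger.info(
        "quantify: %d pairs over %d constructs (%d included)",
        len(pairs),
        len(enrichment),
        int(enrichment["included"].sum()),
    )
    return enrichment
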