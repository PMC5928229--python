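"""Stochastic simulator of barcode dynamics through an in vivo screen.

Each pool of barcoded cell populations passes through three observed
compartments:

``reference``
    the pooled cell pellet frozen at implantation, with equal representation
    of every construct;
``mfp``
    the primary tumor grown in the mammary fat pad (MFP) of each mouse, after
    an engraftment bottleneck and exponential expansion; and
``lung``
    the metastatic lesion(s) macro-dissected from the same mouse's lungs,
    after a severe seeding bottleneck.

Per-construct fitness effects are log2-scaled so that simulator ground truth
and the ΔΔCt read-out share one scale: a primary-growth advantage ``g``
multiplies a construct's expansion by ``2**(g * primary_doublings)``, and a
metastasis advantage ``m`` multiplies its expected number of seeded lung
cells by ``2**m`` (seeding and metastatic outgrowth are deliberately folded
into the single parameter ``m``; endpoint genomic DNA cannot distinguish
them).

Abundances are read out as qPCR quantification cycles: each barcode's Cq is
``cq_intercept - log2(relative abundance)`` plus Gaussian technical noise,
censored at the instrument's ``detection_limit``; every sample also carries a
total-DNA reference probe (``DNA_REF``) used downstream for normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import PoolPlan
from .errors import ConfigError, DataError
from .seeds import substream

__all__ = [
    "DNA_REF",
    "COMPARTMENTS",
    "SimulationConfig",
    "TruthRecord",
    "ScreenTruth",
    "simulate_pool",
    "simulate_screen",
    "driver_detection",
    "complexity_experiment",
]

logger = logging.getLogger("metscreen.simulate")

DNA_REF = "DNA_REF"
COMPARTMENTS = ("reference", "mfp", "lung")

CQ_COLUMNS = [
    "sample_id",
    "mouse_id",
    "pool_id",
    "compartment",
    "probe",
    "replicate",
    "cq",
    "censored",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the generative model.

    Parameters
    ----------
    n_engraft
        Cells sampled per mouse at implantation (multinomial bottleneck).
    primary_doublings
        Dimensionless expansion time of the primary tumor; a construct with
        growth advantage ``g`` gains ``2**(g * primary_doublings)``-fold.
    lung_seeding_rate
        Expected number of cells founding lung metastases per mouse (Poisson
        mean, summed over a neutral pool).  The default of 1.5 encodes the
        severe inefficiency of spontaneous metastasis — a macroscopic lesion
        descends from a handful of founder cells — and is calibrated so that
        the neutral GFP control's mean lung enrichment score is ≈5 under the
        default screen format, the empirical-control level the hit cutoff is
        anchored to (pooled over 10 simulated screens, 2.0 gives 5.05).
    effects
        Mapping ``orf_id -> (g, m)`` of log2 fitness effects; constructs not
        listed are neutral (g = m = 0).
    metastasis_take_rate
        Probability that an engrafted mouse develops any lung lesion at all.
    cq_intercept, cq_noise_sd
        Cq at relative abundance 1, and the per-replicate technical noise SD
        in cycles.
    dna_probe_mu, dna_probe_sd
        Mean and SD of the total-DNA reference probe's Cq.
    detection_limit
        Maximum cycle; higher values are censored ("undetermined" wells).
    exact_proportions
        Replace the multinomial and Poisson bottlenecks by their
        expectations; used for closed-form checks.
    """

    n_engraft: int = 200_000
    primary_doublings: float = 10.0
    lung_seeding_rate: float = 2.0
    effects: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    metastasis_take_rate: float = 0.9
    cq_intercept: float = 20.0
    cq_noise_sd: float = 0.25
    dna_probe_mu: float = 18.0
    dna_probe_sd: float = 0.25
    detection_limit: float = 40.0
    technical_replicates: int = 3
    mice_per_pool: int = 10
    exact_proportions: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_engraft < 1:
            raise ConfigError("n_engraft must be positive")
        if self.lung_seeding_rate < 0:
            raise ConfigError("lung_seeding_rate must be non-negative")
        if not 0.0 <= self.metastasis_take_rate <= 1.0:
            raise ConfigError("metastasis_take_rate must lie in [0, 1]")
        for name in ("cq_noise_sd", "dna_probe_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.technical_replicates < 1:
            raise ConfigError("technical_replicates must be at least 1")
        if self.mice_per_pool < 1:
            raise ConfigError("mice_per_pool must be positive")

    def effect(self, orf_id: str) -> tuple[float, float]:
        return tuple(self.effects.get(orf_id, (0.0, 0.0)))


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one construct: effects and true compartment abundances."""

    orf_id: str
    g: float
    m: float
    # mapping (mouse_id or None for reference, compartment) -> relative abundance
    abundance: Mapping[tuple[str | None, str], float]


@dataclass
class ScreenTruth:
    """Simulator ground truth for a whole screen.

    ``effects`` has one row per construct (orf_id, g, m); ``proportions`` is
    long-format with one row per (pool, mouse, compartment, orf) giving the
    true relative abundance.  Within each (mouse, compartment) the abundances
    sum to one.
    """

    effects: pd.DataFrame
    proportions: pd.DataFrame

    def records(self) -> list[TruthRecord]:
        recs = []
        for _, row in self.effects.iterrows():
            sub = self.proportions[self.proportions["orf_id"] == row["orf_id"]]
            abundance = {
                (m if pd.notna(m) else None, c): p
                for m, c, p in zip(sub["mouse_id"], sub["compartment"], sub["proportion"])
            }
            recs.append(TruthRecord(row["orf_id"], row["g"], row["m"], abundance))
        return recs


def _emit_sample(
    rows: list,
    rng: np.random.Generator,
    config: SimulationConfig,
    sample_id: str,
    mouse_id: str | None,
    pool_id: str,
    compartment: str,
    orf_ids: Sequence[str],
    proportions: np.ndarray,
) -> None:
    """Append Cq rows (all probes × replicates, plus DNA_REF) for one sample."""
    n_rep = config.technical_replicates
    for orf, p in zip(orf_ids, proportions):
        if p > 0:
            base = config.cq_intercept - np.log2(p)
            noise = (
                rng.normal(0.0, config.cq_noise_sd, size=n_rep)
                if config.cq_noise_sd > 0
                else np.zeros(n_rep)
            )
            cqs = base + noise
        else:
            cqs = np.full(n_rep, np.inf)
        for rep, cq in enumerate(cqs, start=1):
            censored = bool(cq > config.detection_limit)
            rows.append(
                (
                    sample_id,
                    mouse_id,
                    pool_id,
                    compartment,
                    orf,
                    rep,
                    config.detection_limit if censored else float(cq),
                    censored,
                )
            )
    dna_noise = (
        rng.normal(0.0, config.dna_probe_sd, size=n_rep)
        if config.dna_probe_sd > 0
        else np.zeros(n_rep)
    )
    for rep, cq in enumerate(config.dna_probe_mu + dna_noise, start=1):
        censored = bool(cq > config.detection_limit)
        rows.append(
            (
                sample_id,
                mouse_id,
                pool_id,
                compartment,
                DNA_REF,
                rep,
                config.detection_limit if censored else float(cq),
                censored,
            )
        )


def simulate_pool(
    pool: PoolPlan,
    config: SimulationConfig,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, ScreenTruth]:
    """Simulate one pool through the reference / MFP / lung compartments.

    The generative chain per mouse is: equal reference proportions →
    multinomial engraftment of ``n_engraft`` cells → deterministic expansion
    by ``2**(g * primary_doublings)`` and renormalization (MFP proportions) →
    per-construct Poisson lung seeding with mean
    ``lung_seeding_rate * p_mfp * 2**m`` → normalization of seeded counts
    (lung proportions).  A mouse yields no lung sample if the Bernoulli take
    fails or no cell seeds.  Cq read-out per compartment sample is described
    in the module docstring.  With ``exact_proportions`` the two bottlenecks
    are replaced by their expectations.

    Returns the long-format Cq table and the ground truth.
    """
    if rng is None:
        rng = substream(config.rng_seed if seed is None else seed, "pool", pool.pool_id)

    orf_ids = list(pool.member_orf_ids)
    k = len(orf_ids)
    g = np.array([config.effect(o)[0] for o in orf_ids])
    m = np.array([config.effect(o)[1] for o in orf_ids])

    rows: list = []
    truth_rows: list = []
    p_ref = np.full(k, 1.0 / k)

    _emit_sample(
        rows, rng, config, f"{pool.pool_id}_ref", None, pool.pool_id, "reference", orf_ids, p_ref
    )
    truth_rows += [
        (pool.pool_id, None, "reference", o, p) for o, p in zip(orf_ids, p_ref)
    ]

    growth = 2.0 ** (g * config.primary_doublings)
    for j in range(1, config.mice_per_pool + 1):
        mouse_id = f"{pool.pool_id}_m{j:02d}"

        if config.exact_proportions:
            p_engraft = p_ref
        else:
            counts = rng.multinomial(config.n_engraft, p_ref)
            p_engraft = counts / counts.sum()

        w = p_engraft * growth
        p_mfp = w / w.sum()
        _emit_sample(
            rows, rng, config, f"{mouse_id}_mfp", mouse_id, pool.pool_id, "mfp", orf_ids, p_mfp
        )
        truth_rows += [
            (pool.pool_id, mouse_id, "mfp", o, p) for o, p in zip(orf_ids, p_mfp)
        ]

        lam = config.lung_seeding_rate * p_mfp * 2.0**m
        takes = (
            config.metastasis_take_rate > 0
            if config.exact_proportions
            else rng.random() < config.metastasis_take_rate
        )
        seeded = lam if config.exact_proportions else rng.poisson(lam).astype(float)
        if not takes or seeded.sum() <= 0:
            continue
        p_lung = seeded / seeded.sum()
        _emit_sample(
            rows, rng, config, f"{mouse_id}_lung", mouse_id, pool.pool_id, "lung", orf_ids, p_lung
        )
        truth_rows += [
            (pool.pool_id, mouse_id, "lung", o, p) for o, p in zip(orf_ids, p_lung)
        ]

    cq = pd.DataFrame(rows, columns=CQ_COLUMNS)
    truth = ScreenTruth(
        effects=pd.DataFrame({"orf_id": orf_ids, "g": g, "m": m}),
        proportions=pd.DataFrame(
            truth_rows, columns=["pool_id", "mouse_id", "compartment", "orf_id", "proportion"]
        ),
    )
    return cq, truth


def simulate_screen(
    pools: Sequence[PoolPlan],
    config: SimulationConfig,
    seed: int | None = None,
) -> tuple[pd.DataFrame, ScreenTruth]:
    """Simulate a whole screen: every pool with an independent substream.

    Sample ids are globally unique (prefixed by pool id); each pool carries
    one shared reference-pellet sample.  Deterministic for a fixed seed.
    """
    ids = [p.pool_id for p in pools]
    if len(set(ids)) != len(ids):
        raise DataError("duplicate pool_ids in screen")
    root = config.rng_seed if seed is None else seed

    cq_parts, eff_parts, prop_parts = [], [], []
    for pool in pools:
        cq, truth = simulate_pool(pool, config, seed=root)
        cq_parts.append(cq)
        eff = truth.effects.copy()
        eff.insert(0, "pool_id", pool.pool_id)
        eff_parts.append(eff)
        prop_parts.append(truth.proportions)
    cq_all = pd.concat(cq_parts, ignore_index=True)
    effects = (
        pd.concat(eff_parts, ignore_index=True)
        .drop_duplicates(subset=["orf_id"], keep="first")
        .drop(columns=["pool_id"])
        .reset_index(drop=True)
    )
    truth_all = ScreenTruth(
        effects=effects, proportions=pd.concat(prop_parts, ignore_index=True)
    )
    n_lung = cq_all.query("compartment == 'lung'")["sample_id"].nunique()
    logger.info(
        "simulate: %d pools, %d samples (%d lung-positive mice)",
        len(pools),
        cq_all["sample_id"].nunique(),
        n_lung,
    )
    return cq_all, truth_all


def driver_detection(
    n_neutral: int,
    config: SimulationConfig,
    reps: int,
    seed: int,
    driver_effect: float = 3.0,
    control_orf_id: str = "GFP",
    fallback_cutoff: float = 5.0,
    min_pairs: int = 3,
    label: str | None = None,
) -> dict:
    """Replicate-screen detection rate of one driver among ``n_neutral``
    neutral constructs (plus the negative control).

    Each of ``reps`` screens simulates one pool and quantifies it with the
    ΔΔCt chain.  The hit cutoff is the empirical-control level at this exact
    pool format: the control's matched-pair lung-vs-MFP ratios pooled across
    all replicate screens and averaged (``fallback_cutoff`` if the control is
    never detected in any lung).  The driver is detected in a screen when it
    passes the minimum-pair rule and its enrichment score reaches the cutoff.

    Returns a dict with ``power``, ``se``, ``cutoff``, ``reps``.
    """
    from .quantify import (
        collapse_replicates,
        fold_change_vs_reference,
        matched_pairs,
        normalize_to_dna,
    )

    if reps < 1:
        raise ConfigError("reps must be at least 1")
    if n_neutral < 1:
        raise ConfigError("need at least one neutral construct")
    members = (
        ["DRIVER"] + [f"NEUT{i:03d}" for i in range(1, n_neutral + 1)] + [control_orf_id]
    )
    pool = PoolPlan(pool_id=label or f"drv1to{n_neutral}", member_orf_ids=tuple(members))
    cfg = replace(config, effects={"DRIVER": (0.0, float(driver_effect))})

    driver_stats: list[tuple[int, float]] = []  # (n_pairs, score) per rep
    control_ratios: list[float] = []
    for rep in range(reps):
        rng = substream(seed, "detection", pool.pool_id, f"rep={rep}")
        cq, _ = simulate_pool(pool, cfg, rng=rng)
        fc = fold_change_vs_reference(normalize_to_dna(collapse_replicates(cq)))
        pairs = matched_pairs(fc)
        drv = pairs[pairs["orf_id"] == "DRIVER"]
        driver_stats.append((len(drv), float(drv["lung_vs_mfp"].mean()) if len(drv) else np.nan))
        control_ratios += list(pairs.loc[pairs["orf_id"] == control_orf_id, "lung_vs_mfp"])

    cutoff = float(np.mean(control_ratios)) if control_ratios else float(fallback_cutoff)
    hits = sum(1 for n, s in driver_stats if n >= min_pairs and s >= cutoff)
    power = hits / reps
    se = float(np.sqrt(power * (1.0 - power) / reps))
    return {"power": power, "se": se, "cutoff": cutoff, "reps": reps}


def complexity_experiment(
    dilution: int,
    config: SimulationConfig | None = None,
    reps: int = 200,
    seed: int = 0,
    driver_effect: float = 3.0,
    fallback_cutoff: float = 5.0,
) -> pd.DataFrame:
    """Detection frequency of one driver diluted 1:``dilution`` among neutral
    constructs.

    Emulates the library-complexity pilot: one metastasis driver (log2
    advantage ``driver_effect``) is pooled with ``dilution`` neutral ORFs plus
    the GFP control and screened in ``mice_per_pool`` mice per replicate;
    detection follows :func:`driver_detection`.  Returns a one-row DataFrame
    with columns ``dilution``, ``frequency``, ``se``, ``cutoff``, ``reps``.
    """
    if dilution < 1:
        raise ConfigError("dilution denominator must be at least 1")
    if config is None:
        config = SimulationConfig()
    res = driver_detection(
        n_neutral=dilution,
        config=config,
        reps=reps,
        seed=seed,
        driver_effect=driver_effect,
        fallback_cutoff=fallback_cutoff,
        label=f"dil1to{dilution}",
    )
    return pd.DataFrame(
        [
            {
                "dilution": dilution,
                "frequency": res["power"],
                "se": res["se"],
                "cutoff": res["cutoff"],
                "reps": res["reps"],
            }
        ]
    )
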