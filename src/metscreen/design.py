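"""Screen design: barcoded libraries, pool partitioning, pool-size power.

The screen format emulated throughout the package is a pooled gain-of-function
metastasis screen: candidate open reading frames (ORFs), each tagged with a
unique DNA barcode, are partitioned into implantation pools of at most
``max_pool_size`` candidates, every pool additionally carries one GFP
negative-control construct, and each pool is engrafted into ``mice_per_pool``
recipient mice.  The defaults (12 candidates per pool, 10 mice per pool)
reproduce the published screen format; the pool-size ceiling itself is
justified by a Monte-Carlo power analysis (:func:`pool_size_power`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DesignInfeasibleError
from .seeds import substream

__all__ = [
    "Role",
    "LibraryEntry",
    "PoolPlan",
    "DesignConfig",
    "generate_barcodes",
    "partition_library",
    "default_library",
    "pool_size_power",
]

_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)


class Role:
    """String constants for library-entry roles."""

    CANDIDATE = "candidate"
    NEGATIVE_CONTROL = "negative_control"
    POSITIVE_CONTROL = "positive_control"

    ALL = (CANDIDATE, NEGATIVE_CONTROL, POSITIVE_CONTROL)


@dataclass(frozen=True)
class LibraryEntry:
    """One barcoded construct in the library."""

    orf_id: str
    gene_symbol: str
    role: str = Role.CANDIDATE
    barcode: str = ""

    def __post_init__(self) -> None:
        if self.role not in Role.ALL:
            raise ConfigError(f"unknown role {self.role!r} for {self.orf_id!r}")
        if self.barcode and set(self.barcode) - set("ACGT"):
            raise ConfigError(f"barcode for {self.orf_id!r} is not a DNA string")


@dataclass(frozen=True)
class PoolPlan:
    """Assignment of library entries (by orf_id) to one implantation pool."""

    pool_id: str
    member_orf_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.member_orf_ids:
            raise ConfigError(f"pool {self.pool_id!r} is empty")
        object.__setattr__(self, "member_orf_ids", tuple(self.member_orf_ids))


@dataclass(frozen=True)
class DesignConfig:
    """Screen-format parameters.

    Defaults reproduce the published format: at most 12 candidate ORFs per
    pool (the GFP control is counted separately, so a full pool carries 13
    constructs) and 10 mice per pool.
    """

    max_pool_size: int = 12
    barcode_length: int = 20
    min_hamming_distance: int = 5
    mice_per_pool: int = 10
    chunk_policy: str = "fixed"  # "fixed" (last pool smaller) or "balanced"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.max_pool_size < 1:
            raise ConfigError("max_pool_size must be positive")
        if self.barcode_length < 1:
            raise ConfigError("barcode_length must be positive")
        if self.min_hamming_distance < 0:
            raise ConfigError("min_hamming_distance must be non-negative")
        if self.min_hamming_distance > self.barcode_length:
            raise ConfigError("min_hamming_distance cannot exceed barcode_length")
        if self.mice_per_pool < 1:
            raise ConfigError("mice_per_pool must be positive")
        if self.chunk_policy not in ("fixed", "balanced"):
            raise ConfigError(f"unknown chunk_policy {self.chunk_policy!r}")


def generate_barcodes(
    n: int,
    length: int,
    min_dist: int,
    seed: int = 0,
    max_attempts_per_code: int = 10_000,
) -> list[str]:
    """Generate ``n`` distinct DNA barcodes with pairwise Hamming distance
    at least ``min_dist``.

    Uses rejection sampling: candidate codewords are drawn uniformly and kept
    when they clear the distance constraint against all accepted codewords.
    Deterministic for a fixed seed.

    Raises
    ------
    DesignInfeasibleError
        If a codeword cannot be placed within ``max_attempts_per_code``
        attempts (the requested code is too dense for this sampler).
    """
    if n < 1:
        raise ConfigError("need at least one barcode")
    if length < 1:
        raise ConfigError("barcode length must be positive")
    if min_dist > length:
        raise ConfigError("min_dist cannot exceed barcode length")
    if 4**length < n:
        raise ConfigError(f"4^{length} sequences cannot hold {n} distinct barcodes")

    rng = substream(seed, "barcodes")
    accepted = np.empty((n, length), dtype=np.uint8)
    count = 0
    while count < n:
        for attempt in range(max_attempts_per_code):
            cand = rng.integers(0, 4, size=length).astype(np.uint8)
            if count == 0:
                break
            dists = (accepted[:count] != cand).sum(axis=1)
            # min_dist == 0 still requires distinctness
            if dists.min() >= max(min_dist, 1):
                break
        else:
            raise DesignInfeasibleError(
                f"could not place barcode {count + 1}/{n} at Hamming distance "
                f"≥{min_dist} within {max_attempts_per_code} attempts"
            )
        accepted[count] = cand
        count += 1
    return ["".join(chr(_ALPHABET[b]) for b in row) for row in accepted]


def _chunk_sizes(n_candidates: int, max_pool_size: int, policy: str) -> list[int]:
    n_pools = math.ceil(n_candidates / max_pool_size)
    if policy == "fixed":
        sizes = [max_pool_size] * (n_candidates // max_pool_size)
        if n_candidates % max_pool_size:
            sizes.append(n_candidates % max_pool_size)
        return sizes
    # balanced: pool count as for "fixed", sizes differing by at most one
    base, extra = divmod(n_candidates, n_pools)
    return [base + 1] * extra + [base] * (n_pools - extra)


def partition_library(
    entries: Sequence[LibraryEntry], config: DesignConfig
) -> list[PoolPlan]:
    """Partition candidate entries into pools, adding the negative control to
    every pool.

    Candidates are shuffled with the configured seed and chunked.  The default
    ``fixed`` policy fills pools to ``max_pool_size`` and leaves the remainder
    in a final smaller pool (the screen fixed pool size, not pool count); the
    ``balanced`` policy equalises pool sizes instead.  The library's single
    negative-control construct (the GFP plasmid in the published screen) is
    appended to every pool; positive controls are never assigned to screening
    pools.
    """
    candidates = [e for e in entries if e.role == Role.CANDIDATE]
    controls = [e for e in entries if e.role == Role.NEGATIVE_CONTROL]
    if not candidates:
        raise ConfigError("library contains no candidate entries")
    if not controls:
        raise ConfigError("library contains no negative_control entry")
    if len(controls) > 1:
        raise ConfigError("library must contain exactly one negative_control entry")
    control = controls[0]

    rng = substream(config.rng_seed, "partition")
    order = rng.permutation(len(candidates))
    shuffled = [candidates[i] for i in order]

    sizes = _chunk_sizes(len(candidates), config.max_pool_size, config.chunk_policy)
    width = max(2, len(str(len(sizes))))
    pools: list[PoolPlan] = []
    start = 0
    for i, size in enumerate(sizes, start=1):
        members = [e.orf_id for e in shuffled[start : start + size]]
        members.append(control.orf_id)
        pools.append(PoolPlan(pool_id=f"pool{i:0{width}d}", member_orf_ids=tuple(members)))
        start += size
    return pools


def default_library(
    n_candidates: int = 230,
    barcode_length: int = 20,
    min_hamming_distance: int = 5,
    seed: int = 0,
) -> list[LibraryEntry]:
    """Synthetic candidate library in the published format: ``n_candidates``
    barcoded ORFs plus one GFP negative control."""
    n_total = n_candidates + 1
    barcodes = generate_barcodes(n_total, barcode_length, min_hamming_distance, seed)
    entries = [
        LibraryEntry(
            orf_id=f"ORF{i + 1:03d}",
            gene_symbol=f"GENE{i + 1:03d}",
            role=Role.CANDIDATE,
            barcode=barcodes[i],
        )
        for i in range(n_candidates)
    ]
    entries.append(
        LibraryEntry(
            orf_id="GFP",
            gene_symbol="GFP",
            role=Role.NEGATIVE_CONTROL,
            barcode=barcodes[-1],
        )
    )
    return entries


def pool_size_power(
    pool_sizes: Iterable[int],
    driver_effect: float,
    config: DesignConfig,
    sim_config=None,
    reps: int = 200,
    seed: int = 0,
    control_orf_id: str = "GFP",
    fallback_cutoff: float = 5.0,
) -> pd.DataFrame:
    """Monte-Carlo detection power of a single metastasis driver as a function
    of pool size.

    For each pool size ``k``, ``reps`` screens of one driver (log2 metastasis
    advantage ``driver_effect``) with ``k - 1`` neutral ORFs plus the GFP
    control are simulated and quantified by the ΔΔCt pipeline.  Because the
    lung-enrichment score of a detected construct scales with pool size (it
    is measured against a ``1/k`` baseline), the hit cutoff is re-derived
    from the empirical control at every format: the control's matched-pair
    lung-vs-MFP ratios are pooled across the replicate screens of that size
    and averaged (falling back to the configured absolute cutoff if the
    control is never detected).  Power is the fraction of screens in which
    the driver passes the minimum-pair rule and reaches that cutoff; a
    Monte-Carlo standard error accompanies each estimate.

    Returns a DataFrame with columns ``pool_size``, ``power``, ``se``,
    ``cutoff``, ``reps``.
    """
    from .simulate import SimulationConfig, driver_detection

    if sim_config is None:
        sim_config = SimulationConfig()
    sim_config = replace(sim_config, mice_per_pool=config.mice_per_pool)
    sizes = [int(s) for s in pool_sizes]
    if any(s < 2 for s in sizes):
        raise ConfigError("pool sizes must be at least 2")

    rows = []
    for size in sizes:
        res = driver_detection(
            n_neutral=size - 1,
            config=sim_config,
            reps=reps,
            seed=seed,
            driver_effect=driver_effect,
            control_orf_id=control_orf_id,
            fallback_cutoff=fallback_cutoff,
            label=f"size={size}",
        )
        rows.append({"pool_size": size, **res})
    return pd.DataFrame(rows)[["pool_size", "power", "se", "cutoff", "reps"]]
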