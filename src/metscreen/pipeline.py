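"""End-to-end pipeline: design → simulate → quantify → call.

:class:`RunConfig` collects every stage's options; its defaults reproduce the
screen's published constants (pools of at most 12 candidates, 10 mice per
pool, minimum 3 matched pairs, fallback cutoff 5, two-fold mammary-depletion
threshold).  :func:`run_pipeline` writes all stage artifacts plus a JSON run
report and is fully deterministic for a fixed root seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import io as mio
from .design import DesignConfig, default_library, partition_library, Role
from .errors import ConfigError
from .hits import call_and_rank, control_cutoff
from .quantify import quantify_pool
from .simulate import SimulationConfig, simulate_screen

__all__ = [
    "QuantifyConfig",
    "HitConfig",
    "RunConfig",
    "run_pipeline",
    "recovery_experiment",
]

logger = logging.getLogger("metscreen.pipeline")


@dataclass(frozen=True)
class QuantifyConfig:
    min_pairs: int = 3
    pair_policy: str = "detected"
    mean_type: str = "arithmetic"
    replicate_policy: str = "mean"


@dataclass(frozen=True)
class HitConfig:
    control_orf_ids: tuple[str, ...] = ("GFP",)
    fallback_cutoff: float = 5.0
    hit_mode: str = "lung"
    mfp_threshold: float = 1.0
    depletion_fold: float = 2.0


@dataclass(frozen=True)
class RunConfig:
    """Full-pipeline configuration; defaults are the published screen format."""

    manifest_path: str | None = None
    n_candidates: int = 230
    outdir: str = "metscreen_out"
    design: DesignConfig = field(default_factory=DesignConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    quantify: QuantifyConfig = field(default_factory=QuantifyConfig)
    hit: HitConfig = field(default_factory=HitConfig)
    rng_seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        """Build a RunConfig from a plain (YAML/JSON) mapping."""
        kwargs = dict(data)
        for key, sub in (
            ("design", DesignConfig),
            ("simulation", SimulationConfig),
            ("quantify", QuantifyConfig),
            ("hit", HitConfig),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                try:
                    kwargs[key] = sub(**kwargs[key])
                except TypeError as exc:
                    raise ConfigError(f"bad {key} configuration: {exc}") from exc
        if "hit" in kwargs and isinstance(kwargs["hit"], HitConfig):
            pass
        try:
            return cls(**kwargs)
        except TypeError as exc:
            raise ConfigError(f"bad run configuration: {exc}") from exc

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"]["effects"] = {
            k: list(v) for k, v in self.simulation.effects.items()
        }
        return d


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def recovery_experiment(
    seeds=(0, 1, 2, 3, 4),
    n_candidates: int = 230,
    n_drivers: int = 10,
    driver_effect: float = 3.0,
    design: DesignConfig | None = None,
    simulation: SimulationConfig | None = None,
    quantify: QuantifyConfig | None = None,
    hit: HitConfig | None = None,
) -> dict:
    """Driver-recovery benchmark of the whole analysis chain.

    For each seed, a fresh library is designed and partitioned, ``n_drivers``
    randomly chosen candidates receive a log2 metastasis advantage of
    ``driver_effect``, the screen is simulated and quantified, and hits are
    called at the GFP-derived cutoff.  Returns per-seed results plus recall
    (fraction of true drivers called hits) and neutral false-positive rate
    aggregated over all seeds.
    """
    from .seeds import substream

    design = design or DesignConfig()
    simulation = simulation or SimulationConfig()
    quantify_cfg = quantify or QuantifyConfig()
    hit_cfg = hit or HitConfig()

    per_seed = []
    tp = fn = fp = tn = 0
    for seed in seeds:
        lib = default_library(
            n_candidates,
            barcode_length=design.barcode_length,
            min_hamming_distance=design.min_hamming_distance,
            seed=seed,
        )
        pools = partition_library(lib, dataclasses.replace(design, rng_seed=seed))
        candidates = [e.orf_id for e in lib if e.role == Role.CANDIDATE]
        rng = substream(seed, "recovery-drivers")
        drivers = set(rng.choice(candidates, size=n_drivers, replace=False))
        sim_cfg = dataclasses.replace(
            simulation,
            effects={d: (0.0, float(driver_effect)) for d in drivers},
            mice_per_pool=design.mice_per_pool,
        )
        cq, _ = simulate_screen(pools, sim_cfg, seed=seed)
        enrichment = quantify_pool(
            cq,
            min_pairs=quantify_cfg.min_pairs,
            pair_policy=quantify_cfg.pair_policy,
            mean_type=quantify_cfg.mean_type,
        )
        cutoff = control_cutoff(
            enrichment,
            list(hit_cfg.control_orf_ids),
            fallback=hit_cfg.fallback_cutoff,
            warn=False,
        )
        calls = call_and_rank(
            enrichment,
            cutoff,
            roles={e.orf_id: e.role for e in lib},
            hit_mode=hit_cfg.hit_mode,
        )
        cand_calls = calls[calls["role"] == "candidate"]
        is_driver = cand_calls["orf_id"].isin(drivers)
        s_tp = int((cand_calls["is_hit"] & is_driver).sum())
        s_fp = int((cand_calls["is_hit"] & ~is_driver).sum())
        tp += s_tp
        fn += int(n_drivers - s_tp)
        fp += s_fp
        tn += int((~is_driver).sum() - s_fp)
        per_seed.append(
            {
                "seed": int(seed),
                "cutoff": cutoff,
                "recall": s_tp / n_drivers,
                "fpr": s_fp / max(int((~is_driver).sum()), 1),
            }
        )
    return {
        "per_seed": per_seed,
        "recall": tp / (tp + fn),
        "fpr": fp / (fp + tn),
        "n_drivers_total": tp + fn,
        "n_neutral_total": fp + tn,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run design → simulate → quantify → call and write all artifacts.

    Returns the run report (also written to ``report.json``): configuration,
    per-stage counts, the applied cutoff, and SHA-256 hashes of every output
    file, so that bit-reproducibility under one seed can be asserted by
    comparing reports.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.rng_seed

    # design
    if config.manifest_path:
        entries = mio.read_manifest(config.manifest_path)
    else:
        entries = default_library(
            n_candidates=config.n_candidates,
            barcode_length=config.design.barcode_length,
            min_hamming_distance=config.design.min_hamming_distance,
            seed=seed,
        )
        mio.write_manifest(outdir / "manifest.tsv", entries)
    design_cfg = dataclasses.replace(config.design, rng_seed=seed)
    pools = partition_library(entries, design_cfg)
    mio.write_pools(outdir / "pools.json", pools)
    logger.info("design: %d entries partitioned into %d pools", len(entries), len(pools))

    # simulate
    sim_cfg = dataclasses.replace(
        config.simulation, mice_per_pool=config.design.mice_per_pool
    )
    cq, truth = simulate_screen(pools, sim_cfg, seed=seed)
    mio.write_cq(outdir / "cq.csv", cq)
    mio.write_truth(outdir / "truth_effects.tsv", outdir / "truth_proportions.tsv", truth)

    # quantify
    enrichment = quantify_pool(
        cq,
        min_pairs=config.quantify.min_pairs,
        pair_policy=config.quantify.pair_policy,
        mean_type=config.quantify.mean_type,
        replicate_policy=config.quantify.replicate_policy,
        detection_limit=sim_cfg.detection_limit,
    )
    mio.write_enrichment(outdir / "enrichment.tsv", enrichment)

    # call
    roles = {e.orf_id: e.role for e in entries}
    symbols = {e.orf_id: e.gene_symbol for e in entries}
    cutoff = control_cutoff(
        enrichment,
        [o for o in config.hit.control_orf_ids if o in roles] or list(config.hit.control_orf_ids),
        fallback=config.hit.fallback_cutoff,
    )
    hits = call_and_rank(
        enrichment,
        cutoff,
        roles=roles,
        gene_symbols=symbols,
        hit_mode=config.hit.hit_mode,
        mfp_threshold=config.hit.mfp_threshold,
        depletion_fold=config.hit.depletion_fold,
    )
    mio.write_hits(outdir / "hits_full.tsv", hits)
    mio.write_hits(outdir / "hits.tsv", hits, hits_only=True)

    artifacts = [
        "pools.json",
        "cq.csv",
        "truth_effects.tsv",
        "truth_proportions.tsv",
        "enrichment.tsv",
        "hits_full.tsv",
        "hits.tsv",
    ]
    if not config.manifest_path:
        artifacts.insert(0, "manifest.tsv")
    report = {
        "seed": seed,
        "config": config.to_dict(),
        "counts": {
            "library_entries": len(entries),
            "candidates": sum(1 for e in entries if e.role == Role.CANDIDATE),
            "pools": len(pools),
            "samples": int(cq["sample_id"].nunique()),
            "lung_samples": int(
                cq.loc[cq["compartment"] == "lung", "sample_id"].nunique()
            ),
            "constructs_scored": int(len(enrichment)),
            "constructs_included": int(enrichment["included"].sum()),
            "hits": int(hits["is_hit"].sum()),
        },
        "cutoff": cutoff,
        "artifact_hashes": {name: _file_hash(outdir / name) for name in artifacts},
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
        fh.write("\n")
    logger.info("pipeline: %d hits at cutoff %.3g", report["counts"]["hits"], cutoff)
    return report
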