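from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from metscreen import DesignConfig, PoolPlan, SimulationConfig

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


@pytest.fixture
def small_pool() -> PoolPlan:
    return PoolPlan("poolA", ("ORF1", "ORF2", "ORF3", "ORF4", "GFP"))


@pytest.fixture
def noiseless_cfg() -> SimulationConfig:
    """Exact-proportion, noise-free configuration for closed-form checks."""
    return SimulationConfig(
        exact_proportions=True,
        cq_noise_sd=0.0,
        dna_probe_sd=0.0,
        metastasis_take_rate=1.0,
        mice_per_pool=4,
    )


@pytest.fixture
def design_cfg() -> DesignConfig:
    return DesignConfig(rng_seed=0)


def random_cq_table(
    rng: np.random.Generator,
    n_orfs: int = 4,
    n_mice: int = 3,
    n_reps: int = 3,
    censor_prob: float = 0.0,
    detection_limit: float = 40.0,
) -> pd.DataFrame:
    """Small random Cq table (one pool) for oracle and invariance tests."""
    orfs = [f"O{i}" for i in range(1, n_orfs + 1)]
    rows = []

    def sample(sample_id, mouse_id, compartment):
        # the reference pellet has ample, evenly represented template: only
        # tumor samples can drop below the detection limit
        can_censor = compartment != "reference"
        for probe in orfs + ["DNA_REF"]:
            base = rng.uniform(18, 30)
            for rep in range(1, n_reps + 1):
                cq = base + rng.normal(0, 0.3)
                censored = (
                    can_censor and probe != "DNA_REF" and rng.random() < censor_prob
                )
                rows.append(
                    (
                        sample_id,
                        mouse_id,
                        "p1",
                        compartment,
                        probe,
                        rep,
                        detection_limit if censored else cq,
                        censored,
                    )
                )

    sample("p1_ref", None, "reference")
    for j in range(1, n_mice + 1):
        sample(f"m{j}_mfp", f"m{j}", "mfp")
        if rng.random() > 0.2:  # some mice lack lung lesions
            sample(f"m{j}_lung", f"m{j}", "lung")
    return pd.DataFrame(rows, columns=CQ_COLUMNS)
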