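import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from metscreen import (
    ConfigError,
    DataError,
    DesignConfig,
    SimulationConfig,
    aggregate_genes,
    collapse_replicates,
    default_library,
    fold_change,
    fold_change_vs_reference,
    matched_pairs,
    normalize_to_dna,
    partition_library,
    quantify_pool,
    simulate_pool,
    simulate_screen,
)
from conftest import CQ_COLUMNS, random_cq_table
from oracle_ddct import brute_force_enrichment, brute_force_fold_changes


def cq_rows(*rows):
    return pd.DataFrame(list(rows), columns=CQ_COLUMNS)


class TestCollapseReplicates:
    def test_mean_of_uncensored(self):
        cq = cq_rows(
            ("s1", "m1", "p", "mfp", "O1", 1, 24.0, False),
            ("s1", "m1", "p", "mfp", "O1", 2, 24.2, False),
            ("s1", "m1", "p", "mfp", "O1", 3, 24.4, False),
        )
        out = collapse_replicates(cq)
        assert out.loc[0, "cq"] == pytest.approx(24.2)
        assert out.loc[0, "n_replicates_used"] == 3
        assert not out.loc[0, "censored"]

    def test_partial_censoring_uses_remaining_wells(self):
        cq = cq_rows(
            ("s1", "m1", "p", "mfp", "O1", 1, 25.0, False),
            ("s1", "m1", "p", "mfp", "O1", 2, 40.0, True),
        )
        out = collapse_replicates(cq)
        assert out.loc[0, "cq"] == pytest.approx(25.0)
        assert out.loc[0, "n_replicates_used"] == 1

    def test_fully_censored_row_propagates(self):
        cq = cq_rows(
            ("s1", "m1", "p", "mfp", "O1", 1, 40.0, True),
            ("s1", "m1", "p", "mfp", "O1", 2, 40.0, True),
        )
        out = collapse_replicates(cq)
        assert out.loc[0, "censored"]
        assert out.loc[0, "n_replicates_used"] == 0

    def test_unknown_policy_rejected(self):
        with pytest.raises(ConfigError):
            collapse_replicates(cq_rows(("s", "m", "p", "mfp", "O1", 1, 20.0, False)), "mode")


class TestNormalizeToDna:
    def _collapsed(self, barcode_cq, dna_cq):
        cq = cq_rows(
            ("s1", "m1", "p", "mfp", "O1", 1, barcode_cq, False),
            ("s1", "m1", "p", "mfp", "DNA_REF", 1, dna_cq, False),
        )
        return collapse_replicates(cq)

    @pytest.mark.parametrize("bc,dna,expected", [(25.0, 20.0, 5.0), (20.0, 20.0, 0.0)])
    def test_delta_ct(self, bc, dna, expected):
        out = normalize_to_dna(self._collapsed(bc, dna))
        assert out.loc[0, "delta_ct"] == pytest.approx(expected)

    def test_missing_dna_ref_names_sample(self):
        cq = cq_rows(("sampleX", "m1", "p", "mfp", "O1", 1, 25.0, False))
        with pytest.raises(DataError, match="sampleX"):
            normalize_to_dna(collapse_replicates(cq))


class TestFoldChange:
    @pytest.mark.parametrize("ds,dr,expected", [(5.0, 6.0, 2.0), (3.0, 3.0, 1.0)])
    def test_scalar_examples(self, ds, dr, expected):
        assert fold_change(ds, dr) == pytest.approx(expected)

    def test_missing_pool_reference_is_an_error(self):
        cq = cq_rows(
            ("s1", "m1", "p", "mfp", "O1", 1, 25.0, False),
            ("s1", "m1", "p", "mfp", "DNA_REF", 1, 20.0, False),
        )
        with pytest.raises(DataError, match="p"):
            fold_change_vs_reference(normalize_to_dna(collapse_replicates(cq)))

    def test_self_reference_identity(self):
        rng = np.random.default_rng(0)
        cq = random_cq_table(rng)
        fc = fold_change_vs_reference(normalize_to_dna(collapse_replicates(cq)))
        ref = fc[fc["compartment"] == "reference"]
        assert np.allclose(ref["fold_change"], 1.0, atol=1e-12)


class TestPipelineInvariants:
    @pytest.mark.parametrize("seed", range(100))
    def test_sample_wide_shift_invariance(self, seed):
        """Adding a constant to every Cq of one sample (DNA_REF included)
        changes no fold change — the point of total-DNA normalization."""
        rng = np.random.default_rng(seed)
        cq = random_cq_table(rng, n_orfs=3, n_mice=2)
        shifted = cq.copy()
        target = rng.choice(cq["sample_id"].unique())
        shifted.loc[shifted["sample_id"] == target, "cq"] += rng.uniform(-3, 3)
        a = fold_change_vs_reference(normalize_to_dna(collapse_replicates(cq)))
        b = fold_change_vs_reference(normalize_to_dna(collapse_replicates(shifted)))
        merged = a.merge(b, on=["sample_id", "orf_id"], suffixes=("_a", "_b"))
        assert np.allclose(merged["fold_change_a"], merged["fold_change_b"], rtol=1e-9)

    def test_monotonicity_in_single_barcode(self):
        """Lowering one barcode's Cq in one tumor sample strictly increases
        that (sample, orf) fold change and no other."""
        rng = np.random.default_rng(7)
        cq = random_cq_table(rng, n_orfs=4, n_mice=3)
        target_sample = "m1_mfp"
        target_orf = "O2"
        bumped = cq.copy()
        mask = (bumped["sample_id"] == target_sample) & (bumped["probe"] == target_orf)
        bumped.loc[mask, "cq"] -= 1.0
        a = fold_change_vs_reference(normalize_to_dna(collapse_replicates(cq)))
        b = fold_change_vs_reference(normalize_to_dna(collapse_replicates(bumped)))
        merged = a.merge(b, on=["sample_id", "orf_id"], suffixes=("_a", "_b"))
        hit = (merged["sample_id"] == target_sample) & (merged["orf_id"] == target_orf)
        assert (merged.loc[hit, "fold_change_b"] > merged.loc[hit, "fold_change_a"]).all()
        assert np.allclose(
            merged.loc[~hit, "fold_change_a"], merged.loc[~hit, "fold_change_b"], rtol=1e-9
        )

    @pytest.mark.parametrize("seed", range(20))
    def test_brute_force_ddct_oracle(self, seed):
        """Pipeline fold changes equal an independent loop-and-dict ΔΔCt
        recomputation to ≤1e−12 relative error on small random tables."""
        rng = np.random.default_rng(1000 + seed)
        cq = random_cq_table(
            rng,
            n_orfs=int(rng.integers(2, 6)),
            n_mice=int(rng.integers(1, 5)),
            censor_prob=0.1,
        )
        expected = brute_force_fold_changes(cq.to_dict("records"))
        fc = fold_change_vs_reference(normalize_to_dna(collapse_replicates(cq)))
        got = {
            (r.sample_id, r.orf_id): r.fold_change
            for r in fc.itertuples()
            if not r.censored
        }
        assert set(expected) == set(got)
        for key, val in expected.items():
            assert got[key] == pytest.approx(val, rel=1e-12)


class TestMatchedPairs:
    def _fc(self, *rows):
        return pd.DataFrame(
            list(rows),
            columns=["sample_id", "mouse_id", "pool_id", "compartment", "orf_id",
                     "fold_change", "censored", "censored_ref"],
        )

    def test_ratio_example(self):
        fc = self._fc(
            ("s1", "m1", "p", "mfp", "O1", 2.0, False, False),
            ("s2", "m1", "p", "lung", "O1", 8.0, False, False),
        )
        pairs = matched_pairs(fc)
        assert pairs.loc[0, "lung_vs_mfp"] == pytest.approx(4.0)

    def test_mouse_without_lung_contributes_no_pair(self):
        fc = self._fc(("s1", "m1", "p", "mfp", "O1", 2.0, False, False))
        assert len(matched_pairs(fc)) == 0

    def test_censored_well_voids_pair_by_default(self):
        fc = self._fc(
            ("s1", "m1", "p", "mfp", "O1", 2.0, False, False),
            ("s2", "m1", "p", "lung", "O1", 1e-6, True, False),
        )
        assert len(matched_pairs(fc)) == 0
        assert len(matched_pairs(fc, pair_policy="imputed")) == 1

    def test_duplicate_measurements_rejected(self):
        fc = self._fc(
            ("s1", "m1", "p", "mfp", "O1", 2.0, False, False),
            ("s1b", "m1", "p", "mfp", "O1", 3.0, False, False),
        )
        with pytest.raises(DataError):
            matched_pairs(fc)

    def test_pairs_match_truth_in_exact_mode(self, small_pool, noiseless_cfg):
        """In the noiseless exact-proportion limit, each pair ratio equals the
        simulator's true lung/MFP abundance ratio."""
        cfg = dataclasses.replace(noiseless_cfg, effects={"ORF1": (0.1, 2.0)})
        cq, truth = simulate_pool(small_pool, cfg, seed=0)
        fc = fold_change_vs_reference(normalize_to_dna(collapse_replicates(cq)))
        pairs = matched_pairs(fc)
        props = truth.proportions.pivot_table(
            index=["mouse_id", "orf_id"], columns="compartment", values="proportion"
        ).reset_index()
        merged = pairs.merge(props, on=["mouse_id", "orf_id"])
        # reference proportions are equal, so fc ratio = (p_lung/p_ref)/(p_mfp/p_ref)
        assert np.allclose(
            merged["lung_vs_mfp"], merged["lung"] / merged["mfp"], rtol=1e-9
        )


class TestAggregateGenes:
    def _pairs(self, values, orf="O1"):
        return pd.DataFrame(
            {
                "pool_id": "p",
                "mouse_id": [f"m{i}" for i in range(len(values))],
                "orf_id": orf,
                "fc_mfp": 1.0,
                "fc_lung": values,
                "lung_vs_mfp": values,
            }
        )

    def test_mean_and_inclusion(self):
        out = aggregate_genes(self._pairs([6.0, 7.0, 8.0]))
        assert out.loc[0, "mean_lung_vs_mfp"] == pytest.approx(7.0)
        assert bool(out.loc[0, "included"])

    def test_below_min_pairs_is_excluded_but_retained(self):
        out = aggregate_genes(self._pairs([50.0, 60.0]))
        assert not bool(out.loc[0, "included"])
        assert out.loc[0, "n_pairs"] == 2

    def test_geometric_mean_option(self):
        out = aggregate_genes(self._pairs([2.0, 8.0]), min_pairs=1, mean_type="geometric")
        assert out.loc[0, "mean_lung_vs_mfp"] == pytest.approx(4.0)

    def test_zero_pair_constructs_added_from_universe(self):
        universe = pd.DataFrame({"orf_id": ["O1", "O2"], "pool_id": "p"})
        out = aggregate_genes(self._pairs([1.0, 2.0, 3.0]), all_orfs=universe)
        o2 = out[out["orf_id"] == "O2"].iloc[0]
        assert o2["n_pairs"] == 0 and not o2["included"]


class TestScoreRecoversEffectRanking:
    def test_spearman_against_true_metastasis_advantage(self):
        """With graded true metastasis advantages across a 230-ORF screen the
        enrichment scores recover the effect ranking (undetected constructs
        rank at the bottom: no lung detection is evidence of no enrichment)."""
        seed = 0
        lib = default_library(230, seed=seed)
        pools = partition_library(lib, DesignConfig(rng_seed=seed))
        rng = np.random.default_rng(123)
        effects = {
            f"ORF{i + 1:03d}": (0.0, float(v))
            for i, v in enumerate(rng.uniform(0, 4, 230))
        }
        cfg = dataclasses.replace(SimulationConfig(), effects=effects)
        cq, _ = simulate_screen(pools, cfg, seed=seed)
        enr = quantify_pool(cq)
        cand = enr[enr["orf_id"] != "GFP"].copy()
        cand["m_true"] = cand["orf_id"].map(lambda o: effects[o][1])
        score = np.where(cand["included"], cand["mean_lung_vs_mfp"], 0.0)
        rho = spearmanr(cand["m_true"], score).statistic
        assert rho > 0.6
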