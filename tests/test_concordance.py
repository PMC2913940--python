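import numpy as np
import pandas as pd
import pytest

from cndiff import concordance as cc
from cndiff import synthetic_data as sd
from cndiff.calling import build_region_grid

from _oracles import bh_oracle, pooled_t_oracle


def _expression_setup(beta, seed=0, n=20, f=0.5):
    region = sd.PlantedRegion("chr1", 5_000_000, 10_000_000, "gain", f_a=f, f_b=f)
    cfg = sd.SimulationConfig(
        n_group_a=n,
        n_group_b=n,
        chrom_lengths=sd.default_chrom_lengths(n_chrom=2, length=20_000_000),
        regions=(region,),
        seed=seed,
    )
    _, _, cohort, truth = sd.simulate_cohort(cfg)
    grid = build_region_grid(cfg.chrom_lengths)
    calls = sd.region_calls_from_truth(truth, grid)
    expr, annot = sd.simulate_expression(truth, genes_per_region=10, beta=beta, noise_sd=0.5, seed=seed)
    return expr, annot, calls, cohort, grid


class TestExpressionByCnTtest:
    def test_identical_arms_give_t_zero_p_one(self):
        expr = pd.DataFrame({"s1": [1.0], "s2": [2.0], "s3": [1.0], "s4": [2.0]}, index=["g"])
        annot = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100], "gene_id": ["g"]})
        calls = pd.DataFrame(
            {"s1": ["gain"], "s2": ["gain"], "s3": ["normal"], "s4": ["normal"]},
            index=pd.Index(["chr1:0"], name="region_id"),
        )
        cohort = pd.DataFrame({"sample_id": ["s1", "s2", "s3", "s4"], "group": ["AA"] * 4})
        grid = pd.DataFrame({"region_id": ["chr1:0"], "chrom": ["chr1"], "start": [0], "end": [5_000_000]})
        res = cc.expression_by_cn_ttest(expr, annot, calls, ["chr1:0"], cohort, grid)
        assert len(res) == 1
        assert res[0].t == 0.0 and res[0].p == 1.0

    def test_pooled_t_closed_form(self):
        from scipy.stats import ttest_ind

        t, p = ttest_ind([1, 2, 3], [2, 3, 4], equal_var=True)
        assert np.isclose(t, -1.224744871, atol=1e-8)
        assert np.isclose(p, 0.2878641347, atol=1e-8)
        ot, op = pooled_t_oracle([1, 2, 3], [2, 3, 4])
        assert np.isclose(t, ot) and np.isclose(p, op)

    def test_t_matches_closed_form_on_random_arms(self):
        """Pooled t equals the textbook closed form on small random arms."""
        from scipy.stats import ttest_ind

        rng = np.random.default_rng(5)
        for _ in range(200):
            x = rng.normal(size=rng.integers(2, 6))
            y = rng.normal(size=rng.integers(2, 6))
            t, p = ttest_ind(x, y, equal_var=True)
            ot, op = pooled_t_oracle(x, y)
            assert np.isclose(t, ot, atol=1e-10)
            assert np.isclose(p, op, atol=1e-10)

    def test_small_arm_skipped(self):
        expr, annot, calls, cohort, grid = _expression_setup(beta=3.0, seed=1, n=20, f=0.5)
        # force group CA to have a single gain carrier: contrast must vanish
        ca = [s for s in calls.columns if s.startswith("CA")]
        calls.loc[:, ca] = "normal"
        calls.loc[calls.index[1], ca[0]] = "gain"
        res = cc.expression_by_cn_ttest(expr, annot, calls, list(calls.index), cohort, grid)
        assert all(not (r.group == "CA" and r.contrast == "gain_vs_normal") for r in res)

    def test_strong_coupling_detected(self):
        expr, annot, calls, cohort, grid = _expression_setup(beta=3.0, seed=2)
        res = cc.expression_by_cn_ttest(expr, annot, calls, list(calls.index), cohort, grid)
        assert res, "expected some contrasts"
        frac = np.mean([r.significant for r in res])
        assert frac >= 0.9


class TestAdjustPvalues:
    def test_bh_worked_example(self):
        np.testing.assert_allclose(
            cc.adjust_pvalues([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert cc.adjust_pvalues([0.3])[0] == 0.3

    def test_matches_stepup_oracle(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=50)
        np.testing.assert_allclose(cc.adjust_pvalues(p), bh_oracle(p), atol=1e-12)

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=30)
        assert (cc.adjust_pvalues(p) >= p - 1e-15).all()

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            cc.adjust_pvalues([0.5, 1.5])


def _two_block_expression(n_a=19, n_b=14, beta=5.0, noise=0.5, seed=0):
    cfg = sd.SimulationConfig(
        n_group_a=n_a,
        n_group_b=n_b,
        chrom_lengths=sd.default_chrom_lengths(n_chrom=2, length=20_000_000),
        regions=(
            # opposite-carrier blocks: cohort A high in block 1, cohort B
            # high in block 2, so the centered profiles anti-correlate
            sd.PlantedRegion("chr1", 0, 10_000_000, "gain", f_a=1.0, f_b=0.0),
            sd.PlantedRegion("chr2", 0, 10_000_000, "gain", f_a=0.0, f_b=1.0),
        ),
        seed=seed,
    )
    _, _, cohort, truth = sd.simulate_cohort(cfg)
    expr, _ = sd.simulate_expression(truth, genes_per_region=25, beta=beta, noise_sd=noise, seed=seed)
    return expr, cohort


class TestHierarchicalCluster:
    def test_separable_blocks_classify_perfectly(self):
        expr, cohort = _two_block_expression()
        _, labels, mis = cc.hierarchical_cluster(expr, cohort)
        assert mis == 0

    def test_sample_order_invariant(self):
        expr, cohort = _two_block_expression()
        perm = list(expr.columns[::-1])
        _, labels_a, mis_a = cc.hierarchical_cluster(expr, cohort)
        _, labels_b, mis_b = cc.hierarchical_cluster(expr[perm], cohort)
        assert mis_a == mis_b
        # same partition regardless of labelling of the two clusters
        part_a = frozenset(frozenset(s for s in labels_a if labels_a[s] == c) for c in (1, 2))
        part_b = frozenset(frozenset(s for s in labels_b if labels_b[s] == c) for c in (1, 2))
        assert part_a == part_b

    def test_duplicate_sample_joins_same_cluster(self):
        expr, cohort = _two_block_expression()
        dup = expr["AA01"].rename("AA01b")
        expr2 = pd.concat([expr, dup], axis=1)
        cohort2 = pd.concat(
            [cohort, pd.DataFrame([{"sample_id": "AA01b", "group": "AA"}])], ignore_index=True
        )
        _, labels, _ = cc.hierarchical_cluster(expr2, cohort2)
        assert labels["AA01"] == labels["AA01b"]

    def test_zero_variance_sample_dropped(self, caplog):
        expr, cohort = _two_block_expression()
        expr["CA01"] = 1.0
        with caplog.at_level("WARNING"):
            _, labels, _ = cc.hierarchical_cluster(expr, cohort)
        assert "CA01" not in labels


class TestHeatmapTable:
    def test_single_gene_block(self):
        expr = pd.DataFrame({"s1": [1.0], "s2": [2.0]}, index=["g"])
        annot = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100], "gene_id": ["g"]})
        calls = pd.DataFrame(
            {"s1": ["gain"], "s2": ["normal"]}, index=pd.Index(["chr1:0"], name="region_id")
        )
        grid = pd.DataFrame({"region_id": ["chr1:0"], "chrom": ["chr1"], "start": [0], "end": [5_000_000]})
        block, states = cc.region_expression_heatmap_table(expr, annot, calls, "chr1:0", grid)
        assert block.shape == (1, 2)
        assert list(states.index) == list(block.columns)

    def test_values_not_rescaled(self):
        expr, annot, calls, cohort, grid = _expression_setup(beta=2.0, seed=3)
        rid = calls.index[1]
        block, _ = cc.region_expression_heatmap_table(expr, annot, calls, rid, grid)
        for g in block.index:
            assert sorted(block.loc[g]) == sorted(expr.loc[g, block.columns])

    def test_empty_region_errors(self):
        expr, annot, calls, cohort, grid = _expression_setup(beta=2.0, seed=3)
        with pytest.raises(ValueError):
            cc.region_expression_heatmap_table(expr, annot, calls, "chr2:3", grid)

    def test_opposite_carrier_groups_order_expression(self):
        """Gains in 8 cohort-A samples and losses in 6 cohort-B samples
        push in-region expression apart in the expected direction."""
        cfg = sd.SimulationConfig(
            n_group_a=20,
            n_group_b=21,
            chrom_lengths=sd.default_chrom_lengths(n_chrom=1, length=20_000_000),
            regions=(sd.PlantedRegion("chr1", 0, 5_000_000, "gain", f_a=8 / 20, f_b=0.0),),
            seed=12,
        )
        _, _, _, truth = sd.simulate_cohort(cfg)
        # flip the non-carrier B samples into loss carriers for 6 of them
        ca = [s for s in truth.carriers.index if s.startswith("CA")]
        label = truth.carriers.columns[0]
        truth.carriers.loc[ca, label] = "normal"
        truth.carriers.loc[ca[:6], label] = "loss"
        expr, _ = sd.simulate_expression(truth, genes_per_region=10, beta=3.0, noise_sd=0.5, seed=12)
        gains = truth.carriers.index[truth.carriers[label] == "gain"]
        losses = truth.carriers.index[truth.carriers[label] == "loss"]
        assert len(losses) == 6
        assert expr[gains].to_numpy().mean() > expr[losses].to_numpy().mean()
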