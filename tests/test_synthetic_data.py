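import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cndiff import synthetic_data as sd
from cndiff.calling import build_region_grid


def _region_probe_mask(pm, region):
    return (pm.chrom == region.chrom) & (pm.position - 1 >= region.start) & (pm.position - 1 < region.end)


class TestSimulateCohort:
    def test_same_seed_bit_identical(self):
        cfg = sd.SimulationConfig(n_group_a=4, n_group_b=4, seed=9)
        pm1, prof1, cohort1, truth1 = sd.simulate_cohort(cfg)
        pm2, prof2, cohort2, truth2 = sd.simulate_cohort(cfg)
        for a, b in zip(prof1, prof2):
            np.testing.assert_array_equal(a.values, b.values)
        assert cohort1.equals(cohort2)
        assert truth1.carriers.equals(truth2.carriers)

    def test_full_penetrance_separates_groups(self):
        region = sd.PlantedRegion("chr1", 5_000_000, 15_000_000, "gain", delta=1.0, f_a=1.0, f_b=0.0)
        cfg = sd.SimulationConfig(
            n_group_a=8, n_group_b=8, sigma=0.05, regions=(region,), seed=5
        )
        pm, profiles, cohort, truth = sd.simulate_cohort(cfg)
        mask = _region_probe_mask(pm, region)
        means = {p.sample_id: p.values[mask].mean() for p in profiles}
        a = [means[s] for s in means if s.startswith("AA")]
        b = [means[s] for s in means if s.startswith("CA")]
        assert min(a) > max(b)

    def test_null_region_mean_moments(self):
        """With nothing planted, per-sample region means follow
        Normal(baseline, sigma/sqrt(m)) to within Monte-Carlo error."""
        cfg = sd.SimulationConfig(
            n_group_a=150, n_group_b=150, sigma=0.2, baseline=0.1, seed=2,
            chrom_lengths=sd.default_chrom_lengths(n_chrom=1, length=40_000_000),
        )
        pm, profiles, _, _ = sd.simulate_cohort(cfg)
        m = len(pm)
        means = np.array([p.values.mean() for p in profiles])
        se = cfg.sigma / np.sqrt(m)
        assert abs(means.mean() - 0.1) < 4 * se / np.sqrt(len(means))
        assert 0.8 < means.std() / se < 1.2

    def test_carrier_fraction_matches_frequency(self):
        region = sd.PlantedRegion("chr1", 0, 5_000_000, "loss", delta=0.5, f_a=0.3, f_b=0.7)
        cfg = sd.SimulationConfig(
            n_group_a=500, n_group_b=500, regions=(region,), seed=3,
            chrom_lengths=sd.default_chrom_lengths(n_chrom=1, length=10_000_000),
        )
        _, _, _, truth = sd.simulate_cohort(cfg)
        carried = truth.carriers[region.label] == "loss"
        for prefix, f in (("AA", 0.3), ("CA", 0.7)):
            frac = carried[[s for s in carried.index if s.startswith(prefix)]].mean()
            assert abs(frac - f) < 3 * np.sqrt(f * (1 - f) / 500)

    def test_bac_duplicates_halve_noise_variance(self):
        base = dict(n_group_a=100, n_group_b=1, sigma=0.2, seed=4,
                    chrom_lengths=sd.default_chrom_lengths(n_chrom=1, length=50_000_000))
        _, single, _, _ = sd.simulate_cohort(sd.SimulationConfig(**base))
        _, dup, _, _ = sd.simulate_cohort(sd.SimulationConfig(bac_duplicates=True, **base))
        v1 = np.mean([p.values.var() for p in single])
        v2 = np.mean([p.values.var() for p in dup])
        assert 0.4 < v2 / v1 < 0.6

    def test_region_outside_bounds_errors(self):
        with pytest.raises(ValueError, match="bounds"):
            sd.SimulationConfig(
                regions=(sd.PlantedRegion("chr1", 0, 99_000_000_000, "gain"),)
            )

    def test_overlapping_regions_error(self):
        with pytest.raises(ValueError, match="overlap"):
            sd.SimulationConfig(
                regions=(
                    sd.PlantedRegion("chr1", 0, 10_000_000, "gain"),
                    sd.PlantedRegion("chr1", 5_000_000, 15_000_000, "loss"),
                )
            )


class TestSimulateExpression:
    @pytest.fixture
    def truth(self):
        cfg = sd.SimulationConfig(
            n_group_a=20, n_group_b=20,
            regions=(sd.PlantedRegion("chr1", 0, 10_000_000, "gain", f_a=0.5, f_b=0.5),),
            seed=6,
        )
        return sd.simulate_cohort(cfg)[3]

    def test_same_seed_identical(self, truth):
        e1, _ = sd.simulate_expression(truth, beta=1.0, seed=8)
        e2, _ = sd.simulate_expression(truth, beta=1.0, seed=8)
        assert e1.equals(e2)

    def test_coupling_shift_matches_beta(self, truth):
        """gain-carrier minus normal-carrier mean expression ~ beta (CLT bound)."""
        expr, _ = sd.simulate_expression(truth, genes_per_region=20, beta=3.0, noise_sd=0.5, seed=8)
        label = truth.regions["label"].iloc[0]
        carriers = truth.carriers[label]
        gain = expr.loc[:, carriers == "gain"].to_numpy().mean()
        normal = expr.loc[:, carriers == "normal"].to_numpy().mean()
        assert abs((gain - normal) - 3.0) < 0.3

    def test_null_pvalues_uniform(self, truth):
        """beta = 0 decouples expression from copy state: per-gene t-test
        p-values are uniform (KS check)."""
        expr, _ = sd.simulate_expression(truth, genes_per_region=150, beta=0.0, noise_sd=0.5, seed=9)
        label = truth.regions["label"].iloc[0]
        carriers = truth.carriers[label]
        gain_cols = expr.columns[carriers[expr.columns] == "gain"]
        norm_cols = expr.columns[carriers[expr.columns] == "normal"]
        pvals = [
            stats.ttest_ind(row[gain_cols], row[norm_cols], equal_var=True).pvalue
            for _, row in expr.iterrows()
        ]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_zero_genes_errors(self, truth):
        with pytest.raises(ValueError):
            sd.simulate_expression(truth, genes_per_region=0)

    def test_genes_placed_inside_regions(self, truth):
        _, annot = sd.simulate_expression(truth, genes_per_region=5, seed=1)
        reg = truth.regions.iloc[0]
        assert (annot["chrom"] == reg["chrom"]).all()
        mid = (annot["start"] + annot["end"]) // 2
        assert ((mid >= reg["start"]) & (mid < reg["end"])).all()


class TestClinicalTable:
    def test_psa_means_match_design(self):
        """Cohort PSA means approach 8.5 (AA) and 8.3 (CA) over replicates."""
        frames = [sd.simulate_clinical_table(200, 210, seed=s) for s in range(10)]
        df = pd.concat(frames)
        mean = df.groupby("group")["psa"].mean()
        assert abs(mean["AA"] - 8.5) < 0.15
        assert abs(mean["CA"] - 8.3) < 0.15

    def test_psa_within_ranges(self):
        df = sd.simulate_clinical_table(300, 300, seed=1)
        aa = df[df["group"] == "AA"]["psa"]
        ca = df[df["group"] == "CA"]["psa"]
        assert aa.between(4, 17).all()
        assert ca.between(3, 17).all()

    def test_fixed_seed_identical(self):
        assert sd.simulate_clinical_table(20, 21, seed=7).equals(
            sd.simulate_clinical_table(20, 21, seed=7)
        )

    def test_category_proportions(self):
        df = sd.simulate_clinical_table(4000, 4000, seed=2)
        aa = df[df["group"] == "AA"]
        assert abs((aa["stage"] == "II").mean() - 0.60) < 0.03
        assert abs((aa["gleason"] == 7).mean() - 0.80) < 0.03


class TestTruthProjection:
    def test_region_calls_from_truth_marks_carriers(self):
        region = sd.PlantedRegion("chr1", 5_000_000, 10_000_000, "gain", f_a=1.0, f_b=0.0)
        cfg = sd.SimulationConfig(n_group_a=3, n_group_b=3, regions=(region,), seed=0)
        _, _, _, truth = sd.simulate_cohort(cfg)
        grid = build_region_grid(cfg.chrom_lengths)
        calls = sd.region_calls_from_truth(truth, grid)
        assert (calls.loc["chr1:1", ["AA01", "AA02", "AA03"]] == "gain").all()
        assert (calls.loc["chr1:1", ["CA01", "CA02", "CA03"]] == "normal").all()
        assert (calls.drop(index="chr1:1") == "normal").all().all()
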