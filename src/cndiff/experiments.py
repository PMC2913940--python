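"""Reference desk-scale experiments exercising the whole pipeline.

These bundle the canonical study conditions used to validate the method on
synthetic data: a null calibration of the per-region exact test (planted
alterations at equal frequency in both cohorts), a power/recovery experiment
for a group-differential region, a dosage-concordance experiment, and a
two-block clustering separability experiment.  Problem sizes are chosen so
each experiment runs in minutes on one CPU while keeping the statistical
checks meaningful: sparse (1-2 Mb) probe spacing, 8 synthetic autosomes, and
the 20-vs-21 cohort layout of the sparse-platform design.
"""

from __future__ import annotations

import numpy as np

from . import synthetic_data as sd
from .concordance import expression_by_cn_ttest, hierarchical_cluster
from .differential import select_noteworthy
from .calling import build_region_grid
from .pipeline import differential_pipeline
from .segmentation import CbsParams

__all__ = [
    "null_calibration",
    "planted_region_recovery",
    "recovery_ceiling",
    "concordance_power",
    "clustering_separability",
]

_CBS_PERM = 200  # permutation count for simulation studies (alpha = 0.01 resolvable)


def _null_config(seed: int) -> sd.SimulationConfig:
    """20-vs-21 cohorts, 200 5-Mb regions, 40 planted CNVs carried with the
    same 30% frequency in both groups: real copy-number variation, no
    group difference."""
    lengths = sd.default_chrom_lengths(n_chrom=8, length=125_000_000)
    regions = []
    for c in range(8):
        for k in range(5):
            start = (3 + 4 * k) * 5_000_000
            state = "gain" if (c + k) % 2 == 0 else "loss"
            regions.append(
                sd.PlantedRegion(f"chr{c + 1}", start, start + 5_000_000, state, delta=0.6, f_a=0.3, f_b=0.3)
            )
    return sd.SimulationConfig(
        chrom_lengths=lengths, probe_spacing=2_000_000, sigma=0.1, regions=tuple(regions), seed=seed
    )


def null_calibration(seed: int = 0, alpha: float = 0.05):
    """Full-pipeline type-I behavior with no group differences.

    Returns ``(n_regions_tested, rejection_rate)`` at the given alpha.
    """
    cfg = _null_config(seed)
    pm, profiles, cohort, _ = sd.simulate_cohort(cfg)
    _, results = differential_pipeline(
        pm, profiles, cohort, cfg.chrom_lengths, params=CbsParams(n_perm=_CBS_PERM, seed=seed), mode="bac"
    )
    ps = np.array([r.p for r in results])
    return len(ps), float((ps < alpha).mean())


def _recovery_config(seed: int) -> sd.SimulationConfig:
    region = sd.PlantedRegion("chr1", 10_000_000, 15_000_000, "gain", delta=0.6, f_a=0.5, f_b=0.05)
    return sd.SimulationConfig(regions=(region,), sigma=0.1, seed=seed)


RECOVERY_REGION_ID = "chr1:2"


def planted_region_recovery(n_seeds: int = 100, base_seed: int = 0, alpha: float = 0.05):
    """Fraction of replicates in which the planted differential region
    (delta = 0.6, sigma = 0.1, carried in 50% of cohort A vs 5% of cohort B)
    survives the p < alpha screen."""
    hits = 0
    for s in range(n_seeds):
        cfg = _recovery_config(base_seed + s)
        pm, profiles, cohort, _ = sd.simulate_cohort(cfg)
        _, results = differential_pipeline(
            pm, profiles, cohort, cfg.chrom_lengths,
            params=CbsParams(n_perm=_CBS_PERM, seed=base_seed + s), mode="bac",
        )
        survivors = {r.region_id for r in select_noteworthy(results, alpha=alpha)}
        hits += RECOVERY_REGION_ID in survivors
    return hits / n_seeds


def recovery_ceiling(n_reps: int = 5000, seed: int = 0, alpha: float = 0.05):
    """Ideal-detection recovery bound for the planted-region experiment.

    Even with every carrier called perfectly, recovery is limited by the
    binomial carrier draw: the region survives only when the exact test on
    the drawn carrier counts (Bin(20, 0.5) vs Bin(21, 0.05)) rejects.  This
    simulates that bound directly, skipping probes and segmentation.
    """
    from .differential import fisher_exact_3x2

    rng = np.random.default_rng(seed)
    cfg = _recovery_config(0)
    region = cfg.regions[0]
    n_a, n_b = cfg.n_group_a, cfg.n_group_b
    rej = 0
    for _ in range(n_reps):
        a = rng.binomial(n_a, region.f_a)
        b = rng.binomial(n_b, region.f_b)
        rej += fisher_exact_3x2([[a, b], [n_a - a, n_b - b], [0, 0]]) < alpha
    return rej / n_reps


def concordance_power(beta: float, n_seeds: int = 20, base_seed: int = 0):
    """Fraction of in-region gene tests significant at adjusted p < 0.05.

    Copy-number states come from the planted truth (isolating the expression
    statistics from segmentation noise); carriers are drawn at 50% in both
    cohorts so both per-cohort contrasts are populated.
    """
    region = sd.PlantedRegion("chr1", 5_000_000, 10_000_000, "gain", f_a=0.5, f_b=0.5)
    n_sig = 0
    n_tests = 0
    for s in range(n_seeds):
        cfg = sd.SimulationConfig(
            chrom_lengths=sd.default_chrom_lengths(n_chrom=2, length=20_000_000),
            regions=(region,),
            seed=base_seed + s,
        )
        _, _, cohort, truth = sd.simulate_cohort(cfg)
        grid = build_region_grid(cfg.chrom_lengths)
        calls = sd.region_calls_from_truth(truth, grid)
        expr, annot = sd.simulate_expression(
            truth, genes_per_region=10, beta=beta, noise_sd=0.5, seed=base_seed + s
        )
        results = expression_by_cn_ttest(expr, annot, calls, list(calls.index), cohort, grid)
        n_sig += sum(r.significant for r in results)
        n_tests += len(results)
    return n_sig / n_tests if n_tests else float("nan")


def clustering_separability(seed: int = 0, n_group_a: int = 19, n_group_b: int = 14):
    """Misclassified-sample count for two cohorts with opposite strong
    expression-block signatures (beta = 5, noise 0.5)."""
    cfg = sd.SimulationConfig(
        n_group_a=n_group_a,
        n_group_b=n_group_b,
        chrom_lengths=sd.default_chrom_lengths(n_chrom=2, length=20_000_000),
        regions=(
            sd.PlantedRegion("chr1", 0, 10_000_000, "gain", f_a=1.0, f_b=0.0),
            sd.PlantedRegion("chr2", 0, 10_000_000, "gain", f_a=0.0, f_b=1.0),
        ),
        seed=seed,
    )
    _, _, cohort, truth = sd.simulate_cohort(cfg)
    expr, _ = sd.simulate_expression(truth, genes_per_region=25, beta=5.0, noise_sd=0.5, seed=seed)
    _, _, mis = hierarchical_cluster(expr, cohort)
    return mis
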