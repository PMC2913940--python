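"""Two-cohort aCGH simulator with planted group-differential CNV regions.

The generator emulates the kind of data the pipeline was built for: per-tumor
log2 test/reference ratio profiles on a sparse (BAC-like, ~1 Mb spacing) or
dense (oligo-like, ~9 kb) array, for two patient cohorts (labelled AA and CA)
of 20 and 21 samples by default.  Each planted region is carried
independently per sample with a group-specific frequency; probes inside a
carried region are drawn ``Normal(baseline +/- delta, sigma)`` and elsewhere
``Normal(baseline, sigma)``.  A companion generator couples gene expression
to the carried state (shift ``+beta`` for gain carriers, ``-beta`` for loss
carriers), and a third draws a clinical covariate table whose marginal
distributions follow the frequency-matched design of the study population
the pipeline targets (PSA means 8.5 / 8.3 ng/mL within truncated ranges,
matched age, stage, and Gleason strata).

Randomness uses one global seed expanded into counter-based substreams (one
per sample), so results do not depend on evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
import yaml
from scipy import optimize
from scipy import stats as sstats

from .io_formats import CopyNumberProfile, ProbeMap, chrom_sort_key, normalize_chrom

__all__ = [
    "PlantedRegion",
    "SimulationConfig",
    "GroundTruth",
    "default_chrom_lengths",
    "simulate_cohort",
    "simulate_expression",
    "simulate_clinical_table",
    "region_calls_from_truth",
    "load_config",
]

BAC_SPACING = 1_000_000  # ~1 Mb clone spacing
OLIGO_SPACING = 9_000  # ~9 kb average oligo spacing


@dataclass(frozen=True)
class PlantedRegion:
    """A group-differential CNV to plant: carried with frequency ``f_a`` in
    cohort A and ``f_b`` in cohort B, shifting probe means by ``+delta``
    (gain) or ``-delta`` (loss)."""

    chrom: str
    start: int
    end: int
    state: str  # "gain" | "loss"
    delta: float = 0.6
    f_a: float = 0.5
    f_b: float = 0.05

    @property
    def label(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.state}"


def default_chrom_lengths(n_chrom: int = 8, length: int = 40_000_000) -> pd.DataFrame:
    """A compact synthetic autosome set used by the default simulations."""
    return pd.DataFrame({"chrom": [f"chr{i + 1}" for i in range(n_chrom)], "length": length})


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated two-cohort aCGH experiment.

    Defaults mirror the discovery-cohort design the pipeline targets:
    20 vs 21 samples on a sparse BAC-like array (1 Mb spacing) with probe
    noise sigma = 0.1 log2 units around a baseline of 0, and planted
    alterations of delta = 0.6 log2 units.
    """

    n_group_a: int = 20
    n_group_b: int = 21
    chrom_lengths: pd.DataFrame = field(default_factory=default_chrom_lengths)
    probe_spacing: int = BAC_SPACING
    sigma: float = 0.1
    regions: tuple[PlantedRegion, ...] = ()
    baseline: float = 0.0
    bac_duplicates: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        lengths = dict(zip(self.chrom_lengths["chrom"], self.chrom_lengths["length"]))
        spans: dict[str, list[tuple[int, int]]] = {}
        for r in self.regions:
            if r.state not in {"gain", "loss"}:
                raise ValueError(f"planted state must be gain or loss: {r.state!r}")
            if not 0 <= r.f_a <= 1 and 0 <= r.f_b <= 1:
                raise ValueError("carrier frequencies must lie in [0, 1]")
            if r.delta <= 0:
                raise ValueError("delta must be positive")
            if r.chrom not in lengths:
                raise ValueError(f"planted region on unknown chromosome {r.chrom}")
            if not 0 <= r.start < r.end <= lengths[r.chrom]:
                raise ValueError(f"planted region outside chromosome bounds: {r.label}")
            for s, e in spans.get(r.chrom, []):
                if r.start < e and s < r.end:
                    raise ValueError("planted regions overlap")
            spans.setdefault(r.chrom, []).append((r.start, r.end))


@dataclass(frozen=True)
class GroundTruth:
    """What was planted: per-region metadata and per-sample carried states.

    ``carriers`` is a sample x region frame of {"gain", "loss", "normal"};
    ``regions`` records each planted region with its configured group
    frequencies.
    """

    regions: pd.DataFrame
    carriers: pd.DataFrame
    group_of: dict[str, str]


def _sample_ids(config: SimulationConfig) -> tuple[list[str], list[str]]:
    a = [f"AA{i + 1:02d}" for i in range(config.n_group_a)]
    b = [f"CA{i + 1:02d}" for i in range(config.n_group_b)]
    return a, b


def _probe_map(config: SimulationConfig) -> ProbeMap:
    ids, chroms, pos = [], [], []
    lengths = config.chrom_lengths.sort_values("chrom", key=lambda s: s.map(chrom_sort_key))
    for chrom, length in zip(lengths["chrom"], lengths["length"]):
        chrom = normalize_chrom(chrom)
        p = np.arange(config.probe_spacing // 2, int(length), config.probe_spacing, dtype=np.int64) + 1
        ids.extend(f"P_{chrom}_{k}" for k in range(len(p)))
        chroms.extend([chrom] * len(p))
        pos.append(p)
    return ProbeMap(
        probe_id=np.array(ids, dtype=object),
        chrom=np.array(chroms, dtype=object),
        position=np.concatenate(pos) if pos else np.array([], dtype=np.int64),
    )


def simulate_cohort(config: SimulationConfig):
    """Draw one two-cohort aCGH experiment.

    Returns ``(probe_map, profiles, cohort_table, truth)``.  Each sample
    carries each planted region independently with its group's frequency;
    carrier state applies to the whole region.  Deterministic for a fixed
    ``config.seed`` regardless of evaluation order (per-sample substreams).
    """
    pm = _probe_map(config)
    ids_a, ids_b = _sample_ids(config)
    samples = ids_a + ids_b
    group_of = {s: ("AA" if s in set(ids_a) else "CA") for s in samples}

    region_probe_idx = []
    for r in config.regions:
        on_chrom = pm.chrom == r.chrom
        inside = (pm.position - 1 >= r.start) & (pm.position - 1 < r.end)
        region_probe_idx.append(np.flatnonzero(on_chrom & inside))

    profiles = []
    carried_rows = {}
    for i, sid in enumerate(samples):
        rng = np.random.default_rng([config.seed, i])
        f = np.array([r.f_a if group_of[sid] == "AA" else r.f_b for r in config.regions])
        carried = rng.random(len(config.regions)) < f if len(config.regions) else np.zeros(0, bool)
        values = config.baseline + config.sigma * rng.standard_normal(len(pm))
        if config.bac_duplicates:
            # duplicate-spot arrays report the average of two independent spots
            second = config.baseline + config.sigma * rng.standard_normal(len(pm))
            values = (values + second) / 2.0
        for carried_flag, r, idx in zip(carried, config.regions, region_probe_idx):
            if carried_flag:
                values[idx] += r.delta if r.state == "gain" else -r.delta
        profiles.append(CopyNumberProfile(sid, values))
        carried_rows[sid] = [
            (r.state if c else "normal") for c, r in zip(carried, config.regions)
        ]

    truth = GroundTruth(
        regions=pd.DataFrame(
            {
                "label": [r.label for r in config.regions],
                "chrom": [r.chrom for r in config.regions],
                "start": [r.start for r in config.regions],
                "end": [r.end for r in config.regions],
                "state": [r.state for r in config.regions],
                "delta": [r.delta for r in config.regions],
                "f_a": [r.f_a for r in config.regions],
                "f_b": [r.f_b for r in config.regions],
            }
        ),
        carriers=pd.DataFrame.from_dict(
            carried_rows, orient="index", columns=[r.label for r in config.regions]
        ),
        group_of=group_of,
    )
    cohort = simulate_clinical_table(config.n_group_a, config.n_group_b, seed=config.seed)
    cohort["sample_id"] = samples
    return pm, profiles, cohort, truth


def simulate_expression(
    truth: GroundTruth,
    genes_per_region: int = 10,
    beta: float = 1.0,
    noise_sd: float = 0.5,
    baseline: float = 6.0,
    seed: int = 0,
    samples=None,
):
    """Expression matrix coupled to the planted copy-number states.

    ``genes_per_region`` genes are placed evenly inside each planted region;
    a sample's expression of an in-region gene is
    ``baseline + beta*s + Normal(0, noise_sd)`` with ``s`` = +1 for gain
    carriers, -1 for loss carriers and 0 otherwise.  Returns the genes x
    samples frame plus a BED-like gene annotation frame.
    """
    if genes_per_region < 1:
        raise ValueError("need at least one gene per region")
    if beta < 0:
        raise ValueError("beta must be non-negative")
    if samples is None:
        samples = list(truth.carriers.index)
    rng = np.random.default_rng([seed, 104729])

    gene_rows = []
    values = []
    for ri, reg in enumerate(truth.regions.itertuples(index=False)):
        width = (reg.end - reg.start) / genes_per_region
        s = truth.carriers.loc[samples, reg.label].map({"gain": 1.0, "loss": -1.0, "normal": 0.0}).to_numpy()
        for g in range(genes_per_region):
            mid = reg.start + (g + 0.5) * width
            gstart = int(mid) - 500
            gene_rows.append((reg.chrom, max(gstart, reg.start), max(gstart, reg.start) + 1000, f"g{ri}_{g}"))
            values.append(baseline + beta * s + noise_sd * rng.standard_normal(len(samples)))
    annot = pd.DataFrame(gene_rows, columns=["chrom", "start", "end", "gene_id"])
    expr = pd.DataFrame(np.array(values), index=annot["gene_id"].tolist(), columns=samples)
    expr.index.name = "gene_id"
    return expr, annot


# Clinical strata of the frequency-matched two-cohort design: age bracket,
# stage and Gleason category probabilities, and PSA mean/SD with the observed
# range used as truncation limits.
_AGE_BRACKETS = [(50, 54), (55, 59), (60, 64), (65, 75)]
_CLINICAL = {
    "AA": {
        "age_p": (0.35, 0.30, 0.10, 0.25),
        "psa": (8.5, 3.5, 4.0, 17.0),
        "stage_p": (0.60, 0.40),
        "gleason_p": (0.15, 0.80, 0.05),
    },
    "CA": {
        "age_p": (5 / 21, 10 / 21, 3 / 21, 3 / 21),
        "psa": (8.3, 4.0, 3.0, 17.0),
        "stage_p": (16 / 21, 5 / 21),
        "gleason_p": (6 / 21, 11 / 21, 4 / 21),
    },
}


@lru_cache(maxsize=None)
def _truncnorm_for_mean(target_mean: float, scale: float, lo: float, hi: float):
    """Location parameter whose [lo, hi]-truncated normal has the target mean.

    Truncation pulls the mean toward the interval's center, so the published
    cohort mean is matched by solving for the underlying location; the
    realized SD is then slightly below the nominal scale.
    """

    def f(loc):
        a, b = (lo - loc) / scale, (hi - loc) / scale
        return sstats.truncnorm.mean(a, b, loc=loc, scale=scale) - target_mean

    loc = optimize.brentq(f, lo - 10 * scale, hi + 10 * scale)
    return loc


def simulate_clinical_table(n_a: int, n_b: int, seed: int = 0) -> pd.DataFrame:
    """Draw a frequency-matched clinical covariate table for two cohorts.

    PSA is truncated-normal with cohort means 8.5 (A) and 8.3 (B) ng/mL and
    nominal SDs 3.5 / 4.0 within ranges [4, 17] and [3, 17]; age, stage, and
    Gleason strata are sampled with the matched cohort proportions.
    """
    if n_a <= 0 or n_b <= 0:
        raise ValueError("cohort sizes must be positive")
    rows = []
    for gi, (group, n) in enumerate((("AA", n_a), ("CA", n_b))):
        spec = _CLINICAL[group]
        rng = np.random.default_rng([seed, 9973 + gi])
        mean, sd, lo, hi = spec["psa"]
        loc = _truncnorm_for_mean(mean, sd, lo, hi)
        a, b = (lo - loc) / sd, (hi - loc) / sd
        psa = sstats.truncnorm.rvs(a, b, loc=loc, scale=sd, size=n, random_state=rng)
        age_cat = rng.choice(len(_AGE_BRACKETS), size=n, p=spec["age_p"])
        ages = [int(rng.integers(_AGE_BRACKETS[c][0], _AGE_BRACKETS[c][1] + 1)) for c in age_cat]
        stage = rng.choice(["II", "III"], size=n, p=spec["stage_p"])
        gleason = rng.choice([6, 7, 8], size=n, p=spec["gleason_p"])
        for i in range(n):
            rows.append(
                {
                    "sample_id": f"{group}{i + 1:02d}",
                    "group": group,
                    "age": ages[i],
                    "psa": float(psa[i]),
                    "stage": stage[i],
                    "gleason": int(gleason[i]),
                }
            )
    return pd.DataFrame(rows)


def region_calls_from_truth(truth: GroundTruth, grid: pd.DataFrame) -> pd.DataFrame:
    """Oracle region x sample state matrix implied by the planted truth.

    Grid regions overlapping a planted region take each sample's carried
    state there; everything else is normal.  Useful for exercising the
    downstream statistics without running segmentation.
    """
    samples = list(truth.carriers.index)
    out = pd.DataFrame("normal", index=grid["region_id"], columns=samples, dtype=object)
    for reg in truth.regions.itertuples(index=False):
        hit = grid[(grid["chrom"] == reg.chrom) & (grid["start"] < reg.end) & (reg.start < grid["end"])]
        states = truth.carriers[reg.label]
        for rid in hit["region_id"]:
            for s in samples:
                if states[s] != "normal":
                    out.loc[rid, s] = states[s]
    return out


def load_config(path) -> SimulationConfig:
    """Read a flat YAML simulation config (regions as a list of mappings)."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    regions = tuple(PlantedRegion(**r) for r in raw.pop("regions", []))
    lengths = raw.pop("chrom_lengths", None)
    cfg = SimulationConfig(regions=regions, **raw)
    if lengths is not None:
        cfg = replace(cfg, chrom_lengths=pd.DataFrame(lengths, columns=["chrom", "length"]))
    return cfg
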