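import numpy as np
import pandas as pd
import pytest

from cndiff import catalog_enrichment as ce
from cndiff import synthetic_data as sd


@pytest.fixture(scope="session")
def bands():
    return ce.load_bundled_cytobands()


@pytest.fixture(scope="session")
def bac_catalog(bands):
    return ce.load_bundled_catalog("bac", bands)


@pytest.fixture(scope="session")
def oligo_catalog(bands):
    return ce.load_bundled_catalog("oligo", bands)


@pytest.fixture
def toy_lengths():
    return pd.DataFrame({"chrom": ["chr1", "chr2"], "length": [12_000_000, 5_000_000]})


@pytest.fixture
def small_cohort_sim():
    """One small two-cohort simulation with a strongly differential region."""
    cfg = sd.SimulationConfig(
        n_group_a=6,
        n_group_b=6,
        chrom_lengths=sd.default_chrom_lengths(n_chrom=4, length=30_000_000),
        regions=(
            sd.PlantedRegion("chr1", 10_000_000, 15_000_000, "gain", delta=1.0, f_a=1.0, f_b=0.0),
        ),
        sigma=0.05,
        seed=42,
    )
    return cfg, sd.simulate_cohort(cfg)


def write_lines(path, lines):
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


@pytest.fixture
def toy_ratio_file(tmp_path):
    return write_lines(
        tmp_path / "ratios.tsv",
        [
            "probe_id\tchrom\tposition\tS1\tS2",
            "p1\t1\t100\t0.1\t-0.2",
            "p2\t1\t200\t0.0\t0.3",
            "p3\t2\t50\t-0.1\t0.05",
        ],
    )
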