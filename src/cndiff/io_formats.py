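"""Readers and writers for the on-disk artifacts of the copy-number pipeline.

All genomic intervals are held internally as 0-based half-open ``[start, end)``;
1-based probe positions appear only at parse/serialize boundaries.  Chromosome
names are normalized to the ``chr``-prefixed form on input, so ``"3"`` and
``"chr3"`` refer to the same chromosome.  Every reader ignores ``#``-prefixed
comment lines and expects UTF-8 text.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "ProbeMap",
    "CopyNumberProfile",
    "normalize_chrom",
    "chrom_sort_key",
    "read_log_ratio_matrix",
    "write_log_ratio_matrix",
    "read_chrom_lengths",
    "read_cohort_table",
    "read_cytoband_table",
    "write_segment_table",
    "read_segment_table",
    "write_region_call_matrix",
    "read_region_call_matrix",
    "read_expression_matrix",
    "read_gene_annotation",
    "read_gene_sets",
    "read_region_catalog",
]


def normalize_chrom(name) -> str:
    """Return the ``chr``-prefixed form of a chromosome name."""
    s = str(name).strip()
    return s if s.startswith("chr") else "chr" + s


def chrom_sort_key(chrom: str):
    """Natural sort key: chr1..chr22 numerically, then chrX, chrY, others."""
    body = chrom[3:] if chrom.startswith("chr") else chrom
    if body.isdigit():
        return (0, int(body), "")
    return (1, {"X": 0, "Y": 1}.get(body, 2), body)


@dataclass(frozen=True)
class ProbeMap:
    """The array's coordinate system: one row per probe, sorted by position.

    Positions are 1-based (as printed in probe annotation files); the map is
    sorted by (chromosome, position) with positions strictly increasing within
    each chromosome.
    """

    probe_id: np.ndarray
    chrom: np.ndarray
    position: np.ndarray

    def __post_init__(self):
        ids = np.asarray(self.probe_id, dtype=object)
        uniq, counts = np.unique(ids, return_counts=True)
        if (counts > 1).any():
            dup = uniq[counts > 1][0]
            raise ValueError(f"duplicate probe id: {dup!r}")
        for c, sl in _chrom_slices(np.asarray(self.chrom)).items():
            pos = np.asarray(self.position)[sl]
            if not (np.diff(pos) > 0).all():
                raise ValueError(f"positions not strictly increasing on {c}")

    def __len__(self) -> int:
        return len(self.probe_id)

    def chrom_index(self) -> dict[str, slice]:
        """Mapping chromosome -> contiguous slice of probe indices."""
        return _chrom_slices(np.asarray(self.chrom))

    def chroms(self) -> list[str]:
        return list(self.chrom_index())


def _chrom_slices(chrom_arr: np.ndarray) -> dict[str, slice]:
    out: dict[str, slice] = {}
    start = 0
    for i in range(1, len(chrom_arr) + 1):
        if i == len(chrom_arr) or chrom_arr[i] != chrom_arr[start]:
            c = str(chrom_arr[start])
            if c in out:
                raise ValueError(f"chromosome {c} not contiguous in probe map")
            out[c] = slice(start, i)
            start = i
    return out


@dataclass(frozen=True)
class CopyNumberProfile:
    """One sample's log2 test/reference ratios aligned to a :class:`ProbeMap`.

    Missing measurements are NaN; all non-missing values must be finite.
    """

    sample_id: str
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if np.isinf(v).any():
            raise ValueError(f"non-finite log2 ratio in sample {self.sample_id}")
        object.__setattr__(self, "values", v)

    @property
    def mask(self) -> np.ndarray:
        """Boolean mask of missing entries."""
        return np.isnan(self.values)


# ---------------------------------------------------------------------------
# log2-ratio matrix


def read_log_ratio_matrix(path) -> tuple[ProbeMap, list[CopyNumberProfile]]:
    """Parse a tab-delimited probe x sample log2-ratio matrix.

    The header row is ``probe_id  chrom  position  <sample> ...``.  Empty cells
    become missing values.  Rows are sorted by (chromosome, position); if the
    input was unsorted a warning is logged.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str, 1: str})
    if df.shape[1] < 4:
        raise ValueError("expected columns probe_id, chrom, position, then samples")
    df.columns = ["probe_id", "chrom", "position", *df.columns[3:]]
    dup = df["probe_id"][df["probe_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate probe id: {dup.iloc[0]!r}")
    df["chrom"] = df["chrom"].map(normalize_chrom)
    df["position"] = pd.to_numeric(df["position"], errors="raise").astype(np.int64)
    sample_cols = list(df.columns[3:])
    for col in sample_cols:
        df[col] = pd.to_numeric(df[col], errors="raise")

    order = sorted(range(len(df)), key=lambda i: (chrom_sort_key(df["chrom"].iat[i]), df["position"].iat[i]))
    if order != list(range(len(df))):
        log.warning("log2-ratio matrix was not sorted by (chrom, position); sorting")
        df = df.iloc[order].reset_index(drop=True)

    pm = ProbeMap(
        probe_id=df["probe_id"].to_numpy(dtype=object),
        chrom=df["chrom"].to_numpy(dtype=object),
        position=df["position"].to_numpy(),
    )
    profiles = [CopyNumberProfile(s, df[s].to_numpy(dtype=float)) for s in sample_cols]
    return pm, profiles


def write_log_ratio_matrix(probe_map: ProbeMap, profiles, path) -> None:
    df = pd.DataFrame(
        {
            "probe_id": probe_map.probe_id,
            "chrom": probe_map.chrom,
            "position": probe_map.position,
        }
    )
    for p in profiles:
        df[p.sample_id] = p.values
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# small tables


def read_chrom_lengths(path) -> pd.DataFrame:
    """Two-column whitespace-delimited chromosome-length table."""
    df = pd.read_csv(path, sep=r"\s+", comment="#", header=None, names=["chrom", "length"])
    df["chrom"] = df["chrom"].map(normalize_chrom)
    df["length"] = pd.to_numeric(df["length"], errors="raise").astype(np.int64)
    if (df["length"] <= 0).any():
        raise ValueError("chromosome lengths must be positive")
    if df["chrom"].duplicated().any():
        raise ValueError("duplicate chromosome in length table")
    return df.sort_values("chrom", key=lambda s: s.map(chrom_sort_key)).reset_index(drop=True)


def read_cohort_table(path) -> pd.DataFrame:
    """Sample metadata: sample_id, group, age, psa, stage, gleason."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"sample_id", "group"}
    if not required.issubset(df.columns):
        raise ValueError(f"cohort table must carry columns {sorted(required)}")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in cohort table")
    if df["group"].isna().any():
        raise ValueError("missing group label in cohort table")
    return df


def read_cytoband_table(path) -> pd.DataFrame:
    """Parse a UCSC cytoBand-dialect file (chrom start end band stain).

    Band labels are stored without the chromosome prefix.  Bands must be
    non-overlapping within a chromosome; the table is returned sorted.
    """
    df = pd.read_csv(
        path,
        sep=r"\s+",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "band", "stain"],
        dtype={0: str, 3: str, 4: str},
    )
    if len(df) == 0:
        return df
    df["chrom"] = df["chrom"].map(normalize_chrom)
    df["start"] = pd.to_numeric(df["start"], errors="raise").astype(np.int64)
    df["end"] = pd.to_numeric(df["end"], errors="raise").astype(np.int64)
    if (df["end"] <= df["start"]).any():
        bad = df[df["end"] <= df["start"]].iloc[0]
        raise ValueError(f"cytoband {bad['chrom']}{bad['band']}: end <= start")
    df = df.sort_values(["chrom", "start"], key=lambda s: s.map(chrom_sort_key) if s.name == "chrom" else s)
    df = df.reset_index(drop=True)
    for chrom, sub in df.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if (starts[1:] < ends[:-1]).any():
            raise ValueError(f"overlapping cytobands on {chrom}")
        if (starts[1:] > ends[:-1]).any():
            log.warning("cytoband table has gaps on %s", chrom)
    return df


# ---------------------------------------------------------------------------
# segment tables (BED-like, round-trips SegmentCallSet)


def write_segment_table(callset, path) -> None:
    """Serialize a :class:`~cndiff.calling.SegmentCallSet` as BED-like text.

    Columns: chrom, start (0-based), end (half-open), sample_id, segment mean,
    n_probes, state.  Per-sample mu/sigma thresholds are kept in ``#`` header
    lines so the file round-trips losslessly through :func:`read_segment_table`.
    """
    buf = io.StringIO()
    for sample, (mu, sigma) in callset.stats.items():
        buf.write(f"# sample_stats\t{sample}\t{mu!r}\t{sigma!r}\n")
    cols = ["chrom", "start", "end", "sample_id", "mean", "n_probes", "state"]
    buf.write("\t".join(cols) + "\n")
    for row in callset.segments.itertuples(index=False):
        buf.write(
            f"{row.chrom}\t{row.start}\t{row.end}\t{row.sample_id}\t"
            f"{row.mean!r}\t{row.n_probes}\t{row.state}\n"
        )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


def read_segment_table(path):
    """Inverse of :func:`write_segment_table`."""
    from .calling import SegmentCallSet  # local import: avoids a module cycle

    stats: dict[str, tuple[float, float]] = {}
    rows = []
    header = None
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].strip().split("\t")
                if parts and parts[0] == "sample_stats":
                    stats[parts[1]] = (float(parts[2]), float(parts[3]))
                continue
            if header is None:
                header = line.split("\t")
                continue
            rows.append(line.split("\t"))
    df = pd.DataFrame(rows, columns=header)
    if len(df):
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["mean"] = df["mean"].astype(float)
        df["n_probes"] = df["n_probes"].astype(np.int64)
    else:
        df = df.astype(
            {"start": np.int64, "end": np.int64, "mean": float, "n_probes": np.int64},
            errors="ignore",
        )
    return SegmentCallSet(segments=df, stats=stats)


# ---------------------------------------------------------------------------
# region-call matrix (region x sample categorical states)

_STATE_TO_CHAR = {"gain": "G", "normal": "N", "loss": "L", "no_data": "."}
_CHAR_TO_STATE = {v: k for k, v in _STATE_TO_CHAR.items()}


def write_region_call_matrix(matrix: pd.DataFrame, path) -> None:
    """Serialize a region x sample state matrix using {G, N, L, .} codes."""
    coded = matrix.map(lambda s: _STATE_TO_CHAR[s])
    coded.to_csv(path, sep="\t", index_label="region_id")


def read_region_call_matrix(path) -> pd.DataFrame:
    coded = pd.read_csv(path, sep="\t", comment="#", index_col="region_id", dtype=str)
    bad = set(np.unique(coded.to_numpy())) - set(_CHAR_TO_STATE)
    if bad:
        raise ValueError(f"unknown state codes in region-call matrix: {sorted(bad)}")
    return coded.map(lambda c: _CHAR_TO_STATE[c])


# ---------------------------------------------------------------------------
# expression and annotation inputs


def read_expression_matrix(path) -> pd.DataFrame:
    """Normalized genes x samples expression matrix (tab-delimited)."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if df.index.duplicated().any():
        raise ValueError("duplicate gene id in expression matrix")
    values = df.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("non-finite expression value")
    return df


def read_gene_annotation(path) -> pd.DataFrame:
    """BED-like gene coordinates: chrom, start, end, gene_id (0-based half-open)."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "gene_id"],
        dtype={0: str, 3: str},
    )
    df["chrom"] = df["chrom"].map(normalize_chrom)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    if (df["end"] <= df["start"]).any():
        raise ValueError("gene annotation interval with end <= start")
    if df["gene_id"].duplicated().any():
        raise ValueError("duplicate gene_id in annotation")
    return df


def read_gene_sets(path) -> pd.DataFrame:
    """GMT-like gene-set table: term_id, term_name, then one gene per column."""
    records = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"gene-set line needs term_id, term_name, genes: {line[:50]!r}")
            records.append((parts[0], parts[1], frozenset(g for g in parts[2:] if g)))
    return pd.DataFrame(records, columns=["term_id", "term_name", "genes"])


def read_region_catalog(path) -> pd.DataFrame:
    """Tab-delimited cytoband-region catalog: label, direction."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if not {"label", "direction"}.issubset(df.columns):
        raise ValueError("region catalog needs columns label, direction")
    if df["label"].duplicated().any():
        raise ValueError("duplicate label in region catalog")
    return df
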