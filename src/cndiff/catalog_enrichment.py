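"""Cytoband-addressed region catalogs, cross-platform overlap, and
EASE-score gene-set enrichment.

A catalog entry names a genomic region by its cytolocation as printed in
results tables: a single band (``3q26.1``), a band with all its sub-bands
(``3q26``), or a band range (``5p15-p14``, arm-crossing ranges like
``20p11-20q11`` allowed).  Labels resolve to bp intervals against a
cytoband table, after which catalogs from different platforms can be
intersected.  Genes in validated regions are scored for functional
enrichment with the EASE statistic: the upper-tail hypergeometric
probability computed after removing one query gene from the overlap, which
is always at least as large (more conservative) than the plain one-sided
Fisher p-value.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .io_formats import normalize_chrom, read_cytoband_table, read_region_catalog

__all__ = [
    "CytobandRegion",
    "RegionCatalog",
    "parse_cytoband_region",
    "intersect_catalogs",
    "overlap_loci",
    "ease_score",
    "EnrichmentResult",
    "enrich",
    "load_bundled_cytobands",
    "load_bundled_catalog",
]

_LABEL_RE = re.compile(
    r"^(?P<chrom>(?:chr)?(?:\d+|X|Y))(?P<arm>[pq])(?P<band>\d+(?:\.\d+)?)"
    r"(?:-(?P<chrom2>(?:chr)?(?:\d+|X|Y))?(?P<arm2>[pq])(?P<band2>\d+(?:\.\d+)?))?$"
)


@dataclass(frozen=True)
class CytobandRegion:
    """A printed cytolocation resolved to a bp interval."""

    label: str
    chrom: str
    start: int
    end: int

    def overlaps(self, other: "CytobandRegion") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class RegionCatalog:
    """Platform-tagged list of (resolved region, direction class) entries."""

    platform: str
    entries: tuple[tuple[CytobandRegion, str], ...]

    @classmethod
    def from_frame(cls, platform: str, frame: pd.DataFrame, bands: pd.DataFrame) -> "RegionCatalog":
        if frame["label"].duplicated().any():
            raise ValueError("duplicate label in catalog")
        entries = tuple(
            (parse_cytoband_region(lab, bands), direction)
            for lab, direction in zip(frame["label"], frame["direction"])
        )
        return cls(platform=platform, entries=entries)

    def __len__(self) -> int:
        return len(self.entries)


def _match_band(bands: pd.DataFrame, chrom: str, spec: str) -> pd.DataFrame:
    """Bands equal to ``spec`` or sub-bands of it (``q26`` matches ``q26.31``)."""
    sub = bands[bands["chrom"] == chrom]
    hit = sub[(sub["band"] == spec) | sub["band"].str.startswith(spec + ".")]
    if len(hit) == 0:
        raise KeyError(f"band {chrom}{spec} not present in cytoband table")
    return hit


def parse_cytoband_region(label: str, bands: pd.DataFrame) -> CytobandRegion:
    """Resolve a printed cytolocation label to a bp interval.

    A bare band label unions the band and all its sub-bands; a ranged label
    unions everything from the first band matched by the left endpoint
    through the last band matched by the right endpoint, in genomic order.
    Range endpoints must be on the same chromosome (the arm may differ, so a
    range may span the centromere).
    """
    m = _LABEL_RE.match(label.strip())
    if not m:
        raise ValueError(f"cannot parse cytoband label {label!r}")
    chrom = normalize_chrom(m["chrom"])
    first = _match_band(bands, chrom, m["arm"] + m["band"])
    if m["arm2"] is None:
        return CytobandRegion(label, chrom, int(first["start"].min()), int(first["end"].max()))
    chrom2 = normalize_chrom(m["chrom2"]) if m["chrom2"] else chrom
    if chrom2 != chrom:
        raise ValueError(f"range endpoints on different chromosomes in {label!r}")
    second = _match_band(bands, chrom, m["arm2"] + m["band2"])
    start = min(int(first["start"].min()), int(second["start"].min()))
    end = max(int(first["end"].max()), int(second["end"].max()))
    return CytobandRegion(label, chrom, start, end)


def intersect_catalogs(a: RegionCatalog, b: RegionCatalog) -> list[tuple]:
    """All cross-catalog entry pairs whose resolved intervals share >= 1 bp.

    Each overlapping pair is returned once, ordered by (chrom, start) of the
    intersection.
    """
    from .io_formats import chrom_sort_key

    pairs = []
    for ra, da in a.entries:
        for rb, db in b.entries:
            if ra.overlaps(rb):
                inter = (max(ra.start, rb.start), min(ra.end, rb.end))
                pairs.append(((ra, da), (rb, db), inter))
    pairs.sort(key=lambda p: (chrom_sort_key(p[0][0].chrom), p[2][0], p[2][1]))
    return [(pa, pb) for pa, pb, _ in pairs]


def overlap_loci(pairs) -> list[dict]:
    """Collapse overlapping pairs into distinct genomic loci.

    Pairs whose intersection intervals touch or share a member are merged,
    so one focal region matched by several broader regions counts once.
    Returns one record per locus with the contributing labels from each
    catalog.
    """
    items = []
    for (ra, _da), (rb, _db) in pairs:
        items.append(
            {
                "chrom": ra.chrom,
                "start": max(ra.start, rb.start),
                "end": min(ra.end, rb.end),
                "labels_a": {ra.label},
                "labels_b": {rb.label},
            }
        )
    items.sort(key=lambda d: (d["chrom"], d["start"]))
    merged: list[dict] = []
    for it in items:
        prev = merged[-1] if merged else None
        if (
            prev is not None
            and prev["chrom"] == it["chrom"]
            and (it["start"] < prev["end"] or prev["labels_a"] & it["labels_a"] or prev["labels_b"] & it["labels_b"])
        ):
            prev["end"] = max(prev["end"], it["end"])
            prev["labels_a"] |= it["labels_a"]
            prev["labels_b"] |= it["labels_b"]
        else:
            merged.append(it)
    for m in merged:
        m["labels_a"] = sorted(m["labels_a"])
        m["labels_b"] = sorted(m["labels_b"])
    return merged


def ease_score(k: int, n: int, K: int, N: int) -> float:
    """EASE enrichment probability for a query/term overlap.

    With ``k`` query genes in the term, query size ``n``, term size ``K`` and
    background size ``N``, the EASE score is the upper-tail hypergeometric
    probability of observing at least ``k - 1`` term genes — i.e. the
    one-sided Fisher p after removing one overlapping gene, which penalizes
    single-gene overlaps (``k <= 1`` scores 1) and is never smaller than the
    unmodified one-sided p.
    """
    if not (0 <= k <= min(n, K)) or n > N or K > N:
        raise ValueError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")
    if k <= 1:
        return 1.0
    # P(X >= k-1) for X ~ Hypergeom(N, K, n)
    return float(hypergeom.sf(k - 2, N, K, n))


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int
    n: int
    K: int
    N: int
    fraction: float
    ease_p: float
    passes_ease_max: bool
    significant: bool


def enrich(
    query_genes,
    annotation: pd.DataFrame,
    background,
    min_count: int = 2,
    ease_max: float = 0.1,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """EASE-score enrichment of a query gene set over an annotation table.

    ``annotation`` has columns term_id, term_name, genes (a set per row).
    Terms overlapping the query in at least ``min_count`` genes are scored;
    each result carries both the screening flag (``ease_p <= ease_max``) and
    the significance flag (``ease_p < alpha``).  Results are sorted by
    increasing EASE score, then decreasing gene count.
    """
    background = set(background)
    if not background:
        raise ValueError("empty background")
    query = set(query_genes) & background
    n = len(query)
    N = len(background)

    out = []
    for term_id, term_name, genes in zip(annotation["term_id"], annotation["term_name"], annotation["genes"]):
        term = set(genes) & background
        K = len(term)
        k = len(query & term)
        if k < min_count or K == 0:
            continue
        p = ease_score(k, n, K, N)
        out.append(
            EnrichmentResult(
                term_id=str(term_id),
                term_name=str(term_name),
                k=k,
                n=n,
                K=K,
                N=N,
                fraction=k / K,
                ease_p=p,
                passes_ease_max=bool(p <= ease_max),
                significant=bool(p < alpha),
            )
        )
    return sorted(out, key=lambda r: (r.ease_p, -r.k, r.term_id))


# ---------------------------------------------------------------------------
# bundled reference tables


def _data_path(name: str):
    return resources.files("cndiff").joinpath("data", name)


def load_bundled_cytobands() -> pd.DataFrame:
    """The package's synthetic ideogram (autosomes, UCSC cytoBand dialect)."""
    with resources.as_file(_data_path("cytobands_synthetic.txt")) as p:
        return read_cytoband_table(p)


def load_bundled_catalog(platform: str, bands: pd.DataFrame | None = None) -> RegionCatalog:
    """Bundled differential-region catalog: ``"bac"`` or ``"oligo"``."""
    if platform not in {"bac", "oligo"}:
        raise ValueError("platform must be 'bac' or 'oligo'")
    if bands is None:
        bands = load_bundled_cytobands()
    with resources.as_file(_data_path(f"{platform}_catalog.tsv")) as p:
        frame = read_region_catalog(p)
    return RegionCatalog.from_frame(platform, frame, bands)
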