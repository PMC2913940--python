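"""Gain/loss calling of segments and projection onto a fixed 5 Mb grid.

A sample's segments are classified against that sample's own distribution of
segment means: writing ``mu`` and ``sigma`` for the unweighted mean and sample
(n-1) standard deviation of the segment means, a segment is a *gain* when its
mean strictly exceeds ``mu + multiplier*sigma``, a *loss* when it is strictly
below ``mu - multiplier*sigma``, and *normal* otherwise.  Sparse platforms are
then summarized on a fixed-width genomic grid (5 Mb by default): each grid
region takes, per sample, the state class covering the largest bp extent of
the region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import chrom_sort_key
from .segmentation import Segment

log = logging.getLogger(__name__)

__all__ = [
    "SegmentCallSet",
    "call_segments",
    "build_region_grid",
    "project_calls_to_regions",
    "STATES",
]

STATES = ("gain", "normal", "loss")
DEFAULT_REGION_WIDTH = 5_000_000


@dataclass
class SegmentCallSet:
    """Called segments plus the per-sample thresholds that produced them.

    ``segments`` columns: sample_id, chrom, start, end, mean, n_probes, state.
    ``stats`` maps sample_id -> (mu, sigma) over that sample's segment means
    (sigma is NaN when degenerate).
    """

    segments: pd.DataFrame
    stats: dict[str, tuple[float, float]]

    def __eq__(self, other):
        if not isinstance(other, SegmentCallSet):
            return NotImplemented
        if set(self.stats) != set(other.stats):
            return False
        for s in self.stats:
            a, b = self.stats[s], other.stats[s]
            if not (np.allclose(a, b, equal_nan=True)):
                return False
        cols = ["sample_id", "chrom", "start", "end", "mean", "n_probes", "state"]
        da = self.segments[cols].reset_index(drop=True) if len(self.segments) else self.segments
        db = other.segments[cols].reset_index(drop=True) if len(other.segments) else other.segments
        if len(da) != len(db):
            return False
        if len(da) == 0:
            return True
        return da.equals(db)


def _segments_frame(segments) -> pd.DataFrame:
    if isinstance(segments, pd.DataFrame):
        return segments.copy()
    rows = [
        (s.sample_id, s.chrom, s.start, s.end, s.mean, s.n_probes)
        for s in segments
    ]
    return pd.DataFrame(rows, columns=["sample_id", "chrom", "start", "end", "mean", "n_probes"])


def call_segments(segments, multiplier: float = 2.0) -> SegmentCallSet:
    """Classify segments as gain/normal/loss by the per-sample mean +/- k*SD rule.

    ``segments`` is a list of :class:`~cndiff.segmentation.Segment` (one or
    more samples).  mu and sigma are computed over the sample's segment means
    with every segment weighted equally and an n-1 denominator.  A sample with
    fewer than 3 segments has a degenerate spread estimate: all its segments
    are called normal and a warning is logged.
    """
    df = _segments_frame(segments)
    if len(df) == 0:
        raise ValueError("no segments to call")
    stats: dict[str, tuple[float, float]] = {}
    states = np.full(len(df), "normal", dtype=object)
    for sample, idx in df.groupby("sample_id", sort=False).indices.items():
        means = df["mean"].to_numpy()[idx]
        mu = float(means.mean())
        if len(means) < 3:
            log.warning("sample %s has %d segments; spread degenerate, all called normal", sample, len(means))
            stats[str(sample)] = (mu, float("nan"))
            continue
        sigma = float(means.std(ddof=1))
        stats[str(sample)] = (mu, sigma)
        states[idx[means > mu + multiplier * sigma]] = "gain"
        states[idx[means < mu - multiplier * sigma]] = "loss"
    df["state"] = states
    return SegmentCallSet(segments=df, stats=stats)


def build_region_grid(chrom_lengths: pd.DataFrame, width: int = DEFAULT_REGION_WIDTH) -> pd.DataFrame:
    """Tile every chromosome with fixed-width regions (last one truncated).

    Returns a frame with columns region_id, chrom, start, end; region ids
    encode chromosome and ordinal (``chr3:7``).  The grid restarts at each
    chromosome, so no region spans a chromosome boundary.
    """
    if width <= 0:
        raise ValueError("region width must be positive")
    rows = []
    lengths = chrom_lengths.sort_values("chrom", key=lambda s: s.map(chrom_sort_key))
    for chrom, length in zip(lengths["chrom"], lengths["length"]):
        n = int(np.ceil(length / width))
        for k in range(n):
            rows.append((f"{chrom}:{k}", chrom, k * width, min((k + 1) * width, int(length))))
    grid = pd.DataFrame(rows, columns=["region_id", "chrom", "start", "end"])
    assert (grid["end"] > grid["start"]).all()
    assert int((grid["end"] - grid["start"]).sum()) == int(lengths["length"].sum())
    return grid


def project_calls_to_regions(callset: SegmentCallSet, grid: pd.DataFrame) -> pd.DataFrame:
    """Region x sample state matrix by majority-bp overlap.

    Per (region, sample), bp overlap is accumulated per state class; the
    class with the largest extent wins.  A tie between normal and a
    non-normal class goes to the non-normal class; a gain/loss tie goes to
    the class whose overlapping segment deviates more from the sample's mu.
    Regions with no overlapping segment are ``no_data``.
    """
    samples = list(callset.stats)
    out = pd.DataFrame("no_data", index=grid["region_id"], columns=samples, dtype=object)

    seg = callset.segments
    for sample in samples:
        mu = callset.stats[sample][0]
        sub = seg[seg["sample_id"] == sample]
        for chrom, chrom_seg in sub.groupby("chrom", sort=False):
            g = grid[grid["chrom"] == chrom]
            if len(g) == 0:
                continue
            s_start = chrom_seg["start"].to_numpy()
            s_end = chrom_seg["end"].to_numpy()
            s_state = chrom_seg["state"].to_numpy()
            s_dev = np.abs(chrom_seg["mean"].to_numpy() - mu)
            for rid, r_start, r_end in zip(g["region_id"], g["start"], g["end"]):
                ov = np.minimum(s_end, r_end) - np.maximum(s_start, r_start)
                hit = ov > 0
                if not hit.any():
                    continue
                bp = {st: 0 for st in STATES}
                dev = {st: -1.0 for st in STATES}
                for o, st, d in zip(ov[hit], s_state[hit], s_dev[hit]):
                    bp[st] += int(o)
                    dev[st] = max(dev[st], float(d))
                top = max(bp.values())
                tied = [st for st in STATES if bp[st] == top]
                if len(tied) == 1:
                    out.loc[rid, sample] = tied[0]
                    continue
                non_normal = [st for st in tied if st != "normal"]
                if len(non_normal) == 1:
                    out.loc[rid, sample] = non_normal[0]
                else:  # gain vs loss: larger deviation from mu wins
                    out.loc[rid, sample] = max(non_normal, key=lambda st: dev[st])
    return out
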