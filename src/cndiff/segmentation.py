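"""Circular binary segmentation (CBS) of single-sample log2-ratio profiles.

CBS treats each chromosome's ordered probe values as a circle, finds the arc
whose mean differs most from its complement (a two-sample t-like statistic
pooled over both pieces), and accepts the split when a permutation test on the
maximal statistic is significant.  Accepted splits are applied recursively
until no piece can be split further; the emitted pieces are the segments of
homogeneous copy number.

The scan is exact (all arcs are evaluated, via prefix sums), not a heuristic:
for an n-probe chromosome every arc ``[i, j)`` with arc and complement each at
least ``min_width`` probes long is considered.  Wrap-around arcs need no
special handling because the complement of a linear arc is exactly the
wrapped arc with the same statistic magnitude.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_formats import CopyNumberProfile, ProbeMap

log = logging.getLogger(__name__)

__all__ = ["Segment", "CbsParams", "max_arc_statistic", "permutation_pvalue", "cbs_segment"]

_TIE_RTOL = 1e-10  # relative |T| tolerance for arc tie-breaking


@dataclass(frozen=True)
class Segment:
    """A maximal run of probes with homogeneous mean in one sample.

    ``start_idx``/``end_idx`` index the chromosome's non-missing probes
    (0-based half-open); ``start``/``end`` are the 0-based half-open bp span
    from the first to the last member probe position.
    """

    sample_id: str
    chrom: str
    start_idx: int
    end_idx: int
    start: int
    end: int
    mean: float
    n_probes: int


@dataclass(frozen=True)
class CbsParams:
    """Tuning constants for the segmentation.

    alpha      significance level for accepting a split
    n_perm     permutations for the max-statistic null
    min_width  minimum probes in any arc or complement
    seed       base seed for the permutation stream
    """

    alpha: float = 0.01
    n_perm: int = 1000
    min_width: int = 2
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_perm < 100:
            raise ValueError("n_perm must be at least 100")
        if self.min_width < 2:
            raise ValueError("min_width must be at least 2")


def _arc_scan(X: np.ndarray, min_width: int):
    """Maximal |T| arc per row of ``X``.

    Returns ``(i, j, t, abs_t)`` arrays, one entry per row, where ``[i, j)``
    is the maximizing arc and ``t`` the signed statistic.  Ties are broken by
    smallest ``i``, then smallest ``j``.  Rows shorter than ``2*min_width``
    are rejected by the caller.
    """
    X = np.asarray(X, dtype=float)
    R, n = X.shape
    zeros = np.zeros((R, 1))
    S = np.concatenate([zeros, np.cumsum(X, axis=1)], axis=1)
    Q = np.concatenate([zeros, np.cumsum(X * X, axis=1)], axis=1)
    tot = S[:, -1]
    totq = Q[:, -1]

    best = np.full(R, -1.0)
    best_i = np.zeros(R, dtype=np.int64)
    best_j = np.zeros(R, dtype=np.int64)
    best_t = np.zeros(R)

    rows = np.arange(R)
    for k in range(min_width, n - min_width + 1):
        s1 = S[:, k:] - S[:, :-k]  # arc sums for i = 0 .. n-k
        q1 = Q[:, k:] - Q[:, :-k]
        m1 = s1 / k
        m0 = (tot[:, None] - s1) / (n - k)
        ss = q1 - k * m1 * m1 + (totq[:, None] - q1) - (n - k) * m0 * m0
        np.clip(ss, 0.0, None, out=ss)  # guard tiny negative round-off
        diff = m1 - m0
        with np.errstate(divide="ignore", invalid="ignore"):
            denom = np.sqrt(ss / (n - 2) * (1.0 / k + 1.0 / (n - k)))
            t = diff / denom
            t = np.where(denom > 0, t, np.where(diff != 0, np.sign(diff) * np.inf, 0.0))
        abs_t = np.abs(t)
        # smallest i attaining the row max up to the tie tolerance
        thresh = abs_t.max(axis=1, keepdims=True) * (1 - _TIE_RTOL)
        idx = np.argmax(abs_t >= thresh, axis=1)
        cand = abs_t[rows, idx]
        # an arc and its complement carry the same |T| up to round-off, so
        # ties are judged with a relative tolerance before the (i, j) rule
        with np.errstate(invalid="ignore"):
            better = cand > best * (1 + _TIE_RTOL)
            tied = ~better & (cand >= best * (1 - _TIE_RTOL))
        tied &= (idx < best_i) | ((idx == best_i) & (idx + k < best_j))
        upd = better | tied
        best = np.where(upd, cand, best)
        best_i = np.where(upd, idx, best_i)
        best_j = np.where(upd, idx + k, best_j)
        best_t = np.where(upd, t[rows, idx], best_t)
    return best_i, best_j, best_t, best


def max_arc_statistic(x, min_width: int = 2):
    """Scan all arcs of the circularized vector for the maximal-|T| split.

    Returns ``(i, j, t)`` where ``x[i:j]`` is the maximizing arc and ``t`` the
    signed pooled two-sample statistic between arc and complement, or ``None``
    when the vector is too short to admit any split.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-d vector")
    if not np.isfinite(x).all():
        raise ValueError("non-finite value in segmentation input")
    if len(x) < 2 * min_width:
        return None
    i, j, t, _ = _arc_scan(x[None, :], min_width)
    return int(i[0]), int(j[0]), float(t[0])


def permutation_pvalue(x, t_obs: float, params: CbsParams, rng=None) -> float:
    """Permutation p-value of the maximal arc statistic.

    ``p = (1 + #{permutations whose max |T| >= |t_obs|}) / (n_perm + 1)`` under
    uniform shuffles of ``x``.  Deterministic for a fixed ``params.seed``; an
    explicit ``rng`` may be supplied by recursive callers to continue one
    reproducible stream.
    """
    x = np.asarray(x, dtype=float)
    if rng is None:
        rng = np.random.default_rng(params.seed)
    perms = rng.permuted(np.broadcast_to(x, (params.n_perm, len(x))), axis=1)
    _, _, _, max_abs = _arc_scan(perms, params.min_width)
    exceed = int(np.count_nonzero(max_abs >= abs(t_obs)))
    return (1 + exceed) / (params.n_perm + 1)


def cbs_segment(profile: CopyNumberProfile, probe_map: ProbeMap, params: CbsParams | None = None) -> list[Segment]:
    """Segment one profile chromosome-by-chromosome into homogeneous pieces.

    Missing probes are excluded before segmentation; a segment's ``n_probes``
    counts non-missing member probes only.  Chromosomes with no usable probe
    produce no segments (logged).  Output segments per chromosome are sorted,
    non-overlapping, and jointly cover every non-missing probe.
    """
    if params is None:
        params = CbsParams()
    if len(profile.values) != len(probe_map):
        raise ValueError("profile not aligned to probe map")
    rng = np.random.default_rng(params.seed)
    segments: list[Segment] = []

    for chrom, sl in probe_map.chrom_index().items():
        vals = profile.values[sl]
        pos = np.asarray(probe_map.position[sl])
        keep = np.isfinite(vals)
        if not keep.any():
            log.warning("sample %s: chromosome %s entirely missing; skipped", profile.sample_id, chrom)
            continue
        v = vals[keep]
        p = pos[keep]

        out: list[tuple[int, int]] = []
        stack = [(0, len(v))]
        while stack:
            lo, hi = stack.pop()
            res = max_arc_statistic(v[lo:hi], params.min_width) if hi - lo >= 2 * params.min_width else None
            split = False
            if res is not None:
                i, j, t = res
                pval = permutation_pvalue(v[lo:hi], t, params, rng=rng)
                if pval < params.alpha:
                    cuts = sorted(c for c in (lo + i, lo + j) if lo < c < hi)
                    pieces = [lo, *cuts, hi]
                    # depth-first, left-to-right emission order
                    for a, b in zip(reversed(pieces[:-1]), reversed(pieces[1:])):
                        stack.append((a, b))
                    split = True
            if not split:
                out.append((lo, hi))
        out.sort()
        for lo, hi in out:
            member = v[lo:hi]
            segments.append(
                Segment(
                    sample_id=profile.sample_id,
                    chrom=chrom,
                    start_idx=lo,
                    end_idx=hi,
                    start=int(p[lo]) - 1,
                    end=int(p[hi - 1]),
                    mean=float(member.mean()),
                    n_probes=hi - lo,
                )
            )
    return segments
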