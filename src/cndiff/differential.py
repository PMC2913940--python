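"""Cross-cohort testing of regional copy-number states.

For every grid region a 3x2 contingency table is formed (rows: patients with
gain / normal / loss in that region; columns: the two cohorts) and tested
with an exact conditional test: the p-value is the total multivariate
hypergeometric probability, over all tables with the observed margins, of
tables no more probable than the one observed.  Samples with no data in a
region drop out of that region's table.  P-values are deliberately not
adjusted for multiplicity in the screening workflow; downstream filtering is
by the stated thresholds.

Two screening conventions are provided: a small-cohort workflow that keeps
regions at p < 0.05 with a qualitative direction class, and a large-cohort
workflow that first requires alteration in a minimum fraction of samples and
then flags regions at p <= 1e-4 after ranking by p.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "RegionTestResult",
    "fisher_exact_3x2",
    "test_all_regions",
    "select_noteworthy",
    "classify_direction",
    "oligo_workflow",
    "results_to_frame",
]

_TIE_RTOL = 1e-7


@dataclass(frozen=True)
class RegionTestResult:
    """Exact-test summary for one region.

    ``counts`` is the 3x2 table with rows (gain, normal, loss) and columns
    (group A, group B); ``alt_freq_*`` are the non-normal fractions among the
    samples counted for that group.
    """

    region_id: str
    counts: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
    p: float
    alt_freq_a: float
    alt_freq_b: float
    direction: str = "none"
    significant: bool | None = None


def fisher_exact_3x2(table) -> float:
    """Two-sided exact conditional p-value for a 3x2 contingency table.

    The null distribution is multivariate hypergeometric on tables with the
    observed row and column margins; the p-value sums the probability of all
    tables whose probability is at most that of the observed table (relative
    tie tolerance 1e-7).  Enumeration is over the two free cells of the first
    column, so the cost is quadratic in the first column's sum.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (3, 2):
        raise ValueError("expected a 3x2 table")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    r = t.sum(axis=1)
    c = t.sum(axis=0)
    if (c == 0).any():
        raise ValueError("both column sums must be positive")
    n_tot = int(t.sum())

    # log P(a, b) for first-column cells a (gain) and b (loss); the rest of
    # the table is determined by the margins.
    a = np.arange(min(r[0], c[0]) + 1)
    b = np.arange(min(r[2], c[0]) + 1)
    A, B = np.meshgrid(a, b, indexing="ij")
    n10 = c[0] - A - B
    valid = (n10 >= 0) & (n10 <= r[1])
    const = gammaln(r + 1).sum() + gammaln(c + 1).sum() - gammaln(n_tot + 1)
    with np.errstate(invalid="ignore"):
        logp = (
            const
            - gammaln(A + 1)
            - gammaln(B + 1)
            - gammaln(n10 + 1)
            - gammaln(r[0] - A + 1)
            - gammaln(r[2] - B + 1)
            - gammaln(r[1] - n10 + 1)
        )
    logp = np.where(valid, logp, -np.inf)
    logp_obs = logp[t[0, 0], t[2, 0]]
    keep = (logp <= logp_obs + np.log1p(_TIE_RTOL)) & valid
    # normalize by the total enumerated mass so round-off cannot push the
    # all-tables case away from exactly 1
    p = float(np.exp(logp[keep]).sum() / np.exp(logp[valid]).sum())
    return min(p, 1.0)


def _region_counts(states: pd.Series, groups: pd.Series, group_labels) -> np.ndarray:
    counts = np.zeros((3, 2), dtype=np.int64)
    state_row = {"gain": 0, "normal": 1, "loss": 2}
    for sample, state in states.items():
        if state == "no_data":
            continue
        col = 0 if groups[sample] == group_labels[0] else 1
        counts[state_row[state], col] += 1
    return counts


def test_all_regions(matrix: pd.DataFrame, cohort: pd.DataFrame, group_labels=("AA", "CA")) -> list[RegionTestResult]:
    """One exact test per grid region; ``no_data`` samples drop per region.

    ``matrix`` is region x sample states, ``cohort`` carries sample_id and
    group.  P-values are not multiplicity-adjusted.
    """
    groups = cohort.set_index("sample_id")["group"]
    missing = [s for s in matrix.columns if s not in groups.index]
    if missing:
        raise ValueError(f"samples absent from cohort table: {missing[:3]}")
    present = set(groups[matrix.columns])
    for lab in group_labels:
        if lab not in present:
            raise ValueError(f"group {lab!r} has no samples in the matrix")

    results = []
    for rid, states in matrix.iterrows():
        counts = _region_counts(states, groups, group_labels)
        col = counts.sum(axis=0)
        if (col == 0).any():
            # every counted sample fell in one group; no contrast possible
            p = 1.0
        else:
            p = fisher_exact_3x2(counts)
        alt = counts[0] + counts[2]
        with np.errstate(invalid="ignore"):
            fa = float(alt[0] / col[0]) if col[0] else 0.0
            fb = float(alt[1] / col[1]) if col[1] else 0.0
        res = RegionTestResult(
            region_id=str(rid),
            counts=tuple(tuple(int(x) for x in row) for row in counts),
            p=p,
            alt_freq_a=fa,
            alt_freq_b=fb,
        )
        results.append(replace(res, direction=classify_direction(res)))
    return results


def select_noteworthy(results, alpha: float = 0.05) -> list[RegionTestResult]:
    """Regions with p strictly below ``alpha``, sorted by increasing p."""
    if not results:
        raise ValueError("no results to select from")
    kept = [r for r in results if r.p < alpha]
    return sorted(kept, key=lambda r: (r.p, r.region_id))


def classify_direction(result: RegionTestResult, ratio: float = 2.0, floor: float = 0.15) -> str:
    """Qualitative direction of a differential region.

    If one group's alteration frequency is at least ``ratio`` times the
    other's, the region is labelled for that group (``A_more``/``B_more``).
    Otherwise, if both frequencies reach ``floor`` and the two groups'
    dominant non-normal states differ (gain in one, loss in the other), the
    region is ``both_diff_dir``.  Otherwise the higher-frequency group wins;
    exactly equal frequencies give ``none``.
    """
    fa, fb = result.alt_freq_a, result.alt_freq_b
    counts = np.asarray(result.counts)
    if fa == 0.0 and fb == 0.0:
        return "none"
    if fa >= ratio * fb and fa > fb:
        return "A_more"
    if fb >= ratio * fa and fb > fa:
        return "B_more"

    def dominant(col):
        gain, loss = counts[0, col], counts[2, col]
        if gain == loss:
            return None
        return "gain" if gain > loss else "loss"

    da, db = dominant(0), dominant(1)
    if fa >= floor and fb >= floor and da is not None and db is not None and da != db:
        return "both_diff_dir"
    if fa > fb:
        return "A_more"
    if fb > fa:
        return "B_more"
    return "none"


def oligo_workflow(
    matrix: pd.DataFrame,
    cohort: pd.DataFrame,
    min_frac: float = 0.10,
    p_max: float = 1e-4,
    min_frac_scope: str = "pooled",
    group_labels=("AA", "CA"),
) -> list[RegionTestResult]:
    """Dense-platform screen: alteration-frequency filter, then p-ranking.

    Regions altered (gain or loss) in at least ``min_frac`` of the samples
    are tested and returned ranked by increasing p; results with
    p <= ``p_max`` (inclusive) carry ``significant=True``.  ``min_frac_scope``
    chooses how the filter fraction is computed: over the pooled samples
    (``"pooled"``), requiring the threshold in each group (``"each"``), or in
    at least one group (``"either"``).
    """
    if min_frac_scope not in {"pooled", "each", "either"}:
        raise ValueError("min_frac_scope must be pooled, each or either")
    groups = cohort.set_index("sample_id")["group"]

    keep_rows = []
    for rid, states in matrix.iterrows():
        counted = states[states != "no_data"]
        if len(counted) == 0:
            continue
        altered = counted.isin(["gain", "loss"])
        if min_frac_scope == "pooled":
            ok = altered.mean() >= min_frac
        else:
            fracs = []
            for lab in group_labels:
                sub = altered[groups[counted.index] == lab]
                fracs.append(sub.mean() if len(sub) else 0.0)
            ok = all(f >= min_frac for f in fracs) if min_frac_scope == "each" else any(
                f >= min_frac for f in fracs
            )
        if ok:
            keep_rows.append(rid)

    results = test_all_regions(matrix.loc[keep_rows], cohort, group_labels) if keep_rows else []
    results = sorted(results, key=lambda r: (r.p, r.region_id))
    return [replace(r, significant=bool(r.p <= p_max)) for r in results]


def results_to_frame(results) -> pd.DataFrame:
    """Flatten test results into a tab-friendly table."""
    rows = []
    for r in results:
        (ga, gb), (na, nb), (la, lb) = r.counts
        rows.append(
            {
                "region_id": r.region_id,
                "gain_a": ga,
                "normal_a": na,
                "loss_a": la,
                "gain_b": gb,
                "normal_b": nb,
                "loss_b": lb,
                "p": r.p,
                "alt_freq_a": r.alt_freq_a,
                "alt_freq_b": r.alt_freq_b,
                "direction": r.direction,
                "significant": r.significant,
            }
        )
    return pd.DataFrame(rows)
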