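"""End-to-end composition: segment -> call -> grid -> cross-cohort test."""

from __future__ import annotations

import pandas as pd

from .calling import DEFAULT_REGION_WIDTH, build_region_grid, call_segments, project_calls_to_regions
from .differential import RegionTestResult, oligo_workflow, test_all_regions
from .segmentation import CbsParams, cbs_segment


def region_call_matrix(
    probe_map,
    profiles,
    chrom_lengths: pd.DataFrame,
    params: CbsParams | None = None,
    multiplier: float = 2.0,
    region_width: int = DEFAULT_REGION_WIDTH,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Segment every profile, call gains/losses, and project onto the grid.

    Returns ``(grid, matrix)``.  Each profile gets its own permutation
    substream derived from ``params.seed`` and its index, so the result does
    not depend on processing order.
    """
    if params is None:
        params = CbsParams()
    segments = []
    for i, profile in enumerate(profiles):
        sub = CbsParams(
            alpha=params.alpha,
            n_perm=params.n_perm,
            min_width=params.min_width,
            seed=(params.seed * 1_000_003 + i) % (2**31),
        )
        segments.extend(cbs_segment(profile, probe_map, sub))
    callset = call_segments(segments, multiplier=multiplier)
    grid = build_region_grid(chrom_lengths, width=region_width)
    return grid, project_calls_to_regions(callset, grid)


def differential_pipeline(
    probe_map,
    profiles,
    cohort: pd.DataFrame,
    chrom_lengths: pd.DataFrame,
    params: CbsParams | None = None,
    mode: str = "bac",
    multiplier: float = 2.0,
    region_width: int = DEFAULT_REGION_WIDTH,
    **mode_kwargs,
) -> tuple[pd.DataFrame, list[RegionTestResult]]:
    """Full per-region cross-cohort analysis from raw profiles.

    ``mode="bac"`` runs the unfiltered per-region tests (screen afterwards
    with :func:`~cndiff.differential.select_noteworthy`); ``mode="oligo"``
    applies the alteration-frequency filter and p-ranking.
    """
    grid, matrix = region_call_matrix(
        probe_map, profiles, chrom_lengths, params=params, multiplier=multiplier, region_width=region_width
    )
    if mode == "bac":
        results = test_all_regions(matrix, cohort, **mode_kwargs)
    elif mode == "oligo":
        results = oligo_workflow(matrix, cohort, **mode_kwargs)
    else:
        raise ValueError("mode must be 'bac' or 'oligo'")
    return matrix, results
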