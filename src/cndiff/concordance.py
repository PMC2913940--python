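"""DNA-RNA dosage concordance and sample clustering.

Within each differential region, each gene's normalized expression is
compared between the samples of one cohort that carry a copy-number gain in
the region and those with normal copy number (and likewise loss vs normal),
with a two-sample t-test per (gene, cohort, contrast) and false-discovery
adjustment across all tests.  Sample-level structure is summarized by
average-linkage hierarchical clustering under a correlation distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

__all__ = [
    "ConcordanceResult",
    "expression_by_cn_ttest",
    "adjust_pvalues",
    "hierarchical_cluster",
    "region_expression_heatmap_table",
    "concordance_to_frame",
]

CONTRASTS = {"gain_vs_normal": "gain", "loss_vs_normal": "loss"}


@dataclass(frozen=True)
class ConcordanceResult:
    gene_id: str
    region_id: str
    group: str
    contrast: str
    n_alt: int
    n_normal: int
    t: float
    p: float
    p_adj: float = float("nan")
    significant: bool = False


def _map_genes_to_regions(annotation: pd.DataFrame, grid: pd.DataFrame) -> dict[str, list[str]]:
    """region_id -> gene ids whose midpoint falls inside the region."""
    out: dict[str, list[str]] = {}
    mid = (annotation["start"].to_numpy() + annotation["end"].to_numpy()) // 2
    for gene, chrom, m in zip(annotation["gene_id"], annotation["chrom"], mid):
        g = grid[(grid["chrom"] == chrom) & (grid["start"] <= m) & (m < grid["end"])]
        if len(g) == 0:
            log.warning("gene %s midpoint outside every grid region; excluded", gene)
            continue
        out.setdefault(g["region_id"].iloc[0], []).append(gene)
    return out


def expression_by_cn_ttest(
    expr: pd.DataFrame,
    annotation: pd.DataFrame,
    calls: pd.DataFrame,
    regions,
    cohort: pd.DataFrame,
    grid: pd.DataFrame,
    group_labels=("AA", "CA"),
    equal_var: bool = True,
    alpha: float = 0.05,
    adjust_method: str = "BH",
) -> list[ConcordanceResult]:
    """Per-gene altered-vs-normal expression tests within differential regions.

    ``regions`` is the list of region ids to interrogate; genes are assigned
    to the region containing their midpoint.  For each cohort separately, the
    gain carriers are compared with copy-neutral samples (and loss carriers
    likewise); a contrast is skipped when either arm has fewer than two
    samples.  P-values are adjusted jointly across every test performed.
    """
    groups = cohort.set_index("sample_id")["group"]
    gene_map = _map_genes_to_regions(annotation, grid)
    region_ids = [r for r in regions if r in gene_map]

    results: list[ConcordanceResult] = []
    for rid in region_ids:
        states = calls.loc[rid]
        for lab in group_labels:
            members = [s for s in expr.columns if s in groups.index and groups[s] == lab and s in states.index]
            member_states = states[members]
            normal_arm = [s for s in members if member_states[s] == "normal"]
            for contrast, alt_state in CONTRASTS.items():
                alt_arm = [s for s in members if member_states[s] == alt_state]
                if len(alt_arm) < 2 or len(normal_arm) < 2:
                    continue
                for gene in gene_map[rid]:
                    x = expr.loc[gene, alt_arm].to_numpy(dtype=float)
                    y = expr.loc[gene, normal_arm].to_numpy(dtype=float)
                    t, p = sstats.ttest_ind(x, y, equal_var=equal_var)
                    results.append(
                        ConcordanceResult(
                            gene_id=str(gene),
                            region_id=str(rid),
                            group=lab,
                            contrast=contrast,
                            n_alt=len(alt_arm),
                            n_normal=len(normal_arm),
                            t=float(t),
                            p=float(p),
                        )
                    )
    if not results:
        return results
    adj = adjust_pvalues(np.array([r.p for r in results]), method=adjust_method)
    return [
        ConcordanceResult(
            r.gene_id, r.region_id, r.group, r.contrast, r.n_alt, r.n_normal, r.t, r.p,
            p_adj=float(a), significant=bool(a < alpha),
        )
        for r, a in zip(results, adj)
    ]


def adjust_pvalues(p, method: str = "BH") -> np.ndarray:
    """Multiple-testing adjustment, order-preserving with the input.

    ``method`` is one of BH (Benjamini-Hochberg step-up, the default),
    bonferroni, or holm.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    key = {"bh": "fdr_bh", "fdr_bh": "fdr_bh", "bonferroni": "bonferroni", "holm": "holm"}[method.lower()]
    return multipletests(p, method=key)[1]


def hierarchical_cluster(expr: pd.DataFrame, cohort: pd.DataFrame, linkage: str = "average"):
    """Cluster samples by 1 - Pearson correlation and cut into two clusters.

    Returns ``(linkage_matrix, labels, misclassified)`` where ``labels`` maps
    sample id -> cluster (1 or 2) and ``misclassified`` counts the samples on
    the wrong side under the better of the two cluster-to-group assignments.
    Zero-variance samples (undefined correlation) are dropped with a warning.
    """
    if expr.shape[0] < 2 or expr.shape[1] < 2:
        raise ValueError("need at least two genes and two samples")
    X = expr.to_numpy(dtype=float).T  # samples x genes
    sd = X.std(axis=1)
    keep = sd > 0
    if not keep.all():
        dropped = list(expr.columns[~keep])
        log.warning("dropping zero-variance samples: %s", dropped)
    X = X[keep]
    samples = list(expr.columns[keep])
    corr = np.corrcoef(X)
    dist = np.clip(1.0 - corr, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method=linkage)
    cut = hierarchy.fcluster(Z, t=2, criterion="maxclust")
    labels = dict(zip(samples, (int(c) for c in cut)))

    groups = cohort.set_index("sample_id")["group"]
    glabs = sorted(set(groups[s] for s in samples))
    agree = 0
    if len(glabs) == 2:
        a, b = glabs
        match1 = sum((labels[s] == 1) == (groups[s] == a) for s in samples)
        agree = max(match1, len(samples) - match1)
    else:
        agree = len(samples)
    return Z, labels, len(samples) - agree


def region_expression_heatmap_table(
    expr: pd.DataFrame,
    annotation: pd.DataFrame,
    calls: pd.DataFrame,
    region_id: str,
    grid: pd.DataFrame,
):
    """Gene x sample expression block for one region, clustered for display.

    Values are the input expression values unchanged; rows and columns are
    reordered by average-linkage correlation clustering (when at least two of
    each), and the per-sample copy-number state of the region is returned as
    an annotation series aligned to the column order.
    """
    gene_map = _map_genes_to_regions(annotation, grid)
    genes = gene_map.get(region_id, [])
    if not genes:
        raise ValueError(f"region {region_id} contains no annotated gene")
    block = expr.loc[genes]
    block = block.loc[:, [s for s in block.columns if s in calls.columns]]

    def _order(mat: np.ndarray) -> np.ndarray:
        if mat.shape[0] < 2:
            return np.arange(mat.shape[0])
        sd = mat.std(axis=1)
        if (sd == 0).any():
            d = np.array([[np.linalg.norm(u - v) for v in mat] for u in mat])
        else:
            d = np.clip(1.0 - np.corrcoef(mat), 0.0, None)
        np.fill_diagonal(d, 0.0)
        Z = hierarchy.linkage(squareform(d, checks=False), method="average")
        return np.asarray(hierarchy.leaves_list(Z))

    block = block.iloc[_order(block.to_numpy(dtype=float))]
    block = block.iloc[:, _order(block.to_numpy(dtype=float).T)]
    states = calls.loc[region_id, block.columns]
    return block, states


def concordance_to_frame(results) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
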