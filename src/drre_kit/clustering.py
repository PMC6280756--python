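"""Sliding-window hypergeometric detection of coexpressed gene clusters.

Chromosomes are tiled with windows of 30 kb advanced by 10 kb.  A window
holding n genes of which k belong to the differentially expressed set (K DE
genes among N genes genome-wide) is scored with the hypergeometric upper
tail P(X >= k).  Windows with k >= 3 and p <= 0.05 surviving
Benjamini-Hochberg correction (applied over all tested windows, per
direction) merge into clusters whose interval spans the member DE genes.
Hotspots are groups of >= 2 clusters whose starts fall within a 1 Mb
window; no p-value is involved at that level.

Gene membership in a window is decided by the TSS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionMatrix, coregulation
from .genes import GeneModel
from .intervals import GenomicInterval

__all__ = ["GeneCluster", "Hotspot", "find_clusters", "find_hotspots",
           "cluster_coregulation", "gene_positions"]


@dataclass(frozen=True)
class GeneCluster:
    cluster_id: str
    interval: GenomicInterval
    members: Tuple[str, ...]   # DE gene ids, sorted by TSS position
    direction: str
    p_value: float
    q_value: float


@dataclass(frozen=True)
class Hotspot:
    interval: GenomicInterval
    cluster_ids: Tuple[str, ...]


def gene_positions(genes: Iterable[GeneModel]) -> pd.DataFrame:
    """gene_id / chrom / tss table from gene models."""
    rows = [(g.gene_id, g.chrom, g.tss) for g in genes]
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "tss"])


def window_pvalue(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric probability of >= k DE genes in a window.

    N genes genome-wide, K of them DE, n genes in the window, k of those DE.
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError("inconsistent hypergeometric counts")
    return float(hypergeom.sf(k - 1, N, K, n))


def find_clusters(
    genes: pd.DataFrame,
    de_set: Set[str],
    direction: str,
    window: int = 30_000,
    offset: int = 10_000,
    min_genes: int = 3,
    alpha: float = 0.05,
) -> List[GeneCluster]:
    """Chromosomal clusters of DE genes.

    ``genes`` is a gene_id/chrom/tss table (see :func:`gene_positions`);
    ``de_set`` the DE gene ids for one direction at one timepoint.
    """
    if offset <= 0:
        raise ValueError("offset must be positive")
    if genes.empty or not de_set:
        return []
    unknown = de_set - set(genes.gene_id)
    if unknown:
        raise ValueError(f"DE genes missing from gene table: {sorted(unknown)[:5]}")

    N = len(genes)
    K = len(de_set)
    records = []  # (chrom, win_start, n, k, p)
    for chrom, sub in genes.groupby("chrom"):
        tss = np.sort(sub.tss.values)
        de_tss = np.sort(sub.loc[sub.gene_id.isin(de_set), "tss"].values)
        if len(tss) == 0:
            continue
        starts = np.arange(0, tss.max() + 1, offset)
        n = np.searchsorted(tss, starts + window, "left") - np.searchsorted(tss, starts, "left")
        k = (np.searchsorted(de_tss, starts + window, "left")
             - np.searchsorted(de_tss, starts, "left"))
        tested = n >= 1
        p = hypergeom.sf(k[tested] - 1, N, K, n[tested])
        for s, nn, kk, pp in zip(starts[tested], n[tested], k[tested], p):
            records.append((chrom, int(s), int(nn), int(kk), float(pp)))

    if not records:
        return []
    pvals = np.array([r[4] for r in records])
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")

    surviving: Dict[str, List[Tuple[GenomicInterval, float, float]]] = {}
    for (chrom, s, n, k, p), q in zip(records, qvals):
        if k >= min_genes and p <= alpha and q <= alpha:
            surviving.setdefault(chrom, []).append(
                (GenomicInterval(chrom, s, s + window), p, q)
            )

    clusters: List[GeneCluster] = []
    for chrom in sorted(surviving):
        wins = sorted(surviving[chrom], key=lambda t: t[0])
        # merge overlapping/book-ended significant windows
        groups: List[List[Tuple[GenomicInterval, float, float]]] = []
        for item in wins:
            if groups and item[0].start <= groups[-1][-1][0].end:
                groups[-1].append(item)
            else:
                groups.append([item])
        sub = genes[genes.chrom == chrom]
        de_sub = sub[sub.gene_id.isin(de_set)].sort_values("tss")
        for group in groups:
            lo = group[0][0].start
            hi = max(w[0].end for w in group)
            members = de_sub[(de_sub.tss >= lo) & (de_sub.tss < hi)]
            if members.empty:  # pragma: no cover - cannot happen with k >= 1
                continue
            interval = GenomicInterval(
                chrom, int(members.tss.min()), int(members.tss.max()) + 1
            )
            clusters.append(GeneCluster(
                cluster_id="",
                interval=interval,
                members=tuple(members.gene_id),
                direction=direction,
                p_value=min(w[1] for w in group),
                q_value=min(w[2] for w in group),
            ))
    clusters.sort(key=lambda c: c.interval)
    return [
        GeneCluster(f"{direction}_cluster_{i + 1:03d}", c.interval, c.members,
                    c.direction, c.p_value, c.q_value)
        for i, c in enumerate(clusters)
    ]


def find_hotspots(
    clusters: Sequence[GeneCluster],
    window: int = 1_000_000,
    min_clusters: int = 2,
) -> List[Hotspot]:
    """Maximal groups of clusters whose starts fall within one sliding window."""
    per_chrom: Dict[str, List[GeneCluster]] = {}
    for c in clusters:
        per_chrom.setdefault(c.interval.chrom, []).append(c)
    hotspots = []
    for chrom in sorted(per_chrom):
        cs = sorted(per_chrom[chrom], key=lambda c: c.interval.start)
        starts = np.array([c.interval.start for c in cs])
        in_group = np.zeros(len(cs), dtype=bool)
        for i in range(len(cs)):
            j = int(np.searchsorted(starts, starts[i] + window, "right"))
            if j - i >= min_clusters:
                in_group[i:j] = True
        # contiguous runs of flagged clusters form maximal hotspots
        i = 0
        while i < len(cs):
            if not in_group[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(cs) and in_group[j + 1] and \
                    starts[j + 1] - starts[j] <= window:
                j += 1
            members = cs[i:j + 1]
            hotspots.append(Hotspot(
                GenomicInterval(chrom,
                                members[0].interval.start,
                                max(m.interval.end for m in members)),
                tuple(m.cluster_id for m in members),
            ))
            i = j + 1
    return hotspots


def cluster_coregulation(
    cluster: GeneCluster,
    expr: ExpressionMatrix,
    condition: str = "regeneration",
    eps: float = 0.01,
) -> Dict[str, float]:
    """Pairwise Pearson r summary over the cluster's member gene pairs.

    Correlations are computed on log(FPKM + eps) over the timepoint means of
    ``condition``.  Pairs with undefined r (zero log-variance) are excluded.
    Returns mean_r, median_r and n_pairs.
    """
    means = expr.timepoint_means(condition)
    members = [g for g in cluster.members if g in means.index]
    if len(members) < 2:
        warnings.warn(f"{cluster.cluster_id}: fewer than 2 scorable members")
        return {"mean_r": float("nan"), "median_r": float("nan"), "n_pairs": 0}
    rs = []
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            r = coregulation(means.loc[members[i]].values,
                             means.loc[members[j]].values, eps)
            if not np.isnan(r):
                rs.append(r)
    if not rs:
        return {"mean_r": float("nan"), "median_r": float("nan"), "n_pairs": 0}
    return {
        "mean_r": float(np.mean(rs)),
        "median_r": float(np.median(rs)),
        "n_pairs": len(rs),
    }
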