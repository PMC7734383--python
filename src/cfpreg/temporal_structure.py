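"""Correlation structure of cfRNA trajectories across gestation.

Transcripts from one tissue of origin rise and fall together over
pregnancy, so their week-averaged trajectories are strongly correlated
within a tissue group and more weakly across groups. This module computes
pairwise Pearson correlations on per-gestational-week mean profiles
(antepartum only), summarises within-/cross-group medians, and produces a
deterministic gene ordering for heatmap display via average-linkage
clustering on the 1 - r distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .qpcr_io import ExpressionMatrix


@dataclass
class CorrelationResult:
    matrix: pd.DataFrame               # gene x gene Pearson r
    pvalues: pd.DataFrame              # gene x gene correlation p
    n_obs: pd.DataFrame                # aligned weeks per pair
    group_medians: dict[str, float] = field(default_factory=dict)
    cross_medians: dict[tuple[str, str], float] = field(default_factory=dict)


def weekly_profiles(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene mean log10 abundance per antepartum gestational week."""
    ante = ~matrix.sample_meta["postpartum_flag"].astype(bool)
    vals = matrix.values.loc[ante.values]
    week = np.floor(matrix.sample_meta.loc[ante.values, "ga_weeks"]).astype(int)
    return vals.groupby(week.values).mean()  # weeks x genes


def pairwise_pearson(matrix: ExpressionMatrix,
                     min_points: int = 3) -> CorrelationResult:
    """Pearson r for every gene pair on weekly mean profiles.

    Pairwise-complete over weeks; p-values from the exact t transform of r
    with n - 2 degrees of freedom. Pairs with a constant profile or fewer
    than ``min_points`` aligned weeks are reported missing (NaN), never 0.
    """
    prof = weekly_profiles(matrix)
    genes = list(prof.columns)
    k = len(genes)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    arr = prof.to_numpy()
    for i in range(k):
        r[i, i] = 1.0
        p[i, i] = 0.0
        n[i, i] = np.isfinite(arr[:, i]).sum()
        for j in range(i + 1, k):
            ok = np.isfinite(arr[:, i]) & np.isfinite(arr[:, j])
            m = int(ok.sum())
            n[i, j] = n[j, i] = m
            if m < min_points:
                continue
            x, y = arr[ok, i], arr[ok, j]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue  # undefined, stays NaN
            rij = float(np.corrcoef(x, y)[0, 1])
            rij = max(-1.0, min(1.0, rij))
            if abs(rij) == 1.0:
                pij = 0.0
            else:
                t = rij * np.sqrt((m - 2) / (1.0 - rij * rij))
                pij = 2.0 * stats.t.sf(abs(t), m - 2)
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    idx = pd.Index(genes, name="gene")
    return CorrelationResult(pd.DataFrame(r, index=idx, columns=idx),
                             pd.DataFrame(p, index=idx, columns=idx),
                             pd.DataFrame(n, index=idx, columns=idx))


def group_median_correlations(result: CorrelationResult,
                              gene_groups: dict[str, str]) -> CorrelationResult:
    """Fill within-group and cross-group median correlations.

    Within-group medians are over off-diagonal pairs of one group;
    cross medians over all pairs straddling two groups. Singleton groups
    yield NaN with a warning.
    """
    genes = list(result.matrix.index)
    groups = sorted({gene_groups.get(g, "other") for g in genes})
    members = {grp: [g for g in genes if gene_groups.get(g, "other") == grp]
               for grp in groups}
    rmat = result.matrix

    for grp, mem in members.items():
        if len(mem) < 2:
            warnings.warn(f"group {grp!r} has fewer than 2 genes; "
                          "within-group median undefined")
            result.group_medians[grp] = float("nan")
            continue
        sub = rmat.loc[mem, mem].to_numpy()
        off = sub[np.triu_indices(len(mem), k=1)]
        result.group_medians[grp] = float(np.nanmedian(off))

    for a_i, a in enumerate(groups):
        for b in groups[a_i + 1:]:
            if not members[a] or not members[b]:
                continue
            sub = rmat.loc[members[a], members[b]].to_numpy()
            result.cross_medians[(a, b)] = float(np.nanmedian(sub))
    return result


def cluster_order(result: CorrelationResult) -> list[str]:
    """Deterministic leaf order from average-linkage clustering on 1 - r.

    Genes are canonicalized to lexicographic order before linkage so the
    ordering is invariant to input column permutations; missing correlations
    are an error (impute or drop those genes first).
    """
    genes = sorted(result.matrix.index)
    rmat = result.matrix.loc[genes, genes].to_numpy()
    if np.isnan(rmat).any():
        raise ValueError("correlation matrix has missing entries; impute or "
                         "drop genes with undefined correlations first")
    dist = 1.0 - rmat
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    leaves = hierarchy.leaves_list(link)
    return [genes[i] for i in leaves]
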