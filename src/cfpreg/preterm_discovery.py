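"""Count-based differential-expression screen for preterm delivery.

Separates spontaneous-preterm from full-term cfRNA-seq libraries with two
tests run gene by gene and combined by intersection (a gene is significant
only if every test calls it at p < 0.001):

- a conditional negative-binomial exact test with common dispersion, applied
  after scaling libraries to a common size: conditional on a gene's total
  count, the group-1 subtotal follows a ratio of NB probability products,
  and the two-sided p doubles the smaller tail (capped at 1). With
  dispersion 0 this reduces exactly to the binomial split test.
- a seeded two-sided permutation test on the difference of group means of
  log2 CPM (distribution-free stand-in for a parametric second screen),
  exhaustive when the number of label splits is small.

Also provides CPM normalisation, a pooled method-of-moments dispersion
estimate, two-group hierarchical clustering of z-scores, and cross-platform
log-fold-change concordance.
"""

from __future__ import annotations

import math
import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.special import gammaln, logsumexp

from .preterm_classifier import bh_fdr, hedges_g


def cpm_normalize(counts: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Counts-per-million per library (genes x samples).

    Zero-count libraries are flagged and excluded from the returned matrix.
    """
    arr = counts.to_numpy()
    if (arr < 0).any():
        raise ValueError("counts must be nonnegative")
    lib = counts.sum(axis=0)
    zero = lib == 0
    if zero.any():
        warnings.warn(f"zero-count libraries excluded: {list(lib.index[zero])}")
    keep = counts.loc[:, ~zero]
    cpm = keep / lib[~zero] * 1.0e6
    return cpm, lib


def equalize_libraries(counts: pd.DataFrame) -> pd.DataFrame:
    """Scale every library to the geometric-mean library size and round.

    The exact test's conditional construction assumes equal library sizes;
    this is the documented stand-in for the study's (unavailable) library
    normalisation.
    """
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("cannot equalize zero-count libraries")
    target = float(np.exp(np.log(lib).mean()))
    scaled = counts * (target / lib)
    return scaled.round().astype(int)


def estimate_common_dispersion(counts: pd.DataFrame, groups) -> float:
    """Pooled method-of-moments NB dispersion across genes.

    Within each group, var = mu + phi * mu^2; phi is estimated by
    least-squares regression through the origin of (var - mean) on mean^2,
    pooled over all (gene, group) cells, truncated at 0.
    """
    groups = np.asarray(groups)
    arr = counts.to_numpy(dtype=float)
    if arr.sum() == 0:
        raise ValueError("all-zero count matrix")
    num = 0.0
    den = 0.0
    for g in np.unique(groups):
        sub = arr[:, groups == g]
        if sub.shape[1] < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        ok = m > 0
        num += float(np.sum((v[ok] - m[ok]) * m[ok] ** 2))
        den += float(np.sum(m[ok] ** 4))
    if den == 0:
        return 0.0
    return max(0.0, num / den)


def _conditional_log_weights(total: int, n1: int, n2: int, phi: float) -> np.ndarray:
    """Unnormalized log P(Y1 = y | Y1 + Y2 = total), y = 0..total.

    Group subtotals are NB with sizes n1/phi and n2/phi and a common success
    probability, which cancels conditionally, leaving only the gamma terms.
    phi = 0 is the Poisson limit: a binomial(total, n1/(n1+n2)) split.
    """
    y = np.arange(total + 1, dtype=float)
    if phi == 0.0:
        logp = math.log(n1 / (n1 + n2))
        logq = math.log(n2 / (n1 + n2))
        return (gammaln(total + 1) - gammaln(y + 1) - gammaln(total - y + 1)
                + y * logp + (total - y) * logq)
    r1, r2 = n1 / phi, n2 / phi
    return (gammaln(y + r1) - gammaln(y + 1) - gammaln(r1)
            + gammaln(total - y + r2) - gammaln(total - y + 1) - gammaln(r2))


def nb_exact_test(counts_g, groups, phi: float) -> float:
    """Two-sided NB exact test p for one gene's counts split by group.

    Conditions on the gene's total count; tails are P(Y1 <= s1) and
    P(Y1 >= s1) under the conditional null; p doubles the smaller tail,
    capped at 1. Assumes libraries already equalized.
    """
    if phi < 0:
        raise ValueError("dispersion must be >= 0")
    counts_g = np.asarray(counts_g, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValueError("exactly two groups required")
    g1 = groups == labels[0]
    s1 = int(round(counts_g[g1].sum()))
    total = int(round(counts_g.sum()))
    if total == 0:
        return 1.0
    logw = _conditional_log_weights(total, int(g1.sum()),
                                    int((~g1).sum()), phi)
    logz = logsumexp(logw)
    left = float(np.exp(logsumexp(logw[:s1 + 1]) - logz))
    right = float(np.exp(logsumexp(logw[s1:]) - logz))
    return min(1.0, 2.0 * min(left, right))


def permutation_test(values_g, groups, n_perm: int = 4999,
                     seed: int | None = 0, exhaustive: str | bool = "auto",
                     ) -> float:
    """Two-sided permutation p for a difference of group means.

    Sampled mode: p = (1 + #{perm |dmean| >= observed}) / (n_perm + 1).
    Exhaustive mode enumerates every label split (automatic when that is
    cheaper than ``n_perm`` draws) and returns the exact tail fraction.
    """
    if n_perm < 999:
        raise ValueError("n_perm must be >= 999")
    values_g = np.asarray(values_g, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValueError("exactly two nonempty groups required")
    g1 = np.flatnonzero(groups == labels[0])
    n, n1 = len(values_g), len(g1)
    obs = abs(values_g[g1].mean() - np.delete(values_g, g1).mean())

    n_splits = math.comb(n, n1)
    use_exhaustive = (exhaustive is True or
                      (exhaustive == "auto" and n_splits <= n_perm))
    tol = 1e-12 * (1.0 + obs)
    if use_exhaustive:
        hits = 0
        idx = np.arange(n)
        for combo in combinations(idx, n1):
            sel = np.asarray(combo)
            d = abs(values_g[sel].mean() -
                    np.delete(values_g, sel).mean())
            if d >= obs - tol:
                hits += 1
        return hits / n_splits
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)[:n1]
        d = abs(values_g[perm].mean() - np.delete(values_g, perm).mean())
        if d >= obs - tol:
            hits += 1
    return (1 + hits) / (n_perm + 1)


def _batch_permutation_pvalues(values: np.ndarray, groups: np.ndarray,
                               n_perm: int, seed: int) -> np.ndarray:
    """Vectorized sampled permutation test over all genes at once.

    ``values`` is genes x samples; the same label permutations are applied
    to every gene (valid: genes are tested marginally).
    """
    labels = np.unique(groups)
    g1 = groups == labels[0]
    n, n1 = len(groups), int(g1.sum())
    n2 = n - n1
    obs = np.abs(values[:, g1].mean(axis=1) -
                 values[:, ~g1].mean(axis=1))
    rng = np.random.default_rng(seed)
    col_sum = values.sum(axis=1)
    hits = np.zeros(values.shape[0], dtype=int)
    # Indicator matrix of permuted group-1 memberships, in manageable blocks.
    block = max(1, min(n_perm, 512))
    done = 0
    tol = 1e-12 * (1.0 + obs)
    while done < n_perm:
        b = min(block, n_perm - done)
        ind = np.zeros((b, n))
        for i in range(b):
            ind[i, rng.permutation(n)[:n1]] = 1.0
        s1 = values @ ind.T                       # genes x b group-1 sums
        d = np.abs(s1 / n1 - (col_sum[:, None] - s1) / n2)
        hits += (d >= obs[:, None] - tol[:, None]).sum(axis=1)
        done += b
    return (1 + hits) / (n_perm + 1)


def discover_de_genes(counts: pd.DataFrame, groups,
                      phi: float | None = None, alpha: float = 0.001,
                      n_perm: int = 4999, seed: int = 0) -> pd.DataFrame:
    """Per-gene DE statistics and the intersection significance call.

    ``groups`` labels the columns of ``counts`` (preterm/term). A gene is
    ``significant`` iff the NB exact test AND the permutation test both give
    p < ``alpha``. Effect sizes (log2 fold-change, Hedges' g) and BH q-values
    (on the exact-test p) are reported alongside.
    """
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValueError("exactly two groups required")
    # Preterm-vs-term orientation when those labels are present.
    if set(labels) == {"preterm", "term"}:
        lab1, lab2 = "preterm", "term"
    else:
        lab1, lab2 = labels[0], labels[1]
    g1 = groups == lab1
    if g1.sum() < 3 or (~g1).sum() < 3:
        raise ValueError("permutation screening needs >= 3 samples per group")

    eq = equalize_libraries(counts)
    if phi is None:
        phi = estimate_common_dispersion(eq, groups)
    cpm, _ = cpm_normalize(counts)
    logcpm = np.log2(cpm.to_numpy() + 1.0)

    p_exact = np.array([nb_exact_test(eq.iloc[i].to_numpy(), groups, phi)
                        for i in range(len(eq))])
    p_perm = _batch_permutation_pvalues(
        np.ascontiguousarray(logcpm), groups, n_perm, seed)

    mean1 = cpm.loc[:, g1].mean(axis=1)
    mean2 = cpm.loc[:, ~g1].mean(axis=1)
    logfc = np.log2((mean1 + 0.5) / (mean2 + 0.5))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        g_vals = np.array([hedges_g(logcpm[i, g1], logcpm[i, ~g1])
                           for i in range(logcpm.shape[0])])
    out = pd.DataFrame({
        "gene": counts.index,
        f"mean_cpm_{lab1}": mean1.to_numpy(),
        f"mean_cpm_{lab2}": mean2.to_numpy(),
        "logFC": logfc.to_numpy(),
        "p_exact": p_exact,
        "p_perm": p_perm,
        "q_bh": bh_fdr(p_exact),
        "g_hedges": g_vals,
        "significant": (p_exact < alpha) & (p_perm < alpha),
    }).set_index("gene")
    out.attrs["dispersion"] = phi
    return out


def two_group_cluster(values: pd.DataFrame, true_labels=None,
                      ) -> tuple[np.ndarray, float | None]:
    """Cluster samples into two groups on per-gene z-scores.

    ``values`` is genes x samples (e.g. log2 CPM). Genes constant across
    samples are dropped from z-scoring with a warning. Clustering is
    agglomerative with Euclidean distance and average linkage, cut at two
    clusters. If ``true_labels`` is given, returns the best label-pairing
    classification agreement as well.
    """
    arr = values.to_numpy(dtype=float)
    if arr.shape[1] < 2:
        raise ValueError("need >= 2 samples to cluster")
    sd = arr.std(axis=1, ddof=0)
    const = sd == 0
    if const.any():
        warnings.warn(f"{const.sum()} constant gene(s) dropped from z-scoring")
    arr = arr[~const]
    z = (arr - arr.mean(axis=1, keepdims=True)) / arr[:, :].std(
        axis=1, keepdims=True, ddof=0)
    link = hierarchy.linkage(z.T, method="average", metric="euclidean")
    clusters = hierarchy.fcluster(link, t=2, criterion="maxclust")
    if true_labels is None:
        return clusters, None
    truth = np.asarray(true_labels)
    lab = np.unique(truth)
    acc = max(
        np.mean((clusters == 1) == (truth == lab[0])),
        np.mean((clusters == 2) == (truth == lab[0])),
    )
    return clusters, float(acc)


def platform_concordance(logfc_a, logfc_b) -> tuple[float, float]:
    """Pearson r (+p) between per-gene log fold-changes on two platforms."""
    a = np.asarray(logfc_a, dtype=float)
    b = np.asarray(logfc_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("fold-change vectors must align")
    if len(a) < 3:
        raise ValueError("need >= 3 shared genes for concordance")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)
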