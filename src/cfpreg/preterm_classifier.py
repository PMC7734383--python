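"""Effect-size/FDR gene screen and the 3-gene combination ensemble.

Candidate preterm markers pass the screen when their Benjamini-Hochberg
q-value is <= 5% and their Hedges' g (pooled-SD standardized mean
difference, small-sample corrected) is >= 0.8. The classifier then
enumerates every unique k-gene combination (k = 3) of the passing panel;
each combination scores a sample by the mean z-score of its genes against
the term-group reference (training term mean and SD per gene), with a
per-combination operating threshold chosen by Youden's J on training data.
A sample is called preterm when at least a ``vote_threshold`` fraction of
combinations fire. Performance is summarised by the arithmetic mean of
per-combination AUCs plus confusion counts at the operating point.

The statistical kernels here (Hedges' g, BH FDR, Fisher exact test,
pair-counting/trapezoidal AUC) are self-contained, enumeration-friendly
implementations.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .qpcr_io import ExpressionMatrix


# --------------------------------------------------------------------------
# statistical kernels

def hedges_g(x1, x2) -> float:
    """Small-sample-corrected standardized mean difference.

    g = J * (mean1 - mean2) / s_pooled, with
    s_pooled = sqrt(((n1-1) s1^2 + (n2-1) s2^2) / (n1 + n2 - 2)) and
    J = 1 - 3 / (4 (n1 + n2) - 9). Zero pooled SD gives signed infinity
    (flagged by a warning) so callers can exclude the gene from screens.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    n1, n2 = len(x1), len(x2)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs >= 2 values")
    s_pooled = math.sqrt(((n1 - 1) * x1.var(ddof=1) + (n2 - 1) * x2.var(ddof=1))
                         / (n1 + n2 - 2))
    diff = float(x1.mean() - x2.mean())
    j = 1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0)
    if s_pooled == 0.0:
        warnings.warn("zero pooled SD in hedges_g; returning signed infinity")
        return math.copysign(math.inf, diff) if diff != 0 else math.nan
    return j * diff / s_pooled


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving.

    q_(i) = min_{j >= i} (m * p_(j) / j), clipped at 1, returned in the
    input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def fisher_exact_detection(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table of detection counts.

    Sums hypergeometric probabilities of all tables (same margins) whose
    probability does not exceed the observed table's. A zero margin makes
    the table degenerate: p = 1 is returned with a warning.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with nonnegative integer entries")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or (b + d) == 0:
        warnings.warn("degenerate 2x2 table (zero margin); p = 1")
        return 1.0

    def log_hyper(x: int) -> float:
        return (gammaln(r1 + 1) - gammaln(x + 1) - gammaln(r1 - x + 1)
                + gammaln(r2 + 1) - gammaln(c1 - x + 1)
                - gammaln(r2 - c1 + x + 1)
                - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1)))

    lo, hi = max(0, c1 - r2), min(r1, c1)
    logps = np.array([log_hyper(x) for x in range(lo, hi + 1)])
    probs = np.exp(logps - logps.max())
    probs /= probs.sum()
    p_obs = probs[a - lo]
    return float(min(1.0, probs[probs <= p_obs * (1.0 + 1e-7)].sum()))


def roc_auc(scores, labels, positive="preterm",
            ) -> tuple[float, pd.DataFrame]:
    """AUC with the pair-counting tie convention, plus ROC curve points.

    AUC = (#{pos > neg} + 0.5 #{pos == neg}) / (n_pos * n_neg), identical to
    trapezoidal integration of the tie-aware ROC curve, whose (fpr, tpr)
    points over all distinct score thresholds are returned as well.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels) == positive
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    pos, neg = s[y], s[~y]
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    auc = (greater + 0.5 * ties) / (n_pos * n_neg)

    thresholds = np.concatenate(([np.inf], np.unique(s)[::-1]))
    points = [{"threshold": float(t),
               "tpr": float((pos >= t).mean()),
               "fpr": float((neg >= t).mean())} for t in thresholds]
    return float(auc), pd.DataFrame(points)


# --------------------------------------------------------------------------
# screen

@dataclass
class EffectScreen:
    table: pd.DataFrame        # per gene: g_hedges, p_perm, q_bh, p_fisher, passes
    passing: list[str]         # ranked by descending g among passers
    alpha: float = 0.05
    g_min: float = 0.8

    def top_genes(self, n: int = 7) -> list[str]:
        """The n panel transcripts with the largest Hedges' g.

        The study's classifier is built on the "top" screened transcripts;
        ranking is by descending effect size (lexicographic symbol order
        breaks ties), restricted to finite effect estimates.
        """
        tab = self.table[np.isfinite(self.table["g_hedges"])]
        ranked = (tab.sort_index()
                  .sort_values("g_hedges", ascending=False, kind="stable"))
        return ranked.index[:n].tolist()


def _per_subject_values(matrix: ExpressionMatrix,
                        outcomes: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Antepartum sample values with preterm/term labels per row."""
    ante = ~matrix.sample_meta["postpartum_flag"].astype(bool).to_numpy()
    vals = matrix.values.loc[ante]
    subj = matrix.sample_meta.loc[ante, "subject_id"]
    labels = subj.map(outcomes.set_index("subject_id")["label"]).to_numpy()
    return vals, labels


def screen_genes(matrix: ExpressionMatrix, outcomes: pd.DataFrame,
                 alpha: float = 0.05, g_min: float = 0.8,
                 n_perm: int = 4999, seed: int = 0) -> EffectScreen:
    """Effect-size / FDR screen over the panel.

    Per gene: Hedges' g (preterm vs term), permutation-test p on the mean
    difference, BH q over the panel, and a Fisher exact test on per-class
    counts above/below the term-group median. A gene passes iff
    q <= ``alpha`` and g >= ``g_min``; passers are ranked by descending g.
    """
    from .preterm_discovery import permutation_test  # local: avoid cycle

    vals, labels = _per_subject_values(matrix, outcomes)
    if not {"preterm", "term"} <= set(labels):
        raise ValueError("both outcome classes must be present")
    pre = labels == "preterm"
    rows = []
    for gene in vals.columns:
        v = vals[gene].to_numpy(dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            g = hedges_g(v[pre], v[~pre])
        p = permutation_test(v, labels, n_perm=n_perm, seed=seed)
        term_median = float(np.median(v[~pre]))
        above = v > term_median
        tab = [[int((above & pre).sum()), int((~above & pre).sum())],
               [int((above & ~pre).sum()), int((~above & ~pre).sum())]]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p_fisher = fisher_exact_detection(tab)
        rows.append({"gene": gene, "g_hedges": g, "p_perm": p,
                     "p_fisher_detection": p_fisher})
    table = pd.DataFrame(rows).set_index("gene")
    table["q_bh"] = bh_fdr(table["p_perm"].to_numpy())
    finite_g = np.isfinite(table["g_hedges"])
    table["passes"] = (finite_g & (table["q_bh"] <= alpha)
                       & (table["g_hedges"] >= g_min))
    # rank by descending g; lexicographic gene symbol breaks ties
    passing = (table[table["passes"]]
               .sort_index()
               .sort_values("g_hedges", ascending=False, kind="stable")
               .index.tolist())
    return EffectScreen(table, passing, alpha, g_min)


# --------------------------------------------------------------------------
# combination ensemble

@dataclass
class ComboEnsemble:
    combos: list[tuple[str, ...]]
    reference: pd.DataFrame            # per gene: term_mean, term_sd
    thresholds: dict[tuple[str, ...], float]
    per_combo_auc_train: dict[tuple[str, ...], float]
    vote_threshold: float = 0.5
    k: int = 3
    train_subjects: frozenset = field(default_factory=frozenset)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "k": self.k,
            "vote_threshold": self.vote_threshold,
            "reference": self.reference.reset_index().to_dict(orient="list"),
            "combos": [
                {"genes": list(c),
                 "threshold": self.thresholds[c],
                 "train_auc": self.per_combo_auc_train[c]}
                for c in self.combos],
            "train_subjects": sorted(self.train_subjects),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "ComboEnsemble":
        payload = json.loads(Path(path).read_text())
        ref = pd.DataFrame(payload["reference"]).set_index("gene")
        combos = [tuple(c["genes"]) for c in payload["combos"]]
        return cls(
            combos=combos, reference=ref,
            thresholds={tuple(c["genes"]): c["threshold"]
                        for c in payload["combos"]},
            per_combo_auc_train={tuple(c["genes"]): c["train_auc"]
                                 for c in payload["combos"]},
            vote_threshold=payload["vote_threshold"], k=payload["k"],
            train_subjects=frozenset(payload["train_subjects"]))


def combo_scores(values: pd.DataFrame, reference: pd.DataFrame,
                 combos: list[tuple[str, ...]]) -> pd.DataFrame:
    """Mean term-reference z-score per (sample, combination)."""
    z = (values[reference.index] - reference["term_mean"]) / reference["term_sd"]
    return pd.DataFrame({c: z[list(c)].mean(axis=1) for c in combos},
                        index=values.index)


def _youden_threshold(scores: np.ndarray, is_pos: np.ndarray) -> float:
    """Operating threshold maximizing TPR - FPR (midpoint between scores)."""
    order = np.argsort(scores)[::-1]
    s_sorted = scores[order]
    y_sorted = is_pos[order]
    n_pos, n_neg = is_pos.sum(), (~is_pos).sum()
    best_j, best_t = -np.inf, float(np.max(scores) + 1.0)
    tp = fp = 0
    i = 0
    while i < len(s_sorted):
        j = i
        while j < len(s_sorted) and s_sorted[j] == s_sorted[i]:
            tp += int(y_sorted[j])
            fp += int(~y_sorted[j])
            j += 1
        youden = tp / n_pos - fp / n_neg
        if youden > best_j:
            best_j = youden
            nxt = s_sorted[j] if j < len(s_sorted) else s_sorted[-1] - 1.0
            best_t = float((s_sorted[i] + nxt) / 2.0)
        i = j
    return best_t


def build_ensemble(matrix_train: ExpressionMatrix, outcomes_train: pd.DataFrame,
                   passing_genes: list[str], k: int = 3,
                   vote_threshold: float = 0.5) -> ComboEnsemble:
    """Enumerate all C(m, k) gene combinations with term-reference scoring.

    Reference statistics (term-group mean and SD per gene) come from the
    training cohort only; genes whose term SD is 0 are dropped with a
    warning. Each combination's operating threshold maximizes Youden's J on
    training scores.
    """
    if len(set(passing_genes)) != len(passing_genes):
        raise ValueError("duplicate gene symbols in passing list")
    if len(passing_genes) < k:
        raise ValueError(f"need >= {k} passing genes, got {len(passing_genes)}")
    vals, labels = _per_subject_values(matrix_train, outcomes_train)
    pre = labels == "preterm"
    term_vals = vals.loc[~pre, passing_genes]
    ref = pd.DataFrame({"term_mean": term_vals.mean(),
                        "term_sd": term_vals.std(ddof=1)})
    ref.index.name = "gene"
    degenerate = ref["term_sd"] == 0
    if degenerate.any():
        warnings.warn(f"genes with zero term-group SD dropped: "
                      f"{list(ref.index[degenerate])}")
        ref = ref[~degenerate]
    usable = [g for g in passing_genes if g in ref.index]
    if len(usable) < k:
        raise ValueError("too few usable genes after dropping zero-SD genes")
    combos = [tuple(c) for c in combinations(sorted(usable), k)]

    scores = combo_scores(vals, ref, combos)
    thresholds: dict[tuple[str, ...], float] = {}
    aucs: dict[tuple[str, ...], float] = {}
    for c in combos:
        s = scores[c].to_numpy()
        auc, _ = roc_auc(s, labels, positive="preterm")
        aucs[c] = auc
        thresholds[c] = _youden_threshold(s, pre)
    return ComboEnsemble(combos, ref, thresholds, aucs, vote_threshold, k,
                         frozenset(outcomes_train["subject_id"]))


def evaluate_ensemble(ensemble: ComboEnsemble, matrix_test: ExpressionMatrix,
                      outcomes_test: pd.DataFrame) -> dict:
    """Mean AUC, per-combination AUCs and confusion at the operating point.

    Test subjects must be disjoint from the training cohort. A sample is
    predicted preterm when the fraction of combinations whose score exceeds
    their operating threshold is >= the ensemble vote threshold.
    """
    overlap = ensemble.train_subjects & set(outcomes_test["subject_id"])
    if overlap:
        raise ValueError(f"test subjects seen in training: {sorted(overlap)}")
    vals, labels = _per_subject_values(matrix_test, outcomes_test)
    pre = labels == "preterm"
    scores = combo_scores(vals, ensemble.reference, ensemble.combos)

    per_combo = {}
    curves = {}
    for c in ensemble.combos:
        auc, curve = roc_auc(scores[c].to_numpy(), labels, positive="preterm")
        per_combo[c] = auc
        curves[c] = curve
    mean_auc = float(np.mean(list(per_combo.values())))

    votes = np.column_stack(
        [scores[c].to_numpy() > ensemble.thresholds[c]
         for c in ensemble.combos])
    frac = votes.mean(axis=1)
    predicted = frac >= ensemble.vote_threshold
    tp = int((predicted & pre).sum())
    fn = int((~predicted & pre).sum())
    fp = int((predicted & ~pre).sum())
    tn = int((~predicted & ~pre).sum())
    return {
        "mean_auc": mean_auc,
        "per_combo_auc": per_combo,
        "roc_curves": curves,
        "vote_fraction": pd.Series(frac, index=vals.index),
        "confusion": {"tp": tp, "fn": fn, "fp": fp, "tn": tn},
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "ppv": tp / (tp + fp) if tp + fp else float("nan"),
        "n_preterm": int(pre.sum()),
        "n_term": int((~pre).sum()),
    }
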