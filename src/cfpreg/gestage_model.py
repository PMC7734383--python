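"""Random-forest time-to-delivery model with forward best-subset selection.

The response for each antepartum blood draw is the time remaining until
delivery, y = GA_delivery - GA_sample (weeks); features are log10 cfRNA
abundances. Feature selection is greedy forward best-subset search ranked by
repeated subject-level k-fold cross-validated RMSE, with the final subset
size chosen by the one-standard-error rule. Cross-validation folds always
split by woman, never by sample, so longitudinal draws from one pregnancy
can never leak between train and test.

Evaluation reports overall Pearson r between predicted and observed
time-to-delivery, per-trimester RMSE, and a delivery-date deviation table
comparing trimester-averaged cfRNA estimates with a first-trimester
ultrasound-like baseline that assumes delivery at 40 weeks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

from .qpcr_io import ExpressionMatrix, trimester_bin

DEVIATION_BINS = ("< -2", "-1 to -2", "+/-1", "+1 to +2", "> +2")


@dataclass(frozen=True)
class CVConfig:
    """Repeated subject-level k-fold settings (default 10-fold x 10)."""
    k: int = 10
    repeats: int = 10
    seed: int = 0


@dataclass
class GestAgeFit:
    selected_genes: list[str]
    cv_trace: pd.DataFrame            # size, gene_added, mean_rmse, sd_rmse
    model: RandomForestRegressor
    train_r: float
    per_trimester_rmse: dict[str, float] = field(default_factory=dict)


def build_features(matrix: ExpressionMatrix, outcomes: pd.DataFrame,
                   include_postpartum: bool = False,
                   ) -> tuple[pd.DataFrame, pd.Series, pd.Series, pd.DataFrame]:
    """Assemble (X, y, subjects, meta) from an expression matrix + outcomes.

    y is weeks from draw to delivery; antepartum rows only unless
    ``include_postpartum`` (postpartum rows have y <= 0 and are reserved for
    evaluation). Samples whose subject lacks an outcome row are an error.
    """
    meta = matrix.sample_meta.copy()
    out = outcomes.set_index("subject_id")
    orphans = sorted(set(meta["subject_id"]) - set(out.index))
    if orphans:
        raise ValueError(f"samples without outcome rows for subjects: {orphans}")
    ga_del = meta["subject_id"].map(out["ga_delivery"])
    y = ga_del - meta["ga_weeks"]
    keep = np.ones(len(meta), dtype=bool) if include_postpartum else \
        ~meta["postpartum_flag"].astype(bool).to_numpy()
    X = matrix.values.loc[keep]
    meta = meta.loc[keep]
    return X, y.loc[keep].rename("weeks_to_delivery"), \
        meta["subject_id"], meta


def _subject_folds(subjects: pd.Series, k: int, repeats: int,
                   seed: int) -> list[list[np.ndarray]]:
    """Row-index folds per repeat; each woman's draws stay in one fold."""
    uniq = np.array(sorted(subjects.unique()))
    if len(uniq) < k:
        raise ValueError(f"need >= {k} subjects for {k}-fold CV, "
                         f"got {len(uniq)}")
    rng = np.random.default_rng(seed)
    subj_arr = subjects.to_numpy()
    folds_per_repeat = []
    for _ in range(repeats):
        perm = rng.permutation(uniq)
        groups = np.array_split(perm, k)
        folds = [np.flatnonzero(np.isin(subj_arr, g)) for g in groups]
        folds_per_repeat.append(folds)
    return folds_per_repeat


def _cv_rmse(Xsub: np.ndarray, y: np.ndarray,
             folds_per_repeat: list[list[np.ndarray]],
             rf_params: dict, seed: int) -> tuple[float, float, int]:
    rmses = []
    for folds in folds_per_repeat:
        for test_idx in folds:
            train_mask = np.ones(len(y), dtype=bool)
            train_mask[test_idx] = False
            rf = RandomForestRegressor(random_state=seed, **rf_params)
            rf.fit(Xsub[train_mask], y[train_mask])
            pred = rf.predict(Xsub[test_idx])
            rmses.append(math.sqrt(np.mean((pred - y[test_idx]) ** 2)))
    return float(np.mean(rmses)), float(np.std(rmses, ddof=1)), len(rmses)


def repeated_kfold_rmse(X: pd.DataFrame, y: pd.Series, subjects: pd.Series,
                        genes: list[str], cv: CVConfig = CVConfig(),
                        rf_params: dict | None = None) -> tuple[float, float]:
    """Mean and SD of held-out RMSE over k x repeats subject-level folds."""
    if not genes:
        raise ValueError("gene subset must be nonempty")
    missing = [g for g in genes if g not in X.columns]
    if missing:
        raise KeyError(f"genes not in feature matrix: {missing}")
    params = {"n_estimators": 100, "min_samples_leaf": 5} | (rf_params or {})
    folds = _subject_folds(subjects, cv.k, cv.repeats, cv.seed)
    mean, sd, _ = _cv_rmse(X[genes].to_numpy(), y.to_numpy(),
                           folds, params, cv.seed)
    return mean, sd


def best_subset_select(X: pd.DataFrame, y: pd.Series, subjects: pd.Series,
                       candidates: list[str], cv: CVConfig = CVConfig(),
                       max_size: int | None = None,
                       rf_params: dict | None = None,
                       ) -> tuple[list[str], pd.DataFrame]:
    """Greedy forward subset search with the one-standard-error rule.

    At each step the candidate whose addition gives the lowest repeated-CV
    RMSE joins the subset (ties broken by gene symbol order). Because the
    per-step minimum over many candidates biases its own score downward
    (winner's curse), every prefix of the greedy path is then re-scored on
    an independent set of CV folds, and the returned subset is the smallest
    size whose unbiased mean RMSE is within one standard error of the
    overall minimum.
    """
    if not candidates:
        raise ValueError("candidate gene list must be nonempty")
    candidates = sorted(dict.fromkeys(candidates))
    if max_size is None:
        max_size = min(len(candidates), 10)
    params = {"n_estimators": 100, "min_samples_leaf": 5} | (rf_params or {})
    folds = _subject_folds(subjects, cv.k, cv.repeats, cv.seed)
    yv = y.to_numpy()

    selected: list[str] = []
    rows = []
    remaining = list(candidates)
    while remaining and len(selected) < max_size:
        best_gene, best_mean = None, np.inf
        for gene in remaining:  # sorted: first strict min wins ties
            trial = selected + [gene]
            mean, _, _ = _cv_rmse(X[trial].to_numpy(), yv, folds,
                                  params, cv.seed)
            if mean < best_mean:
                best_gene, best_mean = gene, mean
        selected.append(best_gene)
        remaining.remove(best_gene)
        rows.append({"size": len(selected), "gene_added": best_gene,
                     "genes": tuple(selected), "selection_rmse": best_mean})

    # Unbiased re-scoring of the greedy path on fresh folds.
    eval_folds = _subject_folds(subjects, cv.k, cv.repeats, cv.seed + 1)
    for row in rows:
        mean, sd, nf = _cv_rmse(X[list(row["genes"])].to_numpy(), yv,
                                eval_folds, params, cv.seed)
        row["mean_rmse"] = mean
        row["sd_rmse"] = sd
        row["se_rmse"] = sd / math.sqrt(nf)
    trace = pd.DataFrame(rows)

    best_row = trace["mean_rmse"].idxmin()
    threshold = trace.loc[best_row, "mean_rmse"] + trace.loc[best_row, "se_rmse"]
    chosen_size = int(trace.loc[trace["mean_rmse"] <= threshold, "size"].min())
    return list(trace.loc[chosen_size - 1, "genes"]), trace


def fit_rf(X: pd.DataFrame, y: pd.Series, genes: list[str],
           rf_params: dict | None = None, seed: int = 0) -> RandomForestRegressor:
    """Fit the time-to-delivery forest on the selected genes (500 trees)."""
    params = {"n_estimators": 500, "min_samples_leaf": 5} | (rf_params or {})
    rf = RandomForestRegressor(random_state=seed, **params)
    rf.fit(X[genes].to_numpy(), y.to_numpy())
    rf.feature_genes_ = list(genes)
    return rf


def predict_rf(model: RandomForestRegressor, X: pd.DataFrame) -> pd.Series:
    """Predict weeks-to-delivery; unseen genes at predict time are an error."""
    genes = model.feature_genes_
    missing = [g for g in genes if g not in X.columns]
    if missing:
        raise KeyError(f"prediction matrix lacks trained genes: {missing}")
    return pd.Series(model.predict(X[genes].to_numpy()), index=X.index,
                     name="predicted_weeks_to_delivery")


def cross_validated_predictions(matrix: ExpressionMatrix,
                                outcomes: pd.DataFrame, genes: list[str],
                                k: int = 10, seed: int = 0,
                                rf_params: dict | None = None) -> pd.Series:
    """Held-out predictions for every sample via subject-level k-fold.

    Each fold's model trains on the antepartum draws of the other folds'
    women and predicts all draws (antepartum and postpartum) of the held-out
    women, so every reported prediction is out-of-sample for that woman.
    """
    X_all, y_all, subjects_all, meta_all = build_features(
        matrix, outcomes, include_postpartum=True)
    ante = ~meta_all["postpartum_flag"].astype(bool).to_numpy()
    folds = _subject_folds(subjects_all, k, 1, seed)[0]
    params = {"n_estimators": 500, "min_samples_leaf": 5} | (rf_params or {})
    pred = pd.Series(np.nan, index=X_all.index,
                     name="predicted_weeks_to_delivery")
    for test_idx in folds:
        test_mask = np.zeros(len(X_all), dtype=bool)
        test_mask[test_idx] = True
        train_mask = ~test_mask & ante
        rf = RandomForestRegressor(random_state=seed, **params)
        rf.fit(X_all.loc[train_mask, genes].to_numpy(),
               y_all.loc[train_mask].to_numpy())
        pred.iloc[test_idx] = rf.predict(
            X_all.loc[test_mask, genes].to_numpy())
    return pred


def evaluate_fit(predictions: pd.Series, truth: pd.Series,
                 bins) -> tuple[dict[str, float], float, float]:
    """Per-trimester RMSE and overall Pearson r (+p) of predictions.

    ``bins`` holds the T1/T2/T3/PP stratum of each sample. Empty strata are
    reported as NaN.
    """
    pred = np.asarray(predictions, dtype=float)
    obs = np.asarray(truth, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError("predictions and truth must align")
    bins = np.asarray(bins)
    per_bin: dict[str, float] = {}
    for b in ("T1", "T2", "T3", "PP"):
        mask = bins == b
        per_bin[b] = (math.sqrt(np.mean((pred[mask] - obs[mask]) ** 2))
                      if mask.any() else float("nan"))
    if np.ptp(pred) == 0 or np.ptp(obs) == 0:
        r, p = float("nan"), float("nan")
    else:
        r, p = stats.pearsonr(pred, obs)
    return per_bin, float(r), float(p)


def _bin_delta(delta: float) -> str:
    """Bin a delivery-date deviation; boundaries go to the inner bin."""
    if abs(delta) <= 1.0:
        return "+/-1"
    if 1.0 < delta <= 2.0:
        return "+1 to +2"
    if -2.0 <= delta < -1.0:
        return "-1 to -2"
    return "> +2" if delta > 2.0 else "< -2"


def deviation_table(pred_meta: pd.DataFrame, outcomes: pd.DataFrame,
                    trimester_sets: dict[str, tuple[str, ...]] | None = None,
                    ultrasound_sd: float = 0.7, seed: int = 0) -> pd.DataFrame:
    """Delivery-date deviation distribution per estimation method.

    ``pred_meta`` has one row per antepartum sample with columns subject_id,
    ga_weeks, postpartum_flag and y_pred (predicted weeks to delivery). For
    each cfRNA method a woman's expected delivery GA is the mean of
    (ga_weeks + y_pred) over her samples in the stated trimester(s); the
    deviation is observed minus expected. The ultrasound baseline assumes
    delivery at 40 weeks from a first-trimester GA estimate simulated as the
    true GA plus N(0, ultrasound_sd) error.

    Returns one row per method: n, percentage per deviation bin, and the
    percentage falling within 14 days (|deviation| <= 2 weeks).
    """
    if trimester_sets is None:
        trimester_sets = {"cfRNA (T2)": ("T2",), "cfRNA (T3)": ("T3",),
                          "cfRNA (T2 and T3)": ("T2", "T3")}
    df = pred_meta.copy()
    df["trimester"] = trimester_bin(df["ga_weeks"], df["postpartum_flag"])
    df["expected_delivery"] = df["ga_weeks"] + df["y_pred"]
    ga_del = outcomes.set_index("subject_id")["ga_delivery"]

    rows = []
    for method, tset in trimester_sets.items():
        sub = df[df["trimester"].isin(tset)]
        per_woman = sub.groupby("subject_id")["expected_delivery"].mean()
        if per_woman.empty:
            rows.append({"method": method, "n": 0,
                         **{b: float("nan") for b in DEVIATION_BINS},
                         "pct_within_14d": float("nan")})
            continue
        delta = ga_del.loc[per_woman.index] - per_woman
        binned = delta.map(_bin_delta)
        n = len(delta)
        row = {"method": method, "n": n}
        for b in DEVIATION_BINS:
            row[b] = 100.0 * (binned == b).sum() / n
        row["pct_within_14d"] = 100.0 * (delta.abs() <= 2.0).sum() / n
        rows.append(row)

    # Ultrasound-like baseline from each woman's earliest T1 draw.
    rng = np.random.default_rng(seed)
    t1 = df[df["trimester"] == "T1"].sort_values("ga_weeks")
    first_t1 = t1.drop_duplicates("subject_id").set_index("subject_id")
    if len(first_t1):
        err = rng.normal(0.0, ultrasound_sd, size=len(first_t1))
        delta = ga_del.loc[first_t1.index] - 40.0 + err
        binned = delta.map(_bin_delta)
        n = len(delta)
        row = {"method": "Ultrasound (T1)", "n": n}
        for b in DEVIATION_BINS:
            row[b] = 100.0 * (binned == b).sum() / n
        row["pct_within_14d"] = 100.0 * (delta.abs() <= 2.0).sum() / n
        rows.append(row)
    return pd.DataFrame(rows).set_index("method")
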