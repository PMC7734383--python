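"""End-to-end pipeline orchestration and machine-readable run reports.

Stages run in dependency order: simulate (synthetic cohorts + panel) ->
normalize (long table -> expression matrix with detection floor) ->
correlate (trajectory correlation structure) -> gestage (time-to-delivery
model) -> preterm (count DE screen, effect screen, combination ensemble).
Every stage derives its own seed deterministically from the one global seed,
writes its outputs under the run directory, and contributes summary metrics
to a JSON report. A failed stage leaves earlier outputs intact.
"""

from __future__ import annotations

import json
import logging
import math
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gestage_model as gm
from . import preterm_classifier as pc
from . import preterm_discovery as pdisc
from . import qpcr_io, synthetic_cohort as sc
from . import temporal_structure as ts

logger = logging.getLogger(__name__)

STAGES = ("simulate", "normalize", "correlate", "gestage", "preterm")

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "out_dir": "results/run",
    "stages": list(STAGES),
    "simulate": {
        "lod": 0.0,
        "preterm_effect_g": 1.2,
        "n_train": 21,
        "n_validation": 10,
        "n_penn": 15,
        "n_alabama": 23,
    },
    "gestage": {
        "cv_folds": 5,
        "cv_repeats": 2,
        "selection_trees": 50,
        "final_trees": 500,
        "max_subset": 9,
        "eval_folds": 10,
        "ultrasound_sd": 0.7,
    },
    "preterm": {
        "n_genes": 300,
        "n_effect": 38,
        "dispersion": 0.2,
        "effect_g_seq": 2.0,
        "n_perm": 4999,
        "alpha_de": 0.001,
        "screen_alpha": 0.05,
        "screen_g_min": 0.8,
        "top_n": 7,
        "combo_k": 3,
        "vote_threshold": 0.5,
        "n_discovery": 34,
        "n_discovery_preterm": 8,
        "n_validation": 23,
        "n_validation_preterm": 5,
        "qpcr_noise_sd": 0.25,
    },
}


class ConfigError(ValueError):
    """A config section or key is unknown or has the wrong type."""


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 from the global seed."""
    return (int(seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2 ** 31)


def load_config(source: str | Path | dict | None = None) -> dict:
    """Merge a YAML file / dict over the defaults, validating every key."""
    cfg = {k: (dict(v) if isinstance(v, dict) else v)
           for k, v in DEFAULT_CONFIG.items()}
    if source is None:
        return cfg
    user = source if isinstance(source, dict) else \
        yaml.safe_load(Path(source).read_text()) or {}
    for key, val in user.items():
        if key not in DEFAULT_CONFIG:
            raise ConfigError(f"unknown config section or key: {key!r}")
        if isinstance(DEFAULT_CONFIG[key], dict):
            if not isinstance(val, dict):
                raise ConfigError(f"config section {key!r} must be a mapping")
            for sub in val:
                if sub not in DEFAULT_CONFIG[key]:
                    raise ConfigError(f"unknown config key: {key}.{sub}")
            cfg[key].update(val)
        else:
            cfg[key] = val
    unknown_stage = set(cfg["stages"]) - set(STAGES)
    if unknown_stage:
        raise ConfigError(f"unknown stage(s): {sorted(unknown_stage)}")
    return cfg


# --------------------------------------------------------------------------
# stages

def run_simulate(cfg: dict, out_dir: Path) -> dict:
    seed = stage_seed(cfg["seed"], "simulate")
    s = cfg["simulate"]
    panel = sc.default_panel()
    sim = sc.SimulationConfig(
        seed=seed,
        cohorts=(
            sc.CohortDesign("denmark_train", s["n_train"], scheme="weekly",
                            preterm_fraction=0.0),
            sc.CohortDesign("denmark_validation", s["n_validation"],
                            scheme="weekly", preterm_fraction=0.0),
            sc.CohortDesign("penn", s["n_penn"], scheme="sparse", n_draws=1,
                            window=(17.0, 35.0),
                            preterm_fraction=8 / 15),
            sc.CohortDesign("alabama", s["n_alabama"], scheme="sparse",
                            n_draws=1, window=(22.0, 34.0),
                            preterm_fraction=5 / 23),
        ),
        preterm_effect_g=s["preterm_effect_g"], lod=s["lod"])
    samples, outcomes = sc.simulate_cohort(sim, panel)
    if (outcomes["label"] == "preterm").any() and s["preterm_effect_g"] != 0:
        samples = sc.inject_preterm_effect(
            samples, outcomes, list(sc.PRETERM_SEVEN),
            s["preterm_effect_g"], lod=s["lod"])
    samples.to_csv(out_dir / "samples.csv", index=False)
    outcomes.to_csv(out_dir / "outcomes.csv", index=False)
    pd.DataFrame({"gene": [m.gene for m in panel],
                  "group": [m.group for m in panel]}
                 ).to_csv(out_dir / "panel.csv", index=False)
    return {"n_samples": int(len(samples) // len(panel)),
            "n_subjects": int(len(outcomes)),
            "files": {"samples": "samples.csv", "outcomes": "outcomes.csv",
                      "panel": "panel.csv"}}


def _load_matrix(out_dir: Path) -> tuple[qpcr_io.ExpressionMatrix, pd.DataFrame]:
    panel = pd.read_csv(out_dir / "panel.csv")
    groups = dict(zip(panel["gene"], panel["group"]))
    if not (out_dir / "outcomes.csv").exists():
        raise FileNotFoundError(out_dir / "outcomes.csv")
    matrix = qpcr_io.read_long_table(out_dir / "samples.csv", groups)
    outcomes = qpcr_io.read_outcomes(out_dir / "outcomes.csv")
    return matrix, outcomes


def run_normalize(cfg: dict, out_dir: Path) -> dict:
    matrix, _ = _load_matrix(out_dir)
    matrix = qpcr_io.apply_noise_floor(matrix, cfg["simulate"]["lod"])
    qpcr_io.write_matrix(matrix, out_dir / "matrix")
    return {"n_samples": int(matrix.values.shape[0]),
            "n_genes": int(matrix.values.shape[1]),
            "pct_detected": float(100.0 * matrix.detected.to_numpy().mean()),
            "files": {"matrix": "matrix.tsv"}}


def run_correlate(cfg: dict, out_dir: Path) -> dict:
    matrix, _ = _load_matrix(out_dir)
    matrix = qpcr_io.apply_noise_floor(matrix, cfg["simulate"]["lod"])
    danish = matrix.subset_samples(
        matrix.sample_meta["cohort"].str.startswith("denmark").to_numpy())
    result = ts.pairwise_pearson(danish)
    groups = dict(zip(danish.gene_meta.index, danish.gene_meta["group"]))
    result = ts.group_median_correlations(result, groups)
    result.matrix.to_csv(out_dir / "correlation.tsv", sep="\t")
    medians = {
        "within": result.group_medians,
        "cross": {f"{a}|{b}": v for (a, b), v in result.cross_medians.items()},
    }
    (out_dir / "correlation_medians.json").write_text(
        json.dumps(medians, indent=1, sort_keys=True))
    return {"group_medians": result.group_medians,
            "cross_medians": medians["cross"],
            "files": {"correlation": "correlation.tsv",
                      "medians": "correlation_medians.json"}}


def run_gestage(cfg: dict, out_dir: Path) -> dict:
    seed = stage_seed(cfg["seed"], "gestage")
    g = cfg["gestage"]
    matrix, outcomes = _load_matrix(out_dir)
    matrix = qpcr_io.apply_noise_floor(matrix, cfg["simulate"]["lod"])

    train_m = matrix.subset_samples(
        (matrix.sample_meta["cohort"] == "denmark_train").to_numpy())
    val_m = matrix.subset_samples(
        (matrix.sample_meta["cohort"] == "denmark_validation").to_numpy())

    X, y, subjects, _ = gm.build_features(train_m, outcomes)
    cv = gm.CVConfig(k=g["cv_folds"], repeats=g["cv_repeats"], seed=seed)
    selected, trace = gm.best_subset_select(
        X, y, subjects, list(X.columns), cv=cv, max_size=g["max_subset"],
        rf_params={"n_estimators": g["selection_trees"]})
    trace.drop(columns="genes").to_csv(out_dir / "cv_trace.tsv", sep="\t",
                                       index=False)

    rf_final = {"n_estimators": g["final_trees"]}
    cv_pred = gm.cross_validated_predictions(
        train_m, outcomes, selected, k=g["eval_folds"], seed=seed,
        rf_params=rf_final)
    _, y_tr_all, _, meta_tr = gm.build_features(train_m, outcomes,
                                                include_postpartum=True)
    bins_tr = qpcr_io.trimester_bin(meta_tr["ga_weeks"],
                                    meta_tr["postpartum_flag"])
    rmse_tr, r_tr, p_tr = gm.evaluate_fit(cv_pred, y_tr_all, bins_tr)

    model = gm.fit_rf(X, y, selected, rf_final, seed)
    Xv, yv, _, meta_v = gm.build_features(val_m, outcomes,
                                          include_postpartum=True)
    pred_v = gm.predict_rf(model, Xv)
    bins_v = qpcr_io.trimester_bin(meta_v["ga_weeks"],
                                   meta_v["postpartum_flag"])
    rmse_v, r_v, p_v = gm.evaluate_fit(pred_v, yv, bins_v)

    # Table-1 style deviation table over all Danish women (cross-validated
    # estimates for the training cohort, model estimates for validation).
    pm_tr = meta_tr.assign(y_pred=cv_pred.to_numpy())
    pm_v = meta_v.assign(y_pred=pred_v.to_numpy())
    pred_meta = pd.concat([pm_tr, pm_v])
    pred_meta = pred_meta[~pred_meta["postpartum_flag"].astype(bool)]
    table1 = gm.deviation_table(pred_meta, outcomes,
                                ultrasound_sd=g["ultrasound_sd"], seed=seed)
    table1.to_csv(out_dir / "table1.tsv", sep="\t")
    pd.concat([pm_tr.assign(cohort="denmark_train"),
               pm_v.assign(cohort="denmark_validation")]
              ).to_csv(out_dir / "gestage_predictions.csv")
    fit_payload = {
        "selected_genes": selected,
        "train_r": r_tr, "train_p": p_tr,
        "validation_r": r_v, "validation_p": p_v,
        "train_rmse": rmse_tr, "validation_rmse": rmse_v,
        "seed": seed,
    }
    (out_dir / "gestage_fit.json").write_text(
        json.dumps(fit_payload, indent=1, sort_keys=True))
    return {
        "selected_genes": selected,
        "n_selected": len(selected),
        "train_r": r_tr, "validation_r": r_v,
        "train_rmse": rmse_tr, "validation_rmse": rmse_v,
        "deviation_table": table1.reset_index().to_dict(orient="records"),
        "files": {"fit": "gestage_fit.json", "trace": "cv_trace.tsv",
                  "table1": "table1.tsv",
                  "predictions": "gestage_predictions.csv"},
    }


def run_preterm(cfg: dict, out_dir: Path) -> dict:
    seed = stage_seed(cfg["seed"], "preterm")
    p = cfg["preterm"]
    ln2 = math.log(2.0)

    # --- cfRNA-seq discovery: counts from the preterm-enriched cohort -----
    seq_panel, effect_weights = sc.make_seq_panel(p["n_genes"], p["n_effect"])
    sd_log2 = math.sqrt(p["dispersion"]) / ln2 if p["dispersion"] > 0 else 0.3
    lfc = {g: p["effect_g_seq"] * w * sd_log2
           for g, w in effect_weights.items()}
    seq_config = sc.SimulationConfig(
        seed=seed,
        cohorts=(sc.CohortDesign("penn_seq", 15, scheme="sparse", n_draws=1,
                                 window=(17.0, 35.0),
                                 preterm_fraction=8 / 15),),
    )
    counts, seq_outcomes = sc.simulate_count_matrix(
        seq_config, seq_panel, p["dispersion"], effect_log2fc=lfc)
    groups = seq_outcomes.set_index("subject_id").loc[counts.columns, "label"]
    de = pdisc.discover_de_genes(counts, groups.to_numpy(),
                                 alpha=p["alpha_de"], n_perm=p["n_perm"],
                                 seed=seed)
    de.to_csv(out_dir / "de_genes.tsv", sep="\t")
    counts.to_csv(out_dir / "counts.tsv", sep="\t")
    sig = de[de["significant"]]
    de_by_exact = de[de["p_exact"] < p["alpha_de"]]

    # Hierarchical two-group separation on the exact-test hits.
    cluster_genes = de_by_exact.index if len(de_by_exact) >= 2 else de.index
    cpm, _ = pdisc.cpm_normalize(counts)
    logcpm = np.log2(cpm.loc[cluster_genes] + 1.0)
    _, agreement = pdisc.two_group_cluster(logcpm, groups.to_numpy())

    # --- qPCR replication of the sequencing hits (platform concordance) ---
    qpcr_panel = [sc.GeneModel(g, "other", "rise_with_baseline", 0.0, 20.0,
                               0.2, baseline=1.0, noise_sd=p["qpcr_noise_sd"])
                  for g in effect_weights]
    qpcr_config = sc.SimulationConfig(
        seed=stage_seed(cfg["seed"], "preterm_qpcr"),
        cohorts=(sc.CohortDesign("penn_qpcr", 15, scheme="sparse", n_draws=1,
                                 window=(17.0, 35.0),
                                 preterm_fraction=8 / 15),),
    )
    q_samples, q_outcomes = sc.simulate_cohort(qpcr_config, qpcr_panel)
    for gene, w in effect_weights.items():
        q_samples = sc.inject_preterm_effect(
            q_samples, q_outcomes, [gene], p["effect_g_seq"] * w)
    q_matrix = qpcr_io.from_long_frame(q_samples)
    q_vals, q_labels = pc._per_subject_values(q_matrix, q_outcomes)
    pre = q_labels == "preterm"
    log2_per_log10 = math.log2(10.0)
    logfc_qpcr = (q_vals[pre].mean() - q_vals[~pre].mean()) * log2_per_log10
    shared = [g for g in effect_weights if g in de.index]
    conc_r, conc_p = pdisc.platform_concordance(
        de.loc[shared, "logFC"].to_numpy(), logfc_qpcr[shared].to_numpy())

    # --- classifier: screen + 3-gene combination ensemble -----------------
    matrix, outcomes = _load_screen_cohorts(cfg)
    disc_mask = (matrix.sample_meta["cohort"] == "discovery").to_numpy()
    disc_m = matrix.subset_samples(disc_mask)
    val_m = matrix.subset_samples(~disc_mask)
    disc_out = outcomes[outcomes["cohort"] == "discovery"]
    val_out = outcomes[outcomes["cohort"] == "validation"]

    screen = pc.screen_genes(disc_m, disc_out, alpha=p["screen_alpha"],
                             g_min=p["screen_g_min"], n_perm=p["n_perm"],
                             seed=seed)
    screen.table.to_csv(out_dir / "screen.tsv", sep="\t")
    top = screen.top_genes(p["top_n"])
    ensemble = pc.build_ensemble(disc_m, disc_out, top, k=p["combo_k"],
                                 vote_threshold=p["vote_threshold"])
    ensemble.to_json(out_dir / "ensemble.json")
    disc_eval = _self_evaluate(ensemble, disc_m, disc_out)
    val_eval = pc.evaluate_ensemble(ensemble, val_m, val_out)
    roc_points = pd.concat(
        [c.assign(combo="|".join(k)) for k, c in val_eval["roc_curves"].items()])
    roc_points.to_csv(out_dir / "roc_validation.tsv", sep="\t", index=False)

    return {
        "dispersion_estimate": float(de.attrs["dispersion"]),
        "n_de_significant": int(sig.shape[0]),
        "n_de_exact_only": int(de_by_exact.shape[0]),
        "cluster_agreement": agreement,
        "platform_concordance_r": conc_r,
        "platform_concordance_p": conc_p,
        "n_screen_passing": int(screen.table["passes"].sum()),
        "top_genes": top,
        "n_combos": len(ensemble.combos),
        "discovery": _eval_summary(disc_eval),
        "validation": _eval_summary(val_eval),
        "files": {"de": "de_genes.tsv", "counts": "counts.tsv",
                  "screen": "screen.tsv", "ensemble": "ensemble.json",
                  "roc": "roc_validation.tsv"},
    }


def _load_screen_cohorts(cfg: dict):
    """Simulate the qPCR screen cohorts (discovery + validation designs)."""
    p = cfg["preterm"]
    s = cfg["simulate"]
    panel = sc.make_screen_panel()
    config = sc.SimulationConfig(
        seed=stage_seed(cfg["seed"], "preterm_screen"),
        cohorts=(
            sc.CohortDesign("discovery", p["n_discovery"], scheme="sparse",
                            n_draws=1, window=(17.0, 35.0),
                            preterm_fraction=p["n_discovery_preterm"]
                            / p["n_discovery"]),
            sc.CohortDesign("validation", p["n_validation"], scheme="sparse",
                            n_draws=1, window=(22.0, 34.0),
                            preterm_fraction=p["n_validation_preterm"]
                            / p["n_validation"]),
        ),
        preterm_effect_g=s["preterm_effect_g"], lod=s["lod"])
    samples, outcomes = sc.simulate_cohort(config, panel)
    samples = sc.inject_preterm_effect(samples, outcomes,
                                       list(sc.PRETERM_SEVEN),
                                       config.preterm_effect_g, lod=s["lod"])
    groups = {m.gene: m.group for m in panel}
    return qpcr_io.from_long_frame(samples, groups), outcomes


def _self_evaluate(ensemble: pc.ComboEnsemble, matrix, outcomes) -> dict:
    """Training-cohort performance (subject-overlap check bypassed)."""
    import dataclasses
    eval_copy = dataclasses.replace(ensemble, train_subjects=frozenset())
    return pc.evaluate_ensemble(eval_copy, matrix, outcomes)


def _eval_summary(ev: dict) -> dict:
    return {"mean_auc": ev["mean_auc"], "confusion": ev["confusion"],
            "sensitivity": ev["sensitivity"],
            "specificity": ev["specificity"], "ppv": ev["ppv"],
            "n_preterm": ev["n_preterm"], "n_term": ev["n_term"]}


# --------------------------------------------------------------------------
# orchestration

_STAGE_FUNCS = {"simulate": run_simulate, "normalize": run_normalize,
                "correlate": run_correlate, "gestage": run_gestage,
                "preterm": run_preterm}


def run_pipeline(config: str | Path | dict | None = None) -> dict:
    """Run the configured stages in dependency order and build a RunReport.

    The report echoes the config, the per-stage seeds and output files, and
    all summary metrics. Any stage error propagates after earlier stages'
    outputs are safely on disk.
    """
    cfg = load_config(config)
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log")
    handler.setFormatter(logging.Formatter(
        "%(asctime)s [%(name)s] %(levelname)s %(message)s"))
    root = logging.getLogger("cfpreg")
    root.addHandler(handler)
    report: dict = {
        "config": cfg,
        "seeds": {st: stage_seed(cfg["seed"], st) for st in cfg["stages"]},
        "stages": {},
    }
    try:
        for st in STAGES:
            if st not in cfg["stages"]:
                continue
            logger.info("running stage %s", st)
            report["stages"][st] = _STAGE_FUNCS[st](cfg, out_dir)
    finally:
        root.removeHandler(handler)
        handler.close()
    return report


def write_report(report: dict, path: str | Path) -> None:
    """Write the JSON report (canonical key order) + a text summary."""
    path = Path(path)
    path.write_text(json.dumps(report, indent=1, sort_keys=True,
                               default=_jsonify))
    lines = ["run report", "=========="]
    stages = report.get("stages", {})
    if "gestage" in stages:
        g = stages["gestage"]
        lines += ["", "time-to-delivery model",
                  f"  selected genes: {', '.join(g['selected_genes'])}",
                  f"  train r = {g['train_r']:.3f}   "
                  f"validation r = {g['validation_r']:.3f}"]
        for name, rmse in (("train", g["train_rmse"]),
                           ("validation", g["validation_rmse"])):
            vals = "  ".join(f"{b}={rmse[b]:.2f}" for b in
                             ("T1", "T2", "T3", "PP") if not _isnan(rmse[b]))
            lines.append(f"  {name} RMSE (weeks): {vals}")
        lines += ["", "delivery-date deviation (% of women per bin)"]
        header = f"  {'method':22s}" + "".join(
            f"{b:>10s}" for b in gm.DEVIATION_BINS) + f"{'n':>5s}"
        lines.append(header)
        for row in g["deviation_table"]:
            lines.append(f"  {row['method']:22s}" + "".join(
                f"{row[b]:10.0f}" for b in gm.DEVIATION_BINS)
                + f"{row['n']:5d}")
    if "preterm" in stages:
        pt = stages["preterm"]
        lines += ["", "preterm classifier",
                  f"  DE genes (intersection rule): {pt['n_de_significant']}",
                  f"  platform concordance r = "
                  f"{pt['platform_concordance_r']:.2f}",
                  f"  top genes: {', '.join(pt['top_genes'])}",
                  f"  mean AUC discovery = {pt['discovery']['mean_auc']:.2f}"
                  f"   validation = {pt['validation']['mean_auc']:.2f}"]
    path.with_suffix(".txt").write_text("\n".join(lines) + "\n")


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _isnan(x) -> bool:
    return isinstance(x, float) and math.isnan(x)


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, (np.ndarray,)):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
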