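"""Synthetic longitudinal cfRNA cohorts.

Generates plasma cell-free RNA abundance trajectories over gestation for
cohorts of pregnant women, with the statistical structure the downstream
analyses assume: tissue-group-specific temporal shapes (placental and fetal
liver transcripts rise through gestation and collapse postpartum; immune
transcripts keep a maternal baseline; chorionic gonadotropin beta peaks in
the first trimester), multiplicative lognormal measurement noise (additive
Gaussian on the log10 scale), left-censoring at a detection floor, cohort
sampling designs (dense weekly draws vs. sparse draws in a gestational
window), and an optional standardized preterm effect injected into a chosen
gene subset.

All abundances are in log10 relative-abundance units; gestational age is in
decimal weeks. A single integer seed fully determines every output.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

GENE_GROUPS = ("placental", "immune", "fetal_liver", "other")
SHAPES = ("rise", "early_peak", "rise_with_baseline")

#: Nine placenta-specific transcripts used by the gestational-age model.
PLACENTAL_NINE = (
    "CGA", "CAPN6", "CGB", "ALPP", "CSHL1", "PLAC4", "PSG7", "PAPPA", "LGALS14",
)

#: Seven transcripts elevated before spontaneous preterm delivery.
PRETERM_SEVEN = (
    "CLCN3", "DAPP1", "PPBP", "MAP3K7CL", "MOB1B", "RAB27B", "RGS18",
)


@dataclass(frozen=True)
class GeneModel:
    """Parametric expected trajectory for one transcript.

    The expected log10 abundance over gestation is a smooth curve determined
    by ``shape``:

    - ``rise``: logistic increase from (below-detection) baseline, stepping
      back to baseline immediately after delivery. Placental/fetal pattern.
    - ``early_peak``: lognormal-in-time bump peaking at ``onset_week`` in
      the first trimester, then decaying (CGB-like).
    - ``rise_with_baseline``: logistic rise on top of a detectable maternal
      floor, returning to that floor postpartum. Immune/ubiquitous pattern.

    Parameters
    ----------
    gene : str
        Transcript symbol.
    group : str
        Tissue group: placental, immune, fetal_liver or other.
    shape : str
        Trajectory family (above).
    amplitude : float
        Height of the gestational rise/bump, log10 units. Must be >= 0.
    onset_week : float
        Logistic midpoint (rise shapes) or bump peak location (early_peak),
        weeks.
    steepness : float
        Logistic slope (1/weeks) for rise shapes; for early_peak it sets the
        bump width (larger = narrower).
    baseline : float
        Non-pregnant (maternal / postpartum) floor, log10 units.
    noise_sd : float
        Measurement noise SD on the log10 scale. Must be >= 0.
    """

    gene: str
    group: str
    shape: str
    amplitude: float
    onset_week: float
    steepness: float
    baseline: float
    noise_sd: float

    def __post_init__(self) -> None:
        if self.group not in GENE_GROUPS:
            raise ValueError(f"unknown group {self.group!r} for gene {self.gene}")
        if self.shape not in SHAPES:
            raise ValueError(f"unknown shape {self.shape!r} for gene {self.gene}")
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be >= 0 (gene {self.gene})")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0 (gene {self.gene})")


@dataclass(frozen=True)
class CohortDesign:
    """Sampling design for one cohort.

    ``scheme`` is "weekly" (one draw per gestational week from an enrollment
    week drawn in ``enroll_window``, plus one postpartum draw) or "sparse"
    (``n_draws`` draws uniform in ``window`` weeks, truncated at delivery).
    """

    name: str
    n_subjects: int
    scheme: str = "weekly"
    n_draws: int = 1
    window: tuple[float, float] = (17.0, 35.0)
    enroll_window: tuple[int, int] = (5, 12)
    preterm_fraction: float | None = None  # None -> config default

    def __post_init__(self) -> None:
        if self.scheme not in ("weekly", "sparse"):
            raise ValueError(f"unknown sampling scheme {self.scheme!r}")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        lo, hi = self.window
        if not (0 <= lo < hi <= 45):
            raise ValueError("sampling window must lie within [0, 45] weeks")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-level simulation settings.

    Defaults mirror the three-cohort design: a dense weekly-sampled term
    cohort split 21 train / 10 validation, and two sparse preterm-risk
    cohorts (15 and 23 women) with elevated preterm fractions.
    """

    seed: int = 0
    cohorts: tuple[CohortDesign, ...] = (
        CohortDesign("denmark_train", 21, scheme="weekly", preterm_fraction=0.0),
        CohortDesign("denmark_validation", 10, scheme="weekly", preterm_fraction=0.0),
        CohortDesign("penn", 15, scheme="sparse", n_draws=1,
                     window=(17.0, 35.0), preterm_fraction=8 / 15),
        CohortDesign("alabama", 23, scheme="sparse", n_draws=1,
                     window=(22.0, 34.0), preterm_fraction=5 / 23),
    )
    term_delivery_mean: float = 40.0
    term_delivery_sd: float = 1.25
    preterm_fraction: float = 0.0
    preterm_delivery_low: float = 29.0
    preterm_delivery_high: float = 36.5
    preterm_effect_genes: tuple[str, ...] = PRETERM_SEVEN
    preterm_effect_g: float = 1.2
    lod: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.preterm_fraction <= 1.0:
            raise ValueError("preterm_fraction must be in [0, 1]")
        if not self.preterm_delivery_high < 37.0:
            raise ValueError("preterm deliveries must occur before 37 weeks")
        if not 0.0 < self.preterm_delivery_low < self.preterm_delivery_high:
            raise ValueError("invalid preterm delivery window")
        for c in self.cohorts:
            f = self.preterm_fraction if c.preterm_fraction is None else c.preterm_fraction
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"preterm fraction for cohort {c.name} not in [0, 1]")


def default_panel() -> list[GeneModel]:
    """51-transcript default qPCR panel.

    Synthetic stand-in for the study panel: the nine named placental
    gestational-age genes (CGB as a first-trimester peak), extra placental
    and fetal-liver risers, immune transcripts with maternal baselines, and
    ubiquitous transcripts including the seven preterm-associated genes.
    Parameter values are chosen to be qPCR-realistic (rises of 1.5-2.5
    decades, log10 noise SD ~0.2, detection floor at 0).
    """
    panel: list[GeneModel] = []

    placental = {
        "CGA": (2.5, 14.0, 0.22), "CAPN6": (1.8, 24.0, 0.25),
        "ALPP": (2.0, 28.0, 0.30), "CSHL1": (2.2, 22.0, 0.24),
        "PLAC4": (1.9, 26.0, 0.28), "PSG7": (2.1, 18.0, 0.22),
        "PAPPA": (2.0, 20.0, 0.20), "LGALS14": (1.7, 27.0, 0.30),
        "PLAC1": (1.8, 25.0, 0.26), "PSG1": (2.0, 19.0, 0.22),
        "TFPI2": (1.6, 29.0, 0.28),
    }
    for g, (amp, onset, steep) in placental.items():
        panel.append(GeneModel(g, "placental", "rise", amp, onset, steep,
                               baseline=-1.2, noise_sd=0.20))
    # CGB: peaks in the first trimester, decays, vanishes postpartum.
    panel.append(GeneModel("CGB", "placental", "early_peak", 2.6, 9.0, 2.2,
                           baseline=-1.2, noise_sd=0.22))

    fetal_rise = {
        "AFP": (2.2, 24.0, 0.22), "APOA2": (1.6, 26.0, 0.24),
        "AHSG": (1.5, 28.0, 0.26), "SERPINC1": (1.4, 27.0, 0.24),
        "ITIH2": (1.3, 29.0, 0.26), "AMBP": (1.5, 25.0, 0.24),
    }
    for g, (amp, onset, steep) in fetal_rise.items():
        panel.append(GeneModel(g, "fetal_liver", "rise", amp, onset, steep,
                               baseline=-1.2, noise_sd=0.22))
    # Fetal-liver genes also expressed in the adult liver: small maternal floor.
    for g, (amp, onset, steep) in {"ALB": (1.2, 26.0, 0.24),
                                   "FGB": (1.1, 27.0, 0.24),
                                   "HPX": (1.0, 28.0, 0.26)}.items():
        panel.append(GeneModel(g, "fetal_liver", "rise_with_baseline",
                               amp, onset, steep, baseline=0.5, noise_sd=0.22))

    immune = {
        "CD8A": (0.6, 22.0, 0.20), "CD19": (0.5, 24.0, 0.20),
        "CCL2": (0.8, 20.0, 0.18), "IL2RB": (0.6, 23.0, 0.20),
        "FCGR3A": (0.5, 25.0, 0.22), "NKG7": (0.7, 21.0, 0.20),
        "GZMB": (0.6, 26.0, 0.22), "CXCL8": (0.8, 19.0, 0.18),
        "S100A8": (0.9, 18.0, 0.18), "LCK": (0.5, 24.0, 0.20),
    }
    for g, (amp, onset, steep) in immune.items():
        panel.append(GeneModel(g, "immune", "rise_with_baseline",
                               amp, onset, steep, baseline=0.8, noise_sd=0.18))

    for g in PRETERM_SEVEN:
        panel.append(GeneModel(g, "other", "rise_with_baseline",
                               0.3, 22.0, 0.20, baseline=1.0, noise_sd=0.20))
    ubiquitous = ("ACTB", "GAPDH", "B2M", "TPT1", "FTL", "RPL23", "EEF1A1",
                  "UBC", "PGK1", "YWHAZ", "POLR2A", "TBP", "HPRT1")
    for g in ubiquitous:
        panel.append(GeneModel(g, "other", "rise_with_baseline",
                               0.15, 20.0, 0.20, baseline=1.2, noise_sd=0.18))

    assert len(panel) == 51
    return panel


def gene_trajectory(model: GeneModel, ga, ga_del: float):
    """Expected log10 abundance at gestational age ``ga`` (weeks).

    Vectorized over ``ga``. Postpartum (ga > ga_del) the curve steps down to
    ``model.baseline`` for every shape: pregnancy-derived signal collapses
    at delivery, maternal transcripts keep their floor.
    """
    ga_arr = np.asarray(ga, dtype=float)
    if np.any(ga_arr < 0):
        raise ValueError("gestational age must be >= 0 weeks")
    if ga_del <= 0:
        raise ValueError("delivery gestational age must be > 0 weeks")

    if model.shape in ("rise", "rise_with_baseline"):
        curve = model.baseline + model.amplitude / (
            1.0 + np.exp(-model.steepness * (ga_arr - model.onset_week)))
    elif model.shape == "early_peak":
        with np.errstate(divide="ignore"):
            logt = np.where(ga_arr > 0, np.log(np.maximum(ga_arr, 1e-12)
                                               / model.onset_week), -np.inf)
        curve = model.baseline + model.amplitude * np.exp(
            -0.5 * (model.steepness * logt) ** 2)
    else:  # pragma: no cover - guarded by GeneModel validation
        raise AssertionError(model.shape)

    out = np.where(ga_arr > ga_del, model.baseline, curve)
    return float(out) if np.isscalar(ga) or out.ndim == 0 else out


def _draw_delivery(rng: np.random.Generator, config: SimulationConfig,
                   preterm: bool) -> float:
    if preterm:
        return float(rng.uniform(config.preterm_delivery_low,
                                 config.preterm_delivery_high))
    # Truncated normal on [37, mean + 4 sd].
    a = (37.0 - config.term_delivery_mean) / config.term_delivery_sd
    return float(stats.truncnorm.rvs(a, 4.0, loc=config.term_delivery_mean,
                                     scale=config.term_delivery_sd,
                                     random_state=rng))


def _preterm_flags(rng: np.random.Generator, config: SimulationConfig,
                   design: CohortDesign) -> np.ndarray:
    """Exact preterm count per cohort (round(fraction * n)), shuffled."""
    frac = (config.preterm_fraction if design.preterm_fraction is None
            else design.preterm_fraction)
    n_pre = int(round(frac * design.n_subjects))
    flags = np.zeros(design.n_subjects, dtype=bool)
    flags[:n_pre] = True
    return rng.permutation(flags)


def _subject_draws(rng: np.random.Generator, design: CohortDesign,
                   ga_del: float) -> tuple[np.ndarray, np.ndarray]:
    """Return (ga_weeks, postpartum_flag) draw times for one subject."""
    if design.scheme == "weekly":
        enroll = int(rng.integers(design.enroll_window[0],
                                  design.enroll_window[1] + 1))
        ante = np.arange(enroll, math.floor(ga_del) + 1, dtype=float)
        ga = np.append(ante, ga_del + 1.0)  # one postpartum draw
        pp = np.zeros(ga.size, dtype=bool)
        pp[-1] = True
        return ga, pp
    lo, hi = design.window
    ga = np.sort(rng.uniform(lo, hi, size=design.n_draws))
    if np.any(ga >= ga_del):
        logger.warning(
            "cohort %s: sampling window (%.1f, %.1f) exceeds delivery at "
            "%.1f weeks; draws truncated at delivery", design.name, lo, hi, ga_del)
        ga = np.where(ga >= ga_del, ga_del - 0.5, ga)
        ga = np.maximum.accumulate(ga)  # keep sorted after truncation
    return ga, np.zeros(ga.size, dtype=bool)


def simulate_cohort(config: SimulationConfig, genes: list[GeneModel],
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate all cohorts in ``config`` for the panel ``genes``.

    Returns
    -------
    samples : DataFrame
        Long format, one row per (subject, draw, gene): subject_id, cohort,
        ga_weeks, postpartum_flag, gene, value_log10, detected. Values below
        the detection floor are censored to ``config.lod`` and flagged
        undetected.
    outcomes : DataFrame
        One row per subject: subject_id, cohort, ga_delivery, label
        (term/preterm), parity, progesterone.
    """
    if not genes:
        raise ValueError("gene panel must be nonempty")
    rng = np.random.default_rng(config.seed)
    sample_rows: list[pd.DataFrame] = []
    outcome_rows: list[dict] = []
    subj_counter = itertools.count(1)
    gene_syms = [m.gene for m in genes]

    for design in config.cohorts:
        flags = _preterm_flags(rng, config, design)
        for preterm in flags:
            sid = f"W{next(subj_counter):04d}"
            ga_del = _draw_delivery(rng, config, preterm)
            ga, pp = _subject_draws(rng, design, ga_del)
            exp = np.column_stack(
                [gene_trajectory(m, ga, ga_del) for m in genes])
            noise = rng.normal(
                0.0, 1.0, size=exp.shape) * np.array([m.noise_sd for m in genes])
            vals = exp + noise
            detected = vals >= config.lod
            vals = np.where(detected, vals, config.lod)
            df = pd.DataFrame({
                "subject_id": np.repeat(sid, ga.size * len(genes)),
                "cohort": design.name,
                "ga_weeks": np.repeat(ga, len(genes)),
                "postpartum_flag": np.repeat(pp, len(genes)),
                "gene": np.tile(gene_syms, ga.size),
                "value_log10": vals.ravel(),
                "detected": detected.ravel(),
            })
            sample_rows.append(df)
            outcome_rows.append({
                "subject_id": sid,
                "cohort": design.name,
                "ga_delivery": ga_del,
                "label": "preterm" if ga_del < 37.0 else "term",
                "parity": int(rng.integers(0, 3)),
                "progesterone": bool(preterm and rng.uniform() < 0.5),
            })

    samples = pd.concat(sample_rows, ignore_index=True)
    outcomes = pd.DataFrame(outcome_rows)
    return samples, outcomes


def inject_preterm_effect(samples: pd.DataFrame, outcomes: pd.DataFrame,
                          genes: list[str], g_target: float,
                          lod: float | None = None) -> pd.DataFrame:
    """Shift preterm subjects' values for ``genes`` by a standardized amount.

    The shift is ``g_target`` times the pooled (preterm/term) per-gene SD of
    the unmodified table, so the realized Hedges' g is approximately
    ``g_target``. Term subjects are untouched. If ``lod`` is given, shifted
    values are re-censored against it and the detection flag refreshed.
    """
    missing = set(genes) - set(samples["gene"].unique())
    if missing:
        raise ValueError(f"genes not present in sample table: {sorted(missing)}")
    labels = outcomes.set_index("subject_id")["label"]
    unknown = set(samples["subject_id"]) - set(labels.index)
    if unknown:
        raise ValueError(f"samples without outcomes: {sorted(unknown)[:5]}")
    sample_label = samples["subject_id"].map(labels)
    if not (sample_label == "preterm").any():
        raise ValueError("no preterm subjects in outcome table")
    if not (sample_label == "term").any():
        raise ValueError("no term subjects in outcome table")

    out = samples.copy()
    for gene in genes:
        mask = out["gene"] == gene
        vals = out.loc[mask, "value_log10"]
        grp = sample_label[mask]
        v1 = vals[grp == "preterm"]
        v2 = vals[grp == "term"]
        n1, n2 = len(v1), len(v2)
        pooled = math.sqrt(((n1 - 1) * v1.var(ddof=1) + (n2 - 1) * v2.var(ddof=1))
                           / (n1 + n2 - 2))
        out.loc[mask & (sample_label == "preterm"), "value_log10"] += \
            g_target * pooled
    if lod is not None:
        below = out["value_log10"] < lod
        out.loc[below, "value_log10"] = lod
        out.loc[below, "detected"] = False
        out.loc[~below, "detected"] = True
    return out


def simulate_count_matrix(config: SimulationConfig, genes: list[GeneModel],
                          dispersion: float, *, mean_library: float = 2.0e5,
                          lib_sigma: float = 0.25,
                          effect_log2fc: float | dict[str, float] = 0.0,
                          effect_genes: tuple[str, ...] | None = None,
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate an integer genes x samples count matrix (cfRNA-seq stand-in).

    One library per sparse-cohort draw (weekly cohorts are skipped: the
    sequencing stage profiles the risk cohorts). Per-gene means are
    proportional to ``10**trajectory`` scaled to a lognormal library size
    (geometric SD ``exp(lib_sigma)``);
    counts are negative binomial with common dispersion ``dispersion``
    (variance mu + dispersion * mu^2; 0 degenerates to Poisson). Preterm
    libraries have the means of ``effect_genes`` multiplied by
    ``2**effect_log2fc``.

    Returns (counts, outcomes) where counts columns are sample ids and
    outcomes carries the subject metadata (label, ga_delivery, ...).
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if not genes:
        raise ValueError("gene panel must be nonempty")
    if isinstance(effect_log2fc, dict):
        lfc_map = dict(effect_log2fc)
    else:
        eff = set(effect_genes if effect_genes is not None
                  else config.preterm_effect_genes)
        lfc_map = {g: float(effect_log2fc) for g in eff}
    rng = np.random.default_rng(config.seed)
    gene_syms = [m.gene for m in genes]
    lfc_vec = np.array([lfc_map.get(g, 0.0) for g in gene_syms])
    any_effect = bool(np.any(lfc_vec != 0.0))

    cols: dict[str, np.ndarray] = {}
    outcome_rows: list[dict] = []
    subj_counter = itertools.count(1)
    for design in config.cohorts:
        if design.scheme != "sparse":
            continue
        flags = _preterm_flags(rng, config, design)
        for preterm in flags:
            sid = f"W{next(subj_counter):04d}"
            ga_del = _draw_delivery(rng, config, preterm)
            ga, _ = _subject_draws(rng, design, ga_del)
            ga_draw = float(ga[0])
            expr = np.array([10.0 ** gene_trajectory(m, ga_draw, ga_del)
                             for m in genes])
            if preterm and any_effect:
                expr = expr * 2.0 ** lfc_vec
            lib = mean_library * rng.lognormal(0.0, lib_sigma)
            mu = expr / expr.sum() * lib
            if dispersion == 0.0:
                counts = rng.poisson(mu)
            else:
                r = 1.0 / dispersion
                counts = rng.negative_binomial(r, r / (r + mu))
            cols[sid] = counts
            outcome_rows.append({
                "subject_id": sid, "cohort": design.name,
                "ga_delivery": ga_del, "ga_weeks": ga_draw,
                "label": "preterm" if ga_del < 37.0 else "term",
                "parity": int(rng.integers(0, 3)),
                "progesterone": bool(preterm and rng.uniform() < 0.5),
            })
    counts = pd.DataFrame(cols, index=gene_syms)
    return counts, pd.DataFrame(outcome_rows)


def make_seq_panel(n_genes: int = 300, n_effect: int = 38,
                   ) -> tuple[list[GeneModel], dict[str, float]]:
    """Gene set for the cfRNA-seq count stage, with designated effect genes.

    The first ``n_effect`` genes (the seven preterm panel transcripts plus
    numbered SPD symbols) are the differential-expression targets; each gets
    a deterministic relative effect weight in [0.4, 1.6] so fold-changes
    vary gene to gene as in real screens, where hits span small to several-
    fold differences. The remaining genes are flat
    background transcripts with abundances cycling over roughly two decades
    so the simulated libraries have a realistic dynamic range.

    Returns (panel, {effect gene: relative weight}).
    """
    if n_effect < len(PRETERM_SEVEN):
        raise ValueError("n_effect must cover the seven panel transcripts")
    if n_genes < n_effect:
        raise ValueError("n_genes must be >= n_effect")
    effect = list(PRETERM_SEVEN) + [
        f"SPD{i:02d}" for i in range(len(PRETERM_SEVEN) + 1, n_effect + 1)]
    background = [f"BG{i:04d}" for i in range(1, n_genes - n_effect + 1)]
    panel = []
    for i, g in enumerate(effect + background):
        baseline = 0.8 + 1.6 * ((i * 7) % 11) / 10.0   # 0.8 .. 2.4 decades
        panel.append(GeneModel(g, "other", "rise_with_baseline",
                               0.0, 20.0, 0.2, baseline=baseline,
                               noise_sd=0.2))
    weights = {g: 0.4 + 1.2 * ((i * 5) % 7) / 6.0 for i, g in enumerate(effect)}
    return panel, weights


def make_screen_panel(n_null: int = 31, effect_noise_sd: float = 0.25,
                      ) -> list[GeneModel]:
    """38-transcript qPCR screen panel: the seven preterm markers + nulls.

    Used by the classifier stage; the preterm effect itself is injected
    afterwards with :func:`inject_preterm_effect`, so here all genes are
    flat maternal transcripts.
    """
    panel = [GeneModel(g, "other", "rise_with_baseline", 0.1, 22.0, 0.2,
                       baseline=1.0, noise_sd=effect_noise_sd)
             for g in PRETERM_SEVEN]
    panel += [GeneModel(f"CTRL{i:02d}", "other", "rise_with_baseline",
                        0.1, 22.0, 0.2,
                        baseline=0.8 + 0.8 * ((i * 3) % 9) / 8.0,
                        noise_sd=0.25)
              for i in range(1, n_null + 1)]
    return panel


def make_recovery_panel(n_signal: int = 3, n_null: int = 9,
                        noise_sd: float = 0.15) -> list[GeneModel]:
    """Small panel where exactly ``n_signal`` genes carry gestational signal.

    Signal genes are placental risers with staggered onsets (early, mid,
    late gestation) so each one is informative over a different window; null
    genes are flat maternal transcripts (amplitude 0). Used by model
    recovery studies.
    """
    onsets = np.linspace(12.0, 32.0, n_signal)
    panel = [GeneModel(f"SIG{i+1}", "placental", "rise", 2.0, float(o), 0.30,
                       baseline=-1.2, noise_sd=noise_sd)
             for i, o in enumerate(onsets)]
    panel += [GeneModel(f"NULL{i+1:02d}", "other", "rise_with_baseline",
                        0.0, 20.0, 0.2, baseline=1.0, noise_sd=0.2)
              for i in range(n_null)]
    return panel
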