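"""Tables, Ct conversion, detection floor and trimester binning.

The pipeline's central currency is the :class:`ExpressionMatrix`: a samples
x genes matrix of log10 relative abundances with a congruent detection mask
and per-row / per-column metadata. This module assembles it from long-format
delimited tables, converts raw qPCR cycle values to relative abundance,
applies the detection noise floor, bins samples into trimesters, and
summarises per-gene weekly trajectories (mean +/- SEM).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LONG_COLUMNS = ("subject_id", "cohort", "ga_weeks", "postpartum_flag",
                "gene", "value_log10", "detected")
OUTCOME_COLUMNS = ("subject_id", "cohort", "ga_delivery", "label",
                   "parity", "progesterone")

TERM_CUTOFF_WEEKS = 37.0


class SchemaError(ValueError):
    """A required column is missing or a table violates its contract."""


@dataclass
class ExpressionMatrix:
    """Samples x genes log10 relative abundance with a detection mask.

    Attributes
    ----------
    values : DataFrame
        Rows indexed by sample id, columns by gene symbol.
    detected : DataFrame
        Boolean, same shape/labels as ``values``.
    sample_meta : DataFrame
        Indexed like ``values`` rows: subject_id, cohort, ga_weeks,
        postpartum_flag.
    gene_meta : DataFrame
        Indexed like ``values`` columns: tissue ``group`` per gene.
    """

    values: pd.DataFrame
    detected: pd.DataFrame
    sample_meta: pd.DataFrame
    gene_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.shape != self.detected.shape:
            raise SchemaError("values and detection mask differ in shape")
        if not self.values.index.equals(self.detected.index) or \
                not self.values.columns.equals(self.detected.columns):
            raise SchemaError("values and detection mask differ in labels")
        if not self.values.index.equals(self.sample_meta.index):
            raise SchemaError("sample_meta index does not match values rows")
        if not self.values.columns.equals(self.gene_meta.index):
            raise SchemaError("gene_meta index does not match values columns")
        if (self.sample_meta["ga_weeks"] < 0).any():
            raise SchemaError("negative gestational ages in sample metadata")

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.detected.copy(),
                                self.sample_meta.copy(), self.gene_meta.copy())

    def subset_samples(self, mask) -> "ExpressionMatrix":
        """Row subset by boolean mask aligned with the sample axis."""
        mask = np.asarray(mask, dtype=bool)
        return ExpressionMatrix(self.values.loc[mask], self.detected.loc[mask],
                                self.sample_meta.loc[mask], self.gene_meta)

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[genes], self.detected[genes],
                                self.sample_meta, self.gene_meta.loc[genes])


def from_long_frame(df: pd.DataFrame,
                    gene_groups: dict[str, str] | None = None) -> ExpressionMatrix:
    """Pivot a long-format sample table into an :class:`ExpressionMatrix`.

    Genes absent from ``gene_groups`` are tolerated with group "other" and a
    logged warning. Duplicate (subject, ga_weeks, gene) triples are an error.
    """
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"long table missing required column(s): {missing}")
    dup = df.duplicated(subset=["subject_id", "ga_weeks", "gene"], keep=False)
    if dup.any():
        offenders = (df.loc[dup, ["subject_id", "ga_weeks", "gene"]]
                     .drop_duplicates().head(10))
        raise SchemaError(
            "duplicated (subject, ga_weeks, gene) triples:\n"
            f"{offenders.to_string(index=False)}")
    if (df["ga_weeks"] < 0).any():
        raise SchemaError("negative ga_weeks in long table")

    work = df.copy()
    work["sample_id"] = (work["subject_id"].astype(str) + "@" +
                         work["ga_weeks"].map(lambda g: f"{g:.2f}"))
    values = work.pivot(index="sample_id", columns="gene", values="value_log10")
    detected = work.pivot(index="sample_id", columns="gene",
                          values="detected").astype(bool)
    meta = (work.drop_duplicates("sample_id")
            .set_index("sample_id")[["subject_id", "cohort", "ga_weeks",
                                     "postpartum_flag"]])
    meta = meta.loc[values.index]

    groups = {} if gene_groups is None else dict(gene_groups)
    unknown = [g for g in values.columns if g not in groups]
    if gene_groups is not None and unknown:
        logger.warning("genes without annotation, assigned group 'other': %s",
                       unknown)
    gene_meta = pd.DataFrame(
        {"group": [groups.get(g, "other") for g in values.columns]},
        index=values.columns)
    return ExpressionMatrix(values, detected, meta, gene_meta)


def to_long_frame(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Inverse of :func:`from_long_frame` (lossless for finite values)."""
    stacked = matrix.values.stack().rename("value_log10").reset_index()
    det = matrix.detected.stack().rename("detected").reset_index()
    stacked["detected"] = det["detected"]
    meta = matrix.sample_meta.reset_index()
    out = stacked.merge(meta, on="sample_id")
    return out[list(LONG_COLUMNS)]


def _read_delimited(path: str | Path, delimiter: str | None) -> pd.DataFrame:
    if delimiter is not None:
        return pd.read_csv(path, sep=delimiter)
    return pd.read_csv(path, sep=None, engine="python")  # sniff , vs \t


def read_long_table(path: str | Path, gene_groups: dict[str, str] | None = None,
                    delimiter: str | None = None) -> ExpressionMatrix:
    """Read a long-format CSV/TSV sample table (delimiter sniffed)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return from_long_frame(_read_delimited(path, delimiter), gene_groups)


def write_long_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    to_long_frame(matrix).to_csv(path, index=False)


def read_outcomes(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    """Read the subject-outcome table and check the preterm label contract.

    A subject is preterm iff delivery occurred before 37 weeks gestation.
    """
    df = _read_delimited(path, delimiter)
    missing = [c for c in ("subject_id", "ga_delivery", "label")
               if c not in df.columns]
    if missing:
        raise SchemaError(f"outcome table missing required column(s): {missing}")
    bad = df[(df["label"] == "preterm") != (df["ga_delivery"] < TERM_CUTOFF_WEEKS)]
    if len(bad):
        raise SchemaError(
            "label/ga_delivery mismatch (preterm <=> delivery < 37 wk) for "
            f"subjects: {bad['subject_id'].tolist()[:10]}")
    return df


def write_matrix(matrix: ExpressionMatrix, prefix: str | Path) -> None:
    """Persist as <prefix>.tsv (values), <prefix>.detected.tsv, sidecar JSON."""
    prefix = Path(prefix)
    matrix.values.to_csv(prefix.with_suffix(".tsv"), sep="\t")
    matrix.detected.to_csv(prefix.with_suffix(".detected.tsv"), sep="\t")
    sidecar = {
        "sample_meta": matrix.sample_meta.reset_index().to_dict(orient="list"),
        "gene_meta": matrix.gene_meta.reset_index()
                     .rename(columns={"index": "gene"}).to_dict(orient="list"),
        "convention": "log10 relative abundance (delta-Ct vs reference assay)",
    }
    prefix.with_suffix(".meta.json").write_text(
        json.dumps(sidecar, indent=1, sort_keys=True))


def ct_to_relative_abundance(ct, ct_ref):
    """Relative abundance 2**(ct_ref - ct) (one PCR cycle = one doubling)."""
    ct = np.asarray(ct, dtype=float)
    ct_ref = np.asarray(ct_ref, dtype=float)
    if not (np.all(np.isfinite(ct)) and np.all(np.isfinite(ct_ref))):
        raise ValueError("Ct values must be finite")
    out = 2.0 ** (ct_ref - ct)
    return float(out) if out.ndim == 0 else out


def apply_noise_floor(matrix: ExpressionMatrix, lod: float) -> ExpressionMatrix:
    """Left-censor values below ``lod`` and flag them undetected. Idempotent."""
    if not np.isfinite(lod):
        raise ValueError("lod must be finite")
    out = matrix.copy()
    below = out.values < lod
    out.values[below] = lod
    out.detected[below] = False
    return out


def trimester_bin(ga_weeks, postpartum_flag):
    """Bin samples into T1 (<=13 wk), T2 (13, 27], T3 (>27) or PP.

    Boundary samples go to the earlier trimester (standard obstetric
    convention); any postpartum draw is PP regardless of its week value.
    """
    ga = np.asarray(ga_weeks, dtype=float)
    pp = np.asarray(postpartum_flag, dtype=bool)
    if np.any(ga < 0):
        raise ValueError("gestational age must be >= 0 weeks")
    out = np.where(ga <= 13.0, "T1", np.where(ga <= 27.0, "T2", "T3"))
    out = np.where(pp, "PP", out)
    if np.isscalar(ga_weeks) or out.ndim == 0:
        return str(out)
    return out


def trajectory_summary(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene, per-gestational-week mean and SEM of log10 abundance.

    Weeks are integer floors of ``ga_weeks``. Weeks observed in a single
    sample get SEM 0 and ``single_obs=True``.
    """
    if matrix.values.size == 0:
        raise ValueError("empty expression matrix")
    week = np.floor(matrix.sample_meta["ga_weeks"]).astype(int)
    pp = matrix.sample_meta["postpartum_flag"].astype(bool)
    long = matrix.values.copy()
    long["week"] = week.values
    long["postpartum"] = pp.values
    melted = long.melt(id_vars=["week", "postpartum"], var_name="gene",
                       value_name="value")
    grp = melted.groupby(["gene", "week", "postpartum"])["value"]
    summary = grp.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
    summary["sd"] = summary["sd"].fillna(0.0)
    summary["sem"] = summary["sd"] / np.sqrt(summary["n"])
    summary["single_obs"] = summary["n"] == 1
    return summary.drop(columns="sd").reset_index()
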