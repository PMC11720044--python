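"""Readers and writers for the plain-text formats the pipeline consumes.

All tabular inputs are TSV (registry incidence tables, organ kinetics,
expression matrices with sample metadata, ligand-receptor annotations,
population cohorts); fitted curves and models round-trip through JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .age_curves import AgeSeries, FittedCurve
from .errors import ValidationError
from .risk_model import OrganKinetics
from .signal_discovery import ExpressionStudy

__all__ = [
    "read_age_series",
    "write_age_series",
    "read_organ_kinetics",
    "read_expression_study",
    "write_expression_study",
    "read_ligand_receptor_table",
    "read_cohort",
    "write_curve_json",
    "read_curve_json",
]


def read_age_series(path, age_col: str = "age", value_col: str = "rate",
                    label: str | None = None, sex: str | None = None) -> AgeSeries:
    """Load an (age, value) series from a TSV incidence-style table.

    If the table has a ``sex`` column and ``sex`` is given, rows are filtered
    to that sex first.
    """
    df = pd.read_csv(path, sep="\t")
    if sex is not None and "sex" in df.columns:
        df = df[df["sex"] == sex]
    df = df.sort_values(age_col)
    return AgeSeries(
        ages=df[age_col].to_numpy(dtype=float),
        values=df[value_col].to_numpy(dtype=float),
        label=label if label is not None else Path(path).stem,
        sex=sex or "both",
    )


def write_age_series(series: AgeSeries, path, value_col: str = "rate") -> None:
    pd.DataFrame({
        "age": series.ages, value_col: series.values, "sex": series.sex,
    }).to_csv(path, sep="\t", index=False)


def read_organ_kinetics(path) -> list[OrganKinetics]:
    """Load an organ kinetics table with columns organ, s, d_yr."""
    df = pd.read_csv(path, sep="\t")
    for col in ("organ", "s", "d_yr"):
        if col not in df.columns:
            raise ValidationError(f"organ kinetics table is missing column {col!r}")
    return [OrganKinetics(organ=r.organ, s=float(r.s), d_yr=float(r.d_yr))
            for r in df.itertuples()]


def read_expression_study(tpm_path, meta_path, counts_path=None) -> ExpressionStudy:
    """Load a genes x samples TPM TSV plus a per-sample metadata TSV."""
    tpm = pd.read_csv(tpm_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    counts = pd.read_csv(counts_path, sep="\t", index_col=0) if counts_path else None
    return ExpressionStudy(tpm=tpm, sample_meta=meta, counts=counts)


def write_expression_study(study: ExpressionStudy, tpm_path, meta_path,
                           counts_path=None) -> None:
    study.tpm.to_csv(tpm_path, sep="\t")
    study.sample_meta.to_csv(meta_path, sep="\t")
    if counts_path is not None and study.counts is not None:
        study.counts.to_csv(counts_path, sep="\t")


LIGAND_RECEPTOR_COLUMNS = ("ligand", "receptor", "bloodborne")


def read_ligand_receptor_table(path) -> pd.DataFrame:
    """Load a ligand-receptor annotation TSV.

    Required columns: ligand, receptor, bloodborne; optional: organ, role,
    brain_flag, hypothalamus_flag (used for signal-source construction).
    """
    df = pd.read_csv(path, sep="\t")
    for col in LIGAND_RECEPTOR_COLUMNS:
        if col not in df.columns:
            raise ValidationError(f"ligand-receptor table is missing column {col!r}")
    return df


def read_cohort(path) -> pd.DataFrame:
    """Load a per-individual cohort TSV (age, sex, analytes, markers)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("age", "sex"):
        if col not in df.columns:
            raise ValidationError(f"cohort table is missing column {col!r}")
    return df


def write_curve_json(curve: FittedCurve, path) -> None:
    Path(path).write_text(curve.to_json())


def read_curve_json(path) -> FittedCurve:
    return FittedCurve.from_dict(json.loads(Path(path).read_text()))
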