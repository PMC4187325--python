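"""Tab-delimited readers and writers for the pipeline's file dialect.

All tables are plain TSV with ``NA`` for missing values. The expression
matrix has the probe id in the first column and one column per sample;
values round-trip at full double precision (17 significant digits).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .containers import CLINICAL_COLUMNS, ExpressionMatrix, validate_clinical

_FLOAT_FMT = "%.17g"


def write_expression(x: ExpressionMatrix, values_path, probes_path) -> None:
    """Write the value matrix and probe annotation of ``x`` to TSV files."""
    df = x.values.copy()
    df.index.name = "probe_id"
    df.to_csv(values_path, sep="\t", na_rep="NA", float_format=_FLOAT_FMT)
    ann = x.probe_annotation.copy()
    ann.index.name = "probe_id"
    ann.to_csv(probes_path, sep="\t", na_rep="NA")


def read_expression(values_path, probes_path, sample_annotation: pd.DataFrame) -> ExpressionMatrix:
    """Read a TSV expression matrix plus probe annotation.

    ``sample_annotation`` (typically sliced from the clinical table) supplies
    the study/tissue columns for each sample.
    """
    values = pd.read_csv(values_path, sep="\t", index_col="probe_id", na_values=["NA"])
    ann = pd.read_csv(probes_path, sep="\t", index_col="probe_id", na_values=["NA"])
    ann["is_control"] = ann["is_control"].astype(bool)
    return ExpressionMatrix(values, ann, sample_annotation.loc[values.columns])


def write_clinical(clinical: pd.DataFrame, path) -> None:
    df = validate_clinical(clinical).copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", na_rep="NA", float_format=_FLOAT_FMT)


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        index_col="sample_id",
        na_values=["NA"],
        keep_default_na=False,
        dtype={"pair_id": "string", "study_id": "string", "tissue": "string",
               "recurrence_type": "string"},
    )
    # header-only files come back with object columns; coerce numerics
    for col in df.columns:
        if col not in ("study_id", "tissue", "pair_id", "recurrence_type"):
            df[col] = pd.to_numeric(df[col], errors="coerce")
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"clinical file missing columns: {missing}")
    return df


def sample_annotation_from_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    return clinical[["study_id", "tissue", "pair_id"]].copy()


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", na_rep="NA", index=index, float_format=_FLOAT_FMT)


def read_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col, na_values=["NA"])
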