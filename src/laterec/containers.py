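"""Core in-memory containers for multi-study expression compendia.

An :class:`ExpressionMatrix` holds log-scale expression values (probes x
samples) together with probe-level annotation (gene symbol, control-probe
flag) and sample-level annotation (study of origin, tissue compartment).
Clinical outcome tables are plain :class:`pandas.DataFrame` objects indexed
by sample id and validated with :func:`validate_clinical`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "CLINICAL_COLUMNS",
    "validate_clinical",
]

#: Columns every clinical table must carry. Missing values are allowed and
#: encoded as NaN in memory ("NA" on disk).
CLINICAL_COLUMNS = [
    "study_id",
    "tissue",
    "pair_id",
    "rfs_years",
    "rfs_event",
    "dmfs_years",
    "dmfs_event",
    "os_years",
    "os_event",
    "recurrence_type",
    "node_status",
    "systemic_treated",
    "size_cm",
    "grade",
    "age",
    "ihc_er",
    "ihc_pr",
    "ihc_her2",
]

TISSUES = ("bulk", "epithelium", "stroma")


@dataclass
class ExpressionMatrix:
    """Probes x samples log-scale expression with annotations.

    Parameters
    ----------
    values
        DataFrame of expression values; index = probe ids, columns = sample
        ids. Both must be unique.
    probe_annotation
        DataFrame indexed by probe id with at least ``gene_symbol`` and
        ``is_control`` (bool) columns. Reindexed to ``values.index``.
    sample_annotation
        DataFrame indexed by sample id with at least ``study_id`` and
        ``tissue`` columns. Reindexed to ``values.columns``.
    """

    values: pd.DataFrame
    probe_annotation: pd.DataFrame
    sample_annotation: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate probe ids in expression matrix")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids in expression matrix")
        for col in ("gene_symbol", "is_control"):
            if col not in self.probe_annotation.columns:
                raise ValueError(f"probe_annotation missing column {col!r}")
        for col in ("study_id", "tissue"):
            if col not in self.sample_annotation.columns:
                raise ValueError(f"sample_annotation missing column {col!r}")
        missing = self.values.index.difference(self.probe_annotation.index)
        if len(missing):
            raise ValueError(f"{len(missing)} probes lack annotation")
        missing = self.values.columns.difference(self.sample_annotation.index)
        if len(missing):
            raise ValueError(f"{len(missing)} samples lack annotation")
        # align annotation order with the matrix
        self.probe_annotation = self.probe_annotation.reindex(self.values.index)
        self.sample_annotation = self.sample_annotation.reindex(self.values.columns)

    # -- basic introspection -------------------------------------------------
    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def control_mask(self) -> np.ndarray:
        """Boolean mask over probes flagging invariant control probes."""
        return self.probe_annotation["is_control"].to_numpy(dtype=bool)

    # -- subsetting ----------------------------------------------------------
    def subset_probes(self, probe_ids) -> "ExpressionMatrix":
        probe_ids = pd.Index(probe_ids)
        missing = probe_ids.difference(self.values.index)
        if len(missing):
            raise KeyError(f"probes not in matrix: {list(missing[:5])}")
        return ExpressionMatrix(
            self.values.loc[probe_ids],
            self.probe_annotation.loc[probe_ids],
            self.sample_annotation,
        )

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        sample_ids = pd.Index(sample_ids)
        missing = sample_ids.difference(self.values.columns)
        if len(missing):
            raise KeyError(f"samples not in matrix: {list(missing[:5])}")
        return ExpressionMatrix(
            self.values[sample_ids],
            self.probe_annotation,
            self.sample_annotation.loc[sample_ids],
        )

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.copy(),
            self.probe_annotation.copy(),
            self.sample_annotation.copy(),
        )

    def with_values(self, values: pd.DataFrame) -> "ExpressionMatrix":
        """Return a matrix with the same annotations but new values."""
        if not values.index.equals(self.values.index) or not values.columns.equals(
            self.values.columns
        ):
            raise ValueError("replacement values must keep probe/sample ids")
        return ExpressionMatrix(values, self.probe_annotation, self.sample_annotation)


def validate_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    """Validate a clinical table; returns the table unchanged.

    Requires a unique sample-id index and all :data:`CLINICAL_COLUMNS`.
    """
    if clinical.index.has_duplicates:
        raise ValueError("duplicate sample ids in clinical table")
    missing = [c for c in CLINICAL_COLUMNS if c not in clinical.columns]
    if missing:
        raise ValueError(f"clinical table missing columns: {missing}")
    for col in ("rfs_years", "dmfs_years", "os_years"):
        t = clinical[col].to_numpy(dtype=float)
        if np.nanmin(t, initial=0.0) < 0:
            raise ValueError(f"negative times in {col}")
    return clinical
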