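"""Multi-study merging and control-probe batch-structure removal.

The harmonization model assumes that a designated set of control probes is
biologically invariant, so any structure they show across samples is
technical (study/batch) artifact. That structure is estimated as the first
``n_components`` principal components of the control-probe submatrix
(probes centered across samples), and the contribution of those component
scores is regressed out of every probe by ordinary least squares — a
deterministic factor regression. Typical component counts: 40 for a large
bulk-tumor compendium, 15 for a smaller multi-tissue set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

__all__ = [
    "HarmonizationModel",
    "intersect_platforms",
    "fit_control_structure",
    "remove_structure",
    "confirm_mixing",
    "mixing_statistic",
]


@dataclass
class HarmonizationModel:
    """Control-probe PC scores and per-probe removal coefficients."""

    n_components: int
    component_scores: pd.DataFrame  # samples x n_components
    removal_coefficients: pd.DataFrame  # probes x n_components
    explained_variance_ratio: np.ndarray  # of the control-probe submatrix

    def __post_init__(self) -> None:
        if self.n_components != self.component_scores.shape[1]:
            raise ValueError("component count mismatch")


def _svd(mat: np.ndarray):
    """SVD with a fallback to the slower QR-based LAPACK driver.

    The default divide-and-conquer driver occasionally fails to converge
    on large ill-conditioned matrices; gesvd is slower but reliable.
    """
    try:
        return np.linalg.svd(mat, full_matrices=False)
    except np.linalg.LinAlgError:
        from scipy.linalg import svd as scipy_svd

        return scipy_svd(mat, full_matrices=False, lapack_driver="gesvd")


def intersect_platforms(matrices) -> ExpressionMatrix:
    """Merge matrices onto their common probe set, concatenating samples.

    Probe order follows the first input. Probe annotation is taken from the
    first input; sample annotation is preserved per input. Raises on an
    empty probe intersection or duplicated sample ids across inputs.
    """
    matrices = list(matrices)
    if not matrices:
        raise ValueError("need at least one matrix")
    common = matrices[0].probe_ids
    for m in matrices[1:]:
        common = common[common.isin(m.probe_ids)]
    if len(common) == 0:
        raise ValueError("empty probe intersection across platforms")
    all_samples = pd.Index(np.concatenate([m.sample_ids for m in matrices]))
    if all_samples.has_duplicates:
        dupes = all_samples[all_samples.duplicated()].unique()
        raise ValueError(f"duplicate sample ids across inputs: {list(dupes[:5])}")
    values = pd.concat([m.values.loc[common] for m in matrices], axis=1)
    sample_annotation = pd.concat([m.sample_annotation for m in matrices], axis=0)
    return ExpressionMatrix(
        values, matrices[0].probe_annotation.loc[common], sample_annotation
    )


def fit_control_structure(x: ExpressionMatrix, n_components: int) -> HarmonizationModel:
    """PCA of the control-probe submatrix plus per-probe removal regression.

    Component scores are the sample projections onto the first
    ``n_components`` principal axes of the control probes (each probe
    centered across samples); removal coefficients are the least-squares
    regression of every probe on those scores.
    """
    ctrl = x.values.loc[x.control_mask].to_numpy(dtype=float)
    if ctrl.shape[0] == 0:
        raise ValueError("no control probes present")
    max_k = min(ctrl.shape[0], x.n_samples - 1)
    if n_components < 0:
        raise ValueError("n_components must be nonnegative")
    if n_components > max_k:
        raise ValueError(
            f"n_components={n_components} exceeds min(#control probes, #samples-1)={max_k}"
        )
    if n_components == 0:
        scores = pd.DataFrame(index=x.sample_ids.copy())
        coefs = pd.DataFrame(index=x.probe_ids.copy())
        return HarmonizationModel(0, scores, coefs, np.array([]))

    centered = ctrl - ctrl.mean(axis=1, keepdims=True)
    # samples are observations, control probes are features
    u, s, _vt = _svd(centered.T)
    if s[n_components - 1] <= s[0] * 1e-12:
        raise ValueError("n_components exceeds the rank of the control submatrix")
    scores = u[:, :n_components] * s[:n_components]
    total_var = float((s**2).sum())
    evr = (s[:n_components] ** 2) / total_var if total_var > 0 else s[:n_components] * 0.0

    vals = x.values.to_numpy(dtype=float)
    centered_vals = vals - vals.mean(axis=1, keepdims=True)
    # scores columns are orthogonal, so OLS is a scaled projection
    coefs = centered_vals @ scores / (s[:n_components] ** 2)

    cols = [f"PC{i + 1}" for i in range(n_components)]
    return HarmonizationModel(
        n_components,
        pd.DataFrame(scores, index=x.sample_ids.copy(), columns=cols),
        pd.DataFrame(coefs, index=x.probe_ids.copy(), columns=cols),
        evr,
    )


def remove_structure(x: ExpressionMatrix, model: HarmonizationModel) -> ExpressionMatrix:
    """Subtract each probe's fitted component contribution (residualize).

    Probe means are preserved (scores are centered), so values stay on the
    log-expression scale. Metadata is unchanged.
    """
    if not model.component_scores.index.equals(x.sample_ids):
        raise ValueError("model was fitted on different samples")
    if model.n_components == 0:
        return x.copy()
    coefs = model.removal_coefficients.reindex(x.probe_ids)
    if coefs.isna().any().any():
        raise ValueError("model lacks coefficients for some probes")
    fitted = coefs.to_numpy() @ model.component_scores.to_numpy().T
    residual = x.values.to_numpy(dtype=float) - fitted
    return x.with_values(
        pd.DataFrame(residual, index=x.probe_ids.copy(), columns=x.sample_ids.copy())
    )


def mixing_statistic(pc1: np.ndarray, study: np.ndarray) -> float:
    """Fraction of PC1 variance explained by study label (one-way eta^2)."""
    pc1 = np.asarray(pc1, dtype=float)
    study = np.asarray(study)
    grand = pc1.mean()
    ss_total = float(((pc1 - grand) ** 2).sum())
    if ss_total == 0:
        return 0.0
    ss_between = 0.0
    for s in np.unique(study):
        grp = pc1[study == s]
        ss_between += len(grp) * (grp.mean() - grand) ** 2
    return float(ss_between / ss_total)


def confirm_mixing(x: ExpressionMatrix, n_top_probes: int = 1000):
    """Two-PC sample embedding plus a study-mixing statistic.

    The statistic is the one-way variance ratio (eta^2) of PC1 explained by
    study label: near 0 when studies are well mixed, near 1 when the leading
    axis of variation separates studies. Computed on the ``n_top_probes``
    highest-variance probes.

    Returns ``(embedding, statistic)`` where ``embedding`` is a DataFrame
    indexed by sample with columns PC1/PC2.
    """
    study = x.sample_annotation["study_id"].to_numpy()
    if len(np.unique(study)) < 2:
        raise ValueError("mixing statistic undefined with a single study")
    vals = x.values.to_numpy(dtype=float)
    var = vals.var(axis=1)
    top = np.argsort(var)[::-1][: min(n_top_probes, len(var))]
    sub = vals[top]
    centered = (sub - sub.mean(axis=1, keepdims=True)).T  # samples x probes
    u, s, _ = _svd(centered)
    k = min(2, len(s))
    emb = u[:, :k] * s[:k]
    if k < 2:  # degenerate rank-1 data
        emb = np.column_stack([emb, np.zeros(len(emb))])
    embedding = pd.DataFrame(emb[:, :2], index=x.sample_ids.copy(), columns=["PC1", "PC2"])
    return embedding, mixing_statistic(embedding["PC1"].to_numpy(), study)
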