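"""Receptor-status calling from mRNA and molecular subtype assignment.

ER, PR and HER2 status is bimodally distributed at the mRNA level. Where an
IHC label exists it is taken at face value; where it does not, status is
called from the marker probe's expression using a maximum-likelihood cutoff:
two Gaussians are fitted to the IHC-positive and IHC-negative samples and
the cutoff is the expression value where the prior-weighted class densities
cross (posterior probability 0.5).

Subtypes follow the receptor-rule definitions:
Luminal A = (ER+ and/or PR+), HER2−; Luminal B = (ER+ and/or PR+), HER2+;
HER2 type = ER−, PR−, HER2+; TNBC = ER−, PR−, HER2−.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

__all__ = [
    "MarkerModel",
    "solve_cutoff",
    "fit_marker_model",
    "call_receptors",
    "assign_subtype",
]


@dataclass
class MarkerModel:
    """Fitted two-Gaussian mixture and decision cutoff for one marker."""

    marker: str
    mean_neg: float
    sd_neg: float
    mean_pos: float
    sd_pos: float
    prior_pos: float
    cutoff: float


def solve_cutoff(mean_neg, sd_neg, mean_pos, sd_pos, prior_pos):
    """Solve for the equal prior-weighted-density point between two normals.

    Equating ``log(prior_pos) + log N(x; mean_pos, sd_pos)`` with
    ``log(1-prior_pos) + log N(x; mean_neg, sd_neg)`` gives a quadratic in
    ``x``. The root lying strictly between the class means is returned; with
    equal variances the quadratic degenerates to a single linear root. If
    neither real root falls between the means (possible with very unequal
    variances), the root nearest the pooled mean is used.
    """
    if sd_neg <= 0 or sd_pos <= 0:
        raise ValueError("component standard deviations must be positive")
    if not 0.0 < prior_pos < 1.0:
        raise ValueError("prior_pos must lie in (0, 1)")
    lo, hi = sorted((mean_neg, mean_pos))
    # a x^2 + b x + c = 0
    a = 0.5 * (1.0 / sd_neg**2 - 1.0 / sd_pos**2)
    b = mean_pos / sd_pos**2 - mean_neg / sd_neg**2
    c = (
        0.5 * (mean_neg**2 / sd_neg**2 - mean_pos**2 / sd_pos**2)
        + np.log(sd_neg / sd_pos)
        + np.log(prior_pos / (1.0 - prior_pos))
    )
    if abs(a) < 1e-300:
        if b == 0:
            raise ValueError("degenerate cutoff equation (identical components)")
        return -c / b
    disc = b * b - 4 * a * c
    if disc < 0:
        raise ValueError("no real density crossing for these parameters")
    roots = np.array([(-b - np.sqrt(disc)) / (2 * a), (-b + np.sqrt(disc)) / (2 * a)])
    between = roots[(roots > lo) & (roots < hi)]
    if len(between):
        return float(between[0])
    pooled = 0.5 * (mean_neg + mean_pos)
    return float(roots[np.argmin(np.abs(roots - pooled))])


def fit_marker_model(
    expression, ihc_labels, marker: str = "marker", equal_priors: bool = False
) -> MarkerModel:
    """Fit per-class normals on IHC-labeled samples and derive the cutoff.

    Parameters
    ----------
    expression
        Per-sample marker expression (array-like).
    ihc_labels
        Partial binary labels aligned with ``expression``; NaN = unlabeled.
    equal_priors
        If True the cutoff uses 0.5/0.5 class priors instead of the labeled
        prevalence.
    """
    x = np.asarray(expression, dtype=float)
    lab = np.asarray(ihc_labels, dtype=float)
    if x.shape != lab.shape:
        raise ValueError("expression and labels must align")
    pos = x[lab == 1]
    neg = x[lab == 0]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("need at least 2 labeled samples per class")
    sd_pos = float(np.std(pos))  # MLE (ddof=0) per-class normals
    sd_neg = float(np.std(neg))
    if sd_pos == 0 or sd_neg == 0:
        raise ValueError("a labeled class has zero variance")
    prior = 0.5 if equal_priors else len(pos) / (len(pos) + len(neg))
    cutoff = solve_cutoff(float(np.mean(neg)), sd_neg, float(np.mean(pos)), sd_pos, prior)
    return MarkerModel(
        marker=marker,
        mean_neg=float(np.mean(neg)),
        sd_neg=sd_neg,
        mean_pos=float(np.mean(pos)),
        sd_pos=sd_pos,
        prior_pos=prior,
        cutoff=float(cutoff),
    )


def call_receptors(
    expression: ExpressionMatrix,
    ihc: pd.DataFrame,
    models: dict,
    marker_probes: dict,
) -> pd.DataFrame:
    """Produce final ER/PR/HER2 calls with provenance and subtype.

    IHC labels win wherever observed; otherwise a sample is called positive
    iff its marker-probe expression strictly exceeds the model cutoff (ties
    go to negative).

    Parameters
    ----------
    expression
        Matrix containing the marker probes.
    ihc
        DataFrame indexed by sample id with columns ``ihc_er``, ``ihc_pr``,
        ``ihc_her2`` (NaN where unobserved).
    models
        Mapping marker name ('ER','PR','HER2') -> :class:`MarkerModel`.
    marker_probes
        Mapping marker name -> probe id (configuration, not inference).
    """
    out = pd.DataFrame(index=expression.sample_ids.copy())
    for marker, col in (("ER", "ihc_er"), ("PR", "ihc_pr"), ("HER2", "ihc_her2")):
        probe = marker_probes.get(marker)
        if probe is None or probe not in expression.probe_ids:
            raise KeyError(f"marker probe for {marker} missing from matrix")
        model = models.get(marker)
        if model is None:
            raise KeyError(f"no model supplied for {marker}")
        if model.marker not in (marker, "marker"):
            raise ValueError(f"model for {model.marker} passed as {marker}")
        vals = expression.values.loc[probe].reindex(out.index)
        lab = ihc[col].reindex(out.index) if col in ihc.columns else pd.Series(
            np.nan, index=out.index
        )
        mrna_call = (vals > model.cutoff).to_numpy(dtype=int)
        observed = lab.notna().to_numpy()
        call = np.where(observed, lab.to_numpy(dtype=float), mrna_call).astype(int)
        key = marker.lower()
        out[key] = np.where(call == 1, "positive", "negative")
        out[f"{key}_src"] = np.where(observed, "IHC", "mRNA")
    out["subtype"] = assign_subtype(out)
    return out


def assign_subtype(calls: pd.DataFrame) -> pd.Series:
    """Map ER/PR/HER2 calls to the four molecular subtypes.

    The four rules partition the 8 possible call combinations.
    """
    for col in ("er", "pr", "her2"):
        if col not in calls.columns:
            raise ValueError(f"missing receptor call column {col!r}")
        if calls[col].isna().any():
            raise ValueError(f"missing calls in column {col!r}")
    erp = calls["er"].eq("positive")
    prp = calls["pr"].eq("positive")
    h2p = calls["her2"].eq("positive")
    hormone = erp | prp
    subtype = pd.Series("TNBC", index=calls.index, dtype=object)
    subtype[hormone & ~h2p] = "LumA"
    subtype[hormone & h2p] = "LumB"
    subtype[~hormone & h2p] = "HER2type"
    return subtype
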