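"""Epithelial late-recurrence signature: three-filter cascade and validation.

The epithelial signature is the set of probes that simultaneously
(a) track the stromal-activation metagene (Pearson r with SPC1 above a
threshold, default 0.25, computed across the paired tumors),
(b) are specifically upregulated in the epithelium of the late-recurrence
subgroup (Welch t, BH FDR below a threshold, default 0.05), and
(c) are directly (positive coefficient) associated with recurrence risk in
the discovery cohort's univariable Cox screen (p below a threshold,
default 0.01, overall scheme by default).

Its first principal component (EPC1) is the per-sample signature score,
validated against metastasis-timing groups: early metastasis (event before
the boundary), late metastasis (event at/after the boundary) and a
no-recurrence reference of patients event-free past a long-follow-up
minimum (default 15 years).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix
from .stroma import MetageneScore, PairedCompartmentSet, first_pc_score, trend_across_groups

__all__ = [
    "CascadeCriteria",
    "cascade_select",
    "timing_groups",
    "validate_signature",
    "concordance_c4",
]

TIMING_LABELS = ("no-recurrence", "early-metastasis", "late-metastasis")


@dataclass(frozen=True)
class CascadeCriteria:
    """Thresholds of the three-filter cascade."""

    r_min: float = 0.25
    de_fdr: float = 0.05
    cox_p: float = 0.01
    cox_scheme: str = "overall"  # or 'late'

    def __post_init__(self):
        if not 0.0 < self.r_min < 1.0:
            raise ValueError("r_min must lie in (0, 1)")
        for name in ("de_fdr", "cox_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


def _pearson_rows(mat: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r between each row of ``mat`` and the vector ``y``."""
    mc = mat - mat.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((mc**2).sum(axis=1)) * np.sqrt((yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        return (mc @ yc) / denom


def cascade_select(
    pairs: PairedCompartmentSet,
    spc1: MetageneScore,
    epithelium_groups: pd.Series,
    screen: pd.DataFrame,
    criteria: CascadeCriteria = CascadeCriteria(),
    target_group: str = "G4",
) -> pd.DataFrame:
    """Apply the three-filter cascade; returns selected probes by descending r.

    Parameters
    ----------
    pairs
        The paired epithelium/stroma set on which SPC1 was defined.
    spc1
        Stromal-activation metagene scored on the *stroma* samples.
    epithelium_groups
        Subgroup labels of the epithelium samples (target = late-like group).
    screen
        Discovery-cohort screen result (``coef_*``/``p_*`` columns).

    Returns a DataFrame indexed by probe with the per-filter statistics and
    a ``selected`` flag; an empty selection is returned with a warning, not
    an error.
    """
    if pairs.epithelium.n_samples == 0:
        raise ValueError("empty paired cohort")
    if len(screen) == 0:
        raise ValueError("empty discovery screen")
    epi_ids = list(pairs.pairing.keys())
    stroma_ids = [pairs.pairing[e] for e in epi_ids]
    spc1_on_pairs = spc1.scores.reindex(stroma_ids)
    if spc1_on_pairs.isna().any():
        raise ValueError("SPC1 scores missing for some paired stroma samples")

    epi = pairs.epithelium.values[epi_ids].to_numpy(dtype=float)
    r = _pearson_rows(epi, spc1_on_pairs.to_numpy(dtype=float))

    groups = epithelium_groups.reindex(epi_ids)
    in_target = (groups == target_group).to_numpy()
    if in_target.sum() < 2 or (~in_target).sum() < 2:
        raise ValueError("need >=2 epithelium samples inside and outside the target group")
    t, p = stats.ttest_ind(
        epi[:, in_target], epi[:, ~in_target], axis=1, equal_var=False
    )
    from statsmodels.stats.multitest import multipletests

    q = np.full_like(p, np.nan)
    valid = np.isfinite(p)
    q[valid] = multipletests(p[valid], method="fdr_bh")[1]

    scheme = criteria.cox_scheme
    scr = screen.reindex(pairs.epithelium.probe_ids)
    cox_coef = scr[f"coef_{scheme}"].to_numpy(dtype=float)
    cox_p = scr[f"p_{scheme}"].to_numpy(dtype=float)

    pass_r = r > criteria.r_min
    pass_de = (q < criteria.de_fdr) & (t > 0)
    pass_cox = (cox_coef > 0) & (cox_p < criteria.cox_p)
    selected = pass_r & pass_de & pass_cox & np.isfinite(r)

    out = pd.DataFrame(
        {
            "r_spc1": r,
            "de_t": t,
            "de_q": q,
            "cox_coef": cox_coef,
            "cox_p": cox_p,
            "pass_r": pass_r,
            "pass_de": pass_de,
            "pass_cox": pass_cox,
            "selected": selected,
        },
        index=pairs.epithelium.probe_ids.copy(),
    )
    out.index.name = "probe_id"
    out = out.sort_values("r_spc1", ascending=False)
    if not selected.any():
        warnings.warn("cascade selected no probes (empty signature)")
    return out


def timing_groups(
    clinical: pd.DataFrame,
    boundary: float = 5.0,
    long_followup: float = 15.0,
    endpoint: str = "dmfs",
) -> pd.Series:
    """Partition samples into metastasis-timing groups.

    * event before ``boundary``  -> 'early-metastasis'
    * event at/after ``boundary`` -> 'late-metastasis'
    * no event and follow-up >= ``long_followup`` -> 'no-recurrence'
    * everything else (insufficient follow-up) is excluded.
    """
    if boundary <= 0 or long_followup <= 0:
        raise ValueError("boundary and long_followup must be positive")
    tcol, ecol = f"{endpoint}_years", f"{endpoint}_event"
    t = clinical[tcol].astype(float)
    e = clinical[ecol].astype(float)
    labels = pd.Series(np.nan, index=clinical.index, dtype=object)
    labels[(e == 1) & (t < boundary)] = "early-metastasis"
    labels[(e == 1) & (t >= boundary)] = "late-metastasis"
    labels[(e == 0) & (t >= long_followup)] = "no-recurrence"
    return labels.dropna()


@dataclass
class ValidationReport:
    pairwise: pd.DataFrame  # Mann-Whitney between timing groups
    anova_f: float
    anova_p: float
    bin_medians: pd.Series
    group_medians: pd.Series


def validate_signature(
    scores,
    groups: pd.Series,
    clinical: pd.DataFrame = None,
    time_bins=(2.0, 5.0, 10.0),
    endpoint: str = "dmfs",
    exact_max_n: int = 25,
) -> ValidationReport:
    """Compare signature scores across metastasis-timing groups.

    Pairwise exact Mann–Whitney tests between all timing-group pairs, and
    (when ``clinical`` is supplied) a one-way ANOVA across event samples
    binned by time of metastasis with the no-recurrence samples as the
    reference bin.
    """
    if isinstance(scores, MetageneScore):
        scores = scores.scores
    scores = pd.Series(scores)
    common = scores.index.intersection(groups.index)
    g = groups.loc[common]
    s = scores.loc[common]
    labels = [lab for lab in TIMING_LABELS if lab in set(g)]
    if len(labels) < 2:
        raise ValueError("need at least 2 non-empty timing groups")
    samples = {lab: s[g == lab].to_numpy(dtype=float) for lab in labels}
    for lab, vals in samples.items():
        if len(vals) < 2:
            raise ValueError(f"timing group {lab!r} has fewer than 2 samples")

    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a, b = samples[labels[i]], samples[labels[j]]
            has_ties = len(np.unique(np.r_[a, b])) < len(a) + len(b)
            exact = len(a) <= exact_max_n and len(b) <= exact_max_n and not has_ties
            method = "exact" if exact else "asymptotic"
            res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
            rows.append(
                {
                    "comparison": f"{labels[i]} vs {labels[j]}",
                    "u": float(res.statistic),
                    "p": float(res.pvalue),
                    "method": method,
                }
            )
    pairwise = pd.DataFrame(rows)

    # ANOVA across time-of-metastasis bins
    anova_f = anova_p = np.nan
    bin_medians = pd.Series(dtype=float)
    if clinical is not None:
        tcol, ecol = f"{endpoint}_years", f"{endpoint}_event"
        clin = clinical.loc[clinical.index.intersection(s.index)]
        ev = clin[clin[ecol] == 1]
        edges = [0.0, *time_bins, np.inf]
        bins = {}
        noner = s[g[g == "no-recurrence"].index.intersection(s.index)]
        if len(noner) >= 2:
            bins["0 (event-free)"] = noner.to_numpy(dtype=float)
        for lo, hi in zip(edges[:-1], edges[1:]):
            members = ev.index[(ev[tcol] >= lo) & (ev[tcol] < hi)]
            vals = s.reindex(members).dropna().to_numpy(dtype=float)
            if len(vals) >= 2:
                bins[f"[{lo:g}, {hi:g})"] = vals
        if len(bins) >= 2:
            anova_f, anova_p = stats.f_oneway(*bins.values())
            bin_medians = pd.Series({k: float(np.median(v)) for k, v in bins.items()})

    return ValidationReport(
        pairwise=pairwise,
        anova_f=float(anova_f),
        anova_p=float(anova_p),
        bin_medians=bin_medians,
        group_medians=pd.Series({k: float(np.median(v)) for k, v in samples.items()}),
    )


def concordance_c4(
    x: ExpressionMatrix, c4_probes, signature_probes
) -> tuple[MetageneScore, MetageneScore, float]:
    """Score two probe sets on the same cohort and return their Pearson r.

    Both metagenes are first-PC scores with the standard orientation
    anchor, so the sign of the correlation is meaningful.
    """
    c4 = first_pc_score(x, c4_probes, name="C4PC1")
    sig = first_pc_score(x, signature_probes, name="EPC1")
    r = float(np.corrcoef(c4.scores.to_numpy(), sig.scores.to_numpy())[0, 1])
    return c4, sig, r
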