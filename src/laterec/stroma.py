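"""Stromal-activation signature discovery from paired epithelium/stroma.

Given tumors for which both microdissected epithelium and matched stroma
were profiled, the stroma of the late-recurrence-like subgroup (assigned
from the epithelium) is compared against the stroma of all other tumors by
per-probe Welch t-tests with Benjamini–Hochberg FDR control. The resulting
up/down probe set is summarized as a metagene: the first principal
component of the standardized probe subset (SPC1), oriented so that higher
scores mean more of the upregulated program.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix

__all__ = [
    "PairedCompartmentSet",
    "MetageneScore",
    "stromal_de",
    "first_pc_score",
    "trend_across_groups",
]


@dataclass
class PairedCompartmentSet:
    """Matched epithelium/stroma expression with a one-to-one pairing.

    ``pairing`` maps epithelium sample id -> stroma sample id.
    """

    epithelium: ExpressionMatrix
    stroma: ExpressionMatrix
    pairing: dict

    def __post_init__(self) -> None:
        epi = set(self.pairing.keys())
        stro = list(self.pairing.values())
        if len(set(stro)) != len(stro):
            raise ValueError("pairing is not one-to-one")
        if not epi <= set(self.epithelium.sample_ids):
            raise ValueError("pairing references unknown epithelium samples")
        if not set(stro) <= set(self.stroma.sample_ids):
            raise ValueError("pairing references unknown stroma samples")
        if not self.epithelium.probe_ids.equals(self.stroma.probe_ids):
            raise ValueError("epithelium and stroma must share the probe universe")

    @classmethod
    def from_cohort(cls, expression: ExpressionMatrix) -> "PairedCompartmentSet":
        """Extract the paired compartments from a full cohort matrix."""
        ann = expression.sample_annotation
        epi = ann.index[ann["tissue"] == "epithelium"]
        stro = ann.index[ann["tissue"] == "stroma"]
        by_pair = (
            ann.loc[stro].rename_axis("sample_id").reset_index()
            .set_index("pair_id")["sample_id"]
        )
        pairing = {
            e: by_pair[ann.loc[e, "pair_id"]]
            for e in epi
            if ann.loc[e, "pair_id"] in by_pair.index
        }
        return cls(
            expression.subset_samples(list(pairing.keys())),
            expression.subset_samples(list(pairing.values())),
            pairing,
        )


@dataclass
class MetageneScore:
    """First-principal-component summary of a probe set across samples."""

    name: str
    probe_set: list
    loadings: pd.Series  # per probe, on standardized data
    scores: pd.Series  # per sample, zero mean over the defining cohort
    sign_anchor: str
    explained_variance_ratio: float


def stromal_de(
    pairs: PairedCompartmentSet,
    epithelium_groups: pd.Series,
    target_group: str = "G4",
    fdr: float = 0.05,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-probe stroma DE of the target epithelial subgroup vs the rest.

    ``epithelium_groups`` labels the *epithelium* samples; the comparison is
    run on their paired stroma profiles. Welch's unequal-variance t-test by
    default. Returns a DataFrame (probe_id index) with t, p, BH q,
    direction ('up'/'down' in the target group's stroma) and ``selected``
    (q < fdr).
    """
    groups = epithelium_groups.reindex(list(pairs.pairing.keys()))
    in_target = groups == target_group
    if int(in_target.sum()) < 2:
        raise ValueError(f"fewer than 2 stroma samples in group {target_group!r}")
    if int((~in_target).sum()) < 2:
        raise ValueError(f"fewer than 2 stroma samples outside group {target_group!r}")
    stroma_of = pairs.pairing
    target_ids = [stroma_of[e] for e in groups.index[in_target]]
    rest_ids = [stroma_of[e] for e in groups.index[~in_target]]
    a = pairs.stroma.values[target_ids].to_numpy(dtype=float)
    b = pairs.stroma.values[rest_ids].to_numpy(dtype=float)
    t, p = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    from statsmodels.stats.multitest import multipletests

    q = np.full_like(p, np.nan)
    valid = np.isfinite(p)
    if valid.any():
        q[valid] = multipletests(p[valid], method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "t": t,
            "p": p,
            "q": q,
            "direction": np.where(t > 0, "up", "down"),
            "selected": (q < fdr) & valid,
        },
        index=pairs.stroma.probe_ids.copy(),
    )
    out.index.name = "probe_id"
    return out


def first_pc_score(
    x: ExpressionMatrix,
    probe_set,
    name: str = "PC1",
    up_probes=None,
) -> MetageneScore:
    """Metagene score: first PC of the standardized probe subset.

    Probes are standardized to zero mean / unit variance across samples
    before the singular value decomposition, so each probe contributes on
    an equal scale. The orientation is fixed so the score correlates
    nonnegatively with the mean standardized expression of ``up_probes``
    (default: all probes in the set) — without an anchor the PC sign is
    arbitrary and cross-run comparisons would be meaningless.
    """
    probe_set = list(probe_set)
    found = [p for p in probe_set if p in set(x.probe_ids)]
    missing = sorted(set(probe_set) - set(found))
    if len(found) < 1:
        raise ValueError(f"no probes of the set present; missing: {missing[:5]}")
    if len(found) < 2 and len(probe_set) >= 2:
        raise ValueError(f"fewer than 2 probes found; missing: {missing[:5]}")
    if x.n_samples < 2:
        raise ValueError("need at least 2 samples")
    sub = x.values.loc[found].to_numpy(dtype=float)
    mean = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, keepdims=True)
    if (sd == 0).any():
        bad = [found[i] for i in np.flatnonzero(sd[:, 0] == 0)]
        raise ValueError(f"constant probes in the set: {bad[:5]}")
    z = (sub - mean) / sd

    from .harmonize import _svd

    u, s, vt = _svd(z.T)  # samples x probes
    scores = u[:, 0] * s[0]
    loadings = vt[0]
    if up_probes is None:
        up = np.ones(len(found), dtype=bool)
    else:
        up_set = set(up_probes)
        up = np.array([p in up_set for p in found])
        if not up.any():
            up = np.ones(len(found), dtype=bool)
    anchor = z[up].mean(axis=0)
    if float(anchor @ scores) < 0:
        scores = -scores
        loadings = -loadings
    total_var = float((s**2).sum())
    return MetageneScore(
        name=name,
        probe_set=found,
        loadings=pd.Series(loadings, index=found, name="loading"),
        scores=pd.Series(scores, index=x.sample_ids.copy(), name=name),
        sign_anchor="nonnegative correlation with mean standardized "
        "expression of the upregulated probes",
        explained_variance_ratio=float(s[0] ** 2 / total_var) if total_var else 0.0,
    )


def project_score(score: MetageneScore, x: ExpressionMatrix) -> pd.Series:
    """Apply fixed loadings to a new cohort (prospective-mode scoring)."""
    sub = x.values.loc[score.probe_set].to_numpy(dtype=float)
    mean = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, keepdims=True)
    z = (sub - mean) / np.where(sd == 0, 1.0, sd)
    return pd.Series(
        z.T @ score.loadings.to_numpy(), index=x.sample_ids.copy(), name=score.name
    )


@dataclass
class TrendResult:
    anova_f: float
    anova_p: float
    pairwise: pd.DataFrame  # adjacent-pair Mann-Whitney results
    rank_means: pd.Series
    monotone_direction: str  # 'increasing', 'decreasing' or 'none'


def trend_across_groups(
    scores, groups: pd.Series, group_order=None, exact_max_n: int = 25
) -> TrendResult:
    """One-way ANOVA across ordered groups plus adjacent Mann–Whitney tests.

    ``groups`` assigns each sample to an outcome-ordered class;
    ``group_order`` fixes the ordering (default: sorted labels). Mann–
    Whitney tests are exact when both groups have at most ``exact_max_n``
    samples and there are no ties, otherwise the tie-corrected normal
    approximation is used (recorded per comparison in the ``method``
    column). A Jonckheere-style summary reports whether mean ranks move
    monotonically along the ordering.
    """
    if isinstance(scores, MetageneScore):
        scores = scores.scores
    scores = pd.Series(scores)
    common = scores.index.intersection(groups.index)
    s = scores.loc[common]
    g = groups.loc[common]
    order = list(group_order) if group_order is not None else sorted(g.dropna().unique())
    samples = {lab: s[g == lab].to_numpy(dtype=float) for lab in order}
    for lab, vals in samples.items():
        if len(vals) < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 samples")
    f, anova_p = stats.f_oneway(*[samples[lab] for lab in order])

    rows = []
    for lab_a, lab_b in zip(order[:-1], order[1:]):
        a, b = samples[lab_a], samples[lab_b]
        has_ties = len(np.unique(np.r_[a, b])) < len(a) + len(b)
        exact = len(a) <= exact_max_n and len(b) <= exact_max_n and not has_ties
        method = "exact" if exact else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        rows.append(
            {
                "comparison": f"{lab_a} vs {lab_b}",
                "u": float(res.statistic),
                "p": float(res.pvalue),
                "method": method,
            }
        )
    ranks = stats.rankdata(np.concatenate([samples[lab] for lab in order]))
    rank_means = {}
    pos = 0
    for lab in order:
        k = len(samples[lab])
        rank_means[lab] = float(ranks[pos:pos + k].mean())
        pos += k
    rm = pd.Series(rank_means)
    diffs = np.diff(rm.to_numpy())
    if (diffs > 0).all():
        mono = "increasing"
    elif (diffs < 0).all():
        mono = "decreasing"
    else:
        mono = "none"
    return TrendResult(
        anova_f=float(f),
        anova_p=float(anova_p),
        pairwise=pd.DataFrame(rows),
        rank_means=rm,
        monotone_direction=mono,
    )
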