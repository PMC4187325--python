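"""Two-way centroid-linkage clustering, enrichment tables and KM curves.

Samples and probes are clustered separately by agglomerative centroid
linkage under correlation distance (1 − centered Pearson between cluster
mean profiles), the default similarity of the classic gene-expression
clustering tools. Trees are cut to a fixed number of groups (default 4 in
each dimension, labelled G1..Gk for samples and C1..Cm for probes, ordered
by dendrogram leaf order).

Subtype-by-subgroup and screen-category-by-cluster enrichment is summarized
with cross-product odds ratios, Woolf logit 95% confidence intervals and
two-sided Fisher exact tests. Subgroup survival uses Kaplan–Meier curves
and the k-group log-rank (Mantel–Cox) test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix
from .survival import apply_scheme

__all__ = [
    "GroupingResult",
    "ContingencyResult",
    "centroid_linkage_corr",
    "cut_linkage",
    "leaf_order",
    "cluster_two_way",
    "enrichment_2x2",
    "subtype_enrichment",
    "cluster_category_enrichment",
    "km_logrank",
]

# conventional 1.96 multiplier of the Woolf logit interval
_Z95 = 1.96


# ---------------------------------------------------------------------------
# centroid linkage under correlation distance
# ---------------------------------------------------------------------------

def _corr_dist_to_centroid(centroid: np.ndarray, others: np.ndarray) -> np.ndarray:
    """1 − Pearson correlation between ``centroid`` and each row of ``others``."""
    c = centroid - centroid.mean()
    o = others - others.mean(axis=1, keepdims=True)
    denom = np.sqrt((c**2).sum()) * np.sqrt((o**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (o @ c) / denom
    return 1.0 - r


def centroid_linkage_corr(data: np.ndarray) -> np.ndarray:
    """Agglomerate rows of ``data`` by centroid linkage, correlation distance.

    Cluster centroids are means of member rows; inter-cluster distance is
    1 − Pearson between centroids. Because centroid linkage is not
    monotone, merge heights may decrease (inversions); they are recorded
    as-is. Returns an (n−1, 4) linkage array in the usual format
    ``[id_a, id_b, height, new_size]`` with new clusters numbered n, n+1...
    Ties are broken by the smallest (id_a, id_b) pair.
    """
    data = np.asarray(data, dtype=float)
    n, p = data.shape
    if n < 2:
        raise ValueError("need at least 2 items to cluster")
    if (data.std(axis=1) == 0).any():
        raise ValueError("constant rows must be removed before clustering")

    centroids = np.zeros((2 * n - 1, p))
    centroids[:n] = data
    sizes = np.ones(2 * n - 1, dtype=int)
    active = list(range(n))
    # full symmetric distance matrix over active slots
    big = 2 * n - 1
    D = np.full((big, big), np.inf)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(data)
    D[:n, :n] = 1.0 - corr
    np.fill_diagonal(D, np.inf)

    merges = np.zeros((n - 1, 4))
    for step in range(n - 1):
        sub = D[np.ix_(active, active)]
        flat = np.argmin(sub)
        i, j = divmod(flat, len(active))
        if i > j:
            i, j = j, i
        a, b = active[i], active[j]
        h = sub[i, j]
        new = n + step
        members_a, members_b = sizes[a], sizes[b]
        centroids[new] = (
            members_a * centroids[a] + members_b * centroids[b]
        ) / (members_a + members_b)
        sizes[new] = members_a + members_b
        merges[step] = (a, b, h, sizes[new])
        active.remove(b)
        active.remove(a)
        if active:
            rest = np.array(active)
            d_new = _corr_dist_to_centroid(centroids[new], centroids[rest])
            D[new, rest] = d_new
            D[rest, new] = d_new
        active.append(new)
    return merges


def cut_linkage(merges: np.ndarray, n: int, k: int) -> np.ndarray:
    """Cut a merge sequence to exactly ``k`` clusters (by merge order).

    Returns integer labels 0..k−1 per original item; labels are arbitrary
    until reordered by :func:`leaf_order`.
    """
    if not 1 <= k <= n:
        raise ValueError("k must be in [1, n]")
    parent = np.arange(2 * n - 1)
    for step in range(n - k):
        a, b = int(merges[step, 0]), int(merges[step, 1])
        parent[a] = n + step
        parent[b] = n + step

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    roots = {}
    labels = np.zeros(n, dtype=int)
    for i in range(n):
        r = find(i)
        if r not in roots:
            roots[r] = len(roots)
        labels[i] = roots[r]
    return labels


def leaf_order(merges: np.ndarray, n: int) -> list:
    """Dendrogram leaf order (left-to-right) of the full tree."""
    children = {}
    for step in range(n - 1):
        children[n + step] = (int(merges[step, 0]), int(merges[step, 1]))
    order = []
    stack = [2 * n - 2] if n > 1 else [0]
    while stack:
        node = stack.pop()
        if node < n:
            order.append(node)
        else:
            a, b = children[node]
            stack.append(b)
            stack.append(a)
    return order


@dataclass
class GroupingResult:
    """Two-way grouping: sample subgroups and probe clusters with linkage."""

    sample_groups: pd.Series  # sample_id -> 'G1'..'Gk'
    probe_clusters: pd.Series  # probe_id -> 'C1'..'Cm'
    sample_linkage: np.ndarray
    probe_linkage: np.ndarray
    sample_group_order: list
    probe_cluster_order: list
    dropped_samples: list = field(default_factory=list)
    dropped_probes: list = field(default_factory=list)
    sample_inversions: int = 0
    probe_inversions: int = 0


def _cluster_dimension(data: np.ndarray, ids: pd.Index, k: int, prefix: str):
    sds = data.std(axis=1)
    dropped = list(ids[sds == 0])
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} constant items before clustering: "
            f"{dropped[:3]}..."
        )
    keep = sds > 0
    data = data[keep]
    ids = ids[keep]
    n = data.shape[0]
    if n < k:
        raise ValueError(f"cannot cut {n} items into {k} clusters")
    merges = centroid_linkage_corr(data)
    inversions = int((np.diff(merges[:, 2]) < -1e-12).sum())
    labels = cut_linkage(merges, n, k)
    order = leaf_order(merges, n)
    # order cluster labels by first appearance along the dendrogram leaves
    seen = []
    for leaf in order:
        if labels[leaf] not in seen:
            seen.append(labels[leaf])
    rename = {old: f"{prefix}{pos + 1}" for pos, old in enumerate(seen)}
    named = pd.Series([rename[v] for v in labels], index=ids)
    return named, merges, [rename[v] for v in seen], dropped, inversions


def cluster_two_way(
    x: ExpressionMatrix, k_samples: int = 4, k_probes: int = 4,
    center_probes: bool = True,
) -> GroupingResult:
    """Cluster samples into G-groups and probes into C-clusters.

    ``x`` should already be restricted to the screen-selected probes. Each
    probe is mean-centered across samples first (the standard preprocessing
    before two-way expression clustering): without it, sample-to-sample
    Pearson correlation is dominated by per-probe baseline differences
    rather than by the sample-specific pattern. Probe-wise distances are
    unaffected by the centering. Constant rows/columns are dropped with a
    warning (correlation with them is undefined).
    """
    vals = x.values.to_numpy(dtype=float)
    if center_probes:
        vals = vals - vals.mean(axis=1, keepdims=True)
    sample_groups, s_link, s_order, s_drop, s_inv = _cluster_dimension(
        vals.T, x.sample_ids, k_samples, "G"
    )
    probe_clusters, p_link, p_order, p_drop, p_inv = _cluster_dimension(
        vals, x.probe_ids, k_probes, "C"
    )
    return GroupingResult(
        sample_groups=sample_groups,
        probe_clusters=probe_clusters,
        sample_linkage=s_link,
        probe_linkage=p_link,
        sample_group_order=s_order,
        probe_cluster_order=p_order,
        dropped_samples=s_drop,
        dropped_probes=p_drop,
        sample_inversions=s_inv,
        probe_inversions=p_inv,
    )


# ---------------------------------------------------------------------------
# 2x2 enrichment statistics
# ---------------------------------------------------------------------------

@dataclass
class ContingencyResult:
    table: tuple  # ((a, b), (c, d))
    odds_ratio: float
    ci_low: float
    ci_high: float
    fisher_p: float
    continuity_corrected: bool = False


def enrichment_2x2(
    members_in_group: int,
    nonmembers_in_group: int,
    members_outside: int,
    nonmembers_outside: int,
) -> ContingencyResult:
    """Cross-product OR, Woolf logit 95% CI and two-sided Fisher exact p.

    For the table ``[[a, b], [c, d]]`` the odds ratio is ``(a·d)/(b·c)``
    and the CI is ``exp(ln OR ± 1.96·sqrt(1/a + 1/b + 1/c + 1/d))``. A zero
    cell yields OR 0 or infinity; the CI then uses the Haldane–Anscombe 0.5
    correction and the result is flagged ``continuity_corrected``.
    """
    a, b, c, d = (
        int(members_in_group),
        int(nonmembers_in_group),
        int(members_outside),
        int(nonmembers_outside),
    )
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be nonnegative")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise ValueError("every table margin must be positive")
    _, fisher_p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    zero_cell = min(a, b, c, d) == 0
    if zero_cell:
        if b * c == 0 and a * d == 0:
            odds_ratio = np.nan
        elif b * c == 0:
            odds_ratio = np.inf
        else:
            odds_ratio = 0.0
        aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        odds_ratio = (a * d) / (b * c)
        aa, bb, cc, dd = a, b, c, d
    log_or = np.log((aa * dd) / (bb * cc))
    half = _Z95 * np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    return ContingencyResult(
        table=((a, b), (c, d)),
        odds_ratio=float(odds_ratio),
        ci_low=float(np.exp(log_or - half)),
        ci_high=float(np.exp(log_or + half)),
        fisher_p=float(fisher_p),
        continuity_corrected=zero_cell,
    )


def subtype_enrichment(sample_groups: pd.Series, subtypes: pd.Series) -> pd.DataFrame:
    """Per (subgroup, subtype) enrichment table mirroring a 2-way census.

    Returns a long-format DataFrame with the in-group count, in-group
    percentage, Fisher p, OR and Woolf CI for every subgroup x subtype
    combination.
    """
    common = sample_groups.index.intersection(subtypes.index)
    g = sample_groups.loc[common]
    s = subtypes.loc[common]
    rows = []
    for grp in sorted(g.unique()):
        in_grp = g == grp
        n_in = int(in_grp.sum())
        for sub in sorted(s.unique()):
            member = s == sub
            a = int((in_grp & member).sum())
            b = n_in - a
            c = int((~in_grp & member).sum())
            d = int((~in_grp).sum()) - c
            res = enrichment_2x2(a, b, c, d)
            rows.append(
                {
                    "subgroup": grp,
                    "subtype": sub,
                    "n": a,
                    "percent": 100.0 * a / n_in if n_in else np.nan,
                    "fisher_p": res.fisher_p,
                    "odds_ratio": res.odds_ratio,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "continuity_corrected": res.continuity_corrected,
                }
            )
    return pd.DataFrame(rows)


def cluster_category_enrichment(
    probe_clusters: pd.Series, screen: pd.DataFrame, threshold: float = 0.001
) -> pd.DataFrame:
    """Enrichment of screen categories (early/late x direct/inverse) per cluster.

    Membership uses the per-scheme p-value at ``threshold`` and the sign of
    the per-scheme coefficient. Every probe in ``probe_clusters`` must be
    present in the screen result.
    """
    missing = probe_clusters.index.difference(screen.index)
    if len(missing):
        raise ValueError(f"screen result missing probes: {list(missing[:5])}")
    scr = screen.loc[probe_clusters.index]
    memberships = {}
    for assoc, scheme in (("early", "early"), ("late", "late")):
        hit = scr[f"p_{scheme}"] < threshold
        memberships[(assoc, "direct")] = hit & (scr[f"coef_{scheme}"] > 0)
        memberships[(assoc, "inverse")] = hit & (scr[f"coef_{scheme}"] < 0)
    rows = []
    for cluster in sorted(probe_clusters.unique()):
        in_cluster = probe_clusters == cluster
        if int(in_cluster.sum()) == 0:
            raise ValueError(f"empty cluster {cluster!r}")
        for (assoc, direction), member in memberships.items():
            member = member.to_numpy()
            a = int((in_cluster & member).sum())
            b = int(in_cluster.sum()) - a
            c = int((~in_cluster & member).sum())
            d = int((~in_cluster).sum()) - c
            if a + c == 0 or b + d == 0:
                # category empty (or universal) among screened probes:
                # association is undefined, report a flagged placeholder
                res = ContingencyResult(
                    ((a, b), (c, d)), np.nan, np.nan, np.nan, 1.0, True
                )
            else:
                res = enrichment_2x2(a, b, c, d)
            rows.append(
                {
                    "cluster": cluster,
                    "association": assoc,
                    "direction": direction,
                    "n_in_cluster": a,
                    "fisher_p": res.fisher_p,
                    "odds_ratio": res.odds_ratio,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "continuity_corrected": res.continuity_corrected,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# subgroup survival
# ---------------------------------------------------------------------------

@dataclass
class KMResult:
    curves: dict  # group -> DataFrame(time, survival)
    statistic: float
    p: float
    scheme: str


def km_logrank(
    clinical: pd.DataFrame,
    groups: pd.Series,
    scheme: str = "overall",
    endpoint: str = "rfs",
    boundary: float = 5.0,
) -> KMResult:
    """Kaplan–Meier curves per group plus the k-group log-rank test.

    The censoring-scheme transform is applied before estimation, so 'early'
    and 'late' views of the same cohort can be compared directly.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    tcol, ecol = f"{endpoint}_years", f"{endpoint}_event"
    common = groups.index.intersection(clinical.index)
    df = pd.DataFrame(
        {
            "group": groups.loc[common],
            "t": clinical.loc[common, tcol],
            "e": clinical.loc[common, ecol],
        }
    ).dropna()
    counts = df["group"].value_counts()
    if len(counts) < 2:
        raise ValueError("need at least 2 non-empty groups")
    if (counts == 0).any():
        raise ValueError("group with zero samples")
    t_s, e_s = apply_scheme(df["t"].to_numpy(), df["e"].to_numpy(dtype=int), scheme, boundary)
    df = df.assign(t=t_s, e=e_s)
    curves = {}
    for grp, sub in df.groupby("group", observed=True):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["t"], sub["e"], label=str(grp))
        sf = kmf.survival_function_
        curves[grp] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
    res = multivariate_logrank_test(df["t"], df["group"], df["e"])
    return KMResult(
        curves=curves,
        statistic=float(res.test_statistic),
        p=float(res.p_value),
        scheme=scheme,
    )
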