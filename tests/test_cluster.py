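"""Centroid-linkage clustering, 2x2 enrichment and subgroup survival."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from laterec import (
    cluster_category_enrichment,
    cluster_two_way,
    enrichment_2x2,
    km_logrank,
    subtype_enrichment,
)
from laterec.cluster import centroid_linkage_corr, cut_linkage, leaf_order

from conftest import make_matrix


# ---------------------------------------------------------------------------
# quadratic-time oracle: recompute every centroid distance from member lists
# ---------------------------------------------------------------------------

def _pearson_dist(a, b):
    return 1.0 - np.corrcoef(a, b)[0, 1]


def oracle_agglomerate(data):
    """Naive centroid linkage: full distance recomputation each step."""
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    clusters = {i: [i] for i in range(n)}
    next_id = n
    merges = []
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                ca = data[clusters[a]].mean(axis=0)
                cb = data[clusters[b]].mean(axis=0)
                d = _pearson_dist(ca, cb)
                if best is None or d < best[0] - 1e-15:
                    best = (d, a, b)
        d, a, b = best
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        merges.append((a, b, d))
        next_id += 1
    return merges


def _partition(merges, n, k):
    """Member sets after n-k merges, as a set of frozensets."""
    clusters = {i: {i} for i in range(n)}
    next_id = n
    for a, b, _ in merges[: n - k]:
        clusters[next_id] = clusters.pop(a) | clusters.pop(b)
        next_id += 1
    return {frozenset(v) for v in clusters.values()}


class TestCentroidLinkage:
    def test_duplicated_profiles_merge_first_at_zero_height(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((5, 12))
        data[3] = data[1]  # exact duplicate
        merges = centroid_linkage_corr(data)
        a, b, h, _ = merges[0]
        assert {int(a), int(b)} == {1, 3}
        assert h == pytest.approx(0.0, abs=1e-12)

    def test_planted_two_block_pattern_recovered_and_matches_oracle(self):
        rng = np.random.default_rng(1)
        base1, base2 = rng.standard_normal((2, 6))
        data = np.vstack(
            [base1 + 0.05 * rng.standard_normal(6) for _ in range(3)]
            + [base2 + 0.05 * rng.standard_normal(6) for _ in range(3)]
        )
        merges = centroid_linkage_corr(data)
        labels = cut_linkage(merges, 6, 2)
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels[0] != labels[3]
        mine = _partition([(int(a), int(b), h) for a, b, h, _ in merges], 6, 2)
        theirs = _partition(oracle_agglomerate(data), 6, 2)
        assert mine == theirs

    @pytest.mark.parametrize("seed", [2, 3, 4, 5])
    def test_random_matrices_match_quadratic_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        data = rng.standard_normal((n, 8))
        merges = centroid_linkage_corr(data)
        oracle = oracle_agglomerate(data)
        for k in range(2, n):
            mine = _partition([(int(a), int(b), h) for a, b, h, _ in merges], n, k)
            assert mine == _partition(oracle, n, k)
        np.testing.assert_allclose(
            merges[:, 2], [h for _, _, h in oracle], atol=1e-10
        )

    def test_cut_at_n_gives_singletons(self):
        rng = np.random.default_rng(7)
        data = rng.standard_normal((5, 10))
        merges = centroid_linkage_corr(data)
        labels = cut_linkage(merges, 5, 5)
        assert len(set(labels)) == 5

    def test_two_way_wrapper_drops_constant_rows(self):
        rng = np.random.default_rng(8)
        values = rng.standard_normal((10, 12))
        values[4] = 3.14  # constant probe
        x = make_matrix(values)
        with pytest.warns(UserWarning, match="constant"):
            res = cluster_two_way(x, k_samples=3, k_probes=3)
        assert "P005" in res.dropped_probes
        assert len(res.probe_clusters) == 9
        assert sorted(res.sample_groups.unique()) == ["G1", "G2", "G3"]
        assert len(res.sample_groups) == 12

    def test_leaf_order_covers_all_items(self):
        rng = np.random.default_rng(9)
        data = rng.standard_normal((7, 6))
        merges = centroid_linkage_corr(data)
        assert sorted(leaf_order(merges, 7)) == list(range(7))


class TestEnrichment2x2:
    def test_uniform_table(self):
        res = enrichment_2x2(1, 1, 1, 1)
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.fisher_p == pytest.approx(1.0)

    def test_swap_symmetries(self):
        res = enrichment_2x2(8, 3, 5, 9)
        both = enrichment_2x2(9, 5, 3, 8)  # swap rows and columns
        assert both.odds_ratio == pytest.approx(res.odds_ratio, rel=1e-12)
        assert both.fisher_p == pytest.approx(res.fisher_p, rel=1e-12)
        rows = enrichment_2x2(5, 9, 8, 3)  # swap rows only
        assert rows.odds_ratio == pytest.approx(1 / res.odds_ratio, rel=1e-12)

    def test_zero_cell_flags_and_uses_continuity_ci(self):
        res = enrichment_2x2(0, 10, 5, 5)
        assert res.odds_ratio == 0.0
        assert res.continuity_corrected
        assert np.isfinite(res.ci_low) and np.isfinite(res.ci_high)
        inf_res = enrichment_2x2(10, 0, 5, 5)
        assert inf_res.odds_ratio == np.inf

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            enrichment_2x2(0, 0, 5, 5)

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(st.integers(0, 12), st.integers(0, 12), st.integers(0, 12),
           st.integers(0, 12))
    def test_fisher_matches_hypergeometric_enumeration(self, a, b, c, d):
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            return
        res = enrichment_2x2(a, b, c, d)
        # exhaustive enumeration over tables with the observed margins
        n = a + b + c + d
        r1, c1 = a + b, a + c
        p_obs = stats.hypergeom.pmf(a, n, c1, r1)
        total = 0.0
        for k in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
            pk = stats.hypergeom.pmf(k, n, c1, r1)
            if pk <= p_obs * (1 + 1e-9):
                total += pk
        assert res.fisher_p == pytest.approx(min(1.0, total), abs=1e-10)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.integers(1, 12), st.integers(1, 12), st.integers(1, 12),
           st.integers(1, 12))
    def test_woolf_ci_contains_point_estimate(self, a, b, c, d):
        res = enrichment_2x2(a, b, c, d)
        assert res.ci_low <= res.odds_ratio <= res.ci_high


class TestCategoryEnrichment:
    def _screen(self, index, p_late, coef_late):
        return pd.DataFrame(
            {
                "p_early": 0.5, "coef_early": 0.1,
                "p_late": p_late, "coef_late": coef_late,
                "p_overall": 0.5, "coef_overall": 0.1,
            },
            index=index,
        )

    def test_constructed_table_matches_direct_arithmetic(self):
        probes = [f"g{i}" for i in range(225)]
        clusters = pd.Series(["C1"] * 25 + ["C2"] * 200, index=probes)
        # 20/25 late-direct inside C1, 10/200 outside
        p_late = np.r_[np.full(20, 1e-5), np.full(5, 0.5),
                       np.full(10, 1e-5), np.full(190, 0.5)]
        screen = self._screen(probes, p_late, 1.0)
        tab = cluster_category_enrichment(clusters, screen)
        row = tab[(tab["cluster"] == "C1") & (tab["association"] == "late")
                  & (tab["direction"] == "direct")].iloc[0]
        assert row["odds_ratio"] == pytest.approx((20 * 190) / (5 * 10))

    def test_zero_cell_category_flagged(self):
        probes = [f"g{i}" for i in range(30)]
        clusters = pd.Series(["C1"] * 10 + ["C2"] * 20, index=probes)
        p_late = np.r_[np.full(10, 0.5), np.full(5, 1e-5), np.full(15, 0.5)]
        tab = cluster_category_enrichment(clusters, self._screen(probes, p_late, 1.0))
        row = tab[(tab["cluster"] == "C1") & (tab["association"] == "late")
                  & (tab["direction"] == "direct")].iloc[0]
        assert row["odds_ratio"] == 0.0
        assert row["continuity_corrected"]

    def test_probe_missing_from_screen_rejected(self):
        clusters = pd.Series(["C1", "C2"], index=["g1", "gX"])
        with pytest.raises(ValueError):
            cluster_category_enrichment(clusters, self._screen(["g1"], [0.5], [1.0]))


class TestSubtypeEnrichment:
    def test_counts_conserved_across_cells(self):
        rng = np.random.default_rng(10)
        samples = [f"s{i}" for i in range(200)]
        groups = pd.Series(rng.choice(["G1", "G2", "G3"], 200), index=samples)
        subtypes = pd.Series(rng.choice(["LumA", "TNBC"], 200), index=samples)
        tab = subtype_enrichment(groups, subtypes)
        assert int(tab["n"].sum()) == 200


class TestKMLogrank:
    def _clin(self, t, e):
        return pd.DataFrame({"rfs_years": t, "rfs_event": e},
                            index=[f"s{i}" for i in range(len(t))])

    def test_identical_groups_give_null_statistic(self):
        t = np.r_[np.linspace(1, 10, 30), np.linspace(1, 10, 30)]
        e = np.r_[np.ones(30), np.ones(30)]
        groups = pd.Series(["A"] * 30 + ["B"] * 30,
                           index=[f"s{i}" for i in range(60)])
        res = km_logrank(self._clin(t, e), groups)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p == pytest.approx(1.0, abs=1e-9)

    def test_strong_hazard_ratio_detected(self):
        rng = np.random.default_rng(17)
        n = 400
        grp = rng.integers(0, 2, n)
        t = np.minimum(rng.exponential(1.0, n) / (0.1 * 3.0**grp), 12.0)
        e = (t < 12.0).astype(int)
        groups = pd.Series(np.where(grp == 1, "hi", "lo"),
                           index=[f"s{i}" for i in range(n)])
        res = km_logrank(self._clin(t, e), groups)
        assert res.p < 0.001
        assert set(res.curves) == {"hi", "lo"}

    def test_single_group_rejected(self):
        t = np.linspace(1, 5, 10)
        groups = pd.Series(["A"] * 10, index=[f"s{i}" for i in range(10)])
        with pytest.raises(ValueError):
            km_logrank(self._clin(t, np.ones(10)), groups)
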