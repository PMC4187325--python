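"""Cascade selection, metastasis-timing groups and signature validation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from laterec import (
    CascadeCriteria,
    CohortSpec,
    PairedCompartmentSet,
    cascade_select,
    concordance_c4,
    first_pc_score,
    generate_cohort,
    timing_groups,
    validate_signature,
)
from laterec.stroma import MetageneScore

from conftest import make_matrix


def _constructed_cascade(seed=41):
    """Pairs where probe truth is controlled filter-by-filter.

    Probes 0-29 satisfy all three criteria; probes 30-39 fail only the Cox
    filter, 40-49 fail only the correlation filter, 50-59 fail only the DE
    filter; 60-99 are background.
    """
    rng = np.random.default_rng(seed)
    n_pairs = 46
    v = rng.standard_normal(n_pairs)  # latent stromal factor
    grp = rng.permutation(np.r_[np.ones(12), np.zeros(n_pairs - 12)]).astype(bool)
    values = np.zeros((100, n_pairs))
    noise = lambda: 0.3 * rng.standard_normal(n_pairs)
    for i in range(30):  # all three
        values[i] = v + 1.5 * grp + noise()
    for i in range(30, 40):  # fails cox only
        values[i] = v + 1.5 * grp + noise()
    for i in range(40, 50):  # fails r only (group shift, no v)
        values[i] = 1.5 * grp + noise()
    for i in range(50, 60):  # fails DE only (v, no group shift)
        values[i] = v + noise()
    for i in range(60, 100):
        values[i] = rng.standard_normal(n_pairs)

    epi = make_matrix(values)
    epi_ids = list(epi.sample_ids)
    stroma_vals = pd.DataFrame(
        values, index=epi.values.index,
        columns=[f"T{j}" for j in range(n_pairs)],
    )
    stroma = make_matrix(stroma_vals.to_numpy(), tissue=["stroma"] * n_pairs)
    stroma.values.columns = stroma_vals.columns
    stroma.sample_annotation.index = stroma_vals.columns
    pairing = dict(zip(epi_ids, stroma_vals.columns))
    pairs = PairedCompartmentSet(epi, stroma, pairing)

    spc1 = MetageneScore(
        name="SPC1", probe_set=[], loadings=pd.Series(dtype=float),
        scores=pd.Series(v - v.mean(), index=list(stroma_vals.columns)),
        sign_anchor="constructed", explained_variance_ratio=1.0,
    )
    groups = pd.Series(np.where(grp, "G4", "G1"), index=epi_ids)
    probe_ids = list(epi.probe_ids)
    cox_p = np.full(100, 0.5)
    cox_coef = np.full(100, 0.0)
    good = list(range(30)) + list(range(40, 60))
    cox_p[good] = 1e-4
    cox_coef[good] = 1.0
    screen = pd.DataFrame(
        {"coef_overall": cox_coef, "p_overall": cox_p,
         "coef_late": cox_coef, "p_late": cox_p},
        index=probe_ids,
    )
    return pairs, spc1, groups, screen, probe_ids


class TestCascade:
    def test_planted_construction_selected_exactly(self):
        pairs, spc1, groups, screen, probe_ids = _constructed_cascade()
        res = cascade_select(pairs, spc1, groups, screen)
        sel = set(res.index[res["selected"]])
        assert sel == set(probe_ids[:30])
        # output ordered by descending correlation with SPC1
        r = res["r_spc1"].to_numpy()
        assert (np.diff(r[np.isfinite(r)]) <= 1e-12).all()

    def test_unattainable_threshold_yields_empty_signature(self):
        pairs, spc1, groups, screen, _ = _constructed_cascade()
        with pytest.warns(UserWarning, match="no probes"):
            res = cascade_select(pairs, spc1, groups, screen,
                                 CascadeCriteria(r_min=0.999999))
        assert not res["selected"].any()

    def test_selection_monotone_in_each_threshold(self):
        pairs, spc1, groups, screen, _ = _constructed_cascade()
        base = cascade_select(pairs, spc1, groups, screen,
                              CascadeCriteria(0.25, 0.05, 0.01))
        base_sel = set(base.index[base["selected"]])
        for crit in (CascadeCriteria(0.10, 0.05, 0.01),
                     CascadeCriteria(0.25, 0.20, 0.01),
                     CascadeCriteria(0.25, 0.05, 0.10)):
            relaxed = cascade_select(pairs, spc1, groups, screen, crit)
            assert base_sel <= set(relaxed.index[relaxed["selected"]])

    def test_filter_intersection_reconstructs_selection(self):
        pairs, spc1, groups, screen, _ = _constructed_cascade()
        res = cascade_select(pairs, spc1, groups, screen)
        recomputed = res["pass_r"] & res["pass_de"] & res["pass_cox"]
        assert (res["selected"] == recomputed).all()


class TestTimingGroups:
    def _clin(self, rows):
        return pd.DataFrame(rows, columns=["dmfs_years", "dmfs_event"],
                            index=[f"s{i}" for i in range(len(rows))])

    def test_rules(self):
        clin = self._clin([(16.0, 0), (4.0, 1), (9.0, 1), (8.0, 0), (5.0, 1)])
        tg = timing_groups(clin)
        assert tg["s0"] == "no-recurrence"
        assert tg["s1"] == "early-metastasis"
        assert tg["s2"] == "late-metastasis"
        assert "s3" not in tg.index  # censored at 8y: insufficient follow-up
        assert tg["s4"] == "late-metastasis"  # boundary counts as late

    def test_partition_no_overlap(self):
        rng = np.random.default_rng(12)
        clin = self._clin(list(zip(rng.uniform(0, 20, 200),
                                   rng.integers(0, 2, 200))))
        tg = timing_groups(clin)
        assert not tg.index.has_duplicates
        eligible = ((clin["dmfs_event"] == 1)
                    | ((clin["dmfs_event"] == 0) & (clin["dmfs_years"] >= 15)))
        assert set(tg.index) == set(clin.index[eligible])

    def test_negative_parameters_rejected(self):
        with pytest.raises(ValueError):
            timing_groups(self._clin([(1.0, 1)]), boundary=-1)


class TestValidate:
    def test_null_scores_give_uniform_late_vs_early_p(self):
        rng = np.random.default_rng(43)
        idx = [f"s{i}" for i in range(120)]
        groups = pd.Series(["early-metastasis"] * 60 + ["late-metastasis"] * 60,
                           index=idx)
        pvals = []
        for _ in range(200):
            scores = pd.Series(rng.standard_normal(120), index=idx)
            rep = validate_signature(scores, groups)
            pvals.append(rep.pairwise["p"].iloc[0])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_planted_late_signature_validates_on_large_cohort(self):
        c = generate_cohort(CohortSpec(seed=45, n_studies=4,
                                       samples_per_study=500, n_probes=300,
                                       stroma_coupling=0.8))
        tumor = c.clinical.index[c.clinical["tissue"] != "stroma"]
        epc1 = first_pc_score(
            c.expression.subset_samples(tumor), c.truth.late_probes, name="EPC1"
        )
        tg = timing_groups(c.clinical)
        rep = validate_signature(epc1, tg, clinical=c.clinical)
        assert (rep.group_medians["late-metastasis"]
                > rep.group_medians["early-metastasis"])
        row = rep.pairwise[rep.pairwise["comparison"]
                           == "early-metastasis vs late-metastasis"]
        assert float(row["p"].iloc[0]) < 0.01
        assert rep.anova_p < 0.01

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(8)
        idx = [f"s{i}" for i in range(60)]
        groups = pd.Series(["early-metastasis"] * 30 + ["late-metastasis"] * 30,
                           index=idx)
        scores = pd.Series(rng.standard_normal(60), index=idx)
        a = validate_signature(scores, groups)
        b = validate_signature(np.exp(3 * scores), groups)
        assert a.pairwise["p"].iloc[0] == pytest.approx(b.pairwise["p"].iloc[0],
                                                        rel=1e-12)

    def test_singleton_group_rejected(self):
        idx = [f"s{i}" for i in range(11)]
        groups = pd.Series(["early-metastasis"] + ["late-metastasis"] * 10,
                           index=idx)
        with pytest.raises(ValueError):
            validate_signature(pd.Series(np.arange(11.0), index=idx), groups)


class TestConcordance:
    def test_identical_sets_perfectly_concordant(self):
        rng = np.random.default_rng(2)
        x = make_matrix(rng.standard_normal((6, 50)))
        _, _, r = concordance_c4(x, list(x.probe_ids[:4]), list(x.probe_ids[:4]))
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_shared_latent_factor_drives_high_concordance(self):
        rng = np.random.default_rng(47)
        n = 200
        f = rng.standard_normal(n)
        coupling = 0.9
        mk = lambda: coupling * f + np.sqrt(1 - coupling**2) * rng.standard_normal(n)
        values = np.vstack([mk() for _ in range(10)])
        x = make_matrix(values)
        probes = list(x.probe_ids)
        _, _, r = concordance_c4(x, probes[:5], probes[5:])
        assert r > 0.8

    def test_independent_factors_give_null_concordance(self):
        rng = np.random.default_rng(49)
        n = 400
        f1, f2 = rng.standard_normal((2, n))
        values = np.vstack(
            [0.9 * f1 + 0.44 * rng.standard_normal(n) for _ in range(5)]
            + [0.9 * f2 + 0.44 * rng.standard_normal(n) for _ in range(5)]
        )
        x = make_matrix(values)
        probes = list(x.probe_ids)
        _, _, r = concordance_c4(x, probes[:5], probes[5:])
        assert abs(r) < 2.0 / np.sqrt(n)

    def test_missing_probe_set_rejected(self):
        rng = np.random.default_rng(3)
        x = make_matrix(rng.standard_normal((4, 20)))
        with pytest.raises(ValueError):
            concordance_c4(x, ["NOPE1", "NOPE2"], list(x.probe_ids[:2]))
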