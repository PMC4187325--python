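"""Censoring schemes, Cox fitters and the genome-scale screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from laterec import (
    CohortSpec,
    censor_early,
    censor_late,
    clinical_param_cox,
    cox_adjusted,
    cox_batch,
    cox_univariable,
    generate_cohort,
    screen_genome,
)
from laterec.survival import apply_scheme


class TestCensoring:
    @pytest.mark.parametrize(
        "time,event,expect", [(3.0, 1, 0), (7.0, 1, 1), (10.0, 0, 0), (5.0, 1, 1)]
    )
    def test_late_scheme(self, time, event, expect):
        t, e = censor_late([time], [event], 5.0)
        assert t[0] == time and e[0] == expect

    @pytest.mark.parametrize(
        "time,event,expect", [(7.0, 1, 0), (3.0, 1, 1), (5.0, 1, 0), (10.0, 0, 0)]
    )
    def test_early_scheme_boundary_counts_as_late(self, time, event, expect):
        # an event at exactly the boundary is 'at or after', so the early
        # transform censors it
        t, e = censor_early([time], [event], 5.0)
        assert t[0] == time and e[0] == expect

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            censor_late([-1.0], [1], 5.0)

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(
        time=st.floats(0, 20, allow_nan=False),
        event=st.integers(0, 1),
        boundary=st.floats(0.5, 10),
    )
    def test_event_partition_and_idempotence(self, time, event, boundary):
        _, e_late = censor_late([time], [event], boundary)
        _, e_early = censor_early([time], [event], boundary)
        # every event survives in exactly one of the two windows
        assert e_late[0] + e_early[0] == event
        t2, e2 = censor_late(*censor_late([time], [event], boundary), boundary)
        assert e2[0] == e_late[0]
        _, e3 = censor_early(*censor_early([time], [event], boundary), boundary)
        assert e3[0] == e_early[0]


class TestCoxUnivariable:
    # 6-sample fixture with an interior partial-likelihood maximum
    times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    events = np.array([1, 1, 1, 0, 0, 0])
    covariate = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0])

    @staticmethod
    def _log_partial_likelihood(b, x, t, e):
        order = np.argsort(t)
        x, t, e = x[order], t[order], e[order]
        ll = 0.0
        for i in range(len(t)):
            if e[i] == 1:
                risk = x[i:]
                ll += b * x[i] - np.log(np.sum(np.exp(b * risk)))
        return ll

    def test_matches_brute_force_grid(self):
        grid = np.arange(-5.0, 5.0, 1e-4)
        lls = [self._log_partial_likelihood(b, self.covariate, self.times,
                                            self.events) for b in grid]
        oracle = grid[int(np.argmax(lls))]
        coef, se, p = cox_univariable(self.covariate, self.times, self.events)
        assert coef == pytest.approx(oracle, abs=2e-4)

    def test_matches_lifelines(self):
        import lifelines

        rng = np.random.default_rng(2)
        x = rng.standard_normal(150)
        t = rng.exponential(4, 150) * np.exp(-0.4 * x)
        t = np.minimum(t, 6.0)
        e = (t < 6.0).astype(int)
        coef, se, p = cox_univariable(x, t, e)
        cph = lifelines.CoxPHFitter().fit(
            pd.DataFrame({"t": t, "e": e, "x": x}), "t", "e"
        )
        assert coef == pytest.approx(float(cph.params_["x"]), abs=1e-4)
        assert se == pytest.approx(float(cph.standard_errors_["x"]), abs=1e-4)

    def test_sign_equivariance(self):
        coef, _, p = cox_univariable(self.covariate, self.times, self.events)
        coef_neg, _, p_neg = cox_univariable(-self.covariate, self.times, self.events)
        assert coef_neg == pytest.approx(-coef, abs=1e-8)
        assert p_neg == pytest.approx(p, abs=1e-10)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError, match="variance"):
            cox_univariable(np.ones(6), self.times, self.events)
        with pytest.raises(ValueError, match="events"):
            cox_univariable(self.covariate, self.times, np.zeros(6, dtype=int))

    def test_efron_ties_match_lifelines(self):
        import lifelines

        rng = np.random.default_rng(4)
        x = rng.standard_normal(120)
        t = np.ceil(rng.exponential(3, 120) * np.exp(-0.5 * x))  # heavy ties
        t = np.minimum(t, 8.0)
        e = (t < 8.0).astype(int)
        coef, se, _ = cox_univariable(x, t, e)
        cph = lifelines.CoxPHFitter().fit(
            pd.DataFrame({"t": t, "e": e, "x": x}), "t", "e"
        )
        assert coef == pytest.approx(float(cph.params_["x"]), abs=1e-4)


class TestScreen:
    def test_recovers_planted_windows(self, cohort_seed5):
        c = cohort_seed5
        bulk = c.clinical.index[c.clinical["tissue"] == "bulk"]
        scr = screen_genome(c.expression.subset_samples(bulk), c.clinical)
        late_sens = (scr.loc[c.truth.late_probes, "p_late"] < 0.001).mean()
        early_leak = (scr.loc[c.truth.early_probes, "p_late"] < 0.001).mean()
        assert late_sens >= 0.70
        assert early_leak <= 0.05
        assert (scr.loc[c.truth.late_probes, "category"]
                .isin(["late-associated", "both"]).mean() >= 0.70)

    def test_null_probes_calibrated(self, cohort_seed5):
        c = cohort_seed5
        bulk = c.clinical.index[c.clinical["tissue"] == "bulk"]
        scr = screen_genome(c.expression.subset_samples(bulk), c.clinical)
        planted = set(
            c.truth.early_probes + c.truth.late_probes
            + c.truth.early_inverse_probes + c.truth.late_inverse_probes
            + c.truth.stromal_probes + list(c.truth.marker_probes.values())
        )
        null = [p for p in scr.index
                if p.startswith("P") and scr.loc[p, "flag"] == ""
                and p not in planted]
        frac = (scr.loc[null, "p_overall"] < 0.001).mean()
        lo, hi = stats.binom.interval(0.99, len(null), 0.001)
        assert lo / len(null) <= frac <= hi / len(null)

    def test_zero_threshold_selects_nothing(self, cohort_seed5):
        c = cohort_seed5
        bulk = c.clinical.index[c.clinical["tissue"] == "bulk"]
        scr = screen_genome(c.expression.subset_samples(bulk), c.clinical,
                            threshold=0.0)
        assert (scr["category"] == "neither").all()

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal((3, 100))
        t = rng.exponential(5, 100)
        e = (t < 8).astype(int)
        t = np.minimum(t, 8)
        a = cox_batch(x, t, e)
        b = cox_batch(3.0 * x + 11.0, t, e)
        assert np.allclose(b["coef"], a["coef"] / 3.0, atol=1e-7)
        assert np.allclose(b["p"], a["p"], atol=1e-9)

    def test_late_scheme_type_one_error_in_band(self):
        # single subtype so null probes are mutually independent (shared
        # subtype effects would correlate their p-values)
        spec = CohortSpec(seed=101, n_studies=4, samples_per_study=200,
                          n_probes=2072, n_batch_factors=0, n_early_genes=0,
                          n_late_genes=0, n_early_inverse_genes=0,
                          n_late_inverse_genes=0, n_stromal_genes=0,
                          stroma_pairs=0,
                          subtype_proportions=(1.0, 0.0, 0.0, 0.0))
        c = generate_cohort(spec)
        null = [p for p in c.expression.probe_ids
                if p not in set(c.truth.marker_probes.values())
                and not c.expression.probe_annotation.loc[p, "is_control"]]
        t, e = apply_scheme(c.clinical["rfs_years"].to_numpy(),
                            c.clinical["rfs_event"].to_numpy(int), "late")
        res = cox_batch(c.expression.values.loc[null].to_numpy(), t, e)
        frac = float((res["p"] < 0.05).mean())
        assert 0.035 <= frac <= 0.065


class TestCoxAdjusted:
    def _sim(self, seed=9, n=300):
        rng = np.random.default_rng(seed)
        grade = rng.integers(1, 4, n).astype(float)
        x = grade + rng.normal(0, 0.5, n)  # confounded with grade
        t = rng.exponential(10, n) * np.exp(-0.6 * grade)
        e = (t < 8).astype(int)
        t = np.minimum(t, 8.0)
        return x, t, e, pd.DataFrame({"grade": grade})

    def test_constant_covariates_reduce_to_univariable(self):
        x, t, e, _ = self._sim()
        covs = pd.DataFrame({"size": 2.0, "grade": 3.0}, index=range(len(x)))
        with pytest.warns(UserWarning, match="dropped"):
            adj = cox_adjusted(x, t, e, covs)
        coef, se, p = cox_univariable(x, t, e)
        assert adj["p"] == pytest.approx(p, abs=1e-8)
        assert adj["coef"] == pytest.approx(coef, abs=1e-8)

    def test_confounder_adjustment_raises_p(self):
        x, t, e, covs = self._sim(seed=9)
        _, _, p_uni = cox_univariable(x, t, e)
        adj = cox_adjusted(x, t, e, covs)
        assert adj["p"] > p_uni

    def test_empty_covariate_table_rejected(self):
        x, t, e, _ = self._sim()
        with pytest.raises(ValueError):
            cox_adjusted(x, t, e, pd.DataFrame(index=range(len(x))))


class TestClinicalParamCox:
    def _clinical(self, grade, t, e):
        return pd.DataFrame({
            "grade": grade, "rfs_years": t, "rfs_event": e,
            "size_cm": 2.0, "age": 55.0,
        })

    def test_null_construction_gives_unit_hr(self):
        t = np.tile(np.r_[np.linspace(0.5, 9, 40)], 2)
        e = np.tile(np.r_[np.ones(20), np.zeros(20)], 2)
        grade = np.r_[np.full(40, 3.0), np.full(40, 1.0)]  # same survival
        res = clinical_param_cox(self._clinical(grade, t, e), "grade")
        assert res["hr"] == pytest.approx(1.0, abs=1e-6)

    def test_recovers_true_hazard_ratio(self):
        rng = np.random.default_rng(13)
        n = 1000
        grp = rng.integers(0, 2, n)
        t = rng.exponential(1.0, n) / (0.1 * 2.0**grp)
        e = (t < 10).astype(int)
        t = np.minimum(t, 10.0)
        grade = np.where(grp == 1, 3.0, 1.0)
        res = clinical_param_cox(self._clinical(grade, t, e), "grade")
        assert 1.7 <= res["hr"] <= 2.35
        assert res["ci_low"] < res["hr"] < res["ci_high"]

    def test_label_swap_inverts_hr_and_ci(self):
        rng = np.random.default_rng(14)
        n = 400
        grp = rng.integers(0, 2, n)
        t = np.minimum(rng.exponential(5, n) * np.exp(-0.5 * grp), 8.0)
        e = (t < 8.0).astype(int)
        a = clinical_param_cox(
            self._clinical(np.where(grp == 1, 3.0, 1.0), t, e), "grade")
        b = clinical_param_cox(
            self._clinical(np.where(grp == 1, 1.0, 3.0), t, e), "grade")
        assert b["hr"] == pytest.approx(1 / a["hr"], rel=1e-6)
        assert b["ci_low"] == pytest.approx(1 / a["ci_high"], rel=1e-6)
        assert b["ci_high"] == pytest.approx(1 / a["ci_low"], rel=1e-6)

    def test_single_level_rejected(self):
        t = np.linspace(1, 5, 10)
        e = np.ones(10)
        with pytest.raises(ValueError, match="single level"):
            clinical_param_cox(self._clinical(np.full(10, 3.0), t, e), "grade")
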