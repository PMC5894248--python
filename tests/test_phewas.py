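"""Status assignment, logistic fitting, BH adjustment, and the scan."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ehrphewas import (
    RegressionSpec,
    STATUS_CASE,
    STATUS_CONTROL,
    STATUS_EXCLUDED,
    assign_phecode_status,
    assign_statuses,
    bh_adjust,
    count_fdr_significant,
    fit_logistic,
    run_phewas,
)
from ehrphewas.phewas import DegenerateOutcomeError

from conftest import make_events


class TestAssignStatus:
    def ev(self, sid, code, date):
        return (sid, code, "ICD9CM", date, "outpatient")

    def test_two_distinct_dates_is_case(self, pmap):
        events = make_events(
            [self.ev("a", "401.0", "2010-01-01"), self.ev("a", "401.0", "2010-02-01")]
        )
        assert assign_phecode_status(events, "401.1", pmap)["a"] == STATUS_CASE

    def test_single_date_is_excluded(self, pmap):
        events = make_events(
            [self.ev("a", "401.0", "2010-01-01"), self.ev("a", "401.0", "2010-01-01")]
        )
        assert assign_phecode_status(events, "401.1", pmap)["a"] == STATUS_EXCLUDED

    def test_no_related_events_is_control(self, pmap):
        events = make_events([self.ev("a", "486", "2010-01-01"), self.ev("a", "486", "2010-02-01")])
        assert assign_phecode_status(events, "401.1", pmap)["a"] == STATUS_CONTROL

    def test_exclusion_range_event_excludes_from_controls(self, pmap):
        # 403.11 maps to 401.22, inside 401.1's exclusion range 401-405.99,
        # but contributes no 401.1 dates -> excluded, not control
        events = make_events([self.ev("a", "403.11", "2010-01-01"),
                              self.ev("a", "403.11", "2010-02-01")])
        assert assign_phecode_status(events, "401.1", pmap)["a"] == STATUS_EXCLUDED

    def test_descendant_dates_count_toward_parent_case(self, pmap):
        # 434.91 maps to 433.21, a positional child of 433
        events = make_events([self.ev("a", "434.91", "2010-01-01"),
                              self.ev("a", "433.10", "2010-02-01")])
        assert assign_phecode_status(events, "433", pmap)["a"] == STATUS_CASE

    def test_unknown_phecode_is_lookup_error(self, pmap):
        with pytest.raises(KeyError):
            assign_phecode_status(make_events([]), "999.99", pmap)

    def test_unmapped_codes_are_ignored(self, pmap):
        events = make_events([self.ev("a", "V70.0", "2010-01-01"),
                              self.ev("a", "V70.0", "2010-02-01")])
        # subject appears in events but maps nowhere -> absent from statuses
        wide = assign_statuses(events, ["401.1"], pmap)
        assert "a" not in wide.index

    def test_status_partition_is_exhaustive_and_exclusive(self, pmap, rng):
        codes = [e.icd9_code for e in load_fixture_entries(pmap)]
        rows = []
        for i in range(60):
            for _ in range(rng.integers(0, 6)):
                day = f"2010-{rng.integers(1, 13):02d}-{rng.integers(1, 29):02d}"
                rows.append((f"s{i}", codes[rng.integers(len(codes))], "ICD9CM", day, "outpatient"))
        if not rows:
            return
        wide = assign_statuses(make_events(rows), pmap.phecodes, pmap)
        assert wide.isin([STATUS_CASE, STATUS_CONTROL, STATUS_EXCLUDED]).all().all()


def load_fixture_entries(pmap):
    return pmap.entries


class TestFitLogistic:
    @staticmethod
    def table_design(a, b, c, d):
        """2x2 table: exposed cases a, exposed controls b, unexposed cases c,
        unexposed controls d."""
        y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
        x = np.r_[np.ones(a + b), np.zeros(c + d)]
        return y, np.column_stack([np.ones_like(x), x])

    def test_cross_product_odds_ratio(self):
        y, X = self.table_design(20, 10, 10, 20)
        fit = fit_logistic(y, X)
        assert fit.converged
        assert np.exp(fit.beta[1]) == pytest.approx(4.0, rel=1e-8)

    def test_balanced_exposure_gives_null_or(self):
        y, X = self.table_design(15, 15, 15, 15)
        fit = fit_logistic(y, X)
        assert fit.beta[1] == pytest.approx(0.0, abs=1e-8)

    def test_label_flip_inverts_odds_ratio(self):
        y, X = self.table_design(17, 8, 11, 23)
        a = fit_logistic(y, X)
        b = fit_logistic(1 - y, X)
        assert np.exp(a.beta[1]) == pytest.approx(1 / np.exp(b.beta[1]), rel=1e-8)

    def test_one_class_outcome_raises(self):
        y = np.ones(10)
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.raises(DegenerateOutcomeError):
            fit_logistic(y, X)

    def test_separation_flagged_not_silently_fixed(self):
        # x perfectly predicts y: MLE at infinity
        y = np.r_[np.ones(10), np.zeros(10)]
        X = np.column_stack([np.ones(20), y.copy()])
        fit = fit_logistic(y, X)
        assert not fit.converged

    def test_matches_statsmodels_on_random_design(self, rng):
        import statsmodels.api as sm

        n = 500
        X = np.column_stack([np.ones(n), rng.normal(size=n), rng.integers(0, 2, n)])
        beta_true = np.array([-0.5, 0.8, 0.4])
        y = (rng.random(n) < 1 / (1 + np.exp(-X @ beta_true))).astype(float)
        ours = fit_logistic(y, X)
        ref = sm.Logit(y, X).fit(disp=0)
        np.testing.assert_allclose(ours.beta, ref.params, rtol=1e-6)
        np.testing.assert_allclose(np.sqrt(np.diag(ours.cov)), ref.bse, rtol=1e-5)


class TestBhAdjust:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_value_identity(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.2])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=200))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_monotone_and_dominates_input(self, pvals):
        adj = bh_adjust(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-15)
        order = np.argsort(pvals, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(300)
        np.testing.assert_allclose(bh_adjust(p), multipletests(p, method="fdr_bh")[1])


def _simulated_scan(rng, n=4000, beta_sle=np.log(3.0)):
    """Small synthetic status table with one planted effect on phecode 'p0'."""
    sle = (rng.random(n) < 0.2).astype(float)
    age = rng.integers(20, 80, n).astype(float)
    subjects = pd.DataFrame(
        {"subject_id": [f"s{i}" for i in range(n)], "sle": sle, "age": age}
    ).set_index("subject_id", drop=False)
    cols = {}
    for j in range(6):
        b = beta_sle if j == 0 else 0.0
        eta = -2.0 + b * sle
        cols[f"p{j}"] = np.where(rng.random(n) < 1 / (1 + np.exp(-eta)), 1, 0).astype("int8")
    statuses = pd.DataFrame(cols, index=subjects.index)
    return subjects, statuses


class TestRunPhewas:
    def test_min_cases_filter_drops_rare_codes(self, rng):
        subjects, statuses = _simulated_scan(rng, n=300)
        statuses["rare"] = np.zeros(len(subjects), dtype="int8")
        statuses.loc[statuses.index[:19], "rare"] = STATUS_CASE
        res = run_phewas(subjects=subjects, statuses=statuses,
                         spec=RegressionSpec(exposure="sle", min_cases=20))
        assert "rare" not in set(res["phecode"])

    def test_planted_effect_found_and_fdr_attached(self, rng):
        subjects, statuses = _simulated_scan(rng)
        res = run_phewas(statuses, subjects, RegressionSpec(exposure="sle", covariates=["age"]))
        assert res.iloc[0]["phecode"] == "p0"
        assert res.iloc[0]["fdr_p"] < 0.05
        assert (res["fdr_p"].dropna() >= res.loc[res["fdr_p"].notna(), "p"]).all()
        # counts partition the population
        row = res.iloc[0]
        assert row["n_case"] + row["n_control"] == len(subjects)

    def test_ci_brackets_or_when_converged(self, rng):
        subjects, statuses = _simulated_scan(rng)
        res = run_phewas(statuses, subjects, RegressionSpec(exposure="sle"))
        ok = res[res["converged"]]
        assert ((ok["ci_low"] <= ok["odds_ratio"]) & (ok["odds_ratio"] <= ok["ci_high"])).all()

    def test_constant_covariate_dropped_not_fatal(self, rng):
        subjects, statuses = _simulated_scan(rng, n=500)
        subjects["sex"] = "female"  # constant -> auto-dropped
        res = run_phewas(statuses, subjects, RegressionSpec(exposure="sle", covariates=["sex"]))
        assert len(res) > 0 and res["converged"].any()

    def test_zero_testable_returns_empty(self, rng):
        subjects, statuses = _simulated_scan(rng, n=100)
        res = run_phewas(statuses, subjects, RegressionSpec(exposure="sle", min_cases=1000))
        assert len(res) == 0

    def test_age_confounding_removed_by_adjustment(self, rng):
        # exposure effect flows only through age
        n = 20000
        age = rng.integers(20, 80, n).astype(float)
        expo = (rng.random(n) < 1 / (1 + np.exp(-(-1.5 + 0.05 * (age - 50))))).astype(float)
        disease = (rng.random(n) < 1 / (1 + np.exp(-(-2.5 + 0.05 * (age - 50))))).astype("int8")
        subjects = pd.DataFrame(
            {"subject_id": [f"s{i}" for i in range(n)], "sle": expo, "age": age}
        ).set_index("subject_id", drop=False)
        statuses = pd.DataFrame({"p0": disease}, index=subjects.index)
        crude = run_phewas(statuses, subjects, RegressionSpec(exposure="sle"))
        adj = run_phewas(statuses, subjects, RegressionSpec(exposure="sle", covariates=["age"]))
        assert crude.iloc[0]["ci_low"] > 1.0  # confounded crude OR
        assert adj.iloc[0]["ci_low"] <= 1.0 <= adj.iloc[0]["ci_high"]

    def test_followup_covariate_leaves_effect_intact(self, rng):
        subjects, statuses = _simulated_scan(rng)
        subjects["followup_years"] = rng.uniform(1, 20, len(subjects))
        res = run_phewas(
            statuses, subjects,
            RegressionSpec(exposure="sle", covariates=["age", "followup_years"]),
        )
        assert res.iloc[0]["phecode"] == "p0" and res.iloc[0]["fdr_p"] < 0.05


class TestCountFdrSignificant:
    def test_empty_results(self):
        assert count_fdr_significant(pd.DataFrame(columns=["fdr_p"]), 0.05) == 0

    def test_monotone_in_alpha(self, rng):
        res = pd.DataFrame({"fdr_p": rng.random(50)})
        assert count_fdr_significant(res, 0.10) >= count_fdr_significant(res, 0.05)
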