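"""Contingency, correlation and survival machinery against hand computations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from immugrade import reference_tables as ref
from immugrade.cohort_io import ClinicalRecord
from immugrade.stats import (
    CoxTerm,
    chisq_from_counts,
    cox_model,
    crosstab_chisq,
    km_survival,
    spearman_corr,
    survival_filter,
    standard_cox_terms,
)


class TestChiSquare:
    def test_sex_by_treatment_printed_p(self):
        _, _, p = chisq_from_counts(ref.SEX_BY_TREATMENT)
        assert round(p, 3) == 0.404

    def test_mucinous_by_treatment_printed_p(self):
        _, _, p = chisq_from_counts(ref.MUCINOUS_BY_TREATMENT)
        assert round(p, 3) == 0.123

    def test_cci_by_treatment_printed_p(self):
        _, _, p = chisq_from_counts(ref.CCI_BY_TREATMENT)
        assert round(p, 3) == 0.009

    def test_identical_distributions_give_null(self):
        a = ["x"] * 20 + ["y"] * 20
        b = (["g1"] * 10 + ["g2"] * 10) * 2
        ct = crosstab_chisq(a, b)
        assert ct.chi2 == pytest.approx(0.0)
        assert ct.p == pytest.approx(1.0)

    def test_missing_levels_complete_case(self):
        a = ["x", "x", "y", "y", "missing", None]
        b = ["g1", "g2", "g1", "g2", "g1", "g2"]
        ct = crosstab_chisq(a, b)
        assert ct.n == 4

    @settings(deadline=None, max_examples=40)
    @given(st.lists(st.integers(1, 50), min_size=4, max_size=4))
    def test_2x2_closed_form(self, cells):
        a, b, c, d = cells
        counts = np.array([[a, b], [c, d]])
        chi2, df, _ = chisq_from_counts(counts)
        n = a + b + c + d
        hand = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert chi2 == pytest.approx(hand)
        assert df == 1


class TestSpearman:
    def test_perfectly_increasing(self):
        rho, _ = spearman_corr([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0)

    def test_perfectly_decreasing(self):
        rho, _ = spearman_corr([1, 2, 3, 4], [4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_hand_rank_example(self):
        rho, _ = spearman_corr([1, 2, 3, 4], [2, 1, 4, 3])
        assert rho == pytest.approx(0.6)

    def test_constant_input_undefined(self):
        with pytest.warns(UserWarning, match="constant"):
            rho, _ = spearman_corr([1, 1, 1], [1, 2, 3])
        assert np.isnan(rho)


def _record(case_id, radicality="R0", postop=False):
    return ClinicalRecord(
        case_id=case_id, age_class="<65", sex="male", cci_class="0-2", treatment="nRT",
        tnm_stage="I", radicality=radicality, lvi=False, trg=None, postop_death=postop,
        time_dss=5.0, event_dss=False, time_os=5.0, event_os=False,
        follicle_count=1, front_length_mm=10.0,
    )


class TestSurvivalFilter:
    def test_only_r0_retained(self):
        records = [_record("a"), _record("b", "R1"), _record("c", "R2")]
        kept, log = survival_filter(records)
        assert [r.case_id for r in kept] == ["a"]
        assert log["removed_not_r0"] == 2

    def test_postoperative_death_removed(self):
        kept, log = survival_filter([_record("a"), _record("b", postop=True)])
        assert [r.case_id for r in kept] == ["a"]
        assert log["removed_postop_death"] == 1

    def test_empty_input(self):
        kept, log = survival_filter([])
        assert kept == [] and log["retained"] == 0


class TestKaplanMeier:
    def test_no_events_horizon_survival_one(self):
        km = km_survival([1, 2, 3], [False] * 3, horizon_years=5)
        assert km.survival_at_horizon["all"] == 1.0

    def test_hand_product_limit(self):
        km = km_survival([1, 2, 3, 4, 5], [1, 1, 0, 1, 0], horizon_years=5)
        curve = km.curves["all"].set_index("time")["survival"]
        assert curve.loc[1.0] == pytest.approx(0.8)
        assert curve.loc[2.0] == pytest.approx(0.6)
        assert curve.loc[4.0] == pytest.approx(0.3)
        assert km.survival_at_horizon["all"] == pytest.approx(0.3)

    def test_km_equals_empirical_without_censoring(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(5, 40)
        km = km_survival(t, [True] * 40, horizon_years=4.0)
        assert km.survival_at_horizon["all"] == pytest.approx(np.mean(t > 4.0))

    def test_identical_groups_logrank_null(self):
        t = [1, 2, 3, 4, 5] * 2
        e = [1, 1, 0, 1, 0] * 2
        g = ["a"] * 5 + ["b"] * 5
        km = km_survival(t, e, g)
        assert km.logrank_chi2 == pytest.approx(0.0, abs=1e-12)
        assert km.logrank_p == pytest.approx(1.0)

    def test_logrank_invariant_to_label_swap(self):
        rng = np.random.default_rng(7)
        t = rng.exponential(5, 60)
        e = rng.uniform(size=60) < 0.7
        g = np.array(["a", "b"] * 30)
        p1 = km_survival(t, e, g).logrank_p
        swapped = np.where(g == "a", "b", "a")
        p2 = km_survival(t, e, swapped).logrank_p
        assert p1 == pytest.approx(p2)


class TestCox:
    def test_identical_groups_hr_near_one(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(5, 200)
        df = pd.DataFrame({
            "time": np.concatenate([t, t]),
            "event": [1] * 400,
            "grp": ["a"] * 200 + ["b"] * 200,
        })
        res = cox_model(df, [CoxTerm("grp", ("a", "b"), "a")], "time", "event")
        hr = res.table.loc["grp=b", "hr"]
        lo, hi = res.table.loc["grp=b", ["ci_low", "ci_high"]]
        assert hr == pytest.approx(1.0, abs=0.01)
        assert lo < 1.0 < hi

    def test_parameter_recovery_binary_covariate(self):
        rng = np.random.default_rng(123)
        n = 1000
        x = rng.uniform(size=n) < 0.5
        t = rng.exponential(1.0 / (0.1 * np.exp(np.log(2.0) * x)))
        c = rng.exponential(1.0 / 0.025, n)  # ~20% censoring
        df = pd.DataFrame({
            "time": np.minimum(t, c),
            "event": (t <= c).astype(int),
            "x": np.where(x, "yes", "no"),
        })
        assert 0.10 <= 1 - df["event"].mean() <= 0.35  # ~20% censoring as intended
        res = cox_model(df, [CoxTerm("x", ("no", "yes"), "no")], "time", "event")
        assert 1.7 <= res.table.loc["x=yes", "hr"] <= 2.35

    def test_ci_coverage_over_replicates(self):
        hits = 0
        for rep in range(50):
            rng = np.random.default_rng(5000 + rep)
            n = 500
            x = rng.uniform(size=n) < 0.5
            t = rng.exponential(1.0 / (0.1 * np.exp(np.log(2.0) * x)))
            c = rng.exponential(1.0 / 0.025, n)
            df = pd.DataFrame({
                "time": np.minimum(t, c),
                "event": (t <= c).astype(int),
                "x": x.astype(float),
            })
            res = cox_model(df, [CoxTerm("x")], "time", "event")
            lo, hi = res.table.loc["x", ["ci_low", "ci_high"]]
            hits += lo <= 2.0 <= hi
        assert hits >= 43

    def test_standard_cox_row_structure(self):
        from immugrade.synthetic import default_config, simulate_cohort, truth_frame

        frame = truth_frame(simulate_cohort(default_config(seed=21, n_cases=400), with_cells=False))
        res = cox_model(frame, standard_cox_terms(), "time_dss", "event_dss")
        assert set(res.table.index) == {
            "cci_class=3", "cci_class=>=4", "sex=male",
            "tnm_stage=II", "tnm_stage=III", "tnm_stage=IV",
            "ig_dichot=low", "lvi=yes",
            "treatment=nRT", "treatment=SRT",
            "trg_modeled=2", "trg_modeled=3",
        }
        assert res.references["ig_dichot"] == "high"
        assert res.references["treatment"] == "CRT"
        assert (res.table["ci_low"] <= res.table["hr"]).all()
        assert (res.table["hr"] <= res.table["ci_high"]).all()


class TestReports:
    def test_report_shapes_and_percent_conservation(self, fixture_cohort):
        import warnings

        from immugrade.scoring import compute_cohort_scores
        from immugrade.spatial import pool_cohort
        from immugrade.stats import build_reports

        scores = compute_cohort_scores(
            pool_cohort(fixture_cohort.cores), fixture_cohort.clinical
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bundle = build_reports(scores, fixture_cohort.clinical)
        assert not bundle.characteristics.empty and not bundle.survival_strata.empty
        assert set(bundle.cox) == {"DSS", "OS"}
        for (var, col) in [("Sex", "nRT_pct"), ("Sex", "all_pct")]:
            block = bundle.characteristics[bundle.characteristics["variable"] == var]
            assert abs(block[col].sum() - 100) <= len(block)  # integer rounding slack

    def test_report_regeneration_identical(self, fixture_cohort, tmp_path):
        import warnings

        from immugrade.scoring import compute_cohort_scores
        from immugrade.spatial import pool_cohort
        from immugrade.stats import build_reports

        scores = compute_cohort_scores(
            pool_cohort(fixture_cohort.cores), fixture_cohort.clinical
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p1 = build_reports(scores, fixture_cohort.clinical).write(tmp_path / "r1")
            p2 = build_reports(scores, fixture_cohort.clinical).write(tmp_path / "r2")
        for a, b in zip(p1, p2):
            assert a.read_bytes() == b.read_bytes()
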