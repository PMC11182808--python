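import pandas as pd
import pytest

from oncolot.cohort import (
    AttritionReport, CohortConfig, apply_tnbc_filters, compute_charlson,
    detect_perioperative, select_mbc_candidates, summarize_baseline,
)
from oncolot.dictionaries import ANTHRACYCLINE_CONTAINING
from oncolot.schema import make_bundle
from oncolot.synthetic import SimulationConfig, generate_bundle, inject_violations


class TestCharlson:
    def test_metastatic_supersedes_primary(self, charlson_map):
        # C50 (any malignancy, 2) suppressed by C79 (metastatic, 6)
        assert compute_charlson(["C50", "C79"], charlson_map) == 6

    def test_single_category(self, charlson_map):
        assert compute_charlson(["I21"], charlson_map) == 1

    def test_empty(self, charlson_map):
        assert compute_charlson([], charlson_map) == 0

    def test_diabetes_hierarchy(self, charlson_map):
        assert compute_charlson(["E119", "E112"], charlson_map) == 2
        assert compute_charlson(["E119"], charlson_map) == 1

    def test_distinct_categories_sum(self, charlson_map):
        # MI (1) + CHF (1) + malignancy (2)
        assert compute_charlson(["I21", "I50", "C50"], charlson_map) == 4


def _periop_bundle(rx_days, surgery_day, base="2016-01-01", extra_rx=()):
    """One patient with a surgery and chemo prescriptions at given day offsets."""
    b = pd.Timestamp(base)
    rx = [("P1", (b + pd.Timedelta(days=d)).strftime("%Y-%m-%d"), code, "outpatient", 100.0)
          for d, code in [*rx_days, *extra_rx]]
    proc = [("P1", (b + pd.Timedelta(days=surgery_day)).strftime("%Y-%m-%d"),
             "breast_surgery", "inpatient", 5000.0)]
    return make_bundle(
        [("P1", "female", 1960, None, "2022-09-30")],
        [("P1", (b + pd.Timedelta(days=rx_days[0][0])).strftime("%Y-%m"), "C50", False)],
        rx, proc, "2015-01-01", "2022-09-30",
    )


class TestPerioperative:
    def test_adjuvant_within_window_after_surgery(self, dictionary, catalog):
        # surgery day 0, first prescription day 41 (< 92 days after)
        b = _periop_bundle([(41, "D030"), (62, "D030")], surgery_day=0)
        labels = detect_perioperative(b, CohortConfig(), dictionary, catalog)
        assert [l.label for l in labels] == ["adjuvant"]

    def test_neoadjuvant_before_surgery(self, dictionary, catalog):
        # last prescription day 60, surgery day 115 (< 92 days later)
        b = _periop_bundle([(0, "D030"), (60, "D030")], surgery_day=115)
        labels = detect_perioperative(b, CohortConfig(), dictionary, catalog)
        assert [l.label for l in labels] == ["neoadjuvant"]

    def test_far_from_surgery_is_none(self, dictionary, catalog):
        b = _periop_bundle([(300, "D030"), (321, "D030")], surgery_day=0)
        labels = detect_perioperative(b, CohortConfig(), dictionary, catalog)
        assert [l.label for l in labels] == ["none"]

    def test_anthracycline_taxane_series(self, dictionary, catalog):
        # adjuvant epirubicin/cyclophosphamide days 30..93, then paclitaxel
        # starting 35 days after its end: both become periop_series
        ec = [(d, code) for d in (30, 51, 72, 93) for code in ("D002", "D038")]
        tax = [(d, "D010") for d in (128, 149, 170)]
        b = _periop_bundle(ec, surgery_day=0, extra_rx=tax)
        labels = detect_perioperative(b, CohortConfig(), dictionary, catalog)
        assert [l.label for l in labels] == ["periop_series", "periop_series"]
        assert labels[0].category == ANTHRACYCLINE_CONTAINING


class TestSelection:
    def test_periop_only_patient_has_no_index(self, dictionary, catalog):
        b = _periop_bundle([(41, "D030"), (62, "D030")], surgery_day=0,
                           base="2017-02-01")
        labels = detect_perioperative(b, CohortConfig(), dictionary, catalog)
        cand, report = select_mbc_candidates(b, CohortConfig(), dictionary,
                                             catalog, labels)
        assert len(cand) == 0
        assert report.steps[1][2] == 1  # excluded at the regimen filter

    def test_index_outside_enrollment_window(self, dictionary, catalog):
        b = make_bundle(
            [("P1", "female", 1960, None, "2022-09-30")],
            [("P1", "2022-04", "C50", False)],
            [("P1", "2022-04-02", "D030", "outpatient", 100.0)],
            [], "2015-01-01", "2022-09-30",
        )
        cand, _ = select_mbc_candidates(b, CohortConfig(), dictionary, catalog, [])
        assert len(cand) == 0

    def test_diagnosis_month_before_index(self, dictionary, catalog):
        b = make_bundle(
            [("P1", "female", 1960, None, "2022-09-30")],
            [("P1", "2019-05", "C50", False)],
            [("P1", "2019-06-10", "D030", "outpatient", 100.0)],
            [], "2015-01-01", "2022-09-30",
        )
        cand, _ = select_mbc_candidates(b, CohortConfig(), dictionary, catalog, [])
        assert list(cand["first_line_index_date"]) == [pd.Timestamp("2019-06-10")]

    def test_suspected_diagnosis_ignored(self, dictionary, catalog):
        b = make_bundle(
            [("P1", "female", 1960, None, "2022-09-30")],
            [("P1", "2019-06", "C50", True)],
            [("P1", "2019-06-10", "D030", "outpatient", 100.0)],
            [], "2015-01-01", "2022-09-30",
        )
        cand, _ = select_mbc_candidates(b, CohortConfig(), dictionary, catalog, [])
        assert len(cand) == 0


@pytest.fixture(scope="module")
def violated(dictionary, catalog):
    bundle, _ = generate_bundle(SimulationConfig(n_patients=400, seed=9),
                                dictionary, catalog)
    kinds = ["hormonal_rx", "anti_her2_rx", "no_receptor_test",
             "no_lookback", "late_bc_diagnosis"]
    mod, injected = inject_violations(bundle, kinds, seed=5, n_per_kind=8)
    return mod, injected


class TestTnbcFilters:
    def _run(self, bundle, dictionary, catalog, charlson_map):
        cfg = CohortConfig()
        labels = detect_perioperative(bundle, cfg, dictionary, catalog)
        report = AttritionReport()
        cand, report = select_mbc_candidates(bundle, cfg, dictionary, catalog,
                                             labels, report=report)
        return apply_tnbc_filters(cand, bundle, cfg, dictionary, report,
                                  labels, charlson_map)

    def test_injected_patients_excluded_under_intended_filter(
            self, violated, dictionary, catalog, charlson_map):
        bundle, injected = violated
        members, report = self._run(bundle, dictionary, catalog, charlson_map)
        kept = set(members["patient_id"])
        for kind, pids in injected.items():
            assert not kept & set(pids), kind
        steps = dict((name, exc) for name, _, exc, _ in report.steps)
        assert steps["bc_diagnosis_same_or_previous_month"] == len(injected["late_bc_diagnosis"])
        assert steps["receptor_tests_before_index"] == len(injected["no_receptor_test"])
        assert steps["no_hormonal_or_anti_her2_rx"] == (
            len(injected["hormonal_rx"]) + len(injected["anti_her2_rx"]))
        assert steps["lookback_period"] == len(injected["no_lookback"])

    def test_attrition_conservation(self, violated, dictionary, catalog, charlson_map):
        bundle, _ = violated
        members, report = self._run(bundle, dictionary, catalog, charlson_map)
        for (_, n_before, n_exc, n_after), nxt in zip(report.steps, report.steps[1:]):
            assert n_before == n_exc + n_after
            assert n_after == nxt[1]
        assert report.final_n == len(members)

    def test_members_satisfy_predicates_independently(
            self, violated, dictionary, catalog, charlson_map):
        """Re-check each exclusion predicate directly, outside the cascade."""
        bundle, _ = violated
        members, _ = self._run(bundle, dictionary, catalog, charlson_map)
        excl = {c for c in dictionary.classes_by_code
                if dictionary.is_hormonal(c) or dictionary.is_anti_her2(c)}
        bad_rx = set(bundle.prescriptions.loc[
            bundle.prescriptions["drug_code"].isin(excl), "patient_id"])
        proc = bundle.procedures
        for row in members.itertuples(index=False):
            idx = row.first_line_index_date
            assert row.patient_id not in bad_rx
            tests = proc.loc[(proc["patient_id"] == row.patient_id)
                             & (proc["date"] < idx), "procedure_code"]
            assert {"her2_test", "er_test", "pr_test"} <= set(tests)
            assert idx <= pd.Timestamp("2022-09-30") - pd.Timedelta(days=180)

    def test_clean_synthetic_cohort_fully_retained(self, small_run):
        report = small_run["attrition"]
        assert all(exc == 0 for _, _, exc, _ in report.steps)
        assert report.final_n == 300


class TestBaseline:
    def test_counts_and_flags(self, charlson_map):
        members = pd.DataFrame([
            {"patient_id": "P1", "sex": "female", "age_at_index": 55,
             "age_group": "under65", "periop_history": "has_periop",
             "surgery": True, "radiation": False, "other_malignancy": False,
             "lymph_node_metastasis": True, "respiratory_digestive_metastasis": True,
             "other_site_metastasis": False, "charlson_index": 8},
            {"patient_id": "P2", "sex": "female", "age_at_index": 70,
             "age_group": "ge65", "periop_history": "no_periop",
             "surgery": False, "radiation": False, "other_malignancy": False,
             "lymph_node_metastasis": False, "respiratory_digestive_metastasis": False,
             "other_site_metastasis": False, "charlson_index": 2},
        ])
        cat = pd.Series({"P1": "other", "P2": "taxane_containing"})
        table = summarize_baseline(members, cat)
        all_row = table.loc[table["group"] == "all"].iloc[0]
        assert all_row["n"] == 2
        assert all_row["sex_female_pct"] == 100.0
        assert all_row["respiratory_digestive_metastasis_n"] == 1
        assert all_row["age_at_index_median"] == 62.5
        assert all_row["charlson_index_median"] == 5.0

    def test_empty_members_rejected(self):
        with pytest.raises(ValueError):
            summarize_baseline(pd.DataFrame(), pd.Series(dtype=object))
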