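import numpy as np
import pandas as pd
import pytest

from oncolot.dictionaries import ANTHRACYCLINE_CONTAINING, OTHER, TAXANE_CONTAINING
from oncolot.regimen import (
    LotConfig, assign_lines, build_regimen, classify_regimen,
    compute_exposure_end, effective_last_prescription_date, lines_table,
)

from conftest import make_rx

D = {"paclitaxel": "D010", "bevacizumab": "D041", "capecitabine": "D030",
     "eribulin": "D033", "epirubicin": "D002", "cyclophosphamide": "D038",
     "atezolizumab": "D020", "nab-paclitaxel": "D012",
     "s1": "D031", "pembrolizumab": "D021", "gemcitabine": "D034",
     "carboplatin": "D035"}


class TestBuildRegimen:
    def test_combination_within_window(self, dictionary, catalog):
        rx = make_rx("P1", [(0, D["paclitaxel"]), (7, D["bevacizumab"])])
        ep = build_regimen(rx, dictionary, catalog)
        assert ep.name == "Bevacizumab/Paclitaxel"
        assert ep.category == TAXANE_CONTAINING

    def test_single_agent(self, dictionary, catalog):
        ep = build_regimen(make_rx("P1", [(0, D["capecitabine"])]), dictionary, catalog)
        assert ep.name == "Capecitabine" and ep.components == {"capecitabine"}

    def test_drug_outside_window_excluded(self, dictionary, catalog):
        rx = make_rx("P1", [(0, D["paclitaxel"]), (40, D["eribulin"])])
        ep = build_regimen(rx, dictionary, catalog)
        assert ep.components == {"paclitaxel"}

    def test_unknown_anchor_drug_errors(self, dictionary, catalog):
        with pytest.raises(KeyError):
            build_regimen(make_rx("P1", [(0, "ZZZ")]), dictionary, catalog)

    def test_component_order_invariance(self, dictionary, catalog):
        base = [(0, D["epirubicin"]), (3, D["cyclophosphamide"]), (21, D["epirubicin"])]
        swapped = [(0, D["cyclophosphamide"]), (3, D["epirubicin"]), (21, D["epirubicin"])]
        a = build_regimen(make_rx("P1", base), dictionary, catalog)
        b = build_regimen(make_rx("P1", swapped), dictionary, catalog)
        assert a.name == b.name == "Epirubicin/Cyclophosphamide"
        assert a.category == b.category == ANTHRACYCLINE_CONTAINING


class TestClassification:
    @pytest.mark.parametrize("codes,category", [
        ([D["epirubicin"], D["cyclophosphamide"]], ANTHRACYCLINE_CONTAINING),
        ([D["atezolizumab"], D["nab-paclitaxel"]], TAXANE_CONTAINING),
        ([D["s1"]], OTHER),
        # an ICI without a taxane still lands in the taxane-containing group
        ([D["pembrolizumab"], D["gemcitabine"], D["carboplatin"]], TAXANE_CONTAINING),
    ])
    def test_categories(self, dictionary, catalog, codes, category):
        rx = make_rx("P1", [(i, c) for i, c in enumerate(codes)])
        assert classify_regimen(build_regimen(rx, dictionary, catalog)) == category


BASE = pd.Timestamp("2018-01-01")


def _day(n):
    return BASE + pd.Timedelta(days=n)


class TestExposureEnd:
    @pytest.mark.parametrize("dates,grace,expected", [
        ([0, 30, 200], 90, 120),
        ([0, 30, 60], 90, 60),
        ([0], 90, 0),
    ])
    def test_effective_last_prescription(self, dates, grace, expected):
        got = effective_last_prescription_date([_day(d) for d in dates], grace)
        assert got == _day(expected)

    def _episode(self, dictionary, catalog, days):
        return build_regimen(make_rx("P1", [(d, D["capecitabine"]) for d in days],
                                     start=BASE), dictionary, catalog)

    def test_death_beats_new_drug(self, dictionary, catalog):
        ep = self._episode(dictionary, catalog, [0, 30, 60, 90])
        end, reason = compute_exposure_end(
            ep, death_date=_day(100), last_visit_date=_day(400),
            new_drug_date=_day(150), study_end=_day(2000))
        assert (end, reason) == (_day(100), "death")

    def test_new_drug_minimum(self, dictionary, catalog):
        ep = self._episode(dictionary, catalog, [0, 30, 60])
        end, reason = compute_exposure_end(
            ep, death_date=None, last_visit_date=_day(300),
            new_drug_date=_day(80), study_end=_day(2000))
        assert (end, reason) == (_day(80), "new_drug")

    def test_tail_grace_lapse(self, dictionary, catalog):
        ep = self._episode(dictionary, catalog, [0, 30])
        end, reason = compute_exposure_end(
            ep, death_date=None, last_visit_date=_day(400),
            new_drug_date=None, study_end=_day(2000))
        assert (end, reason) == (_day(120), "grace_lapse")

    def test_tie_priority_death_first(self, dictionary, catalog):
        ep = self._episode(dictionary, catalog, [0, 30])
        end, reason = compute_exposure_end(
            ep, death_date=_day(120), last_visit_date=_day(120),
            new_drug_date=_day(120), study_end=_day(2000))
        assert (end, reason) == (_day(120), "death")


class TestAssignLines:
    def test_later_drug_starts_second_line(self, dictionary, catalog):
        # sparse first regimen: exposure lapses at day 21+90, the later
        # paclitaxel still opens a second line at its own date
        rx = make_rx("P1", [(0, D["capecitabine"]), (21, D["capecitabine"]),
                            (200, D["paclitaxel"]), (221, D["paclitaxel"])], start=BASE)
        lines, n_more = assign_lines(
            rx, index_date=BASE, death_date=None, last_visit_date=_day(2000),
            study_end=_day(2000), dictionary=dictionary, catalog=catalog)
        assert [l.line_number for l in lines] == [1, 2]
        assert lines[0].end_reason == "grace_lapse"
        assert lines[1].index_date == _day(200)
        assert n_more == 0

    def test_new_drug_switch_while_on_treatment(self, dictionary, catalog):
        rx = make_rx("P1", [(d, D["capecitabine"]) for d in range(0, 211, 21)]
                     + [(150, D["paclitaxel"]), (171, D["paclitaxel"])], start=BASE)
        lines, _ = assign_lines(
            rx, index_date=BASE, death_date=None, last_visit_date=_day(2000),
            study_end=_day(2000), dictionary=dictionary, catalog=catalog)
        assert lines[0].end_reason == "new_drug"
        assert lines[0].exposure_end_date == _day(150)
        assert lines[1].index_date == _day(150)

    def test_death_ends_single_line(self, dictionary, catalog):
        rx = make_rx("P1", [(0, D["capecitabine"]), (21, D["capecitabine"])], start=BASE)
        lines, _ = assign_lines(
            rx, index_date=BASE, death_date=_day(90), last_visit_date=_day(90),
            study_end=_day(2000), dictionary=dictionary, catalog=catalog)
        assert len(lines) == 1
        assert lines[0].end_reason == "death"
        assert lines[0].exposure_end_date == _day(90)

    def test_same_drug_never_triggers_new_line(self, dictionary, catalog):
        rx = make_rx("P1", [(d, D["capecitabine"]) for d in range(0, 400, 21)], start=BASE)
        lines, _ = assign_lines(
            rx, index_date=BASE, death_date=None, last_visit_date=_day(2000),
            study_end=_day(2000), dictionary=dictionary, catalog=catalog)
        assert len(lines) == 1

    def test_restart_after_lapse_is_new_line(self, dictionary, catalog):
        rx = make_rx("P1", [(0, D["capecitabine"]), (300, D["capecitabine"])], start=BASE)
        lines, _ = assign_lines(
            rx, index_date=BASE, death_date=None, last_visit_date=_day(2000),
            study_end=_day(2000), dictionary=dictionary, catalog=catalog)
        assert [l.line_number for l in lines] == [1, 2]
        assert lines[0].end_reason == "grace_lapse"
        assert lines[0].exposure_end_date == _day(90)
        assert lines[1].index_date == _day(300)


def _brute_force_exposure_end(comp_days, grace, death, visit, new_drug, study_end):
    """Day-by-day enumeration of the five exposure-end candidates."""
    comp_days = sorted(comp_days)
    lapse = None
    for day in range(comp_days[0], study_end + grace + 2):
        prior = [d for d in comp_days if d <= day]
        last = max(prior)
        if day - last == grace and not any(last < d <= day for d in comp_days):
            lapse = day
            break
    candidates = [(study_end, "study_end"), (lapse, "grace_lapse")]
    if death is not None:
        candidates.append((death, "death"))
    if visit is not None:
        candidates.append((visit, "last_visit"))
    if new_drug is not None:
        candidates.append((new_drug, "new_drug"))
    prio = {"death": 0, "new_drug": 1, "grace_lapse": 2, "last_visit": 3, "study_end": 4}
    return min(((d, r) for d, r in candidates if d is not None),
               key=lambda c: (c[0], prio[c[1]]))


def test_exposure_end_matches_brute_force_oracle(dictionary, catalog):
    rng = np.random.default_rng(42)
    grace, study_end = 90, 900
    for _ in range(60):
        n_rx = int(rng.integers(1, 15))
        days = sorted(set(np.cumsum(rng.integers(1, 130, n_rx)) - 1))
        death = int(rng.integers(50, 1000)) if rng.random() < 0.4 else None
        visit = int(rng.integers(100, 1200)) if rng.random() < 0.7 else None
        new_drug = int(rng.integers(days[0] + 29, 800)) if rng.random() < 0.5 else None
        ep = build_regimen(make_rx("P1", [(d, D["capecitabine"]) for d in days],
                                   start=BASE), dictionary, catalog)
        got = compute_exposure_end(
            ep, death_date=_day(death) if death else None,
            last_visit_date=_day(visit) if visit else None,
            new_drug_date=_day(new_drug) if new_drug else None,
            study_end=_day(study_end), grace_days=grace)
        exp_day, exp_reason = _brute_force_exposure_end(
            list(days), grace, death, visit, new_drug, study_end)
        assert got == (_day(exp_day), exp_reason)


class TestLineInvariants:
    def test_lines_time_ordered_and_bounded(self, small_run):
        lines = small_run["lines"]
        pat = small_run["bundle"].patients.set_index("patient_id")
        study_end = pd.Timestamp("2022-09-30")
        for pid, g in lines.groupby("patient_id"):
            g = g.sort_values("line_number")
            ends = g["exposure_end_date"].to_list()
            starts = g["index_date"].to_list()
            for e, s_next in zip(ends, starts[1:]):
                assert e <= s_next
            assert all(e <= study_end for e in ends)
            death = pat.loc[pid, "death_date"]
            if pd.notna(death):
                assert all(e <= death for e in ends)
            assert all(e <= pat.loc[pid, "last_visit_date"] for e in ends)

    def test_dense_prescriptions_never_lapse(self, dictionary, catalog):
        rx = make_rx("P1", [(d, D["capecitabine"]) for d in range(0, 420, 21)], start=BASE)
        lines, _ = assign_lines(
            rx, index_date=BASE, death_date=None, last_visit_date=_day(400),
            study_end=_day(2000), dictionary=dictionary, catalog=catalog)
        assert lines[0].end_reason in {"study_end", "death", "new_drug", "last_visit"}
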