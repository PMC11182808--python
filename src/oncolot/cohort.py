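"""Cohort selection: inclusion/exclusion cascade, perioperative chemotherapy
detection, Charlson comorbidity index, and baseline characteristics.

The metastatic first-line cohort is built in two stages.  First, candidates
are patients with a new, non-perioperative, non-hormonal breast-cancer
regimen starting inside the enrollment window whose breast-cancer diagnosis
(C50) falls in the index month or the month before.  Second, the
triple-negative filters remove patients without all three receptor tests
(HER2/ER/PR) strictly before index, patients with any hormonal or anti-HER2
prescription during the data period, patients without a 3-calendar-month
look-back of database activity before index, and patients whose index falls
too late to guarantee the minimum follow-up.

Perioperative (adjuvant/neoadjuvant) chemotherapy is detected from surgery
proximity: a regimen whose first prescription is within the adjuvant window
after surgery is adjuvant; one whose last prescription is within the
neoadjuvant window before surgery is neoadjuvant; an anthracycline regimen
followed by a taxane regimen at a gap of at most six weeks forms a series
that inherits the label when either member qualifies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dictionaries import (
    ANTHRACYCLINE_CONTAINING, TAXANE_CONTAINING,
    CharlsonMap, DrugDictionary, RegimenCatalog,
)
from .regimen import LotConfig, RegimenEpisode
from .schema import ClaimsBundle, same_or_previous_month

PERIOP_LABELS = ("adjuvant", "neoadjuvant", "periop_series", "none")

SURGERY_CODE = "breast_surgery"
RECEPTOR_TEST_CODES = ("her2_test", "er_test", "pr_test")
RADIATION_CODE = "radiation"


@dataclass(frozen=True)
class CohortConfig:
    enrollment_start: pd.Timestamp = pd.Timestamp("2017-01-01")
    enrollment_end: pd.Timestamp = pd.Timestamp("2022-03-31")
    study_end: pd.Timestamp = pd.Timestamp("2022-09-30")
    lookback_months: int = 3
    min_followup_days: int = 180
    adjuvant_window_days: int = 92
    neoadjuvant_window_days: int = 92
    sequential_periop_max_gap_days: int = 42
    ignore_suspected: bool = True

    def __post_init__(self):
        if not (self.enrollment_start < self.enrollment_end <= self.study_end):
            raise ValueError("need enrollment_start < enrollment_end <= study_end")


@dataclass(frozen=True)
class PerioperativeLabel:
    patient_id: str
    start: pd.Timestamp
    end: pd.Timestamp
    label: str
    surgery_date: pd.Timestamp | None
    category: str

    def __post_init__(self):
        if self.label not in PERIOP_LABELS:
            raise ValueError(f"unknown periop label {self.label!r}")
        if self.label != "none" and self.surgery_date is None:
            raise ValueError("periop label requires an anchoring surgery date")


@dataclass
class AttritionReport:
    """Ordered record of (filter, n_before, n_excluded, n_after) steps."""

    steps: list[tuple[str, int, int, int]] = field(default_factory=list)

    def add(self, name: str, n_before: int, n_excluded: int) -> None:
        if self.steps and self.steps[-1][3] != n_before:
            raise ValueError("attrition chain broken: n_before != previous n_after")
        if n_excluded < 0 or n_excluded > n_before:
            raise ValueError("excluded count out of range")
        self.steps.append((name, n_before, n_excluded, n_before - n_excluded))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["filter", "n_before", "n_excluded", "n_after"])

    @property
    def final_n(self) -> int:
        return self.steps[-1][3] if self.steps else 0


# ---------------------------------------------------------------------------
# Episode segmentation over a patient's whole record (pre-cohort)


def segment_episodes(prescriptions: pd.DataFrame, dictionary: DrugDictionary,
                     catalog: RegimenCatalog, config: LotConfig = LotConfig()):
    """Split a patient's breast-cancer prescriptions into regimen episodes.

    Episodes end at a grace lapse or at the first prescription of a drug
    outside the component set; prescription dates are trimmed to the episode.
    Used for perioperative labelling and index-date finding, before any
    cohort anchoring exists.
    """
    from .regimen import _episode_arrays, _lapse_day, _make_episode, bc_stream

    days, codes = bc_stream(prescriptions, dictionary)
    if not len(days):
        return []
    pid = str(prescriptions["patient_id"].iloc[0])
    episodes: list[RegimenEpisode] = []
    anchor: int | None = int(days[0])
    while anchor is not None and anchor <= days[-1]:
        comp, comp_days, new_drug = _episode_arrays(days, codes, anchor,
                                                    config.combo_window_days)
        lapse = _lapse_day(comp_days, config.grace_days)
        end = lapse if new_drug is None else min(lapse, new_drug)
        episodes.append(_make_episode(pid, comp, comp_days, end, dictionary, catalog))
        if new_drug is not None and new_drug <= lapse:
            anchor = new_drug
        else:
            later = np.nonzero(days > lapse)[0]
            anchor = int(days[later[0]]) if later.size else None
    return episodes


# ---------------------------------------------------------------------------
# Perioperative detection


def detect_perioperative(bundle: ClaimsBundle, config: CohortConfig,
                         dictionary: DrugDictionary, catalog: RegimenCatalog,
                         lot_config: LotConfig = LotConfig()) -> list[PerioperativeLabel]:
    """Label every regimen episode of every patient with surgery proximity."""
    surgery = bundle.procedures.loc[bundle.procedures["procedure_code"] == SURGERY_CODE]
    surgery_by_pid = surgery.groupby("patient_id")["date"].agg(list)
    labels: list[PerioperativeLabel] = []
    for pid, rx in bundle.prescriptions.groupby("patient_id"):
        episodes = segment_episodes(rx, dictionary, catalog, lot_config)
        if not episodes:
            continue
        surgeries = surgery_by_pid.get(pid, [])
        ep_labels = []
        for ep in episodes:
            label, surg = _surgery_proximity_label(ep, surgeries, config)
            ep_labels.append([ep, label, surg])
        _apply_series_rule(ep_labels, config)
        labels.extend(PerioperativeLabel(pid, ep.start, ep.rx_dates[-1], lab, surg, ep.category)
                      for ep, lab, surg in ep_labels)
    return labels


def _surgery_proximity_label(ep: RegimenEpisode, surgeries, config: CohortConfig):
    adj = pd.Timedelta(days=config.adjuvant_window_days)
    neo = pd.Timedelta(days=config.neoadjuvant_window_days)
    last = ep.rx_dates[-1]
    for s in surgeries:
        if s <= ep.start <= s + adj:
            return "adjuvant", s
    for s in surgeries:
        if s - neo <= last <= s:
            return "neoadjuvant", s
    return "none", None


def _apply_series_rule(ep_labels, config: CohortConfig) -> None:
    """Anthracycline episode followed by a taxane episode at <= the series gap
    forms a perioperative series when either member already qualifies."""
    gap = pd.Timedelta(days=config.sequential_periop_max_gap_days)
    for (a, lab_a, surg_a), (b, lab_b, surg_b), pair in zip(
            ep_labels, ep_labels[1:], zip(ep_labels, ep_labels[1:])):
        first, second = pair
        if a.category != ANTHRACYCLINE_CONTAINING or b.category != TAXANE_CONTAINING:
            continue
        sequential = (b.start - a.rx_dates[-1] <= gap) or (b.start - a.start <= gap)
        if not sequential:
            continue
        if lab_a != "none" or lab_b != "none":
            surg = surg_a if surg_a is not None else surg_b
            first[1] = second[1] = "periop_series"
            first[2] = second[2] = surg


# ---------------------------------------------------------------------------
# Inclusion cascade


def select_mbc_candidates(bundle: ClaimsBundle, config: CohortConfig,
                          dictionary: DrugDictionary, catalog: RegimenCatalog,
                          periop: list[PerioperativeLabel],
                          lot_config: LotConfig = LotConfig(),
                          report: AttritionReport | None = None):
    """Find metastatic candidates and tentative first-line index dates.

    The tentative index is the start of the earliest episode that is not
    perioperative and begins inside the enrollment window; patients whose
    breast-cancer diagnosis (C50) is not in the index month or the month
    before are then excluded.
    """
    report = report if report is not None else AttritionReport()
    periop_starts = {(l.patient_id, l.start) for l in periop if l.label != "none"}

    all_ids = list(bundle.patients["patient_id"])
    report.add("patients_in_data", len(all_ids), 0)

    index_by_pid: dict[str, pd.Timestamp] = {}
    for pid, rx in bundle.prescriptions.groupby("patient_id"):
        for ep in segment_episodes(rx, dictionary, catalog, lot_config):
            if (pid, ep.start) in periop_starts:
                continue
            # earliest non-perioperative regimen decides; only a start inside
            # the enrollment window qualifies the patient
            if config.enrollment_start <= ep.start <= config.enrollment_end:
                index_by_pid[str(pid)] = ep.start
            break
    report.add("new_regimen_in_enrollment_window", len(all_ids), len(all_ids) - len(index_by_pid))

    dx = bundle.diagnoses
    if config.ignore_suspected:
        dx = dx.loc[~dx["suspected_flag"]]
    c50 = dx.loc[dx["icd10_code"].str.startswith("C50")]
    c50_months = c50.groupby("patient_id")["month"].agg(set)
    kept = {}
    for pid, index_date in index_by_pid.items():
        months = c50_months.get(pid, set())
        if any(same_or_previous_month(m, index_date) for m in months):
            kept[pid] = index_date
    report.add("bc_diagnosis_same_or_previous_month", len(index_by_pid), len(index_by_pid) - len(kept))

    candidates = pd.DataFrame(
        {"patient_id": list(kept), "first_line_index_date": list(kept.values())}
    ).sort_values("patient_id").reset_index(drop=True)
    return candidates, report


def apply_tnbc_filters(candidates: pd.DataFrame, bundle: ClaimsBundle,
                       config: CohortConfig, dictionary: DrugDictionary,
                       report: AttritionReport | None = None,
                       periop: list[PerioperativeLabel] | None = None,
                       charlson: CharlsonMap | None = None):
    """Apply the triple-negative exclusions and build the member table."""
    report = report if report is not None else AttritionReport()
    if not report.steps:
        report.add("mbc_candidates", len(candidates), 0)

    idx = dict(zip(candidates["patient_id"], candidates["first_line_index_date"]))

    # 1. all three receptor tests strictly before index
    proc = bundle.procedures
    tests = proc.loc[proc["procedure_code"].isin(RECEPTOR_TEST_CODES)]
    ok_tests = set()
    for pid, grp in tests.groupby("patient_id"):
        pid = str(pid)
        if pid not in idx:
            continue
        before = grp.loc[grp["date"] < idx[pid]]
        if set(before["procedure_code"]) >= set(RECEPTOR_TEST_CODES):
            ok_tests.add(pid)
    survivors = [p for p in idx if p in ok_tests]
    report.add("receptor_tests_before_index", len(idx), len(idx) - len(survivors))

    # 2. no hormonal or anti-HER2 prescription anywhere in the data period
    rx = bundle.prescriptions
    excl_codes = {c for c in dictionary.classes_by_code
                  if dictionary.is_hormonal(c) or dictionary.is_anti_her2(c)}
    flagged = set(rx.loc[rx["drug_code"].isin(excl_codes), "patient_id"].astype(str))
    n_before = len(survivors)
    survivors = [p for p in survivors if p not in flagged]
    report.add("no_hormonal_or_anti_her2_rx", n_before, n_before - len(survivors))

    # 3. look-back: first database activity >= lookback_months calendar months before index
    first_activity = _first_activity_month(bundle)
    n_before = len(survivors)
    survivors = [p for p in survivors
                 if first_activity.get(p) is not None
                 and first_activity[p] <= idx[p].to_period("M") - config.lookback_months]
    report.add("lookback_period", n_before, n_before - len(survivors))

    # 4. follow-up guarantee: index early enough for the minimum follow-up
    cutoff = config.study_end - pd.Timedelta(days=config.min_followup_days)
    n_before = len(survivors)
    survivors = [p for p in survivors if idx[p] <= cutoff]
    report.add("minimum_followup_window", n_before, n_before - len(survivors))

    members = _build_members(survivors, idx, bundle, config, periop or [], charlson)
    return members, report


def _first_activity_month(bundle: ClaimsBundle) -> dict[str, pd.Period]:
    out: dict[str, pd.Period] = {}
    if len(bundle.diagnoses):
        for pid, m in bundle.diagnoses.groupby("patient_id")["month"].min().items():
            out[str(pid)] = m
    for df in (bundle.prescriptions, bundle.procedures):
        if len(df):
            for pid, d in df.groupby("patient_id")["date"].min().items():
                m = d.to_period("M")
                pid = str(pid)
                if pid not in out or m < out[pid]:
                    out[pid] = m
    return out


def compute_charlson(icd10_codes, cmap: CharlsonMap) -> int:
    """Charlson comorbidity index: sum of weights over matched categories
    after hierarchy rules (a category superseding another suppresses it)."""
    cats = cmap.matched_categories(icd10_codes)
    suppressed = {cmap.superseded_by(c) for c in cats} - {None}
    return sum(cmap.weight_of(c) for c in cats - suppressed)


def _build_members(survivors, idx, bundle, config, periop, charlson_map):
    periop_pids = {l.patient_id for l in periop if l.label != "none"}
    pat = bundle.patients.set_index("patient_id")
    dx = bundle.diagnoses
    if config.ignore_suspected and len(dx):
        dx = dx.loc[~dx["suspected_flag"]]
    dx_by_pid = dict(iter(dx.groupby("patient_id"))) if len(dx) else {}
    proc_by_pid = dict(iter(bundle.procedures.groupby("patient_id")))

    rows = []
    for pid in sorted(survivors):
        index_date = idx[pid]
        index_month = index_date.to_period("M")
        birth_year = int(pat.loc[pid, "birth_year"])
        age = index_date.year - birth_year
        pdx = dx_by_pid.get(pid)
        codes = ()
        if pdx is not None:
            codes = tuple(pdx.loc[pdx["month"] <= index_month, "icd10_code"])
        pproc = proc_by_pid.get(pid)
        had = lambda code: pproc is not None and bool(
            ((pproc["procedure_code"] == code) & (pproc["date"] <= index_date)).any())
        rows.append({
            "patient_id": pid,
            "first_line_index_date": index_date,
            "sex": pat.loc[pid, "sex"],
            "age_at_index": age,
            "age_group": "under65" if age < 65 else "ge65",
            "periop_history": "has_periop" if pid in periop_pids else "no_periop",
            "surgery": had(SURGERY_CODE),
            "radiation": had(RADIATION_CODE),
            "other_malignancy": any(c.startswith("C") and not c.startswith("C50") for c in codes),
            "lymph_node_metastasis": any(c.startswith("C77") for c in codes),
            "respiratory_digestive_metastasis": any(c.startswith("C78") for c in codes),
            "other_site_metastasis": any(c.startswith("C79") for c in codes),
            "charlson_index": (compute_charlson(codes, charlson_map)
                               if charlson_map is not None else 0),
        })
    cols = ["patient_id", "first_line_index_date", "sex", "age_at_index", "age_group",
            "periop_history", "surgery", "radiation", "other_malignancy",
            "lymph_node_metastasis", "respiratory_digestive_metastasis",
            "other_site_metastasis", "charlson_index"]
    return pd.DataFrame(rows, columns=cols)


def summarize_baseline(members: pd.DataFrame, first_line_category: pd.Series) -> pd.DataFrame:
    """Baseline characteristics by first-line regimen category.

    *first_line_category* maps patient_id to the line-1 regimen category.
    Counts and percentages for the categorical rows, median and quartiles
    for age and the Charlson index.
    """
    if members.empty:
        raise ValueError("members must be non-empty")
    df = members.copy()
    df["category"] = df["patient_id"].map(first_line_category)
    groups = {"all": df}
    for cat in (ANTHRACYCLINE_CONTAINING, TAXANE_CONTAINING, "other"):
        groups[cat] = df.loc[df["category"] == cat]

    flag_rows = [
        ("age_under65", df["age_group"] == "under65"),
        ("age_ge65", df["age_group"] == "ge65"),
        ("sex_female", df["sex"] == "female"),
        ("sex_male", df["sex"] == "male"),
        ("periop_history", df["periop_history"] == "has_periop"),
        ("surgery", df["surgery"]),
        ("radiation", df["radiation"]),
        ("other_malignancy", df["other_malignancy"]),
        ("lymph_node_metastasis", df["lymph_node_metastasis"]),
        ("respiratory_digestive_metastasis", df["respiratory_digestive_metastasis"]),
        ("other_site_metastasis", df["other_site_metastasis"]),
    ]
    out = []
    for name, g in groups.items():
        n = len(g)
        row = {"group": name, "n": n}
        for label, mask in flag_rows:
            k = int(mask.loc[g.index].sum())
            row[f"{label}_n"] = k
            row[f"{label}_pct"] = round(100.0 * k / n, 1) if n else float("nan")
        for var in ("age_at_index", "charlson_index"):
            s = g[var]
            row[f"{var}_median"] = float(s.median()) if n else float("nan")
            row[f"{var}_q1"] = float(s.quantile(0.25)) if n else float("nan")
            row[f"{var}_q3"] = float(s.quantile(0.75)) if n else float("nan")
        out.append(row)
    return pd.DataFrame(out)
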