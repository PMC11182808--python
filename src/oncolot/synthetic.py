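"""Synthetic claims generator emulating a Japanese hospital claims database
for the metastatic triple-negative breast cancer (mTNBC) treatment-pattern
analysis.

Every simulated patient is constructed to satisfy the cohort rules: a C50
diagnosis in the index month or the month before, all three receptor tests
(HER2/ER/PR) before the first-line index, a clean 3-month look-back, no
hormonal or anti-HER2 prescriptions, and (for a configurable fraction) a
perioperative surgery + chemotherapy history placed 400–800 days before the
metastatic index so the adjuvant/series rules have real work to do.

The line-transition/death process uses per-line exponential
time-to-next-treatment-or-death (TTNTD) clocks with configurable medians and
per-line transition probabilities.  A line switch is never emitted inside
the combination window (default 28 days): within the window a new drug is
definitionally a combination component, so such draws are floored at
window + 1 days.  This leaves the survival curve unchanged at and beyond
any time larger than the window.  Early treatment discontinuation (a stop of
prescriptions followed by a grace lapse) is drawn independently of the
event clock so that grace-lapse censoring of TTNTD stays non-informative.

Adverse-event co-claims are placed in the calendar month of the line start
(diagnosis code plus AE-treatment drug the same month), matching the
attribution rule; ``ae_month_offset`` moves them to later months to create
true negatives.  Costs are log-normal remuneration points: per-prescription
drug points, monthly outpatient visit claims, and an occasional inpatient
episode, with per-line medians escalating across lines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dictionaries import AE_CATEGORIES, DrugDictionary, RegimenCatalog, load_ae_code_map
from .schema import DAYS_PER_MONTH, ClaimsBundle, make_bundle

VIOLATION_KINDS = ("hormonal_rx", "anti_her2_rx", "no_receptor_test",
                   "no_lookback", "late_bc_diagnosis")

#: per-line regimen frequency weights (patient counts of the treatment-pattern
#: table, with the "Others" mass spread over the remaining named regimens)
DEFAULT_REGIMEN_WEIGHTS: tuple[dict[str, float], ...] = (
    {
        "Capecitabine": 427, "S-1 (Tegafur-Gimeracil-Oteracil)": 324,
        "Epirubicin/Cyclophosphamide": 247, "Bevacizumab/Paclitaxel": 206,
        "Paclitaxel": 196, "Docetaxel": 130, "Doxorubicin/Cyclophosphamide": 100,
        "Epirubicin/Fluorouracil/Cyclophosphamide": 89, "Tegafur-Uracil": 100,
        "Eribulin": 80, "Docetaxel/Cyclophosphamide": 60, "Nab-Paclitaxel": 60,
        "Atezolizumab/Nab-Paclitaxel": 59, "Gemcitabine": 50, "Vinorelbine": 40,
        "Pembrolizumab/Gemcitabine/Carboplatin": 20, "Gemcitabine/Carboplatin": 19,
        "Irinotecan": 17, "Cyclophosphamide/Methotrexate/Fluorouracil": 12,
    },
    {
        "Eribulin": 190, "Bevacizumab/Paclitaxel": 150, "Paclitaxel": 121,
        "Docetaxel": 116, "S-1 (Tegafur-Gimeracil-Oteracil)": 115,
        "Capecitabine": 90, "Gemcitabine": 50, "Tegafur-Uracil": 44,
        "Atezolizumab/Nab-Paclitaxel": 40, "Nab-Paclitaxel": 30, "Vinorelbine": 30,
        "Gemcitabine/Carboplatin": 25, "Docetaxel/Cyclophosphamide": 20,
        "Irinotecan": 20,
    },
    {
        "Eribulin": 90, "Bevacizumab/Paclitaxel": 81,
        "S-1 (Tegafur-Gimeracil-Oteracil)": 52, "Capecitabine": 51,
        "Paclitaxel": 40, "Docetaxel": 30, "Gemcitabine": 29,
        "Atezolizumab/Nab-Paclitaxel": 25, "Vinorelbine": 20, "Nab-Paclitaxel": 20,
        "Tegafur-Uracil": 16, "Irinotecan": 10,
    },
)

#: per-regimen AE probabilities, order = AE_CATEGORIES (nausea/vomiting,
#: neutropenia/leukopenia, febrile neutropenia, anemia, diarrhea, ILD,
#: peripheral neuropathy), as fractions
DEFAULT_AE_PROBS: dict[str, tuple[float, ...]] = {
    "Doxorubicin/Cyclophosphamide": (.941, .445, .118, .160, .067, .034, .059),
    "Epirubicin/Cyclophosphamide": (.923, .470, .140, .120, .033, .007, .037),
    "Epirubicin/Fluorouracil/Cyclophosphamide": (.838, .476, .143, .143, .038, .000, .048),
    "Docetaxel/Cyclophosphamide": (.833, .597, .139, .056, .042, .014, .111),
    "Paclitaxel": (.770, .197, .018, .124, .061, .036, .164),
    "Docetaxel": (.828, .436, .068, .084, .064, .024, .088),
    "Nab-Paclitaxel": (.623, .156, .039, .182, .091, .000, .143),
    "Atezolizumab/Nab-Paclitaxel": (.677, .081, .032, .089, .056, .056, .081),
    "Pembrolizumab/Paclitaxel": (1.00, .000, .000, .250, .000, .250, .000),
    "Pembrolizumab/Nab-Paclitaxel": (.000, .000, .000, .000, .000, .000, .000),
    "Bevacizumab/Paclitaxel": (.796, .110, .030, .098, .057, .018, .137),
    "Cyclophosphamide/Methotrexate/Fluorouracil": (.833, .333, .083, .083, .167, .000, .000),
    "Pembrolizumab/Gemcitabine/Carboplatin": (.927, .268, .098, .293, .049, .000, .122),
    "Eribulin": (.731, .180, .033, .078, .059, .020, .121),
    "Vinorelbine": (.610, .102, .034, .119, .051, .000, .068),
    "Gemcitabine": (.739, .043, .014, .116, .029, .014, .087),
    "Gemcitabine/Carboplatin": (.818, .227, .091, .227, .045, .000, .045),
    "Irinotecan": (.882, .118, .059, .235, .353, .000, .059),
    "Capecitabine": (.273, .023, .005, .036, .152, .005, .080),
    "S-1 (Tegafur-Gimeracil-Oteracil)": (.387, .043, .008, .096, .157, .008, .086),
    "Tegafur-Uracil": (.094, .021, .005, .042, .031, .021, .094),
}

#: representative AE-treatment drug per required class
AE_CLASS_DRUGS = {
    "antiemetic": "granisetron", "g_csf": "filgrastim", "antibiotic": "cefepime",
    "anemia_rx": "epoetin", "antidiarrheal": "loperamide",
    "corticosteroid": "prednisolone", "neuropathy_rx": "pregabalin",
}


@dataclass(frozen=True)
class CostPoints:
    """Log-normal remuneration-point parameters (medians in points)."""

    drug_rx_median: tuple[float, ...] = (6000.0, 10000.0, 13000.0)
    drug_rx_sigma: float = 0.5
    visit_median: tuple[float, ...] = (2000.0, 3000.0, 3500.0)
    visit_sigma: float = 0.6
    inpatient_prob: float = 0.35
    inpatient_median: float = 30000.0
    inpatient_sigma: float = 0.8
    ae_rx_points: float = 500.0
    receptor_test_points: float = 2000.0
    surgery_points: float = 50000.0


@dataclass(frozen=True)
class SimulationConfig:
    n_patients: int = 1000
    seed: int = 0
    line_transition_probs: tuple[float, ...] = (0.47, 0.45)
    ttntd_medians_months: tuple[float, ...] = (8.0, 6.5, 5.2)
    death_vs_next_treatment_ratio: float = 1.0
    prescription_interval_days: int = 21
    discontinuation_prob: float = 0.30
    discontinuation_median_months: float = 2.5
    regimen_catalog_weights: tuple[dict[str, float], ...] = DEFAULT_REGIMEN_WEIGHTS
    ae_probs: dict[str, tuple[float, ...]] = field(default_factory=lambda: dict(DEFAULT_AE_PROBS))
    cost_points: CostPoints = CostPoints()
    periop_history_prob: float = 0.45
    combo_window_days: int = 28
    index_window: tuple[str, str] = ("2017-01-15", "2018-06-30")
    data_start: str = "2015-01-01"
    data_end: str = "2022-09-30"
    death_capture_prob: float = 1.0
    ae_month_offset: int = 0
    max_lines_simulated: int = 5

    def __post_init__(self):
        for p in (*self.line_transition_probs, self.death_vs_next_treatment_ratio,
                  self.discontinuation_prob, self.periop_history_prob,
                  self.death_capture_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if any(m <= 0 for m in self.ttntd_medians_months):
            raise ValueError("TTNTD medians must be positive")
        if self.prescription_interval_days <= 0:
            raise ValueError("prescription_interval_days must be positive")


TRUTH_COLUMNS = ["patient_id", "line_number", "regimen", "index_date",
                 "event_type", "event_date"]


def _pick(rng: np.random.Generator, weights: dict[str, float]) -> str:
    names = list(weights)
    w = np.fromiter(weights.values(), float)
    return names[rng.choice(len(names), p=w / w.sum())]


def _lognormal(rng, median, sigma):
    return float(median * math.exp(sigma * rng.standard_normal()))


class _Collector:
    """Row accumulators for the four claims tables."""

    def __init__(self):
        self.patients, self.diagnoses, self.prescriptions, self.procedures = [], [], [], []

    def dx(self, pid, day, code, suspected=False):
        self.diagnoses.append((pid, _month_str(day), code, suspected))

    def rx(self, pid, day, code, setting, points):
        self.prescriptions.append((pid, _date_str(day), code, setting, round(points, 1)))

    def proc(self, pid, day, code, setting, points):
        self.procedures.append((pid, _date_str(day), code, setting, round(points, 1)))


_EPOCH = pd.Timestamp("1970-01-01")


def _date_str(day: int) -> str:
    return (_EPOCH + pd.Timedelta(days=int(day))).strftime("%Y-%m-%d")


def _month_str(day: int) -> str:
    return (_EPOCH + pd.Timedelta(days=int(day))).strftime("%Y-%m")


def _month_shift_day(day: int, months: int) -> int:
    """A day in the calendar month *months* after the month of *day* (day 15)."""
    p = (_EPOCH + pd.Timedelta(days=int(day))).to_period("M") + months
    return (p.to_timestamp() + pd.Timedelta(days=14) - _EPOCH).days


def generate_bundle(config: SimulationConfig, dictionary: DrugDictionary,
                    catalog: RegimenCatalog):
    """Simulate a claims bundle plus per-line ground truth.

    Returns ``(ClaimsBundle, truth)`` where *truth* is a DataFrame with one
    row per simulated treatment line (true index date, regimen, event type
    and event date).  Deterministic for a given config (seed included).
    """
    rng = np.random.default_rng(config.seed)
    col = _Collector()
    truth_rows: list[tuple] = []

    data_start = (pd.Timestamp(config.data_start) - _EPOCH).days
    data_end = (pd.Timestamp(config.data_end) - _EPOCH).days
    idx_lo = (pd.Timestamp(config.index_window[0]) - _EPOCH).days
    idx_hi = (pd.Timestamp(config.index_window[1]) - _EPOCH).days
    interval = config.prescription_interval_days
    floor_days = config.combo_window_days + 1

    comp_codes = {}  # regimen name -> component drug codes
    for d in catalog.definitions:
        comp_codes[d.name] = [dictionary.code_of(n) for n in sorted(d.components)]
    comp_names = {d.name: d.components for d in catalog.definitions}
    ae_map = load_ae_code_map()
    ae_drug_codes = {cls: dictionary.code_of(name) for cls, name in AE_CLASS_DRUGS.items()}

    for i in range(config.n_patients):
        pid = f"P{i:06d}"
        index1 = int(rng.integers(idx_lo, idx_hi + 1))
        sex = "female" if rng.random() < 0.998 else "male"
        age = int(np.clip(round(rng.normal(64, 12)), 25, 90))
        birth_year = (_EPOCH + pd.Timedelta(days=index1)).year - age
        death_day: int | None = None

        # perioperative history: surgery + adjuvant chemo (optionally a
        # sequential anthracycline -> taxane series) well before index
        if rng.random() < config.periop_history_prob:
            surgery = index1 - int(rng.integers(400, 801))
            if surgery > data_start + 120:
                col.proc(pid, surgery, "breast_surgery", "inpatient",
                         config.cost_points.surgery_points)
                col.dx(pid, surgery, "C50")
                start = surgery + int(rng.integers(15, 61))
                last = start
                for j in range(4):
                    day = start + j * interval
                    for code in comp_codes["Epirubicin/Cyclophosphamide"]:
                        col.rx(pid, day, code, "outpatient",
                               _lognormal(rng, 2000, 0.4))
                    last = day
                if rng.random() < 0.5:
                    tstart = last + int(rng.integers(7, 43))
                    for j in range(4):
                        for code in comp_codes["Paclitaxel"]:
                            col.rx(pid, tstart + j * interval, code, "outpatient",
                                   _lognormal(rng, 2000, 0.4))
                if rng.random() < 0.5:
                    col.proc(pid, surgery + int(rng.integers(30, 90)), "radiation",
                             "outpatient", _lognormal(rng, 1500, 0.3))

        # diagnostic work-up: receptor tests before index with >=3-month look-back
        workup = index1 - int(rng.integers(95, 141))
        for code in ("her2_test", "er_test", "pr_test"):
            col.proc(pid, workup, code, "outpatient",
                     config.cost_points.receptor_test_points)
        col.dx(pid, workup, "C50")
        col.dx(pid, index1, "C50")
        if rng.random() < 0.5:
            col.dx(pid, _month_shift_day(index1, -1), "C50")

        # baseline metastasis and comorbidity diagnoses
        for code, p in (("C77", 0.41), ("C78", 0.25), ("C79", 0.24)):
            if rng.random() < p:
                col.dx(pid, index1, code)
        for code, p in (("I21", 0.05), ("I50", 0.08), ("J44", 0.07),
                        ("E119", 0.12), ("K25", 0.05), ("I63", 0.05)):
            if rng.random() < p:
                col.dx(pid, _month_shift_day(index1, -int(rng.integers(0, 3))), code)
        if rng.random() < 0.05:
            col.dx(pid, _month_shift_day(index1, -1), "C16")

        # treatment trajectory
        index_k = index1
        prev_components: frozenset[str] = frozenset()
        for k in range(1, config.max_lines_simulated + 1):
            tier = min(k, 3) - 1
            weights = config.regimen_catalog_weights[tier]
            regimen = _pick(rng, weights)
            while comp_names[regimen] <= prev_components:
                regimen = _pick(rng, weights)

            median_days = config.ttntd_medians_months[min(k - 1, len(config.ttntd_medians_months) - 1)] * DAYS_PER_MONTH
            t_event = max(1, int(math.ceil(rng.exponential(median_days / math.log(2)))))
            p_next = config.line_transition_probs[min(k - 1, len(config.line_transition_probs) - 1)]
            proceeds = rng.random() < p_next and k < config.max_lines_simulated
            if proceeds:
                t_event = max(t_event, floor_days)  # a switch inside the combo window is a combination, not a new line
                event_type = "next_treatment"
            elif rng.random() < config.death_vs_next_treatment_ratio:
                event_type = "death"
            else:
                event_type = "censored"

            # prescriptions: every `interval` days until the event or an
            # independent early discontinuation
            stop = t_event
            if rng.random() < config.discontinuation_prob:
                u = max(1, int(math.ceil(rng.exponential(
                    config.discontinuation_median_months * DAYS_PER_MONTH / math.log(2)))))
                stop = min(stop, u)
            setting = "outpatient"
            codes = comp_codes[regimen]
            drug_median = config.cost_points.drug_rx_median[tier] / len(codes)
            day = 0
            while day < stop:
                rx_day = index_k + day
                if rx_day > data_end:
                    break
                for code in codes:
                    col.rx(pid, rx_day, code, setting,
                           _lognormal(rng, drug_median, config.cost_points.drug_rx_sigma))
                day += interval

            # outpatient visit claims through the (approximate) exposure window
            window_end = min(t_event, stop + 90)
            vday = 15
            vmedian = config.cost_points.visit_median[tier]
            while vday < window_end:
                if index_k + vday <= data_end:
                    col.proc(pid, index_k + vday, "other", "outpatient",
                             _lognormal(rng, vmedian, config.cost_points.visit_sigma))
                vday += 30
            if rng.random() < config.cost_points.inpatient_prob:
                hday = index_k + int(rng.integers(0, max(1, window_end)))
                if hday <= data_end:
                    col.proc(pid, hday, "other", "inpatient",
                             _lognormal(rng, config.cost_points.inpatient_median,
                                        config.cost_points.inpatient_sigma))

            # AE co-claims in the month of the line start (configurable offset)
            probs = config.ae_probs.get(regimen, (0.0,) * len(AE_CATEGORIES))
            ae_day = (index_k if config.ae_month_offset == 0
                      else _month_shift_day(index_k, config.ae_month_offset))
            if ae_day <= data_end:
                draws = {cat: rng.random() for cat in AE_CATEGORIES}
                febrile = draws["febrile_neutropenia"] < probs[AE_CATEGORIES.index("febrile_neutropenia")]
                for ci, cat in enumerate(AE_CATEGORIES):
                    if cat == "neutropenia_leukopenia":
                        p_only = max(probs[ci] - probs[AE_CATEGORIES.index("febrile_neutropenia")], 0.0)
                        hit = febrile or draws[cat] < p_only
                    elif cat == "febrile_neutropenia":
                        hit = febrile
                    else:
                        hit = draws[cat] < probs[ci]
                    if not hit:
                        continue
                    col.dx(pid, ae_day, ae_map.prefixes[cat][0])
                    for cls in ae_map.drug_classes[cat]:
                        col.rx(pid, ae_day, ae_drug_codes[cls], "outpatient",
                               config.cost_points.ae_rx_points)

            event_day = index_k + t_event
            truth_rows.append((pid, k, regimen,
                               _date_str(index_k), event_type,
                               _date_str(event_day) if event_type != "censored" else ""))
            if event_type == "death":
                if event_day <= data_end:
                    death_day = event_day
                break
            if event_type == "censored" or event_day > data_end:
                break
            prev_components = comp_names[regimen]
            index_k = event_day

        if death_day is not None and rng.random() >= config.death_capture_prob:
            # death outside the hospital: unrecorded, visits simply stop
            last_visit = death_day
            death_day = None
        else:
            last_visit = death_day if death_day is not None else data_end
        col.patients.append((pid, sex, birth_year,
                             _date_str(death_day) if death_day is not None else None,
                             _date_str(last_visit)))

    bundle = make_bundle(
        pd.DataFrame(col.patients, columns=["patient_id", "sex", "birth_year",
                                            "death_date", "last_visit_date"]),
        pd.DataFrame(col.diagnoses, columns=["patient_id", "month", "icd10_code",
                                             "suspected_flag"]),
        pd.DataFrame(col.prescriptions, columns=["patient_id", "date", "drug_code",
                                                 "setting", "points"]),
        pd.DataFrame(col.procedures, columns=["patient_id", "date", "procedure_code",
                                              "setting", "points"]),
        config.data_start, config.data_end, validate=False,
    )
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    truth["index_date"] = pd.to_datetime(truth["index_date"])
    truth["event_date"] = pd.to_datetime(truth["event_date"].replace("", pd.NaT))
    return bundle, truth


def inject_violations(bundle: ClaimsBundle, kinds, seed: int,
                      dictionary: DrugDictionary | None = None,
                      n_per_kind: int = 10):
    """Return a modified copy of *bundle* with cohort-rule violations injected.

    Each violation kind targets *n_per_kind* distinct patients without a
    surgery record (so the patient's earliest breast-cancer prescription is
    their first-line index).  Returns ``(bundle, {kind: [patient_id, ...]})``.
    """
    unknown = set(kinds) - set(VIOLATION_KINDS)
    if unknown:
        raise ValueError(f"unknown violation kind(s): {sorted(unknown)}")
    out = bundle.copy()
    if not kinds:
        return out, {}
    rng = np.random.default_rng(seed)

    surgical = set(out.procedures.loc[out.procedures["procedure_code"] == "breast_surgery",
                                      "patient_id"])
    eligible = [p for p in out.patients["patient_id"] if p not in surgical]
    rng.shuffle(eligible)
    report: dict[str, list[str]] = {}
    pos = 0
    index_by_pid = out.prescriptions.groupby("patient_id")["date"].min()

    for kind in kinds:
        targets = eligible[pos:pos + n_per_kind]
        pos += n_per_kind
        report[kind] = list(targets)
        tset = set(targets)
        if kind == "hormonal_rx" or kind == "anti_her2_rx":
            code = "H001" if kind == "hormonal_rx" else "T001"
            new_rows = [(p, (index_by_pid[p] + pd.Timedelta(days=30)).strftime("%Y-%m-%d"),
                         code, "outpatient", 800.0) for p in targets]
            add = pd.DataFrame(new_rows, columns=out.prescriptions.columns)
            add["date"] = pd.to_datetime(add["date"])
            out.prescriptions = pd.concat([out.prescriptions, add], ignore_index=True)
        elif kind == "no_receptor_test":
            proc = out.procedures
            drop = proc["patient_id"].isin(tset) & proc["procedure_code"].isin(
                ("her2_test", "er_test", "pr_test"))
            out.procedures = proc.loc[~drop].reset_index(drop=True)
        elif kind == "no_lookback":
            for p in targets:
                index_month = index_by_pid[p].to_period("M")
                dxm = out.diagnoses
                drop_dx = (dxm["patient_id"] == p) & (dxm["month"] < index_month - 1)
                out.diagnoses = dxm.loc[~drop_dx].reset_index(drop=True)
                proc = out.procedures
                mask = (proc["patient_id"] == p) & (proc["date"] < index_by_pid[p] - pd.Timedelta(days=20))
                out.procedures.loc[mask, "date"] = index_by_pid[p] - pd.Timedelta(days=20)
        elif kind == "late_bc_diagnosis":
            for p in targets:
                index_month = index_by_pid[p].to_period("M")
                dxm = out.diagnoses
                drop_dx = ((dxm["patient_id"] == p) & (dxm["month"] >= index_month - 1)
                           & dxm["icd10_code"].str.startswith("C50"))
                out.diagnoses = dxm.loc[~drop_dx].reset_index(drop=True)
    out.diagnoses = out.diagnoses.sort_values(["patient_id", "month"]).reset_index(drop=True)
    return out, report
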