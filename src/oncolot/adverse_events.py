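"""Adverse-event (AE) attribution from diagnosis + treatment co-claims.

An AE of interest is attributed to a treatment line when a diagnosis
matching the category's ICD-10 prefixes falls in the line's follow-up
period and an AE-treatment drug of the category *starts* (first
prescription within the follow-up period) in the same calendar month as
that diagnosis.  Categories requiring several drug classes (febrile
neutropenia: G-CSF plus an antibiotic) need a same-month start for each.
Diagnoses are monthly, so the follow-up period is evaluated at month
granularity: from the index month through the exposure-end month.  A line
switch inside a calendar month makes that month belong to both lines'
follow-up; such a boundary-month event is attributed to the newer line
(the regimen that started in that month), never to both.

Frequencies are tabulated with pooled patient-line denominators: a patient
on the same regimen in two lines contributes twice to that regimen's N.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dictionaries import AE_CATEGORIES, AECodeMap, DrugDictionary
from .schema import round_half_up

AE_EVENT_COLUMNS = ["patient_id", "line_number", "ae_category", "month"]


def attribute_aes(lines: pd.DataFrame, diagnoses: pd.DataFrame,
                  prescriptions: pd.DataFrame, code_map: AECodeMap,
                  dictionary: DrugDictionary,
                  ignore_suspected: bool = True) -> pd.DataFrame:
    """Emit at most one AE event per (patient, line, category).

    *lines* is the lines table; the event month recorded is the month of the
    qualifying diagnosis.
    """
    dx = diagnoses
    if ignore_suspected and len(dx):
        dx = dx.loc[~dx["suspected_flag"]]

    rx = prescriptions.copy()
    rx["ae_class"] = rx["drug_code"].map(
        lambda c: dictionary.ae_class_of(c) if c in dictionary.classes_by_code else None)
    rx = rx.loc[rx["ae_class"].notna(), ["patient_id", "date", "ae_class"]]

    # month ordinals + per-category diagnosis masks, grouped per patient
    dx_pid = dx["patient_id"].to_numpy()
    dx_month = pd.PeriodIndex(dx["month"]).asi8
    dx_code = dx["icd10_code"].to_numpy()
    cat_masks = {cat: np.fromiter((c.startswith(tuple(code_map.prefixes[cat]))
                                   for c in dx_code), bool, len(dx_code))
                 for cat in AE_CATEGORIES}
    dx_ix_by_pid: dict[str, np.ndarray] = {}
    for i, p in enumerate(dx_pid):
        dx_ix_by_pid.setdefault(p, []).append(i)
    dx_ix_by_pid = {p: np.asarray(v) for p, v in dx_ix_by_pid.items()}

    rx_pid = rx["patient_id"].to_numpy()
    rx_month = (rx["date"].to_numpy("datetime64[M]").astype("int64")
                + (1970 - 1970) * 12)
    rx_cls = rx["ae_class"].to_numpy()
    rx_ix_by_pid: dict[str, np.ndarray] = {}
    for i, p in enumerate(rx_pid):
        rx_ix_by_pid.setdefault(p, []).append(i)
    rx_ix_by_pid = {p: np.asarray(v) for p, v in rx_ix_by_pid.items()}
    month_base = (pd.Period("1970-01", "M")).ordinal  # Period ordinal of epoch month

    events = []
    for row in lines.itertuples(index=False):
        di = dx_ix_by_pid.get(row.patient_id)
        ri = rx_ix_by_pid.get(row.patient_id)
        if di is None or ri is None:
            continue
        m_lo = row.index_date.to_period("M").ordinal
        m_hi = row.exposure_end_date.to_period("M").ordinal
        dmon = dx_month[di]
        din = di[(dmon >= m_lo) & (dmon <= m_hi)]
        if not din.size:
            continue
        rmon = rx_month[ri] + month_base
        rwin = (rmon >= m_lo) & (rmon <= m_hi)
        if not rwin.any():
            continue
        start_months = {}
        for cls, m in zip(rx_cls[ri[rwin]], rmon[rwin]):
            if cls not in start_months or m < start_months[cls]:
                start_months[cls] = m
        for cat in AE_CATEGORIES:
            needed = code_map.drug_classes[cat]
            starts = [start_months.get(cls) for cls in needed]
            if any(s is None for s in starts) or len(set(starts)) != 1:
                continue
            s = starts[0]
            hit = cat_masks[cat][din] & (dx_month[din] == s)
            if hit.any():
                events.append((row.patient_id, row.line_number, cat, s, m_lo))
    ev = pd.DataFrame(events, columns=[*AE_EVENT_COLUMNS, "_index_month"])
    if len(ev):
        # boundary months shared by two lines: keep the newer line only
        ev = (ev.sort_values(["patient_id", "ae_category", "month", "_index_month"])
                .drop_duplicates(["patient_id", "ae_category", "month"], keep="last"))
    ev = ev.drop(columns="_index_month").reset_index(drop=True)
    ev["month"] = (pd.PeriodIndex([pd.Period(ordinal=int(m), freq="M") for m in ev["month"]])
                   if len(ev) else pd.PeriodIndex([], freq="M"))
    return ev


def ae_frequency_table(events: pd.DataFrame, lines: pd.DataFrame,
                       grouping: str = "by_regimen",
                       patients: pd.DataFrame | None = None) -> pd.DataFrame:
    """Pooled AE frequencies by regimen or by age group.

    The denominator N of a group is the number of patient-lines pooled over
    the first three cohorts; n counts patient-lines with at least one event
    of the category; percentages are n/N to one decimal (half-up).  The
    Total row pools all patient-lines.
    """
    if grouping == "by_regimen":
        keyed = lines.assign(group=lines["regimen"])
    elif grouping == "by_age_group":
        if patients is None:
            raise ValueError("patients table required for by_age_group")
        birth = patients.set_index("patient_id")["birth_year"]
        age = lines["index_date"].dt.year - lines["patient_id"].map(birth).astype(int)
        keyed = lines.assign(group=(age >= 65).map({True: "ge65", False: "under65"}))
    else:
        raise ValueError(f"unknown grouping {grouping!r}")

    ev = events.merge(
        keyed[["patient_id", "line_number", "group"]],
        on=["patient_id", "line_number"], how="inner",
    ).drop_duplicates(["patient_id", "line_number", "ae_category"])

    rows = []
    groups = ["Total"] + sorted(keyed["group"].unique())
    for g in groups:
        sub = keyed if g == "Total" else keyed.loc[keyed["group"] == g]
        sub_ev = ev if g == "Total" else ev.loc[ev["group"] == g]
        n_total = len(sub)
        row = {"group": g, "N": n_total}
        for cat in AE_CATEGORIES:
            n = int((sub_ev["ae_category"] == cat).sum())
            row[f"{cat}_n"] = n
            row[f"{cat}_pct"] = round_half_up(100.0 * n / n_total, 1) if n_total else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
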