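"""Regimen-episode construction and line-of-therapy (LOT) assignment.

A regimen episode starts at an anchor prescription of a breast-cancer drug;
every breast-cancer drug first prescribed within the combination window
(default 28 days) of the anchor becomes a component.  The episode's exposure
ends at the earliest of five candidate dates: study end, death, the last
prescription considering the grace period (a gap between consecutive
prescriptions longer than the grace period, default 90 days, truncates the
regimen at previous prescription + grace; the same rule is applied to the
tail after the final prescription), the first prescription of a
breast-cancer drug outside the component set, and the last hospital visit.

Lines advance when exposure ends with a new drug (its first prescription
date anchors the next line) or when any later breast-cancer prescription
follows a non-drug exposure end.  Lines beyond the third are detected (so
the third line is ended correctly) and counted but not analyzed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dictionaries import (
    ANTHRACYCLINE_CONTAINING, OTHER, TAXANE_CONTAINING,
    DrugDictionary, RegimenCatalog, adhoc_regimen_name,
)

END_REASONS = ("study_end", "death", "grace_lapse", "new_drug", "last_visit")
#: tie-break priority when several exposure-end candidates coincide
_REASON_PRIORITY = {"death": 0, "new_drug": 1, "grace_lapse": 2, "last_visit": 3, "study_end": 4}


@dataclass(frozen=True)
class LotConfig:
    grace_days: int = 90
    combo_window_days: int = 28
    max_lines: int = 3

    def __post_init__(self):
        if self.grace_days <= 0 or self.combo_window_days <= 0:
            raise ValueError("grace_days and combo_window_days must be positive")


@dataclass(frozen=True)
class RegimenEpisode:
    patient_id: str
    name: str
    components: frozenset[str]          # drug names
    component_classes: frozenset[str]   # union of drug classes over components
    category: str
    start: pd.Timestamp
    rx_dates: tuple[pd.Timestamp, ...]  # sorted component prescription dates

    @property
    def last_rx(self) -> pd.Timestamp:
        return self.rx_dates[-1]


@dataclass(frozen=True)
class TreatmentLine:
    patient_id: str
    line_number: int
    episode: RegimenEpisode
    index_date: pd.Timestamp
    exposure_end_date: pd.Timestamp
    end_reason: str
    followup_end_date: pd.Timestamp

    @property
    def regimen(self) -> str:
        return self.episode.name

    @property
    def category(self) -> str:
        return self.episode.category

    @property
    def followup_days(self) -> int:
        """Follow-up length in days, both endpoints included."""
        return (self.followup_end_date - self.index_date).days + 1


def classify_components(component_classes) -> str:
    """Regimen category from the union of component drug classes.

    Anthracycline-containing wins; otherwise any taxane or immune checkpoint
    inhibitor makes the regimen taxane-containing; everything else is other.
    """
    if "anthracycline" in component_classes:
        return ANTHRACYCLINE_CONTAINING
    if "taxane" in component_classes or "ici" in component_classes:
        return TAXANE_CONTAINING
    return OTHER


def classify_regimen(episode: RegimenEpisode) -> str:
    return classify_components(episode.component_classes)


def build_regimen(prescriptions: pd.DataFrame, dictionary: DrugDictionary,
                  catalog: RegimenCatalog, combo_window_days: int = 28,
                  anchor_date=None) -> RegimenEpisode:
    """Build one regimen episode from a patient's prescription stream.

    *prescriptions* must carry ``patient_id``, ``date`` and ``drug_code``
    columns; only breast-cancer drugs at/after the anchor (default: the
    earliest prescription) are considered.  Components are the breast-cancer
    drugs whose first prescription on/after the anchor falls within
    *combo_window_days* of it; the episode collects every later prescription
    of those components.
    """
    df = prescriptions
    codes = df["drug_code"].to_numpy()
    unknown = [c for c in dict.fromkeys(codes) if c not in dictionary.classes_by_code]
    if unknown:
        raise KeyError(f"drug code(s) not in dictionary: {unknown}")
    bc = np.fromiter((dictionary.is_bc_drug(c) for c in codes), bool, len(codes))
    df = df.loc[bc].sort_values("date")
    if anchor_date is not None:
        df = df.loc[df["date"] >= pd.Timestamp(anchor_date)]
    if df.empty:
        raise ValueError("no breast-cancer prescription at/after the anchor")
    anchor = df["date"].iloc[0]
    window_end = anchor + pd.Timedelta(days=combo_window_days)

    first_seen = df.groupby("drug_code")["date"].min()
    component_codes = set(first_seen.index[first_seen <= window_end])
    comp_mask = df["drug_code"].isin(component_codes)
    rx_dates = tuple(sorted(df.loc[comp_mask, "date"]))

    names = frozenset(dictionary.name_of(c) for c in component_codes)
    classes = frozenset().union(*(dictionary.classes_of(c) for c in component_codes))
    matched = catalog.match(names)
    name = matched.name if matched is not None else adhoc_regimen_name(names)
    return RegimenEpisode(
        patient_id=str(df["patient_id"].iloc[0]), name=name, components=names,
        component_classes=classes, category=classify_components(classes),
        start=anchor, rx_dates=rx_dates,
    )


def effective_last_prescription_date(rx_dates, grace_days: int = 90) -> pd.Timestamp:
    """Last prescription date of a regimen, truncated at the first grace lapse.

    Scans consecutive gaps; at the first gap exceeding *grace_days* the
    regimen is deemed to have ended at previous date + grace.  With no lapse
    the final prescription date itself is returned (the end-of-series grace
    tail is applied by :func:`compute_exposure_end`, not here).
    """
    dates = sorted(pd.Timestamp(d) for d in rx_dates)
    if not dates:
        raise ValueError("at least one prescription required")
    grace = pd.Timedelta(days=grace_days)
    for prev, nxt in zip(dates, dates[1:]):
        if nxt - prev > grace:
            return prev + grace
    return dates[-1]


def _grace_lapse_date(rx_dates, grace_days: int) -> pd.Timestamp:
    """Date at which the regimen lapses: first over-grace gap (the tail after
    the final prescription counts as an infinite gap), plus the grace period."""
    dates = sorted(pd.Timestamp(d) for d in rx_dates)
    grace = pd.Timedelta(days=grace_days)
    for prev, nxt in zip(dates, dates[1:]):
        if nxt - prev > grace:
            return prev + grace
    return dates[-1] + grace


def compute_exposure_end(episode: RegimenEpisode, *, death_date, last_visit_date,
                         new_drug_date, study_end, grace_days: int = 90):
    """Earliest of the five exposure-end candidates with its reason tag.

    Ties are broken death > new_drug > grace_lapse > last_visit > study_end.
    """
    candidates = [
        (pd.Timestamp(study_end), "study_end"),
        (_grace_lapse_date(episode.rx_dates, grace_days), "grace_lapse"),
    ]
    if death_date is not None and pd.notna(death_date):
        candidates.append((pd.Timestamp(death_date), "death"))
    if last_visit_date is not None and pd.notna(last_visit_date):
        candidates.append((pd.Timestamp(last_visit_date), "last_visit"))
    if new_drug_date is not None and pd.notna(new_drug_date):
        candidates.append((pd.Timestamp(new_drug_date), "new_drug"))
    return min(candidates, key=lambda c: (c[0], _REASON_PRIORITY[c[1]]))


# ---------------------------------------------------------------------------
# Fast array-based internals (one conversion per patient, plain numpy after)


def _day_of(ts) -> int:
    return pd.Timestamp(ts).normalize().value // 86_400_000_000_000


def _ts_of(day: int) -> pd.Timestamp:
    return pd.Timestamp(np.datetime64(int(day), "D"))


def bc_stream(prescriptions: pd.DataFrame, dictionary: DrugDictionary):
    """Sorted (days, codes) arrays of a patient's breast-cancer prescriptions."""
    codes = prescriptions["drug_code"].to_numpy()
    bc_codes = dictionary.bc_codes()
    mask = np.fromiter((c in bc_codes for c in codes), bool, len(codes))
    days = prescriptions["date"].to_numpy("datetime64[D]").astype("int64")[mask]
    codes = codes[mask]
    order = np.argsort(days, kind="stable")
    return days[order], codes[order]


def _episode_arrays(days, codes, anchor_day: int, window: int):
    """Components, their prescription days, and the first outside-drug day."""
    i = int(np.searchsorted(days, anchor_day))
    sub_days, sub_codes = days[i:], codes[i:]
    first: dict = {}
    for d, c in zip(sub_days, sub_codes):
        if c not in first:
            first[c] = d
    comp = {c for c, d in first.items() if d <= anchor_day + window}
    mask = np.fromiter((c in comp for c in sub_codes), bool, len(sub_codes))
    outside = np.nonzero(~mask)[0]
    new_drug_day = int(sub_days[outside[0]]) if outside.size else None
    return comp, sub_days[mask], new_drug_day


def _lapse_day(comp_days, grace_days: int) -> int:
    gaps = np.diff(comp_days)
    over = np.nonzero(gaps > grace_days)[0]
    stop = comp_days[over[0]] if over.size else comp_days[-1]
    return int(stop) + grace_days


def _make_episode(pid, comp_codes, comp_days, end_day, dictionary, catalog) -> RegimenEpisode:
    names = frozenset(dictionary.name_of(c) for c in comp_codes)
    classes = frozenset().union(*(dictionary.classes_of(c) for c in comp_codes))
    matched = catalog.match(names)
    rx = comp_days[comp_days <= end_day] if end_day is not None else comp_days
    return RegimenEpisode(
        patient_id=pid, name=matched.name if matched else adhoc_regimen_name(names),
        components=names, component_classes=classes,
        category=classify_components(classes), start=_ts_of(comp_days[0]),
        rx_dates=tuple(_ts_of(d) for d in rx),
    )


def assign_lines(prescriptions: pd.DataFrame, *, index_date, death_date,
                 last_visit_date, study_end, dictionary: DrugDictionary,
                 catalog: RegimenCatalog, config: LotConfig = LotConfig()):
    """Assign lines of therapy for one cohort member.

    *prescriptions* is the patient's full prescription table; the first line
    is anchored at *index_date* (the cohort index).  Returns
    ``(lines, n_further_lines)`` where *lines* holds at most
    ``config.max_lines`` :class:`TreatmentLine` rows and *n_further_lines*
    counts detected line starts beyond them.
    """
    pid = str(prescriptions["patient_id"].iloc[0])
    days, codes = bc_stream(prescriptions, dictionary)
    study_end_day = _day_of(study_end)
    death_day = _day_of(death_date) if death_date is not None and pd.notna(death_date) else None
    visit_day = _day_of(last_visit_date) if last_visit_date is not None and pd.notna(last_visit_date) else None

    lines: list[TreatmentLine] = []
    n_further = 0
    anchor: int | None = _day_of(index_date)
    for line_number in range(1, 100):
        if anchor is None or not len(days) or anchor > days[-1] or anchor > study_end_day:
            break
        comp, comp_days, nd = _episode_arrays(days, codes, anchor, config.combo_window_days)
        candidates = [(study_end_day, "study_end"),
                      (_lapse_day(comp_days, config.grace_days), "grace_lapse")]
        if death_day is not None:
            candidates.append((death_day, "death"))
        if visit_day is not None:
            candidates.append((visit_day, "last_visit"))
        if nd is not None:
            candidates.append((nd, "new_drug"))
        end_day, reason = min(candidates, key=lambda c: (c[0], _REASON_PRIORITY[c[1]]))
        if line_number <= config.max_lines:
            episode = _make_episode(pid, comp, comp_days, end_day, dictionary, catalog)
            end_ts = _ts_of(end_day)
            lines.append(TreatmentLine(
                patient_id=pid, line_number=line_number, episode=episode,
                index_date=episode.start, exposure_end_date=end_ts,
                end_reason=reason, followup_end_date=end_ts,
            ))
        else:
            n_further += 1
        if reason == "new_drug":
            anchor = nd
        else:
            later = np.nonzero(days > end_day)[0]
            anchor = int(days[later[0]]) if later.size else None
    return lines, n_further


def lines_table(all_lines) -> pd.DataFrame:
    """Flatten TreatmentLine objects into the lines output table."""
    rows = [{
        "patient_id": ln.patient_id, "line_number": ln.line_number,
        "regimen": ln.regimen, "category": ln.category,
        "index_date": ln.index_date, "exposure_end_date": ln.exposure_end_date,
        "end_reason": ln.end_reason, "followup_end_date": ln.followup_end_date,
        "followup_days": ln.followup_days,
        "last_rx_date": ln.episode.last_rx,
    } for ln in all_lines]
    return pd.DataFrame(rows, columns=[
        "patient_id", "line_number", "regimen", "category", "index_date",
        "exposure_end_date", "end_reason", "followup_end_date", "followup_days",
        "last_rx_date",
    ])
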