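"""Real-world endpoints per treatment line and Kaplan–Meier estimation.

Two endpoints are derived from assigned lines of therapy:

* **TTNTD** — time to next treatment or death.  The clock runs from the
  line's index date; the event is the start of the next treatment (a
  breast-cancer drug outside the regimen) or death, whichever comes first.
  Lines whose exposure ended at the study end, at a grace lapse, or at the
  last hospital visit are censored at the exposure end date.
* **TTD** — time to treatment discontinuation.  Discontinuation for any
  cause (grace lapse), start of the next line, and death are all events;
  administratively ended lines are censored at the last confirmed activity
  date (by default the final regimen prescription).

Both use the inclusive-day convention: time = (event-or-censor date − index
date) + 1 days, converted to months by dividing by 30.4375.

Kaplan–Meier curves carry Greenwood variances and pointwise 95% confidence
intervals on the log(−log) scale; quantiles (25/50/75%) are read off the
curve with Brookmeyer–Crowley-style confidence bounds obtained by inverting
the confidence band.  The product-limit computation is backed by lifelines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .schema import days_to_months

EVENT_TYPES = ("next_treatment", "death", "discontinuation", "censored")

_TTNTD_EVENTS = {"new_drug": "next_treatment", "death": "death"}
_TTD_EVENTS = {"new_drug": "next_treatment", "death": "death",
               "grace_lapse": "discontinuation"}

SURVIVAL_COLUMNS = ["patient_id", "line_number", "time_days", "time_months",
                    "event", "event_type"]


def _records(lines: pd.DataFrame, end_map: dict[str, str],
             censor_dates: pd.Series) -> pd.DataFrame:
    event = lines["end_reason"].isin(end_map)
    end_date = lines["exposure_end_date"].where(event, censor_dates)
    time_days = (end_date - lines["index_date"]).dt.days + 1
    out = pd.DataFrame({
        "patient_id": lines["patient_id"],
        "line_number": lines["line_number"],
        "time_days": time_days.astype(int),
        "time_months": days_to_months(time_days.to_numpy()),
        "event": event,
        "event_type": lines["end_reason"].map(end_map).fillna("censored"),
    })
    if (out["time_days"] < 1).any():
        raise ValueError("survival times must be >= 1 day")
    return out[SURVIVAL_COLUMNS]


def build_ttntd_records(lines: pd.DataFrame, patients: pd.DataFrame | None = None) -> pd.DataFrame:
    """TTNTD records from a lines table (see :func:`oncolot.regimen.lines_table`)."""
    return _records(lines, _TTNTD_EVENTS, lines["exposure_end_date"])


def build_ttd_records(lines: pd.DataFrame, patients: pd.DataFrame | None = None,
                      censor_activity: str = "last_rx") -> pd.DataFrame:
    """TTD records; censored lines end at the last confirmed activity date.

    *censor_activity* is ``last_rx`` (default: the final regimen
    prescription) or ``last_rx_or_visit`` (the later of the final
    prescription and the last hospital visit, capped at the exposure end).
    """
    if censor_activity == "last_rx":
        censor = lines["last_rx_date"]
    elif censor_activity == "last_rx_or_visit":
        if patients is None:
            raise ValueError("patients table required for last_rx_or_visit")
        visit = lines["patient_id"].map(
            patients.set_index("patient_id")["last_visit_date"])
        censor = np.minimum(np.maximum(lines["last_rx_date"], visit),
                            lines["exposure_end_date"])
    else:
        raise ValueError(f"unknown censor_activity {censor_activity!r}")
    censor = np.minimum(censor, lines["exposure_end_date"])
    return _records(lines, _TTD_EVENTS, pd.Series(censor, index=lines.index))


@dataclass(frozen=True)
class KMEstimate:
    """Product-limit estimate on a time grid of observed (event or censor) times."""

    times: np.ndarray       # unique observed times, ascending
    n_at_risk: np.ndarray
    n_events: np.ndarray
    n_censored: np.ndarray
    survival: np.ndarray
    variance: np.ndarray    # Greenwood
    ci_low: np.ndarray      # pointwise 95%, log(-log) scale
    ci_high: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.times, "n_at_risk": self.n_at_risk,
            "n_events": self.n_events, "n_censored": self.n_censored,
            "survival": self.survival, "variance": self.variance,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
        })

    def quantile_table(self) -> pd.DataFrame:
        rows = []
        for q in (0.25, 0.5, 0.75):
            res = km_quantile(self, q)
            t, lo, hi = res if res is not None else (np.nan,) * 3
            rows.append({"q": q, "time": t, "ci_low": lo, "ci_high": hi})
        return pd.DataFrame(rows)


def km_estimate(durations, events, alpha: float = 0.05) -> KMEstimate:
    """Kaplan–Meier product-limit estimate with Greenwood variance and
    pointwise log(−log) confidence intervals.

    Censored observations tied with events at the same time are processed
    after the events (the standard convention).
    """
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=bool)
    if durations.size == 0:
        raise ValueError("at least one record required")
    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(durations, event_observed=events)
    table = kmf.event_table.iloc[1:] if kmf.event_table.index[0] == 0 and \
        kmf.event_table.iloc[0][["observed", "censored"]].sum() == 0 else kmf.event_table
    times = table.index.to_numpy(dtype=float)
    d = table["observed"].to_numpy(dtype=int)
    c = table["censored"].to_numpy(dtype=int)
    n = table["at_risk"].to_numpy(dtype=int)
    surv = kmf.survival_function_at_times(times).to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        greenwood_terms = np.where(n > d, d / (n * (n - d)), np.inf)
    variance = surv ** 2 * np.cumsum(greenwood_terms)
    variance = np.where(np.isfinite(variance), variance, 0.0)
    ci = kmf.confidence_interval_survival_function_
    ci_low = np.interp(times, ci.index.to_numpy(dtype=float), ci.iloc[:, 0].to_numpy())
    ci_high = np.interp(times, ci.index.to_numpy(dtype=float), ci.iloc[:, 1].to_numpy())
    return KMEstimate(times, n, d, c, surv, variance, ci_low, ci_high)


def km_quantile(estimate: KMEstimate, q: float):
    """The q-th survival quantile with 95% bounds, or None if never reached.

    The point estimate is the smallest observed time with S(t) <= 1−q; the
    bounds invert the confidence band (Brookmeyer–Crowley): the lower bound
    is the first time the lower confidence curve drops to 1−q, the upper
    bound the first time the upper curve does.
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    level = 1.0 - q
    eps = 1e-12

    def first_crossing(curve):
        hit = np.nonzero(curve <= level + eps)[0]
        return float(estimate.times[hit[0]]) if hit.size else np.nan

    t = first_crossing(estimate.survival)
    if np.isnan(t):
        return None
    return t, first_crossing(estimate.ci_low), first_crossing(estimate.ci_high)


def km_summary(records: pd.DataFrame, time_col: str = "time_months") -> dict:
    """Fit a KM curve to survival records and summarize median and quartiles."""
    est = km_estimate(records[time_col], records["event"])
    out = {"n": int(len(records)), "n_events": int(records["event"].sum())}
    for q, label in ((0.25, "q25"), (0.5, "median"), (0.75, "q75")):
        res = km_quantile(est, q)
        t, lo, hi = res if res is not None else (np.nan,) * 3
        out[label] = t
        out[f"{label}_ci_low"] = lo
        out[f"{label}_ci_high"] = hi
    return out
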