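"""Medical-cost decomposition per treatment line, in thousand yen.

Remuneration points of every claim (prescription or procedure) dated inside
the closed exposure window [index, exposure end] are converted at a fixed
yen-per-point factor (default 10, the Japanese fee schedule).  Four cost
types are reported: total (all claims), drug (prescription claims only),
hospitalization (inpatient claims), and outpatient (outpatient claims);
hospitalization + outpatient = total by construction.  Per-day variants
divide by the follow-up length in days (both endpoints included).
Cumulative scope sums a patient's available lines, with the summed
follow-up as the per-day divisor.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .schema import ClaimsBundle

COST_TYPES = ("total", "drug", "hospitalization", "outpatient")
SCOPES = ("line1", "line2", "line3", "cumulative_1_to_3")


def _claims_frame(bundle: ClaimsBundle) -> pd.DataFrame:
    rx = bundle.prescriptions[["patient_id", "date", "setting", "points"]].assign(is_drug=True)
    pr = bundle.procedures[["patient_id", "date", "setting", "points"]].assign(is_drug=False)
    return pd.concat([rx, pr], ignore_index=True)


def line_costs(lines: pd.DataFrame, bundle: ClaimsBundle,
               yen_per_point: float = 10.0) -> pd.DataFrame:
    """Per-line cost summaries (thousand yen) for every line in *lines*."""
    if (bundle.prescriptions["points"] < 0).any() or (bundle.procedures["points"] < 0).any():
        raise ValueError("negative remuneration points")
    claims = _claims_frame(bundle).sort_values(["patient_id", "date"])
    factor = yen_per_point / 1000.0

    # per-patient sorted arrays for fast window sums
    by_pid: dict[str, tuple] = {}
    for pid, g in claims.groupby("patient_id", sort=False):
        by_pid[pid] = (g["date"].to_numpy("datetime64[D]").astype("int64"),
                       g["points"].to_numpy(float),
                       g["is_drug"].to_numpy(bool),
                       (g["setting"] == "inpatient").to_numpy())

    rows = []
    for row in lines.itertuples(index=False):
        arrs = by_pid.get(row.patient_id)
        if arrs is not None:
            days, pts, is_drug, is_in = arrs
            lo = np.searchsorted(days, row.index_date.value // 86_400_000_000_000)
            hi = np.searchsorted(days, row.exposure_end_date.value // 86_400_000_000_000, "right")
            drug = float(pts[lo:hi][is_drug[lo:hi]].sum())
            inpat = float(pts[lo:hi][is_in[lo:hi]].sum())
            total = float(pts[lo:hi].sum())
        else:
            drug = inpat = total = 0.0
        days = int(row.followup_days)
        summary = {
            "patient_id": row.patient_id, "line_number": row.line_number,
            "scope": f"line{row.line_number}", "followup_days": days,
            "total": total * factor, "drug": drug * factor,
            "hospitalization": inpat * factor,
            "outpatient": (total - inpat) * factor,
        }
        for t in COST_TYPES:
            summary[f"{t}_per_day"] = summary[t] / days
        rows.append(summary)
    cols = ["patient_id", "line_number", "scope", "followup_days",
            *COST_TYPES, *(f"{t}_per_day" for t in COST_TYPES)]
    return pd.DataFrame(rows, columns=cols)


def cumulative_costs(per_line: pd.DataFrame) -> pd.DataFrame:
    """Cumulative (lines 1..3) summaries per patient.

    Amounts are summed over the lines the patient actually has; the per-day
    divisor is the summed follow-up, so cumulative per-day values are not
    the sum of per-line per-day values.
    """
    sub = per_line.loc[per_line["line_number"] <= 3]
    g = sub.groupby("patient_id", as_index=False).agg(
        followup_days=("followup_days", "sum"),
        **{t: (t, "sum") for t in COST_TYPES},
    )
    g["line_number"] = 0
    g["scope"] = "cumulative_1_to_3"
    for t in COST_TYPES:
        g[f"{t}_per_day"] = g[t] / g["followup_days"]
    return g[per_line.columns]


def cost_distribution_table(summaries: pd.DataFrame, decimals: int = 1) -> pd.DataFrame:
    """Median and quartiles per scope and cost type, thousand yen."""
    rows = []
    for scope, g in summaries.groupby("scope"):
        if g.empty:
            continue
        row = {"scope": scope, "n": len(g)}
        for t in (*COST_TYPES, *(f"{x}_per_day" for x in COST_TYPES)):
            s = g[t]
            row[f"{t}_median"] = round(float(s.median()), decimals)
            row[f"{t}_q1"] = round(float(s.quantile(0.25)), decimals)
            row[f"{t}_q3"] = round(float(s.quantile(0.75)), decimals)
        rows.append(row)
    order = {s: i for i, s in enumerate(SCOPES)}
    return (pd.DataFrame(rows)
            .sort_values("scope", key=lambda s: s.map(lambda v: order.get(v, 99)))
            .reset_index(drop=True))
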