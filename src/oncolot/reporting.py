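"""Treatment-pattern tables, Sankey flows, subgroup splits, and the
end-to-end pipeline orchestration.

The pipeline runs: (optional) simulation → claims reading → perioperative
labelling → cohort cascade → line-of-therapy assignment → TTNTD/TTD
Kaplan–Meier summaries → AE attribution → cost decomposition → pattern
tables, and writes every artifact as CSV/JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from . import costs as costs_mod
from .adverse_events import ae_frequency_table, attribute_aes
from .cohort import AttritionReport, CohortConfig
from .dictionaries import (
    load_ae_code_map, load_charlson_map, load_drug_dictionary, load_regimen_catalog,
)
from .regimen import LotConfig, assign_lines, lines_table
from .schema import read_claims_bundle, round_half_up
from .survival import build_ttd_records, build_ttntd_records, km_summary
from .synthetic import SimulationConfig, generate_bundle

logger = logging.getLogger("oncolot")


def regimen_share_table(lines: pd.DataFrame, line_number: int,
                        top_k: int = 5) -> pd.DataFrame:
    """Most common regimens in one line, with an "Others" aggregate.

    Percentages use the line's own cohort size as denominator, half-up to
    two decimals; the named rows plus Others sum to the cohort size.
    """
    cohort = lines.loc[lines["line_number"] == line_number]
    n_cohort = len(cohort)
    counts = cohort["regimen"].value_counts()
    top = counts.iloc[:top_k]
    rows = [{"line_number": line_number, "regimen": name, "n": int(c),
             "pct": round_half_up(100.0 * c / n_cohort, 2)}
            for name, c in top.items()]
    others = int(counts.iloc[top_k:].sum())
    rows.append({"line_number": line_number, "regimen": "Others", "n": others,
                 "pct": round_half_up(100.0 * others / n_cohort, 2) if n_cohort else float("nan")})
    return pd.DataFrame(rows)


def sankey_flows(lines: pd.DataFrame, top_k: int = 5) -> pd.DataFrame:
    """Patient flows between consecutive lines for a Sankey diagram.

    Node labels are the line's top-k regimens, "others" for a regimen
    outside the top-k, and "none" when the patient has no further line;
    out-flow of every line-k node equals its patient count.
    """
    labels = {}
    for k in sorted(lines["line_number"].unique()):
        cohort = lines.loc[lines["line_number"] == k]
        top = set(cohort["regimen"].value_counts().iloc[:top_k].index)
        labels[k] = {pid: (r if r in top else "others")
                     for pid, r in zip(cohort["patient_id"], cohort["regimen"])}
    edges: dict[tuple[int, str, str], int] = {}
    for k in sorted(labels):
        nxt = labels.get(k + 1, {})
        for pid, src in labels[k].items():
            tgt = nxt.get(pid, "none")
            key = (k, src, tgt)
            edges[key] = edges.get(key, 0) + 1
    return pd.DataFrame(
        [(k, s, t, c) for (k, s, t), c in sorted(edges.items())],
        columns=["from_line", "source", "target", "count"],
    )


def subgroup_split(members: pd.DataFrame, lines: pd.DataFrame, axis: str,
                   top_k: int = 5) -> dict[str, dict[int, pd.DataFrame]]:
    """Per-stratum regimen share tables by age group or perioperative history."""
    if axis not in ("age_group", "periop_history"):
        raise ValueError(f"unknown subgroup axis {axis!r}")
    out: dict[str, dict[int, pd.DataFrame]] = {}
    for stratum, g in members.groupby(axis):
        pids = set(g["patient_id"])
        sub = lines.loc[lines["patient_id"].isin(pids)]
        out[str(stratum)] = {
            int(k): regimen_share_table(sub, int(k), top_k)
            for k in sorted(sub["line_number"].unique())
        }
    return out


# ---------------------------------------------------------------------------
# Pipeline


@dataclass
class PipelineConfig:
    out_dir: Path | str = "oncolot_out"
    input_dir: Path | str | None = None          # four claims CSVs, or
    simulation: SimulationConfig | None = None   # simulate instead
    cohort: CohortConfig = field(default_factory=CohortConfig)
    lot: LotConfig = field(default_factory=LotConfig)
    yen_per_point: float = 10.0
    top_k: int = 5
    drug_dictionary_path: Path | str | None = None
    regimen_catalog_path: Path | str | None = None
    charlson_map_path: Path | str | None = None
    ae_code_map_path: Path | str | None = None

    def __post_init__(self):
        if self.input_dir is None and self.simulation is None:
            raise ValueError("config needs an input_dir or a simulation block")

    @classmethod
    def from_file(cls, path: Path | str) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        sim = raw.pop("simulation", None)
        coh = raw.pop("cohort", None)
        lot = raw.pop("lot", None)
        kw = dict(raw)
        if sim is not None:
            if "cost_points" in sim:
                from .synthetic import CostPoints
                sim["cost_points"] = CostPoints(**{
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in sim["cost_points"].items()})
            for key in ("line_transition_probs", "ttntd_medians_months", "index_window"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            kw["simulation"] = SimulationConfig(**sim)
        if coh is not None:
            for key in ("enrollment_start", "enrollment_end", "study_end"):
                if key in coh:
                    coh[key] = pd.Timestamp(coh[key])
            kw["cohort"] = CohortConfig(**coh)
        if lot is not None:
            kw["lot"] = LotConfig(**lot)
        return cls(**kw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; write artifacts under ``config.out_dir``.

    Returns a dict with every intermediate table (bundle, members, lines,
    survival records, KM summaries, AE tables, cost tables, pattern tables).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dictionary = load_drug_dictionary(config.drug_dictionary_path)
    catalog = load_regimen_catalog(config.regimen_catalog_path)
    charlson = load_charlson_map(config.charlson_map_path)
    ae_map = load_ae_code_map(config.ae_code_map_path)

    truth = None
    if config.simulation is not None:
        logger.info("simulate: n=%d seed=%d", config.simulation.n_patients,
                    config.simulation.seed)
        bundle, truth = generate_bundle(config.simulation, dictionary, catalog)
    else:
        bundle = read_claims_bundle(config.input_dir)
        logger.info("read claims: %d patients", bundle.n_patients)

    # cohort cascade
    periop = cohort_mod.detect_perioperative(bundle, config.cohort, dictionary,
                                             catalog, config.lot)
    report = AttritionReport()
    candidates, report = cohort_mod.select_mbc_candidates(
        bundle, config.cohort, dictionary, catalog, periop, config.lot, report)
    members, report = cohort_mod.apply_tnbc_filters(
        candidates, bundle, config.cohort, dictionary, report, periop, charlson)
    for step in report.steps:
        logger.info("filter %-40s before=%6d excluded=%6d after=%6d", *step)

    # lines of therapy
    pat = bundle.patients.set_index("patient_id")
    rx_by_pid = dict(iter(bundle.prescriptions.groupby("patient_id")))
    all_lines = []
    further = {}
    for row in members.itertuples(index=False):
        lines, n_further = assign_lines(
            rx_by_pid[row.patient_id], index_date=row.first_line_index_date,
            death_date=pat.loc[row.patient_id, "death_date"],
            last_visit_date=pat.loc[row.patient_id, "last_visit_date"],
            study_end=config.cohort.study_end, dictionary=dictionary,
            catalog=catalog, config=config.lot)
        all_lines.extend(lines)
        if n_further:
            further[row.patient_id] = n_further
    lines_df = lines_table(all_lines)

    first_cat = (lines_df.loc[lines_df["line_number"] == 1]
                 .set_index("patient_id")["category"])
    baseline = cohort_mod.summarize_baseline(members, first_cat)

    cohort_sizes = lines_df["line_number"].value_counts().to_dict()
    logger.info("cohorts: %s; lines beyond 3rd in %d patients",
                cohort_sizes, len(further))

    # survival endpoints
    ttntd = build_ttntd_records(lines_df)
    ttd = build_ttd_records(lines_df, bundle.patients)
    km = {}
    for name, rec in (("ttntd", ttntd), ("ttd", ttd)):
        km[name] = {f"line{k}": km_summary(rec.loc[rec["line_number"] == k])
                    for k in (1, 2, 3) if (rec["line_number"] == k).any()}

    # adverse events
    ae_events = attribute_aes(lines_df, bundle.diagnoses, bundle.prescriptions,
                              ae_map, dictionary)
    ae_by_regimen = ae_frequency_table(ae_events, lines_df, "by_regimen")
    ae_by_age = ae_frequency_table(ae_events, lines_df, "by_age_group",
                                   bundle.patients)

    # costs
    per_line_costs = costs_mod.line_costs(lines_df, bundle, config.yen_per_point)
    cum = costs_mod.cumulative_costs(per_line_costs)
    cost_table = costs_mod.cost_distribution_table(
        pd.concat([per_line_costs, cum], ignore_index=True))

    # treatment patterns
    shares = pd.concat([regimen_share_table(lines_df, k, config.top_k)
                        for k in (1, 2, 3) if (lines_df["line_number"] == k).any()],
                       ignore_index=True)
    sankey = sankey_flows(lines_df, config.top_k)
    subgroups = {axis: subgroup_split(members, lines_df, axis, config.top_k)
                 for axis in ("age_group", "periop_history")}

    # artifacts
    report.to_frame().to_csv(out / "attrition.csv", index=False)
    baseline.to_csv(out / "baseline.csv", index=False)
    members.to_csv(out / "members.csv", index=False)
    lines_df.to_csv(out / "lines.csv", index=False)
    ttntd.to_csv(out / "survival_ttntd.csv", index=False)
    ttd.to_csv(out / "survival_ttd.csv", index=False)
    (out / "km_summary.json").write_text(json.dumps(km, indent=2, allow_nan=True))
    ae_by_regimen.to_csv(out / "ae_by_regimen.csv", index=False)
    ae_by_age.to_csv(out / "ae_by_age_group.csv", index=False)
    cost_table.to_csv(out / "cost_table.csv", index=False)
    per_line_costs.to_csv(out / "cost_per_patient.csv", index=False)
    shares.to_csv(out / "regimen_shares.csv", index=False)
    sankey.to_csv(out / "sankey_edges.csv", index=False)
    (out / "sankey_edges.json").write_text(
        sankey.to_json(orient="records", indent=2))
    if truth is not None:
        truth.to_csv(out / "truth.csv", index=False)

    return {
        "bundle": bundle, "truth": truth, "periop": periop, "attrition": report,
        "members": members, "baseline": baseline, "lines": lines_df,
        "further_lines": further, "ttntd": ttntd, "ttd": ttd, "km": km,
        "ae_events": ae_events, "ae_by_regimen": ae_by_regimen,
        "ae_by_age": ae_by_age, "costs_per_line": per_line_costs,
        "costs_cumulative": cum, "cost_table": cost_table,
        "shares": shares, "sankey": sankey, "subgroups": subgroups,
    }
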