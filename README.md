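# oncolot

Line-of-therapy analysis of oncology claims data: cohort selection,
regimen/line construction, real-world endpoints, adverse-event attribution,
and cost decomposition — with a synthetic claims generator so the whole
pipeline is testable without access to a proprietary hospital claims
database.

## The problem

Administrative claims databases (such as Japanese DPC hospital claims)
record diagnoses at monthly granularity, drug prescriptions with exact
dates and remuneration points, and procedures — but no staging, biomarkers,
or progression events. Studying treatment patterns and outcomes for
metastatic triple-negative breast cancer (mTNBC) from such data requires a
chain of derivations that this package implements as a reusable, tested
pipeline for epidemiologists and outcomes researchers:

1. **Cohort selection.** Patients with a new, non-perioperative,
   non-hormonal breast-cancer regimen inside an enrollment window, a C50
   diagnosis in the index month or the month before, all three receptor
   tests (HER2/ER/PR) before index, no hormonal/anti-HER2 prescriptions in
   the data period, and a 3-month look-back. Adjuvant and neoadjuvant
   chemotherapy is recognised from surgery proximity (≤ 92 days after /
   before surgery), including sequential anthracycline → taxane series at
   gaps of ≤ 6 weeks. Every filter emits an attrition count.
2. **Lines of therapy (LOT).** A regimen's components are the
   breast-cancer drugs first prescribed within a 28-day combination window
   of the anchor prescription. Exposure ends at the earliest of: study
   end, death, grace lapse (a gap between prescriptions exceeding the
   90-day grace period truncates the regimen at previous prescription +
   grace), the first prescription of a drug outside the regimen, or the
   last hospital visit. A new drug — or any later breast-cancer
   prescription after a non-drug exposure end — starts the next line.
3. **Endpoints.** Per line, time to next treatment or death
   (TTNTD = (event date − index date) + 1, censored at grace lapse or
   administrative end) and time to treatment discontinuation (TTD, where
   discontinuation for any cause is an event). Kaplan–Meier product-limit
   curves with Greenwood variance, log(−log) 95% bands, and
   Brookmeyer–Crowley quantile intervals (median, Q1, Q3).
4. **Adverse events.** Seven AE categories identified by ICD-10 diagnosis
   plus a same-calendar-month start of the corresponding AE treatment,
   tabulated with pooled patient-line denominators.
5. **Costs.** Remuneration points × 10 yen, decomposed into total / drug /
   hospitalization / outpatient, absolute and per follow-up day, per line
   and cumulative.
6. **Patterns.** Per-line regimen share tables, Sankey flow edges, and
   subgroup splits by age (< 65 / ≥ 65) and perioperative history.

The synthetic generator (`oncolot.synthetic`) emulates the claims
structure this analysis assumes — monthly diagnoses, dated prescriptions
every 21 days, exponential per-line event clocks, line transitions, AE
co-claims, and log-normal costs — and returns per-line ground truth for
parameter-recovery testing.

## Worked example

```python
from oncolot.reporting import PipelineConfig, run_pipeline
from oncolot.synthetic import SimulationConfig

res = run_pipeline(PipelineConfig(out_dir="out",
                                  simulation=SimulationConfig(n_patients=2000, seed=11)))
lines = res["lines"]
print("first-line cohort:", len(res["members"]))
for k in (1, 2, 3):
    s = res["km"]["ttntd"][f"line{k}"]
    print(f"TTNTD line {k}: median {s['median']:.1f} months "
          f"(95% CI {s['median_ci_low']:.1f}-{s['median_ci_high']:.1f}), n={s['n']}")
```

prints

```
first-line cohort: 2000
TTNTD line 1: median 8.1 months (95% CI 7.5-8.7), n=2000
TTNTD line 2: median 6.4 months (95% CI 5.7-6.9), n=922
TTNTD line 3: median 4.8 months (95% CI 4.3-5.4), n=396
```

All 2000 simulated patients pass the cohort cascade (the generator builds
compliant patients unless violations are injected); 922 (46.1%) reach a
second line and 396 (19.8%) a third, and the Kaplan–Meier medians recover
the configured per-line TTNTD medians of 8.0 / 6.5 / 5.2 months within
Monte-Carlo noise. `out/` holds the attrition trail, baseline table, lines
table, survival records, KM summaries, AE and cost tables, regimen shares,
and Sankey edges as CSV/JSON.

The same pipeline runs from the shell:

```bash
oncolot simulate claims/ --n-patients 2000 --seed 11   # four CSVs + truth.csv
oncolot run --input-dir claims/ --out-dir out/         # or --simulate-n / a YAML config
```

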