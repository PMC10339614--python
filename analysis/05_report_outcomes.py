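"""Missingness and characteristics reports, plus score-feasibility counts.

For each built cohort: per-variable missingness at baseline and six
months with its structural component, the clinical characteristics
table, and the fraction of persons for whom JADAS-71 and ACR Pedi 30
are computable from complete cases at the extracted time points —
the practical cost of missingness for composite disease-activity
measures.
"""

import importlib
import json

import pandas as pd

from cohortforge.cohort import CohortDataset
from cohortforge.dialects import ACR_CORE
from cohortforge.io import write_csv
from cohortforge.outcomes import (
    acr_pedi,
    characteristics_table,
    jadas,
    missingness_report,
    plot_missingness,
)

common = importlib.import_module("00_common")


def load_cohort(slug: str) -> CohortDataset:
    rows = pd.read_csv(common.COHORT_DIR / f"cohort_{slug}.csv",
                       dtype=str, keep_default_na=False).replace("", pd.NA)
    for col in rows.columns:
        if col.startswith(("t1_", "t2_")) and not col.endswith(("date", "days")):
            rows[col] = pd.to_numeric(rows[col])
    return CohortDataset(drug_class=slug.upper(), rows=rows,
                         removed=pd.DataFrame(), exclusions=pd.DataFrame(), ledger={})


def score_feasibility(rows: pd.DataFrame) -> dict:
    n = len(rows)
    jadas_ok = sum(
        jadas(r["t1_pga"], r["t1_pge"], r["t1_ajc"], r["t1_esr"]).computable
        for _, r in rows.iterrows()
    )
    acr_ok = responders = 0
    for _, r in rows.iterrows():
        result = acr_pedi(
            {v: r[f"t1_{v}"] for v in ACR_CORE},
            {v: r[f"t2_{v}"] for v in ACR_CORE},
            30,
        )
        if result.computable:
            acr_ok += 1
            responders += bool(result.responder)
    return {
        "n": n,
        "jadas71_computable_t1": jadas_ok,
        "acr30_computable": acr_ok,
        "acr30_responders_among_computable": responders,
    }


def main() -> None:
    summary = {}
    for slug in ("mtx", "tnfi"):
        cohort = load_cohort(slug)
        missing = missingness_report(cohort)
        write_csv(missing, common.RESULTS / f"05_missingness_{slug}.csv")
        write_csv(characteristics_table(cohort),
                  common.RESULTS / f"05_characteristics_{slug}.csv")
        plot_missingness(missing, common.SCRATCH / f"missingness_{slug}.png")
        summary[slug] = {
            "missingness_range_pct": [float(missing["pct_missing"].min()),
                                      float(missing["pct_missing"].max())],
            "scores": score_feasibility(cohort.rows),
        }
    (common.RESULTS / "05_outcomes_summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True) + "\n"
    )
    print(json.dumps(summary, indent=1, sort_keys=True))


if __name__ == "__main__":
    main()
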