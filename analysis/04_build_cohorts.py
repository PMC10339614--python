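"""Build the MTX-starter and TNFi-starter cohort datasets.

For each drug class: identify candidate treatment records, keep one
record per linked person by study precedence (CHARMS > BSPAR-Et > BCRD >
CAPS), screen against the inclusion criteria (ILAR-classified JIA,
treatment-naïve across all linked studies, course continued at least 91
days, at least one core outcome variable at baseline), and extract
baseline and six-month visits inside the [-91, 0] and [+91, +365] day
windows.  The conservation ledger — candidates = rows + duplicates
removed + persons excluded — is checked exactly on every build.
"""

import importlib
import json

import pandas as pd

from cohortforge.cdm import CdmTables
from cohortforge.cohort import build_cohort
from cohortforge.io import write_csv

common = importlib.import_module("00_common")

_NUMERIC = ("ajc", "ljc", "chaq", "esr", "crp", "pga", "pge",
            "pain_vas", "height_cm", "weight_kg", "dose_value")
_DATES = ("date_of_birth", "date_of_diagnosis", "date_of_symptom_onset",
          "visit_date", "start_date", "stop_date")


def load_cdm() -> CdmTables:
    tables = {}
    for table in ("patients", "visits", "episodes"):
        df = pd.read_csv(common.CDM_DIR / f"cdm_{table}.csv",
                         dtype=str, keep_default_na=False)
        for col in df.columns:
            if col in _DATES:
                df[col] = pd.to_datetime(df[col].replace("", pd.NaT))
            elif col in _NUMERIC:
                df[col] = pd.to_numeric(df[col].replace("", None))
            else:
                df[col] = df[col].replace("", pd.NA)
        tables[table] = df
    return CdmTables(**tables)


def main() -> None:
    cdm = load_cdm()
    summary = {}
    for drug_class, slug in (("MTX", "mtx"), ("TNFi", "tnfi")):
        cohort = build_cohort(cdm, drug_class)
        write_csv(cohort.rows, common.COHORT_DIR / f"cohort_{slug}.csv")
        write_csv(cohort.removed, common.COHORT_DIR / f"removed_{slug}.csv")
        write_csv(cohort.exclusions, common.COHORT_DIR / f"exclusions_{slug}.csv")
        reasons = (
            cohort.exclusions["exclusion_reasons"].str.split(";").explode()
            .value_counts().to_dict()
            if len(cohort.exclusions) else {}
        )
        summary[slug] = {"ledger": cohort.ledger, "exclusion_reasons": reasons}

    both = set(
        pd.read_csv(common.COHORT_DIR / "cohort_mtx.csv")["cluster_id"]
    ) & set(pd.read_csv(common.COHORT_DIR / "cohort_tnfi.csv")["cluster_id"])
    summary["persons_in_both_cohorts"] = len(both)

    (common.RESULTS / "04_cohort_ledgers.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True) + "\n"
    )
    print(json.dumps(summary, indent=1, sort_keys=True))


if __name__ == "__main__":
    main()
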