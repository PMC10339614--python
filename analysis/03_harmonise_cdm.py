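"""Map every study dialect into the common data model and pool the tables.

Each extract is decoded with its study's mapping tables (granular codes
collapsed to the most inclusive shared definition), structurally
unavailable variables are left missing, the four CDM sets are pooled
with provenance, and person-level cluster IDs from the linkage step
replace the raw identifiers in every output table.
"""

import importlib
import json

import pandas as pd

from cohortforge.cdm import attach_cluster_ids, map_to_cdm, pool_records
from cohortforge.dialects import STUDIES
from cohortforge.io import read_extracts, write_csv

common = importlib.import_module("00_common")


def main() -> None:
    extracts, _ = read_extracts(common.EXTRACT_DIR)
    cdm_sets = [map_to_cdm(extracts[s], s) for s in STUDIES]
    pooled = pool_records(cdm_sets)

    lookup = pd.read_csv(common.LINKAGE_DIR / "clusters.csv", dtype=str)
    pooled = attach_cluster_ids(pooled, lookup)
    pooled.patients = pooled.patients.drop(columns=["nhs_number"])

    for table in ("patients", "visits", "episodes"):
        write_csv(getattr(pooled, table), common.CDM_DIR / f"cdm_{table}.csv")

    summary = {
        "pooled_patient_rows": len(pooled.patients),
        "pooled_visits": len(pooled.visits),
        "pooled_treatment_records": len(pooled.episodes),
        "structural_missing": {
            s: sorted(v) for s, v in pooled.structural_missing.items()
        },
    }
    (common.RESULTS / "03_cdm_summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True) + "\n"
    )
    print(json.dumps(summary, indent=1, sort_keys=True))


if __name__ == "__main__":
    main()
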