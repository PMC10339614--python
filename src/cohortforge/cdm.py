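"""Common data model: schema, availability, per-study mapping, pooling.

Every study extract is translated into one shared schema before pooling.
Granularity is reduced to the most inclusive coding shared by all four
studies (e.g. any granular non-Caucasian ethnic category collapses to
``Non-Caucasian``); unknown source codes are hard errors rather than
silent missing values, since harmonisation is exactly where coding
errors creep in.  Variables a study never collected are set missing for
all of its records and flagged *structural* so downstream missingness
reports can separate study design from incomplete data entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dialects import (
    EPISODE_VARS,
    MappingConfig,
    PATIENT_VARS,
    STUDIES,
    VISIT_VARS,
)

PATIENT_COLUMNS = ("source_study", "local_id", "nhs_number") + PATIENT_VARS
VISIT_COLUMNS = ("source_study", "local_id") + VISIT_VARS
EPISODE_COLUMNS = ("source_study", "local_id", "record_id", "drug_class") + EPISODE_VARS

_NUMERIC_VARS = {
    "ajc", "ljc", "chaq", "esr", "crp", "pga", "pge", "pain_vas",
    "height_cm", "weight_kg", "dose_value",
}
_DATE_VARS = {
    "date_of_birth", "date_of_diagnosis", "date_of_symptom_onset",
    "visit_date", "start_date", "stop_date",
}

_RANGES = {
    "ajc": (0, 71), "ljc": (0, 71), "chaq": (0, 3),
    "esr": (0, np.inf), "crp": (0, np.inf),
    "pga": (0, 10), "pge": (0, 10), "pain_vas": (0, 10),
    "height_cm": (0, np.inf), "weight_kg": (0, np.inf),
}


class MappingError(ValueError):
    """A source code with no entry in the study's mapping table."""


class SchemaError(ValueError):
    """Inputs whose columns do not conform to the CDM schema."""


@dataclass
class CdmTables:
    """One study's (or the pooled) harmonised tables.

    ``structural_missing`` records, per source study, the CDM variables
    that are missing by design rather than by incomplete collection.
    """

    patients: pd.DataFrame
    visits: pd.DataFrame
    episodes: pd.DataFrame
    structural_missing: dict[str, frozenset[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.patients)


def availability(study: str, variable: str,
                 mapping: MappingConfig | None = None) -> str:
    """'available' or 'unavailable' for one (study, CDM variable) cell."""
    mapping = mapping or MappingConfig.default()
    return mapping.availability(study, variable)


def _decode_column(series: pd.Series, value_map: dict[str, str],
                   study: str, variable: str) -> pd.Series:
    def decode(raw):
        if raw is None or (isinstance(raw, float) and pd.isna(raw)) or str(raw) == "":
            return pd.NA
        raw = str(raw)
        if raw not in value_map:
            raise MappingError(
                f"unmapped {variable} code {raw!r} in study {study}"
            )
        return value_map[raw]

    return series.map(decode)


def _finalise_types(df: pd.DataFrame, study: str) -> pd.DataFrame:
    for col in df.columns:
        if col in _NUMERIC_VARS:
            try:
                df[col] = pd.to_numeric(df[col].replace("", np.nan))
            except (ValueError, TypeError) as exc:
                raise MappingError(f"non-numeric {col} in study {study}: {exc}") from exc
            lo, hi = _RANGES.get(col, (-np.inf, np.inf))
            bad = df[col].dropna()
            bad = bad[(bad < lo) | (bad > hi)]
            if len(bad):
                raise MappingError(
                    f"{col} out of range [{lo}, {hi}] in study {study}: "
                    f"{bad.iloc[0]!r}"
                )
        elif col in _DATE_VARS:
            df[col] = pd.to_datetime(df[col].replace("", pd.NaT), format="%Y-%m-%d")
    return df


def map_to_cdm(tables: dict[str, pd.DataFrame], study: str,
               mapping: MappingConfig | None = None) -> CdmTables:
    """Translate one study's dialect extract into the CDM.

    ``tables`` holds the study's ``patients``, ``visits`` and
    ``episodes`` DataFrames as read from CSV (strings, empty = missing).
    Every CDM field is either populated from the dialect or set missing;
    structurally unavailable variables come back as all-missing columns
    and are flagged in ``structural_missing``.  Nothing is ever invented:
    a field absent from the source row stays missing.
    """
    mapping = mapping or MappingConfig.default()
    if study not in STUDIES:
        raise KeyError(f"unknown study: {study}")
    unavailable = mapping.unavailable_vars(study)

    out: dict[str, pd.DataFrame] = {}
    for table, cdm_cols in (
        ("patients", PATIENT_COLUMNS),
        ("visits", VISIT_COLUMNS),
        ("episodes", EPISODE_COLUMNS),
    ):
        src = tables[table]
        colmap = mapping.columns(study, table)  # cdm var -> source column
        missing_src = [c for c in colmap.values() if c not in src.columns]
        if missing_src:
            raise SchemaError(f"{study} {table}: missing source columns {missing_src}")
        df = pd.DataFrame(index=src.index)
        for var in cdm_cols:
            if var == "source_study":
                df[var] = study
            elif var == "record_id" and table == "episodes":
                df[var] = src["record_id"].astype(str) if "record_id" in src else pd.NA
            elif var == "drug_class":
                continue  # derived below
            elif var in colmap:
                series = src[colmap[var]]
                value_map = mapping.value_map(study, var)
                if value_map is not None:
                    df[var] = _decode_column(series, value_map, study, var)
                else:
                    df[var] = series.replace("", pd.NA) if series.dtype == object else series
            else:
                df[var] = pd.NA  # structurally unavailable
        if table == "episodes":
            df["drug_class"] = df["drug_name"].map(
                lambda d: mapping.drug_class(d) if pd.notna(d) else pd.NA
            )
            df = df[list(EPISODE_COLUMNS)]
        df = _finalise_types(df, study)
        out[table] = df.reset_index(drop=True)

    return CdmTables(
        patients=out["patients"],
        visits=out["visits"],
        episodes=out["episodes"],
        structural_missing={study: frozenset(unavailable)},
    )


def pool_records(cdm_sets: list[CdmTables]) -> CdmTables:
    """Concatenate per-study CDM tables, preserving source-study provenance."""
    if not cdm_sets:
        raise ValueError("nothing to pool")
    pooled = {}
    for table, expected in (
        ("patients", PATIENT_COLUMNS),
        ("visits", VISIT_COLUMNS),
        ("episodes", EPISODE_COLUMNS),
    ):
        frames = [getattr(c, table) for c in cdm_sets]
        for frame in frames:
            if tuple(frame.columns) != expected:
                extra = set(frame.columns) - set(expected)
                missing = set(expected) - set(frame.columns)
                raise SchemaError(
                    f"{table}: schema mismatch (missing {sorted(missing)}, "
                    f"unexpected {sorted(extra)})"
                )
        pooled[table] = pd.concat(frames, ignore_index=True)
    structural: dict[str, frozenset[str]] = {}
    for c in cdm_sets:
        structural.update(c.structural_missing)
    return CdmTables(structural_missing=structural, **pooled)


def attach_cluster_ids(cdm: CdmTables, cluster_lookup: pd.DataFrame) -> CdmTables:
    """Join person-level cluster IDs onto all three CDM tables.

    ``cluster_lookup`` is the (source_study, local_id, record_id,
    cluster_id) table from linkage; all records of one (study, local_id)
    share an identifier and hence a cluster, so the join is patient-level.
    """
    patient_map = cluster_lookup.drop_duplicates(
        subset=["source_study", "local_id"]
    )[["source_study", "local_id", "cluster_id"]]

    def join(df: pd.DataFrame) -> pd.DataFrame:
        merged = df.merge(patient_map, on=["source_study", "local_id"], how="left")
        if merged["cluster_id"].isna().any():
            lost = merged[merged["cluster_id"].isna()][["source_study", "local_id"]]
            raise SchemaError(
                f"records without a cluster assignment: {lost.drop_duplicates().values.tolist()[:5]}"
            )
        cols = ["cluster_id"] + [c for c in merged.columns if c != "cluster_id"]
        return merged[cols]

    return CdmTables(
        patients=join(cdm.patients),
        visits=join(cdm.visits),
        episodes=join(cdm.episodes),
        structural_missing=dict(cdm.structural_missing),
    )
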