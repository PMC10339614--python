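"""CSV/JSON/YAML readers and writers shared by every pipeline stage.

One CSV convention throughout: UTF-8, comma delimiter, header row,
ISO-8601 dates, empty string for missing.  Reading is forgiving at the
row level but never silent: rows that fail to parse are collected in an
error sidecar with a reason, and missing mandatory columns are a schema
error naming the column.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from .dialects import MappingConfig, STUDIES

_DATE_VARS = {
    "date_of_birth", "date_of_diagnosis", "date_of_symptom_onset",
    "visit_date", "start_date", "stop_date",
}

#: File-name slug per study.
STUDY_SLUGS = {"BCRD": "bcrd", "BSPAR-Et": "bspar_et", "CAPS": "caps", "CHARMS": "charms"}
_TABLES = ("patients", "visits", "episodes")


class CsvSchemaError(ValueError):
    pass


def write_csv(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, lineterminator="\n")
    return path


def _is_iso_date(value: str) -> bool:
    if value == "":
        return True
    try:
        pd.Timestamp(f"{value}T00:00:00")  # strict enough: rejects month 13 etc.
        return len(value) == 10 and value[4] == "-" and value[7] == "-"
    except (ValueError, OverflowError):
        return False


def read_study_csv(
    path, study: str, table: str, mapping: MappingConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read one study extract as strings; unparseable rows go to a sidecar.

    Returns ``(records, sidecar)``.  Missing mandatory columns raise
    :class:`CsvSchemaError` naming them; rows whose date fields are not
    ISO-8601 calendar dates are moved to the sidecar with a reason
    instead of being silently dropped.
    """
    mapping = mapping or MappingConfig.default()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    colmap = mapping.columns(study, table)
    mandatory = list(colmap.values()) + (["record_id"] if table == "episodes" else [])
    missing_cols = [c for c in mandatory if c not in df.columns]
    if missing_cols:
        raise CsvSchemaError(f"{path.name}: missing mandatory columns {missing_cols}")

    date_cols = [src for var, src in colmap.items() if var in _DATE_VARS]
    reasons = []
    bad_index = []
    for idx, row in df.iterrows():
        bad = [c for c in date_cols if not _is_iso_date(row[c])]
        if bad:
            bad_index.append(idx)
            reasons.append(f"unparseable date in {bad[0]}: {row[bad[0]]!r}")
    sidecar = df.loc[bad_index].copy()
    sidecar["error_reason"] = reasons
    records = df.drop(index=bad_index).reset_index(drop=True)
    return records, sidecar


def write_extracts(extracts: dict[str, dict[str, pd.DataFrame]], outdir) -> list[Path]:
    """One CSV per (study, table) under *outdir*; returns paths written."""
    outdir = Path(outdir)
    paths = []
    for study in STUDIES:
        for table in _TABLES:
            paths.append(
                write_csv(extracts[study][table], outdir / f"{STUDY_SLUGS[study]}_{table}.csv")
            )
    return paths


def read_extracts(
    indir, mapping: MappingConfig | None = None
) -> tuple[dict[str, dict[str, pd.DataFrame]], dict[str, pd.DataFrame]]:
    """Read all four studies' extracts; sidecars keyed by file stem."""
    indir = Path(indir)
    extracts: dict[str, dict[str, pd.DataFrame]] = {}
    sidecars: dict[str, pd.DataFrame] = {}
    for study in STUDIES:
        extracts[study] = {}
        for table in _TABLES:
            stem = f"{STUDY_SLUGS[study]}_{table}"
            records, sidecar = read_study_csv(
                indir / f"{stem}.csv", study, table, mapping
            )
            extracts[study][table] = records
            if len(sidecar):
                sidecars[stem] = sidecar
    return extracts, sidecars


def read_salt(path) -> bytes:
    """Salt file: raw bytes, trailing newline stripped."""
    data = Path(path).read_bytes().rstrip(b"\r\n")
    if not data:
        raise ValueError(f"salt file {path} is empty")
    return data


def write_json(payload: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n", encoding="utf-8")
    return path


def write_yaml(payload: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(payload, sort_keys=True), encoding="utf-8")
    return path


def sha256_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
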