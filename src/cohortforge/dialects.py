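"""Study dialects, the common-data-model variable set, and the availability matrix.

The four contributing registries (BCRD, BSPAR-Et, CAPS, CHARMS) each export
CSV extracts in their own column naming and value coding.  A mapping
configuration — shipped as editable YAML with defaults matching the four
study designs — declares, per study, the source column for every common
data model (CDM) variable and the value-code translation tables, plus the
availability matrix: which CDM variables a study never collected at all
(structural missingness).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Any

import yaml

STUDIES = ("BCRD", "BSPAR-Et", "CAPS", "CHARMS")

ILAR_SUBTYPES = (
    "systemic",
    "oligo_persistent",
    "oligo_extended",
    "poly_rf_neg",
    "poly_rf_pos",
    "enthesitis_related",
    "psoriatic",
    "undifferentiated",
)

DRUG_CLASSES = ("MTX", "TNFi", "other_biologic")

PATIENT_VARS = (
    "date_of_birth",
    "gender",
    "ethnicity",
    "ilar_subtype",
    "date_of_diagnosis",
    "date_of_symptom_onset",
    "ana",
    "rf",
    "hla_b27",
    "uveitis_ever",
)

VISIT_VARS = (
    "visit_date",
    "ajc",
    "ljc",
    "chaq",
    "esr",
    "crp",
    "pga",
    "pge",
    "pain_vas",
    "height_cm",
    "weight_kg",
)

EPISODE_VARS = (
    "drug_name",
    "start_date",
    "stop_date",
    "dose_value",
    "dose_unit",
    "route",
    "stop_reason",
)

#: The eight core outcome variables captured in the CDM.
COVS = ("ajc", "ljc", "chaq", "esr", "crp", "pga", "pge", "pain_vas")

#: The six-variable core set used by the paediatric response criteria.
ACR_CORE = ("pga", "pge", "chaq", "ajc", "ljc", "esr")

ALL_VARS = ("nhs_number",) + PATIENT_VARS + VISIT_VARS + EPISODE_VARS

#: Which value-translation table each coded CDM variable uses.
_VALUE_MAP_KIND = {
    "gender": "gender",
    "ethnicity": "ethnicity",
    "ilar_subtype": "ilar_subtype",
    "ana": "tristate",
    "rf": "tristate",
    "hla_b27": "tristate",
    "uveitis_ever": "uveitis",
    "stop_reason": "stop_reason",
    "route": "route",
    "drug_name": "drug",
}


class MappingConfigError(ValueError):
    """Raised when a mapping configuration is internally inconsistent."""


@dataclass(frozen=True)
class MappingConfig:
    """Parsed mapping configuration: dialects, value maps, availability."""

    raw: dict[str, Any]

    # -- construction -------------------------------------------------

    @classmethod
    def default(cls) -> "MappingConfig":
        text = (
            importlib.resources.files("cohortforge")
            .joinpath("data/default_mapping.yaml")
            .read_text(encoding="utf-8")
        )
        return cls.from_dict(yaml.safe_load(text))

    @classmethod
    def from_yaml(cls, path) -> "MappingConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "MappingConfig":
        cfg = cls(raw=raw)
        cfg._validate()
        return cfg

    def _validate(self) -> None:
        studies = tuple(self.raw.get("studies", ()))
        if set(studies) != set(STUDIES):
            raise MappingConfigError(f"studies must be {STUDIES}, got {studies}")
        for var in self.raw.get("availability_exceptions", {}):
            if var not in ALL_VARS:
                raise MappingConfigError(f"unknown variable in availability: {var}")
        for study in STUDIES:
            dialect = self.raw["dialects"].get(study)
            if dialect is None:
                raise MappingConfigError(f"no dialect for study {study}")
            unavailable = self.unavailable_vars(study)
            for table, table_vars in (
                ("patients", ("nhs_number",) + PATIENT_VARS),
                ("visits", VISIT_VARS),
                ("episodes", EPISODE_VARS),
            ):
                cols = dialect["columns"][table]
                for var in table_vars:
                    present = var in cols
                    if var in unavailable and present:
                        raise MappingConfigError(
                            f"{study}: {var} is structurally unavailable but mapped"
                        )
                    if var not in unavailable and not present:
                        raise MappingConfigError(
                            f"{study}: available variable {var} has no source column"
                        )

    # -- availability --------------------------------------------------

    def availability(self, study: str, variable: str) -> str:
        """'available' or 'unavailable' per the configured matrix."""
        if study not in STUDIES:
            raise KeyError(f"unknown study: {study}")
        if variable not in ALL_VARS:
            raise KeyError(f"unknown CDM variable: {variable}")
        exceptions = self.raw.get("availability_exceptions", {})
        if study in exceptions.get(variable, ()):
            return "unavailable"
        return "available"

    def unavailable_vars(self, study: str) -> set[str]:
        return {
            var
            for var, studies in self.raw.get("availability_exceptions", {}).items()
            if study in studies
        }

    # -- dialect lookups ----------------------------------------------

    def id_prefix(self, study: str) -> str:
        return self.raw["dialects"][study]["id_prefix"]

    def columns(self, study: str, table: str) -> dict[str, str]:
        """CDM variable -> source column name for one study table."""
        return dict(self.raw["dialects"][study]["columns"][table])

    def value_map(self, study: str, variable: str) -> dict[str, str] | None:
        """Source code -> canonical value for a coded variable, else None."""
        kind = _VALUE_MAP_KIND.get(variable)
        if kind is None:
            return None
        return {str(k): str(v) for k, v in
                self.raw["dialects"][study]["values"][kind].items()}

    def inverse_value_map(self, study: str, variable: str) -> dict[str, list[str]]:
        """Canonical value -> the study's source codes (granular codes fan out)."""
        forward = self.value_map(study, variable)
        if forward is None:
            raise KeyError(f"{variable} has no value map")
        inverse: dict[str, list[str]] = {}
        for src, canon in forward.items():
            inverse.setdefault(canon, []).append(src)
        return inverse

    def drug_class(self, canonical_drug: str) -> str:
        classes = self.raw["drug_classes"]
        if canonical_drug not in classes:
            raise KeyError(f"unknown drug: {canonical_drug}")
        return classes[canonical_drug]
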