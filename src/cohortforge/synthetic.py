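"""Synthetic four-study JIA cohort generator.

Real multi-registry JIA data are governed and cannot be shared, so every
downstream stage of the pipeline is exercised on synthetic extracts that
emulate the *structure* of the four contributing studies: study-specific
entry points (CAPS enrols at diagnosis, the other three at treatment
start), visit schedules, per-study variable availability, planted
person-level overlap across studies, within-study repeat-treatment
records, injected random missingness, and identifier corruption.  The
generator models data structure, not disease biology: clinical values are
drawn from calibrated marginal distributions and do not evolve over time
or respond to treatment.

Alongside the four study extracts the generator returns a
:class:`PlantedTruth` ledger — who each record really belongs to, which
identifiers were corrupted or blanked — against which linkage recovery
and duplicate-resolution behaviour are verified exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, NonNegativeInt, PositiveInt, model_validator

from . import nhs
from .dialects import STUDIES, ILAR_SUBTYPES, MappingConfig

# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------


class MembershipPattern(BaseModel):
    """One row of the exact-count membership table.

    ``count`` individuals belong to ``n_studies`` distinct studies and
    carry ``records`` treatment records in total (default: one per
    study).  ``records > n_studies`` with ``n_studies == 1`` expresses
    the "multiple treatment records within one study" pattern.
    """

    count: NonNegativeInt
    n_studies: int = Field(ge=1, le=4)
    records: Optional[int] = None

    @model_validator(mode="after")
    def _records_cover_studies(self) -> "MembershipPattern":
        if self.records is not None and self.records < self.n_studies:
            raise ValueError("records must be >= n_studies")
        return self

    @property
    def n_records(self) -> int:
        return self.records if self.records is not None else self.n_studies


class DemographicsSpec(BaseModel):
    """Marginal distributions for planted person-level characteristics.

    Defaults are calibrated to the characteristics table of the
    harmonised MTX dataset (female 67.6%, Caucasian 87.3%, age at onset
    mean 6.6 SD 4.3 years truncated at 0, ILAR subtype fractions per the
    same column), so synthetic summaries resemble the published cohort
    without claiming to reproduce it.
    """

    gender_probs: dict[str, float] = Field(
        default_factory=lambda: {"male": 0.321, "female": 0.676, "missing": 0.003}
    )
    ethnicity_probs: dict[str, float] = Field(
        default_factory=lambda: {"Caucasian": 0.873, "Non-Caucasian": 0.125, "missing": 0.002}
    )
    ilar_probs: dict[str, float] = Field(
        default_factory=lambda: {
            "systemic": 0.076,
            "oligo_persistent": 0.195,
            "oligo_extended": 0.150,
            "poly_rf_neg": 0.314,
            "poly_rf_pos": 0.059,
            "enthesitis_related": 0.059,
            "psoriatic": 0.070,
            "undifferentiated": 0.048,
            "missing": 0.029,
        }
    )
    ana_probs: dict[str, float] = Field(
        default_factory=lambda: {"positive": 0.45, "negative": 0.55}
    )
    rf_probs: dict[str, float] = Field(
        default_factory=lambda: {"positive": 0.08, "negative": 0.92}
    )
    hla_b27_probs: dict[str, float] = Field(
        default_factory=lambda: {"positive": 0.12, "negative": 0.88}
    )
    uveitis_probs: dict[str, float] = Field(
        default_factory=lambda: {"yes": 0.14, "no": 0.86}
    )
    age_onset_mean: float = 6.6
    age_onset_sd: float = 4.3
    onset_window: tuple[str, str] = ("2004-01-01", "2016-12-31")

    @model_validator(mode="after")
    def _probs_valid(self) -> "DemographicsSpec":
        for name in ("gender_probs", "ethnicity_probs", "ilar_probs",
                     "ana_probs", "rf_probs", "hla_b27_probs", "uveitis_probs"):
            probs = getattr(self, name)
            if any(p < 0 or p > 1 for p in probs.values()):
                raise ValueError(f"{name}: probabilities must lie in [0, 1]")
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name}: probabilities must sum to 1")
        if self.age_onset_sd <= 0:
            raise ValueError("age_onset_sd must be positive")
        return self


class TreatmentSpec(BaseModel):
    """Per-person drug-episode rules (courses, timing, stops)."""

    p_mtx: float = Field(default=0.80, ge=0, le=1)
    p_tnfi_given_mtx: float = Field(default=0.45, ge=0, le=1)
    p_tnfi_given_no_mtx: float = Field(default=1.0, ge=0, le=1)
    tnfi_drug_probs: dict[str, float] = Field(
        default_factory=lambda: {
            "etanercept": 0.60,
            "adalimumab": 0.25,
            "infliximab": 0.10,
            "golimumab": 0.05,
        }
    )
    diagnosis_to_mtx_days: tuple[int, int] = (0, 180)
    diagnosis_to_tnfi_days: tuple[int, int] = (60, 360)
    mtx_to_tnfi_gap_days: tuple[int, int] = (120, 720)
    p_stop_early: float = Field(default=0.12, ge=0, le=1)  # stops inside 3 months
    early_stop_days: tuple[int, int] = (14, 90)
    p_stop_late: float = Field(default=0.35, ge=0, le=1)
    late_stop_days: tuple[int, int] = (91, 900)
    stop_reason_probs: dict[str, float] = Field(
        default_factory=lambda: {
            "inefficacy": 0.40,
            "adverse_event": 0.25,
            "remission": 0.25,
            "other": 0.10,
        }
    )
    #: chance a multi-study person's record in one study is an *earlier*
    #: course of the same class (prior exposure visible only via linkage)
    p_prior_exposure: float = Field(default=0.05, ge=0, le=1)
    prior_gap_days: tuple[int, int] = (200, 600)
    prior_duration_days: tuple[int, int] = (91, 300)
    repeat_gap_days: tuple[int, int] = (200, 600)

    @model_validator(mode="after")
    def _valid(self) -> "TreatmentSpec":
        if self.p_stop_early + self.p_stop_late > 1.0 + 1e-9:
            raise ValueError("p_stop_early + p_stop_late must not exceed 1")
        if abs(sum(self.tnfi_drug_probs.values()) - 1.0) > 1e-9:
            raise ValueError("tnfi_drug_probs must sum to 1")
        return self


#: Default per-variable random missingness (probability a collected value
#: is blank), spanning the 10-60% band seen across registry variables.
DEFAULT_MISSINGNESS = {
    "ajc": 0.12,
    "ljc": 0.15,
    "chaq": 0.35,
    "esr": 0.30,
    "crp": 0.45,
    "pga": 0.25,
    "pge": 0.30,
    "pain_vas": 0.40,
    "height_cm": 0.20,
    "weight_kg": 0.18,
    "ana": 0.25,
    "rf": 0.22,
    "hla_b27": 0.55,
    "uveitis_ever": 0.15,
    "date_of_symptom_onset": 0.10,
    "date_of_diagnosis": 0.05,
    "dose_value": 0.30,
    "dose_unit": 0.30,
    "route": 0.20,
    "stop_reason": 0.10,
}

#: Nominal visit offsets in days from study entry.  The two biologics
#: registers and CAPS review at 6 and 12 months then annually; CHARMS
#: collects at 3 and 6 months after treatment start.
DEFAULT_VISIT_SCHEDULES = {
    "BCRD": [0, 183, 365, 730],
    "BSPAR-Et": [0, 183, 365, 730],
    "CAPS": [0, 183, 365, 730],
    "CHARMS": [0, 91, 183],
}


class GeneratorConfig(BaseModel):
    """Full specification of one synthetic four-study cohort."""

    mode: Literal["exact_count", "stochastic"] = "exact_count"
    n_individuals: PositiveInt
    membership: Optional[list[MembershipPattern]] = None
    enrolment_probabilities: Optional[dict[str, float]] = None
    extra_duplicate_records: NonNegativeInt = 0
    visit_schedules: dict[str, list[int]] = Field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_VISIT_SCHEDULES.items()}
    )
    visit_jitter_days: NonNegativeInt = 30
    missingness_rates: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_MISSINGNESS)
    )
    identifier_corruption_rate: float = Field(default=0.0, ge=0, le=1)
    identifier_missing_rate: float = Field(default=0.0, ge=0, le=1)
    demographics: DemographicsSpec = Field(default_factory=DemographicsSpec)
    treatment: TreatmentSpec = Field(default_factory=TreatmentSpec)
    seed: int = 0

    @model_validator(mode="after")
    def _consistent(self) -> "GeneratorConfig":
        if self.mode == "exact_count":
            if not self.membership:
                raise ValueError("membership: exact_count mode requires a membership table")
            total = sum(p.count for p in self.membership)
            if total != self.n_individuals:
                raise ValueError(
                    f"membership: pattern counts sum to {total}, "
                    f"but n_individuals = {self.n_individuals}"
                )
        else:
            if not self.enrolment_probabilities:
                raise ValueError(
                    "enrolment_probabilities: stochastic mode requires per-study probabilities"
                )
            unknown = set(self.enrolment_probabilities) - set(STUDIES)
            if unknown:
                raise ValueError(f"enrolment_probabilities: unknown studies {sorted(unknown)}")
            if any(not 0 <= p <= 1 for p in self.enrolment_probabilities.values()):
                raise ValueError("enrolment_probabilities: values must lie in [0, 1]")
        for var, rate in self.missingness_rates.items():
            if not 0 <= rate <= 1:
                raise ValueError(f"missingness_rates[{var}] must lie in [0, 1]")
        unknown = set(self.visit_schedules) - set(STUDIES)
        if unknown:
            raise ValueError(f"visit_schedules: unknown studies {sorted(unknown)}")
        return self


def calibrated_cohort_config(seed: int = 0) -> GeneratorConfig:
    """The published duplication structure as an exact-count configuration.

    5435 individuals across the four studies: 4131 with a single record,
    197 with multiple records within one study, 961 with records in two
    studies, 142 in three, and 4 in all four; 124 extra within-study
    repeat records bring the total to 7013 records, of which 2882 sit in
    multi-record clusters (41.1%).  Identifier corruption is disabled so
    digest linkage recovers the planted structure exactly.
    """
    return GeneratorConfig(
        mode="exact_count",
        n_individuals=5435,
        membership=[
            MembershipPattern(count=4131, n_studies=1),
            MembershipPattern(count=197, n_studies=1, records=2),
            MembershipPattern(count=961, n_studies=2),
            MembershipPattern(count=142, n_studies=3),
            MembershipPattern(count=4, n_studies=4),
        ],
        extra_duplicate_records=124,
        identifier_corruption_rate=0.0,
        identifier_missing_rate=0.0,
        seed=seed,
    )


# --------------------------------------------------------------------------
# planted truth
# --------------------------------------------------------------------------


@dataclass
class RecordTruth:
    """One generated treatment record (the unit counted by linkage)."""

    record_id: str
    study: str
    local_id: str
    drug: str
    drug_class: str
    start: str
    stop: str | None
    stop_reason: str | None
    route: str | None


@dataclass
class PersonTruth:
    person_id: int
    nhs_number: str
    gender: str
    ethnicity: str
    ilar_subtype: str
    ana: str
    rf: str
    hla_b27: str
    uveitis: str
    age_at_onset: float
    date_of_birth: str
    date_of_symptom_onset: str
    date_of_diagnosis: str
    local_ids: dict[str, str] = field(default_factory=dict)  # study -> local id
    records: list[RecordTruth] = field(default_factory=list)

    @property
    def studies(self) -> list[str]:
        return sorted(self.local_ids)

    @property
    def n_records(self) -> int:
        return len(self.records)

    def records_per_study(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.records:
            out[r.study] = out.get(r.study, 0) + 1
        return out

    def class_records(self, drug_class: str) -> list[RecordTruth]:
        return [r for r in self.records if r.drug_class == drug_class]


@dataclass
class PlantedTruth:
    """Ground truth for linkage-recovery and duplicate-resolution tests."""

    persons: list[PersonTruth]
    corrupted_identifiers: list[tuple[str, str, str]]  # (study, local_id, corrupted value)
    missing_identifiers: list[tuple[str, str]]  # (study, local_id)

    def person_of(self, study: str, local_id: str) -> PersonTruth:
        for p in self.persons:
            if p.local_ids.get(study) == local_id:
                return p
        raise KeyError((study, local_id))

    def multiplicity_histogram(self) -> dict[int, int]:
        """Individuals with >= 2 records, keyed by number of studies."""
        hist: dict[int, int] = {}
        for p in self.persons:
            if p.n_records >= 2:
                k = len(p.studies)
                hist[k] = hist.get(k, 0) + 1
        return hist

    def to_json(self) -> str:
        payload = {
            "persons": [dataclasses.asdict(p) for p in self.persons],
            "corrupted_identifiers": [list(t) for t in self.corrupted_identifiers],
            "missing_identifiers": [list(t) for t in self.missing_identifiers],
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PlantedTruth":
        payload = json.loads(text)
        persons = []
        for p in payload["persons"]:
            records = [RecordTruth(**r) for r in p.pop("records")]
            persons.append(PersonTruth(**p, records=records))
        return cls(
            persons=persons,
            corrupted_identifiers=[tuple(t) for t in payload["corrupted_identifiers"]],
            missing_identifiers=[tuple(t) for t in payload["missing_identifiers"]],
        )


# --------------------------------------------------------------------------
# generation
# --------------------------------------------------------------------------

_ISO = "%Y-%m-%d"

#: Which of a person's drug classes a study records first, by design focus.
_CLASS_PREFERENCE = {
    "BCRD": ("TNFi", "MTX"),
    "BSPAR-Et": ("TNFi", "MTX"),
    "CAPS": ("MTX", "TNFi"),
    "CHARMS": ("MTX", "TNFi"),
}

_TNFI_ROUTE = "subcutaneous"


def _choice(rng: np.random.Generator, probs: dict[str, float]) -> str:
    keys = list(probs)
    return keys[rng.choice(len(keys), p=np.array([probs[k] for k in keys]))]


def _uniform_days(rng: np.random.Generator, lo_hi: tuple[int, int]) -> int:
    lo, hi = lo_hi
    return int(rng.integers(lo, hi + 1))


@dataclass
class _Course:
    drug: str
    drug_class: str
    start: date
    stop: date | None
    stop_reason: str | None
    route: str | None


def generate_cohort(
    config: GeneratorConfig, mapping: MappingConfig | None = None
) -> tuple[dict[str, dict[str, pd.DataFrame]], PlantedTruth]:
    """Generate the four study extracts plus the planted-truth ledger.

    Returns ``(extracts, truth)`` where ``extracts[study]`` holds three
    DataFrames (``patients``, ``visits``, ``episodes``) already encoded
    in that study's dialect: its own column names and value codes,
    ISO-8601 dates, empty string for missing, and variables the study
    never collected absent from the frame entirely.
    """
    mapping = mapping or MappingConfig.default()
    streams = np.random.SeedSequence(config.seed).spawn(7)
    rng_member, rng_ident, rng_demo, rng_treat, rng_visit, rng_miss, rng_corrupt = (
        np.random.default_rng(s) for s in streams
    )

    memberships = _draw_memberships(config, rng_member)
    numbers = nhs.generate_test_numbers(config.n_individuals, rng_ident)

    persons: list[PersonTruth] = []
    courses_by_person: list[dict[str, list[_Course]]] = []
    counters = {study: 0 for study in STUDIES}

    for pid, (studies, records_per_study) in enumerate(memberships):
        demo = _draw_demographics(config.demographics, rng_demo)
        person = PersonTruth(person_id=pid, nhs_number=numbers[pid], **demo)
        base_courses = _draw_courses(
            config.treatment, date.fromisoformat(person.date_of_diagnosis), rng_treat
        )
        # one study of a multi-study person may hold an earlier course of
        # the same class instead of the shared one (prior exposure)
        prior_study = None
        if len(studies) >= 2 and rng_treat.random() < config.treatment.p_prior_exposure:
            prior_study = studies[int(rng_treat.integers(0, len(studies)))]

        study_courses: dict[str, list[_Course]] = {}
        for study in studies:
            counters[study] += 1
            local_id = f"{mapping.id_prefix(study)}{counters[study]:05d}"
            person.local_ids[study] = local_id
            n_rec = records_per_study[study]
            assigned = _assign_courses(
                base_courses, study, n_rec, config.treatment, rng_treat
            )
            if study == prior_study:
                assigned[0] = _prior_version(assigned[0], config.treatment, rng_treat)
            study_courses[study] = assigned
            for k, course in enumerate(assigned, start=1):
                person.records.append(
                    RecordTruth(
                        record_id=f"{local_id}-R{k}",
                        study=study,
                        local_id=local_id,
                        drug=course.drug,
                        drug_class=course.drug_class,
                        start=course.start.strftime(_ISO),
                        stop=course.stop.strftime(_ISO) if course.stop else None,
                        stop_reason=course.stop_reason,
                        route=course.route,
                    )
                )
        persons.append(person)
        courses_by_person.append(study_courses)

    # identifier corruption / blanking, per (person, study)
    corrupted: list[tuple[str, str, str]] = []
    missing_ids: list[tuple[str, str]] = []
    stored_identifier: dict[tuple[str, str], str] = {}
    for person in persons:
        for study, local_id in person.local_ids.items():
            ident = person.nhs_number
            u = rng_corrupt.random()
            if u < config.identifier_missing_rate:
                ident = ""
                missing_ids.append((study, local_id))
            elif u < config.identifier_missing_rate + config.identifier_corruption_rate:
                ident = nhs.corrupt_identifier(person.nhs_number, rng_corrupt)
                corrupted.append((study, local_id, ident))
            stored_identifier[(study, local_id)] = ident

    truth = PlantedTruth(
        persons=persons,
        corrupted_identifiers=corrupted,
        missing_identifiers=missing_ids,
    )
    extracts = _emit_extracts(
        config, mapping, persons, courses_by_person, stored_identifier,
        rng_visit, rng_miss,
    )
    return extracts, truth


# -- membership -------------------------------------------------------------


def _draw_memberships(
    config: GeneratorConfig, rng: np.random.Generator
) -> list[tuple[list[str], dict[str, int]]]:
    """Per person: (sorted study list, records per study)."""
    memberships: list[tuple[list[str], dict[str, int]]] = []
    if config.mode == "exact_count":
        for pattern in config.membership or []:
            for _ in range(pattern.count):
                idx = rng.choice(len(STUDIES), size=pattern.n_studies, replace=False)
                studies = sorted(STUDIES[i] for i in idx)
                counts = {s: 1 for s in studies}
                for _extra in range(pattern.n_records - pattern.n_studies):
                    counts[studies[int(rng.integers(0, len(studies)))]] += 1
                memberships.append((studies, counts))
    else:
        probs = config.enrolment_probabilities or {}
        weights = np.array([probs.get(s, 0.0) for s in STUDIES])
        for _ in range(config.n_individuals):
            mask = rng.random(len(STUDIES)) < weights
            studies = [s for s, m in zip(STUDIES, mask) if m]
            if not studies:
                p = weights / weights.sum() if weights.sum() else None
                studies = [STUDIES[rng.choice(len(STUDIES), p=p)]]
            studies = sorted(studies)
            memberships.append((studies, {s: 1 for s in studies}))

    # distribute extra within-study repeat records among multi-record persons
    multi = [i for i, (_, counts) in enumerate(memberships) if sum(counts.values()) >= 2]
    if config.extra_duplicate_records and not multi:
        raise ValueError(
            "extra_duplicate_records requires at least one multi-record individual"
        )
    for _ in range(config.extra_duplicate_records):
        i = multi[int(rng.integers(0, len(multi)))]
        studies, counts = memberships[i]
        counts[studies[int(rng.integers(0, len(studies)))]] += 1
    return memberships


# -- person-level draws -----------------------------------------------------


def _draw_demographics(spec: DemographicsSpec, rng: np.random.Generator) -> dict:
    age = -1.0
    while age < 0:
        age = rng.normal(spec.age_onset_mean, spec.age_onset_sd)
    lo = date.fromisoformat(spec.onset_window[0])
    hi = date.fromisoformat(spec.onset_window[1])
    onset = lo + timedelta(days=int(rng.integers(0, (hi - lo).days + 1)))
    diagnosis = onset + timedelta(days=int(rng.integers(30, 366)))
    dob = onset - timedelta(days=int(round(age * 365.25)))
    return {
        "gender": _choice(rng, spec.gender_probs),
        "ethnicity": _choice(rng, spec.ethnicity_probs),
        "ilar_subtype": _choice(rng, spec.ilar_probs),
        "ana": _choice(rng, spec.ana_probs),
        "rf": _choice(rng, spec.rf_probs),
        "hla_b27": _choice(rng, spec.hla_b27_probs),
        "uveitis": _choice(rng, spec.uveitis_probs),
        "age_at_onset": round(float(age), 2),
        "date_of_birth": dob.strftime(_ISO),
        "date_of_symptom_onset": onset.strftime(_ISO),
        "date_of_diagnosis": diagnosis.strftime(_ISO),
    }


def _draw_stop(
    spec: TreatmentSpec, start: date, rng: np.random.Generator
) -> tuple[date | None, str | None]:
    u = rng.random()
    if u < spec.p_stop_early:
        stop = start + timedelta(days=_uniform_days(rng, spec.early_stop_days))
    elif u < spec.p_stop_early + spec.p_stop_late:
        stop = start + timedelta(days=_uniform_days(rng, spec.late_stop_days))
    else:
        return None, None
    return stop, _choice(rng, spec.stop_reason_probs)


def _draw_courses(
    spec: TreatmentSpec, diagnosis: date, rng: np.random.Generator
) -> dict[str, _Course]:
    """The person's base course per drug class (at least one class)."""
    has_mtx = rng.random() < spec.p_mtx
    p_tnfi = spec.p_tnfi_given_mtx if has_mtx else spec.p_tnfi_given_no_mtx
    has_tnfi = rng.random() < p_tnfi
    if not has_mtx and not has_tnfi:
        has_mtx = True
    courses: dict[str, _Course] = {}
    mtx_start = None
    if has_mtx:
        mtx_start = diagnosis + timedelta(days=_uniform_days(rng, spec.diagnosis_to_mtx_days))
        stop, reason = _draw_stop(spec, mtx_start, rng)
        route = "oral" if rng.random() < 0.7 else "subcutaneous"
        courses["MTX"] = _Course("methotrexate", "MTX", mtx_start, stop, reason, route)
    if has_tnfi:
        if mtx_start is not None:
            tnfi_start = mtx_start + timedelta(days=_uniform_days(rng, spec.mtx_to_tnfi_gap_days))
        else:
            tnfi_start = diagnosis + timedelta(days=_uniform_days(rng, spec.diagnosis_to_tnfi_days))
        stop, reason = _draw_stop(spec, tnfi_start, rng)
        drug = _choice(rng, spec.tnfi_drug_probs)
        courses["TNFi"] = _Course(drug, "TNFi", tnfi_start, stop, reason, _TNFI_ROUTE)
    return courses


def _assign_courses(
    base: dict[str, _Course],
    study: str,
    n_records: int,
    spec: TreatmentSpec,
    rng: np.random.Generator,
) -> list[_Course]:
    """Which courses one study records: preferred classes first, then
    repeat courses of the last class to make up the record count."""
    preference = [c for c in _CLASS_PREFERENCE[study] if c in base]
    assigned = [base[c] for c in preference[:n_records]]
    while len(assigned) < n_records:
        template = assigned[-1]
        start = template.start + timedelta(days=_uniform_days(rng, spec.repeat_gap_days))
        stop, reason = _draw_stop(spec, start, rng)
        assigned.append(
            _Course(template.drug, template.drug_class, start, stop, reason, template.route)
        )
    return assigned


def _prior_version(
    course: _Course, spec: TreatmentSpec, rng: np.random.Generator
) -> _Course:
    start = course.start - timedelta(days=_uniform_days(rng, spec.prior_gap_days))
    stop = start + timedelta(days=_uniform_days(rng, spec.prior_duration_days))
    return _Course(
        course.drug, course.drug_class, start, stop,
        _choice(rng, spec.stop_reason_probs), course.route,
    )


# -- emission ---------------------------------------------------------------


def _maybe_missing(value: str, var: str, rates: dict[str, float],
                   rng: np.random.Generator) -> str:
    rate = rates.get(var, 0.0)
    if rate and rng.random() < rate:
        return ""
    return value


def _encode(mapping: MappingConfig, study: str, var: str, canonical: str,
            rng: np.random.Generator) -> str:
    """Canonical value -> one of the study's source codes for that value."""
    if canonical in ("", "missing", None):
        return ""
    inverse = mapping.inverse_value_map(study, var)
    codes = inverse[canonical]
    if len(codes) == 1:
        return codes[0]
    return codes[int(rng.integers(0, len(codes)))]


def _emit_extracts(
    config: GeneratorConfig,
    mapping: MappingConfig,
    persons: list[PersonTruth],
    courses_by_person: list[dict[str, list[_Course]]],
    stored_identifier: dict[tuple[str, str], str],
    rng_visit: np.random.Generator,
    rng_miss: np.random.Generator,
) -> dict[str, dict[str, pd.DataFrame]]:
    rates = config.missingness_rates
    rows: dict[str, dict[str, list[dict]]] = {
        s: {"patients": [], "visits": [], "episodes": []} for s in STUDIES
    }

    for person, study_courses in zip(persons, courses_by_person):
        for study in person.studies:
            local_id = person.local_ids[study]
            cols = mapping.columns(study, "patients")
            courses = study_courses[study]
            patient = {cols["local_id"]: local_id,
                       cols["nhs_number"]: stored_identifier[(study, local_id)]}
            canonical_values = {
                "date_of_birth": person.date_of_birth,
                "gender": person.gender,
                "ethnicity": person.ethnicity,
                "ilar_subtype": person.ilar_subtype,
                "date_of_diagnosis": person.date_of_diagnosis,
                "date_of_symptom_onset": person.date_of_symptom_onset,
                "ana": person.ana,
                "rf": person.rf,
                "hla_b27": person.hla_b27,
                "uveitis_ever": person.uveitis,
            }
            for var, src_col in cols.items():
                if var in ("local_id", "nhs_number"):
                    continue
                value = canonical_values[var]
                if value == "missing":
                    patient[src_col] = ""
                    continue
                if mapping.value_map(study, var) is not None:
                    value = _encode(mapping, study, var, value, rng_miss)
                if var in ("date_of_diagnosis", "date_of_symptom_onset",
                           "ana", "rf", "hla_b27", "uveitis_ever"):
                    value = _maybe_missing(value, var, rates, rng_miss)
                patient[src_col] = value
            rows[study]["patients"].append(patient)

            rows[study]["visits"].extend(
                _emit_visits(config, mapping, study, local_id, person,
                             courses, rng_visit, rng_miss)
            )
            rows[study]["episodes"].extend(
                _emit_episodes(mapping, study, local_id, courses, rates, rng_miss)
            )

    extracts: dict[str, dict[str, pd.DataFrame]] = {}
    for study in STUDIES:
        tables = {}
        for table in ("patients", "visits", "episodes"):
            columns = list(mapping.columns(study, table).values())
            if table == "episodes":
                columns = columns + ["record_id"]
            df = pd.DataFrame(rows[study][table], columns=columns)
            tables[table] = df.astype(str) if df.empty else df
        extracts[study] = tables
    return extracts


def _emit_visits(
    config: GeneratorConfig,
    mapping: MappingConfig,
    study: str,
    local_id: str,
    person: PersonTruth,
    courses: list[_Course],
    rng_visit: np.random.Generator,
    rng_miss: np.random.Generator,
) -> list[dict]:
    cols = mapping.columns(study, "visits")
    rates = config.missingness_rates
    # CAPS follows children from diagnosis; the other studies from the
    # start of the treatment course that brought the child in
    if study == "CAPS":
        entry = date.fromisoformat(person.date_of_diagnosis)
    else:
        entry = min(c.start for c in courses)
    dob = date.fromisoformat(person.date_of_birth)
    jitter = config.visit_jitter_days
    out = []
    for offset in config.visit_schedules.get(study, []):
        shift = int(rng_visit.integers(-jitter, jitter + 1)) if jitter else 0
        visit_date = entry + timedelta(days=offset + shift)
        age = max((visit_date - dob).days / 365.25, 0.5)
        values = {
            "visit_date": visit_date.strftime(_ISO),
            "ajc": str(int(np.clip(rng_visit.poisson(5), 0, 71))),
            "ljc": str(int(np.clip(rng_visit.poisson(4), 0, 71))),
            "chaq": f"{round(rng_visit.uniform(0, 3) * 8) / 8:.3f}",
            "esr": str(int(np.clip(round(rng_visit.gamma(2.0, 12.0)), 0, 140))),
            "crp": f"{np.clip(rng_visit.gamma(2.0, 9.0), 0, 300):.1f}",
            "pga": f"{rng_visit.uniform(0, 10):.1f}",
            "pge": f"{rng_visit.uniform(0, 10):.1f}",
            "pain_vas": f"{rng_visit.uniform(0, 10):.1f}",
            "height_cm": f"{np.clip(75 + 6.3 * age + rng_visit.normal(0, 4), 55, 195):.1f}",
            "weight_kg": f"{np.clip(9 + 2.9 * age + rng_visit.normal(0, 2), 6, 95):.1f}",
        }
        row = {cols["local_id"]: local_id}
        for var, src_col in cols.items():
            if var == "local_id":
                continue
            value = values[var]
            if var != "visit_date":
                value = _maybe_missing(value, var, rates, rng_miss)
            row[src_col] = value
        out.append(row)
    return out


def _emit_episodes(
    mapping: MappingConfig,
    study: str,
    local_id: str,
    courses: list[_Course],
    rates: dict[str, float],
    rng_miss: np.random.Generator,
) -> list[dict]:
    cols = mapping.columns(study, "episodes")
    out = []
    for k, course in enumerate(courses, start=1):
        if course.drug_class == "MTX":
            dose_value, dose_unit = f"{12.5 + 2.5 * (k % 3):.1f}", "mg/week"
        else:
            dose_value, dose_unit = "0.8", "mg/kg/week"
        values = {
            "drug_name": _encode(mapping, study, "drug_name", course.drug, rng_miss),
            "start_date": course.start.strftime(_ISO),
            "stop_date": course.stop.strftime(_ISO) if course.stop else "",
            "dose_value": _maybe_missing(dose_value, "dose_value", rates, rng_miss),
            "dose_unit": _maybe_missing(dose_unit, "dose_unit", rates, rng_miss),
        }
        if "route" in cols:
            encoded = _encode(mapping, study, "route", course.route or "", rng_miss)
            values["route"] = _maybe_missing(encoded, "route", rates, rng_miss)
        if "stop_reason" in cols:
            if course.stop_reason:
                encoded = _encode(mapping, study, "stop_reason", course.stop_reason, rng_miss)
                values["stop_reason"] = _maybe_missing(encoded, "stop_reason", rates, rng_miss)
            else:
                values["stop_reason"] = ""
        row = {cols["local_id"]: local_id, "record_id": f"{local_id}-R{k}"}
        for var, src_col in cols.items():
            if var == "local_id":
                continue
            row[src_col] = values[var]
        out.append(row)
    return out
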