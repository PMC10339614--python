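"""Time-point selection, duplicate resolution, and drug-cohort construction.

Each drug-specific dataset (MTX starters, TNFi starters) is built person
by person after linkage: among a person's candidate treatment records of
the drug class, one is retained by study precedence (records are kept or
dropped whole — never merged field by field); the retained record is then
screened against the inclusion criteria, and baseline (T1) and six-month
(T2) visits are extracted from the retained study's follow-up inside
fixed day windows.

Month arithmetic is fixed in days for reproducibility: 3 months = 91
days, 6 months = 183 days, 12 months = 365 days, windows inclusive at
both ends.  T1 is the latest visit in [-91, 0] days from drug start; T2
the visit in [+91, +365] closest to day 183, equidistant ties resolved
toward the earlier visit (earlier data are less affected by subsequent
treatment changes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .cdm import CdmTables
from .dialects import COVS

#: Default study precedence for duplicate resolution, highest first.
#: CHARMS was designed around treatment response and carries the lowest
#: core-variable missingness, so it outranks the others; the remainder
#: of the order is configurable.
DEFAULT_PRECEDENCE = ("CHARMS", "BSPAR-Et", "BCRD", "CAPS")

EXCLUSION_REASONS = (
    "no-index-episode",
    "no-JIA-ILAR",
    "not-treatment-naive",
    "stopped-before-3-months",
    "no-COV-data",
)


@dataclass(frozen=True)
class CohortConfig:
    precedence: tuple[str, ...] = DEFAULT_PRECEDENCE
    t1_window: tuple[int, int] = (-91, 0)
    t2_window: tuple[int, int] = (91, 365)
    t2_target_day: int = 183
    min_continuation_days: int = 91

    def __post_init__(self):
        for lower, upper in (self.t1_window, self.t2_window):
            if lower > upper:
                raise ValueError(f"window not well-ordered: ({lower}, {upper})")


@dataclass
class TimepointExtract:
    timepoint: str  # "T1" | "T2"
    window: tuple[int, int]
    selected_visit: pd.Series | None = None
    days_from_start: int | None = None

    @property
    def found(self) -> bool:
        return self.selected_visit is not None


@dataclass
class EligibilityResult:
    cluster_id: str
    drug_class: str
    exclusion_reasons: list[str] = field(default_factory=list)

    @property
    def eligible(self) -> bool:
        return not self.exclusion_reasons


@dataclass
class CohortDataset:
    """One drug-specific harmonised dataset plus its conservation ledger."""

    drug_class: str
    rows: pd.DataFrame
    removed: pd.DataFrame       # duplicate records dropped by precedence
    exclusions: pd.DataFrame    # one row per excluded person with reasons
    ledger: dict[str, int]

    @property
    def removed_duplicates(self) -> int:
        return len(self.removed)


def select_visit(
    visits: pd.DataFrame,
    drug_start,
    timepoint: str,
    config: CohortConfig = CohortConfig(),
) -> TimepointExtract:
    """Pick one visit for a time point, or none if no visit is in window.

    T1 takes the latest visit at or before drug start within the
    baseline window; T2 the visit closest to the six-month target, with
    equidistant pairs resolved toward the earlier visit.
    """
    if timepoint not in ("T1", "T2"):
        raise ValueError(f"unknown timepoint: {timepoint}")
    window = config.t1_window if timepoint == "T1" else config.t2_window
    extract = TimepointExtract(timepoint=timepoint, window=window)
    if visits is None or len(visits) == 0:
        return extract

    days = (pd.to_datetime(visits["visit_date"]) - pd.to_datetime(drug_start)).dt.days
    in_window = visits[(days >= window[0]) & (days <= window[1])].copy()
    if in_window.empty:
        return extract
    in_window["_days"] = days[in_window.index]
    if timepoint == "T1":
        # latest baseline visit == minimal (drug_start - visit_date)
        in_window = in_window.sort_values(
            by=["_days"], ascending=False, kind="mergesort"
        )
    else:
        in_window["_dist"] = (in_window["_days"] - config.t2_target_day).abs()
        in_window = in_window.sort_values(
            by=["_dist", "_days"], ascending=[True, True], kind="mergesort"
        )
    best = in_window.iloc[0]
    extract.days_from_start = int(best["_days"])
    extract.selected_visit = best.drop(labels=[c for c in ("_days", "_dist") if c in best.index])
    return extract


def resolve_duplicates(
    records: pd.DataFrame,
    precedence: tuple[str, ...] = DEFAULT_PRECEDENCE,
) -> tuple[pd.Series, pd.DataFrame]:
    """Retain exactly one of a person's candidate records for one drug class.

    The record whose source study ranks highest in ``precedence`` wins;
    two records from the same study fall back to fewer missing core
    outcome variables (``n_missing_covs`` column, when supplied), then
    earliest start date, then record ID.  No field-level merging across
    records ever occurs.
    """
    if records.empty:
        raise ValueError("no records to resolve")
    unknown = set(records["source_study"]) - set(precedence)
    if unknown:
        raise KeyError(f"studies missing from precedence order: {sorted(unknown)}")
    ranked = records.copy()
    ranked["_rank"] = ranked["source_study"].map(precedence.index)
    ranked["_nmiss"] = (
        ranked["n_missing_covs"] if "n_missing_covs" in ranked.columns else 0
    )
    ranked = ranked.sort_values(
        by=["_rank", "_nmiss", "start_date", "record_id"], kind="mergesort"
    )
    ranked = ranked.drop(columns=["_rank", "_nmiss"])
    retained = ranked.iloc[0]
    removed = ranked.iloc[1:].copy()
    if len(removed):
        removed["removal_reason"] = "duplicate-lower-precedence"
    return retained, removed


def apply_inclusion_criteria(
    patient: pd.Series | None,
    episodes: pd.DataFrame,
    visits: pd.DataFrame,
    drug_class: str,
    config: CohortConfig = CohortConfig(),
    index_episode: pd.Series | None = None,
) -> EligibilityResult:
    """Screen one linked person against the cohort entry criteria.

    Checks, accumulated rather than short-circuited: JIA classified by
    ILAR subtype; treatment-naïve (no same-class episode anywhere in the
    pooled linked data starting before the index episode — linkage
    exists precisely to reveal prior exposure recorded in another
    study); the index course continued at least 3 months (91 days); and
    at least one core outcome variable observed at the baseline extract.
    """
    cluster_id = ""
    if patient is not None and "cluster_id" in patient.index:
        cluster_id = str(patient["cluster_id"])
    result = EligibilityResult(cluster_id=cluster_id, drug_class=drug_class)

    if episodes is None or len(episodes) == 0 or "drug_class" not in episodes.columns:
        same_class = pd.DataFrame(columns=["start_date", "record_id"])
    else:
        same_class = episodes[episodes["drug_class"] == drug_class]
    if index_episode is None:
        if same_class.empty:
            result.exclusion_reasons.append("no-index-episode")
            return result
        index_episode = same_class.sort_values(
            by=["start_date", "record_id"], kind="mergesort"
        ).iloc[0]

    if patient is None or pd.isna(patient.get("ilar_subtype")):
        result.exclusion_reasons.append("no-JIA-ILAR")

    start = index_episode["start_date"]
    earlier = same_class[same_class["start_date"] < start]
    if len(earlier):
        result.exclusion_reasons.append("not-treatment-naive")

    stop = index_episode["stop_date"]
    if pd.notna(stop):
        if (stop - start).days < config.min_continuation_days:
            result.exclusion_reasons.append("stopped-before-3-months")

    t1 = select_visit(visits, start, "T1", config)
    if not t1.found or all(
        pd.isna(t1.selected_visit.get(cov)) for cov in COVS
    ):
        result.exclusion_reasons.append("no-COV-data")
    return result


def _cov_row(extract: TimepointExtract, prefix: str) -> dict:
    row = {f"{prefix}_date": pd.NaT, f"{prefix}_days": pd.NA}
    for cov in COVS:
        row[f"{prefix}_{cov}"] = pd.NA
    if extract.found:
        row[f"{prefix}_date"] = extract.selected_visit["visit_date"]
        row[f"{prefix}_days"] = extract.days_from_start
        for cov in COVS:
            row[f"{prefix}_{cov}"] = extract.selected_visit.get(cov, pd.NA)
    return row


_PATIENT_FIELDS = (
    "date_of_birth", "gender", "ethnicity", "ilar_subtype",
    "date_of_diagnosis", "date_of_symptom_onset",
    "ana", "rf", "hla_b27", "uveitis_ever",
)
_EPISODE_FIELDS = (
    "record_id", "drug_name", "start_date", "stop_date",
    "route", "dose_value", "dose_unit", "stop_reason",
)


def build_cohort(
    cdm: CdmTables,
    drug_class: str,
    config: CohortConfig = CohortConfig(),
) -> CohortDataset:
    """Index records → precedence resolution → inclusion screen → T1/T2 extracts.

    Candidate records are every pooled treatment record of ``drug_class``.
    The conservation ledger holds exactly:
    candidates = rows + removed duplicates + excluded persons.
    A person may legitimately appear in both the MTX and TNFi cohorts,
    having started the two treatments at different times.
    """
    episodes = cdm.episodes[cdm.episodes["drug_class"] == drug_class]
    visits_by_patient = dict(tuple(cdm.visits.groupby(["source_study", "local_id"], sort=False)))
    patients_indexed = cdm.patients.set_index(["source_study", "local_id"])

    rows: list[dict] = []
    removed_frames: list[pd.DataFrame] = []
    exclusion_rows: list[dict] = []

    for cluster_id, group in episodes.groupby("cluster_id", sort=True):
        group = group.copy()
        # per-record baseline completeness, for the same-study tie-break
        n_missing = []
        t1_cache: dict[str, TimepointExtract] = {}
        for _, rec in group.iterrows():
            visits = visits_by_patient.get(
                (rec["source_study"], rec["local_id"]), None
            )
            t1 = select_visit(visits, rec["start_date"], "T1", config)
            t1_cache[rec["record_id"]] = t1
            if t1.found:
                n_missing.append(
                    sum(pd.isna(t1.selected_visit.get(cov)) for cov in COVS)
                )
            else:
                n_missing.append(len(COVS))
        group["n_missing_covs"] = n_missing

        retained, removed = resolve_duplicates(group, config.precedence)
        if len(removed):
            removed_frames.append(
                removed[["cluster_id", "source_study", "local_id", "record_id",
                         "start_date", "removal_reason"]]
            )

        key = (retained["source_study"], retained["local_id"])
        patient = patients_indexed.loc[key]
        if isinstance(patient, pd.DataFrame):
            patient = patient.iloc[0]
        patient = patient.copy()
        patient["cluster_id"] = cluster_id
        visits = visits_by_patient.get(key, None)

        eligibility = apply_inclusion_criteria(
            patient, episodes[episodes["cluster_id"] == cluster_id],
            visits, drug_class, config, index_episode=retained,
        )
        if not eligibility.eligible:
            exclusion_rows.append(
                {
                    "cluster_id": cluster_id,
                    "source_study": retained["source_study"],
                    "exclusion_reasons": ";".join(eligibility.exclusion_reasons),
                }
            )
            continue

        row = {"cluster_id": cluster_id, "source_study": retained["source_study"],
               "local_id": retained["local_id"], "drug_class": drug_class}
        for var in _PATIENT_FIELDS:
            row[var] = patient.get(var, pd.NA)
        for var in _EPISODE_FIELDS:
            row[var] = retained.get(var, pd.NA)
        row.update(_cov_row(t1_cache[retained["record_id"]], "t1"))
        t2 = select_visit(visits, retained["start_date"], "T2", config)
        row.update(_cov_row(t2, "t2"))
        rows.append(row)

    rows_df = pd.DataFrame(rows)
    removed_df = (
        pd.concat(removed_frames, ignore_index=True)
        if removed_frames
        else pd.DataFrame(columns=["cluster_id", "source_study", "local_id",
                                   "record_id", "start_date", "removal_reason"])
    )
    exclusions_df = pd.DataFrame(
        exclusion_rows, columns=["cluster_id", "source_study", "exclusion_reasons"]
    )
    ledger = {
        "candidates": len(episodes),
        "rows": len(rows_df),
        "removed_duplicates": len(removed_df),
        "excluded": len(exclusions_df),
    }
    if ledger["candidates"] != ledger["rows"] + ledger["removed_duplicates"] + ledger["excluded"]:
        raise AssertionError(f"conservation ledger violated: {ledger}")
    if len(rows_df) and rows_df["cluster_id"].duplicated().any():
        raise AssertionError("person-level uniqueness violated")
    return CohortDataset(
        drug_class=drug_class,
        rows=rows_df,
        removed=removed_df,
        exclusions=exclusions_df,
        ledger=ledger,
    )
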