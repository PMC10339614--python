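"""Window selection, precedence resolution, inclusion screening, cohort build."""

from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import cohortforge as cf
from cohortforge.cohort import (
    CohortConfig,
    DEFAULT_PRECEDENCE,
    apply_inclusion_criteria,
    build_cohort,
    resolve_duplicates,
    select_visit,
)

START = pd.Timestamp("2015-06-01")


def visits_at(*day_offsets, **covs):
    rows = []
    for d in day_offsets:
        row = {"visit_date": START + pd.Timedelta(days=d), "ajc": 2.0,
               "ljc": 1.0, "chaq": 0.5, "esr": 20.0, "crp": 5.0,
               "pga": 3.0, "pge": 2.0, "pain_vas": 2.0}
        row.update(covs)
        rows.append(row)
    return pd.DataFrame(rows)


class TestSelectVisit:
    def test_t2_picks_closest_to_six_months(self):
        extract = select_visit(visits_at(100, 200), START, "T2")
        assert extract.days_from_start == 200  # |200-183| = 17 < |100-183| = 83

    def test_t2_outside_window_yields_none(self):
        extract = select_visit(visits_at(400), START, "T2")
        assert not extract.found
        assert extract.days_from_start is None

    def test_t2_equidistant_tie_breaks_to_earlier_visit(self):
        extract = select_visit(visits_at(170, 196), START, "T2")
        assert extract.days_from_start == 170  # both are 13 days from day 183

    def test_t1_takes_latest_baseline_visit(self):
        extract = select_visit(visits_at(-80, -10, -2), START, "T1")
        assert extract.days_from_start == -2
        assert select_visit(visits_at(5), START, "T1").found is False

    def test_window_bounds_inclusive(self):
        assert select_visit(visits_at(-91), START, "T1").days_from_start == -91
        assert select_visit(visits_at(0), START, "T1").days_from_start == 0
        assert select_visit(visits_at(91), START, "T2").days_from_start == 91
        assert select_visit(visits_at(365), START, "T2").days_from_start == 365

    def test_empty_visit_list(self):
        assert not select_visit(visits_at(), START, "T2").found
        assert not select_visit(None, START, "T1").found

    @given(st.lists(st.integers(-200, 500), min_size=1, max_size=12),
           st.sampled_from(["T1", "T2"]))
    def test_selected_visit_in_window_and_distance_minimal(self, offsets, timepoint):
        config = CohortConfig()
        extract = select_visit(visits_at(*offsets), START, timepoint, config)
        window = config.t1_window if timepoint == "T1" else config.t2_window
        in_window = [d for d in offsets if window[0] <= d <= window[1]]
        if not in_window:
            assert not extract.found
            return
        assert window[0] <= extract.days_from_start <= window[1]
        if timepoint == "T1":
            assert extract.days_from_start == max(in_window)
        else:
            target = config.t2_target_day
            best = min(abs(d - target) for d in in_window)
            assert abs(extract.days_from_start - target) == best
            # earlier-visit tie-break
            assert extract.days_from_start == min(
                d for d in in_window if abs(d - target) == best
            )


def episode_row(study, start="2015-06-01", stop=None, record_id="R1",
                n_missing=0, cluster="CL1", drug_class="MTX"):
    return {
        "cluster_id": cluster, "source_study": study, "local_id": f"{study}-P1",
        "record_id": record_id, "drug_class": drug_class, "drug_name": "methotrexate",
        "start_date": pd.Timestamp(start), "stop_date": pd.Timestamp(stop) if stop else pd.NaT,
        "n_missing_covs": n_missing,
    }


class TestResolveDuplicates:
    def test_charms_beats_caps(self):
        records = pd.DataFrame([episode_row("CHARMS"), episode_row("CAPS")])
        retained, removed = resolve_duplicates(records)
        assert retained["source_study"] == "CHARMS"
        assert list(removed["source_study"]) == ["CAPS"]
        assert (removed["removal_reason"] == "duplicate-lower-precedence").all()

    def test_bcrd_beats_caps_under_default_order(self):
        records = pd.DataFrame([episode_row("CAPS"), episode_row("BCRD")])
        retained, _ = resolve_duplicates(records)
        assert retained["source_study"] == "BCRD"

    def test_single_record_retained_unchanged(self):
        records = pd.DataFrame([episode_row("CAPS")])
        retained, removed = resolve_duplicates(records)
        assert retained["record_id"] == "R1"
        assert removed.empty

    def test_same_study_falls_back_to_completeness_then_start(self):
        records = pd.DataFrame([
            episode_row("CAPS", record_id="R1", n_missing=5, start="2015-01-01"),
            episode_row("CAPS", record_id="R2", n_missing=2, start="2015-06-01"),
        ])
        retained, _ = resolve_duplicates(records)
        assert retained["record_id"] == "R2"  # fewer missing COVs wins
        records = pd.DataFrame([
            episode_row("CAPS", record_id="R1", n_missing=2, start="2015-06-01"),
            episode_row("CAPS", record_id="R2", n_missing=2, start="2015-01-01"),
        ])
        retained, _ = resolve_duplicates(records)
        assert retained["record_id"] == "R2"  # then earliest start

    def test_retained_precedence_is_maximal(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            studies = list(rng.choice(DEFAULT_PRECEDENCE,
                                      size=rng.integers(1, 5), replace=False))
            records = pd.DataFrame(
                [episode_row(s, record_id=f"R{i}") for i, s in enumerate(studies)]
            )
            retained, removed = resolve_duplicates(records)
            best = min(DEFAULT_PRECEDENCE.index(s) for s in studies)
            assert DEFAULT_PRECEDENCE.index(retained["source_study"]) == best
            assert len(removed) == len(studies) - 1

    def test_unknown_study_in_precedence_is_error(self):
        records = pd.DataFrame([episode_row("CAPS")])
        with pytest.raises(KeyError):
            resolve_duplicates(records, precedence=("CHARMS",))


def patient_series(ilar="poly_rf_neg"):
    return pd.Series({"cluster_id": "CL1", "ilar_subtype": ilar})


class TestInclusionCriteria:
    def episodes(self, *rows):
        return pd.DataFrame(rows)

    def test_all_pass_case(self):
        result = apply_inclusion_criteria(
            patient_series(), self.episodes(episode_row("CHARMS")),
            visits_at(-10), "MTX",
        )
        assert result.eligible and result.exclusion_reasons == []

    def test_early_stop_excluded(self):
        result = apply_inclusion_criteria(
            patient_series(),
            self.episodes(episode_row("CHARMS", stop="2015-07-31")),  # +60 days
            visits_at(-10), "MTX",
        )
        assert result.exclusion_reasons == ["stopped-before-3-months"]

    def test_stop_at_exactly_91_days_retained(self):
        result = apply_inclusion_criteria(
            patient_series(),
            self.episodes(episode_row("CHARMS", stop="2015-08-31")),  # +91 days
            visits_at(-10), "MTX",
        )
        assert result.eligible

    def test_all_covs_missing_at_baseline_excluded(self):
        empty_covs = {c: np.nan for c in cf.COVS}
        result = apply_inclusion_criteria(
            patient_series(), self.episodes(episode_row("CHARMS")),
            visits_at(-10, **empty_covs), "MTX",
        )
        assert result.exclusion_reasons == ["no-COV-data"]

    def test_missing_ilar_excluded(self):
        result = apply_inclusion_criteria(
            patient_series(ilar=np.nan), self.episodes(episode_row("CHARMS")),
            visits_at(-10), "MTX",
        )
        assert result.exclusion_reasons == ["no-JIA-ILAR"]

    def test_prior_episode_in_another_study_breaks_naivety(self):
        episodes = self.episodes(
            episode_row("CHARMS", start="2015-06-01", record_id="R1"),
            episode_row("CAPS", start="2014-01-01", record_id="R2"),
        )
        index = episodes.iloc[0]
        result = apply_inclusion_criteria(
            patient_series(), episodes, visits_at(-10), "MTX", index_episode=index,
        )
        assert result.exclusion_reasons == ["not-treatment-naive"]

    def test_failures_accumulate_rather_than_short_circuit(self):
        empty_covs = {c: np.nan for c in cf.COVS}
        result = apply_inclusion_criteria(
            patient_series(ilar=np.nan),
            self.episodes(episode_row("CHARMS", stop="2015-07-01")),
            visits_at(-10, **empty_covs), "MTX",
        )
        assert set(result.exclusion_reasons) == {
            "no-JIA-ILAR", "stopped-before-3-months", "no-COV-data"
        }

    def test_no_index_episode(self):
        result = apply_inclusion_criteria(
            patient_series(), self.episodes(), visits_at(-10), "TNFi",
        )
        assert result.exclusion_reasons == ["no-index-episode"]


class TestBuildCohort:
    def test_ledger_conservation_and_uniqueness(self, small_cdm):
        cdm, clusters, truth = small_cdm
        for drug_class in ("MTX", "TNFi"):
            cohort = build_cohort(cdm, drug_class)
            ledger = cohort.ledger
            assert ledger["candidates"] == (
                ledger["rows"] + ledger["removed_duplicates"] + ledger["excluded"]
            )
            assert not cohort.rows["cluster_id"].duplicated().any()

    def test_removed_equal_planted_cross_record_duplicates(self, small_cdm):
        cdm, _, truth = small_cdm
        for drug_class in ("MTX", "TNFi"):
            cohort = build_cohort(cdm, drug_class)
            planted = sum(
                max(0, len(p.class_records(drug_class)) - 1) for p in truth.persons
            )
            assert cohort.removed_duplicates == planted

    def test_retained_study_is_precedence_maximal(self, small_cdm):
        cdm, _, truth = small_cdm
        cohort = build_cohort(cdm, "MTX")
        by_person = {p.local_ids.get(s): p for p in truth.persons for s in p.studies}
        for _, row in cohort.rows.iterrows():
            person = by_person[row["local_id"]]
            candidate_studies = {r.study for r in person.class_records("MTX")}
            best = min(DEFAULT_PRECEDENCE.index(s) for s in candidate_studies)
            assert DEFAULT_PRECEDENCE.index(row["source_study"]) == best

    def test_person_on_both_drugs_appears_in_both_cohorts(self, small_cdm):
        cdm, _, truth = small_cdm
        mtx = build_cohort(cdm, "MTX")
        tnfi = build_cohort(cdm, "TNFi")
        overlap = set(mtx.rows["cluster_id"]) & set(tnfi.rows["cluster_id"])
        both_classes = [
            p for p in truth.persons
            if p.class_records("MTX") and p.class_records("TNFi")
        ]
        assert both_classes  # the fixture plants dual-treatment persons
        assert overlap  # and some survive both screens

    def test_empty_input_empty_cohort(self, small_cdm):
        cdm, _, _ = small_cdm
        empty = cf.CdmTables(
            patients=cdm.patients.iloc[0:0],
            visits=cdm.visits.iloc[0:0],
            episodes=cdm.episodes.iloc[0:0],
        )
        cohort = build_cohort(empty, "MTX")
        assert len(cohort.rows) == 0 and cohort.removed_duplicates == 0
        assert cohort.ledger["candidates"] == 0

    def test_widening_t2_window_never_shrinks_cohort(self, small_cdm):
        cdm, _, _ = small_cdm
        narrow = build_cohort(cdm, "MTX", CohortConfig(t2_window=(121, 245)))
        wide = build_cohort(cdm, "MTX", CohortConfig(t2_window=(91, 365)))
        assert len(wide.rows) >= len(narrow.rows)
        # and the wide run finds at least as many T2 visits
        assert wide.rows["t2_date"].notna().sum() >= narrow.rows["t2_date"].notna().sum()

    def test_selected_visits_lie_in_windows(self, small_cdm):
        cdm, _, _ = small_cdm
        cohort = build_cohort(cdm, "MTX")
        t1 = cohort.rows["t1_days"].dropna().astype(int)
        assert ((t1 >= -91) & (t1 <= 0)).all()
        t2 = cohort.rows["t2_days"].dropna().astype(int)
        assert ((t2 >= 91) & (t2 <= 365)).all()
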