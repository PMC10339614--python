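"""JADAS, ACR Pedi, missingness and characteristics reports."""

import itertools

import numpy as np
import pandas as pd
import pytest

import cohortforge as cf
from cohortforge.cohort import CohortDataset
from cohortforge.dialects import ACR_CORE
from cohortforge.outcomes import (
    acr_pedi,
    characteristics_table,
    jadas,
    missingness_report,
)


class TestJadas:
    @pytest.mark.parametrize(
        "pga,pge,ajc,esr,variant,expected",
        [
            (0, 0, 0, 10, "JADAS-71", 0.0),            # floor: ESR term clamps at 0
            (3.5, 2.0, 5, 40, "JADAS-71", 12.5),        # 3.5 + 2 + 5 + (40-20)/10
            (10, 10, 30, 200, "JADAS-10", 40.0),        # joint cap and ESR clamp active
            (10, 10, 30, 200, "JADAS-27", 57.0),    # 10 + 10 + min(30, 27) + 10
            (10, 10, 71, 200, "JADAS-71", 101.0),       # ceiling of the 71-joint form
            (2, 2, 15, 25, "JADAS-10", 14.5),
        ],
    )
    def test_worked_examples(self, pga, pge, ajc, esr, variant, expected):
        score = jadas(pga, pge, ajc, esr, variant)
        assert score.value == pytest.approx(expected)
        assert score.value == pytest.approx(sum(score.components))

    def test_missing_components_incomputable_and_named(self):
        score = jadas(None, 2.0, np.nan, 30)
        assert not score.computable
        assert score.missing == ("pga", "ajc")
        assert score.value is None

    def test_out_of_range_inputs_rejected(self):
        with pytest.raises(ValueError):
            jadas(11, 0, 0, 0)
        with pytest.raises(ValueError):
            jadas(0, 0, 72, 0)
        with pytest.raises(ValueError):
            jadas(0, 0, 0, -1)
        with pytest.raises(ValueError):
            jadas(0, 0, 0, 0, variant="JADAS-99")

    def test_matches_bruteforce_on_random_valid_inputs(self):
        """1000 random inputs against an independently written arithmetic
        oracle, including boundary draws that activate cap and clamp."""
        rng = np.random.default_rng(11)
        caps = {"JADAS-10": (10, 40.0), "JADAS-27": (27, 57.0), "JADAS-71": (71, 101.0)}
        for _ in range(1000):
            pga = round(float(rng.uniform(0, 10)), 1)
            pge = round(float(rng.uniform(0, 10)), 1)
            ajc = int(rng.integers(0, 72))
            esr = float(rng.choice([0, 10, 20, rng.uniform(0, 250)]))
            variant = str(rng.choice(list(caps)))
            cap, vmax = caps[variant]
            esr_term = (esr - 20.0) / 10.0
            esr_term = 0.0 if esr_term < 0 else (10.0 if esr_term > 10 else esr_term)
            expected = pga + pge + (ajc if ajc < cap else cap) + esr_term
            score = jadas(pga, pge, ajc, esr, variant)
            assert score.value == pytest.approx(expected)
            assert 0.0 <= score.value <= vmax


def truth_table_oracle(changes, level):
    """Direct transcription of the response rule, for cross-checking."""
    improved = sum(1 for c in changes if c <= -level)
    worsened = sum(1 for c in changes if c > 30)
    return improved >= 3 and worsened <= 1


class TestAcrPedi:
    def apply(self, changes, level):
        baseline = {v: 10.0 for v in ACR_CORE}
        followup = {v: 10.0 * (1 + c / 100.0) for v, c in zip(ACR_CORE, changes)}
        return acr_pedi(baseline, followup, level)

    def test_no_change_is_non_response(self):
        result = self.apply([0] * 6, 30)
        assert result.responder is False and result.n_improved == 0

    def test_uniform_fifty_percent_improvement(self):
        for level, expected in [(30, True), (50, True), (70, False)]:
            assert self.apply([-50] * 6, level).responder is expected

    def test_two_worsened_vetoes_response(self):
        result = self.apply([-40, -40, -40, 40, 40, 0], 30)
        assert result.n_improved == 3 and result.n_worsened == 2
        assert result.responder is False

    def test_zero_baseline_rule(self):
        baseline = {v: 10.0 for v in ACR_CORE}
        followup = {v: 3.0 for v in ACR_CORE}  # -70% on five variables
        baseline["ajc"] = 0.0
        followup["ajc"] = 1.0  # flare from zero counts as worsening
        result = acr_pedi(baseline, followup, 30)
        assert result.n_worsened == 1 and result.responder is True
        followup["ajc"] = 0.0  # staying at zero is neither improvement nor worsening
        result = acr_pedi(baseline, followup, 30)
        assert result.n_improved == 5 and result.n_worsened == 0

    def test_missing_variable_incomputable_with_named_gaps(self):
        baseline = {v: 10.0 for v in ACR_CORE}
        followup = {v: 5.0 for v in ACR_CORE}
        del followup["chaq"]
        baseline["esr"] = np.nan
        result = acr_pedi(baseline, followup, 30)
        assert not result.computable
        assert set(result.missing) == {"chaq", "esr"}

    def test_exhaustive_truth_table_over_change_grid(self):
        """Responder status is symmetric in the six variables, so the grid
        {-50, -31, -30, 0, +30, +31, +50} is covered exhaustively by
        multisets; explicit permutations are spot-checked separately."""
        grid = (-50, -31, -30, 0, 30, 31, 50)
        for level in (30, 50, 70):
            for changes in itertools.combinations_with_replacement(grid, 6):
                result = self.apply(list(changes), level)
                assert result.responder == truth_table_oracle(changes, level), (
                    changes, level
                )

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        changes = [-50, -31, 0, 30, 31, 50]
        reference = self.apply(changes, 30).responder
        for _ in range(10):
            perm = list(rng.permutation(changes))
            assert self.apply(perm, 30).responder == reference


def make_cohort(rows: pd.DataFrame, drug_class="MTX") -> CohortDataset:
    return CohortDataset(
        drug_class=drug_class, rows=rows,
        removed=pd.DataFrame(), exclusions=pd.DataFrame(),
        ledger={},
    )


class TestMissingnessReport:
    def test_charms_only_cohort_pain_vas_fully_structurally_missing(self):
        rows = pd.DataFrame({
            "source_study": ["CHARMS"] * 8,
            "t1_pain_vas": [np.nan] * 8,
            "t1_esr": [20.0, np.nan] * 4,
        })
        report = missingness_report(make_cohort(rows), variables=("pain_vas", "esr"),
                                    timepoints=("t1",))
        pain = report[report["variable"] == "pain_vas"].iloc[0]
        assert pain["pct_missing"] == 100.0
        assert pain["pct_structural"] == 100.0
        esr = report[report["variable"] == "esr"].iloc[0]
        assert esr["pct_missing"] == 50.0
        assert esr["pct_structural"] == 0.0

    def test_empty_cohort_flagged_undefined(self):
        report = missingness_report(make_cohort(pd.DataFrame()), timepoints=("t1",))
        assert report["undefined"].all()
        assert report["pct_missing"].isna().all()

    def test_invariant_to_row_order(self):
        rng = np.random.default_rng(0)
        rows = pd.DataFrame({
            "source_study": ["CAPS"] * 50,
            "t1_esr": [np.nan if rng.random() < 0.3 else 20.0 for _ in range(50)],
        })
        a = missingness_report(make_cohort(rows), variables=("esr",), timepoints=("t1",))
        shuffled = rows.sample(frac=1, random_state=1).reset_index(drop=True)
        b = missingness_report(make_cohort(shuffled), variables=("esr",), timepoints=("t1",))
        assert a.equals(b)


class TestCharacteristics:
    def test_hand_counted_gender_block(self):
        rows = pd.DataFrame({
            "source_study": ["CAPS"] * 10,
            "gender": ["female"] * 7 + ["male"] * 2 + [pd.NA],
            "ethnicity": ["Caucasian"] * 10,
            "ilar_subtype": ["systemic"] * 10,
            "uveitis_ever": ["no"] * 10,
            "date_of_birth": [pd.Timestamp("2005-01-01")] * 10,
            "date_of_symptom_onset": [pd.Timestamp("2012-01-01")] * 10,
            "t1_ajc": [4.0] * 10,
            "t1_ljc": [2.0] * 10,
        })
        table = characteristics_table(make_cohort(rows))
        female = table[(table["block"] == "gender") & (table["category"] == "female")].iloc[0]
        assert female["n"] == 7 and female["pct"] == 70.0
        gender_block = table[table["block"] == "gender"]
        assert gender_block["n"].sum() == 10  # categories partition the cohort
        onset = table[table["block"] == "age_at_onset_years"].iloc[0]
        assert onset["mean"] == pytest.approx(7.0, abs=0.1)

    def test_empty_cohort_all_zero(self):
        table = characteristics_table(make_cohort(pd.DataFrame()))
        assert table.iloc[0]["n"] == 0 and len(table) == 1

    def test_categorical_blocks_sum_to_cohort_n(self, small_cdm):
        cdm, _, _ = small_cdm
        cohort = cf.build_cohort(cdm, "MTX")
        table = characteristics_table(cohort)
        n = len(cohort.rows)
        for block in ("gender", "ethnicity", "ilar_subtype", "uveitis"):
            assert table[table["block"] == block]["n"].sum() == n, block
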