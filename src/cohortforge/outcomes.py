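"""Disease-activity scores and cohort reports.

The common data model exists to support the agreed JIA core outcome
variables, from which the standard composite measures derive:

* JADAS — the Juvenile Arthritis Disease Activity Score: physician
  global (0-10) + patient/parent global (0-10) + active joint count
  truncated at 10/27/71 by variant + an ESR term (ESR - 20)/10 clamped
  to [0, 10].  Ranges: 0-40 (JADAS-10), 0-57 (JADAS-27), 0-101
  (JADAS-71).  Only the ESR form is implemented.
* ACR Pedi 30/50/70 — response if at least 3 of the 6 core variables
  (PGA, PGE, CHAQ, AJC, LJC, ESR) improve by >= 30/50/70% with more than
  30% worsening in at most 1.

Scores are computed for complete cases only: a missing component yields
an explicitly incomputable result naming its gaps, never a silently
imputed number.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cdm import CdmTables  # noqa: F401  (type reference in docstrings)
from .cohort import CohortDataset
from .dialects import ACR_CORE, COVS, MappingConfig

_JADAS_CAPS = {"JADAS-10": 10, "JADAS-27": 27, "JADAS-71": 71}
_JADAS_MAX = {"JADAS-10": 40.0, "JADAS-27": 57.0, "JADAS-71": 101.0}


@dataclass
class JadasScore:
    variant: str
    value: float | None
    components: tuple[float, float, float, float] | None  # (pga, pge, ajc term, esr term)
    missing: tuple[str, ...] = ()

    @property
    def computable(self) -> bool:
        return self.value is not None


def jadas(pga, pge, ajc, esr, variant: str = "JADAS-71") -> JadasScore:
    """JADAS = PGA + PGE + min(AJC, cap) + clamp((ESR - 20)/10, 0, 10)."""
    if variant not in _JADAS_CAPS:
        raise ValueError(f"unknown variant: {variant}")
    missing = tuple(
        name for name, v in (("pga", pga), ("pge", pge), ("ajc", ajc), ("esr", esr))
        if v is None or pd.isna(v)
    )
    if missing:
        return JadasScore(variant=variant, value=None, components=None, missing=missing)
    pga, pge, ajc, esr = float(pga), float(pge), float(ajc), float(esr)
    if not 0 <= pga <= 10 or not 0 <= pge <= 10:
        raise ValueError("global assessments must lie in [0, 10]")
    if not 0 <= ajc <= 71:
        raise ValueError("active joint count must lie in [0, 71]")
    if esr < 0:
        raise ValueError("ESR must be non-negative")
    ajc_term = min(ajc, _JADAS_CAPS[variant])
    esr_term = float(np.clip((esr - 20.0) / 10.0, 0.0, 10.0))
    value = pga + pge + ajc_term + esr_term
    return JadasScore(
        variant=variant,
        value=value,
        components=(pga, pge, ajc_term, esr_term),
    )


@dataclass
class AcrPediResult:
    level: int
    responder: bool | None
    n_improved: int | None
    n_worsened: int | None
    missing: tuple[str, ...] = ()

    @property
    def computable(self) -> bool:
        return self.responder is not None


def acr_pedi(baseline: dict, followup: dict, level: int = 30) -> AcrPediResult:
    """ACR Pedi responder status over the six core outcome variables.

    Per-variable percent change is 100 x (followup - baseline)/baseline;
    a zero baseline admits no improvement, and counts as worsening iff
    the follow-up value is positive.  Responder iff >= 3 variables
    improved by at least ``level`` percent and at most 1 worsened by
    more than 30 percent.
    """
    if level not in (30, 50, 70):
        raise ValueError(f"level must be 30, 50 or 70, got {level}")
    missing = tuple(
        var for var in ACR_CORE
        if var not in baseline or pd.isna(baseline[var])
        or var not in followup or pd.isna(followup[var])
    )
    if missing:
        return AcrPediResult(level=level, responder=None,
                             n_improved=None, n_worsened=None, missing=missing)
    n_improved = n_worsened = 0
    for var in ACR_CORE:
        b, f = float(baseline[var]), float(followup[var])
        if b == 0.0:
            if f > 0.0:
                n_worsened += 1
            continue
        change = 100.0 * (f - b) / b
        if change <= -level:
            n_improved += 1
        if change > 30.0:
            n_worsened += 1
    responder = n_improved >= 3 and n_worsened <= 1
    return AcrPediResult(level=level, responder=responder,
                         n_improved=n_improved, n_worsened=n_worsened)


# --------------------------------------------------------------------------
# reports
# --------------------------------------------------------------------------


def missingness_report(
    cohort: CohortDataset,
    variables: tuple[str, ...] = COVS,
    timepoints: tuple[str, ...] = ("t1", "t2"),
    mapping: MappingConfig | None = None,
) -> pd.DataFrame:
    """Percentage missing per (variable, timepoint) over the cohort rows.

    The denominator is the cohort size.  Missingness decomposes into a
    structural part — rows retained from a study that never collected
    the variable — and the remainder (not recorded, or no visit fell in
    the window).  An empty cohort yields rows flagged undefined.
    """
    mapping = mapping or MappingConfig.default()
    rows = []
    n = len(cohort.rows)
    for timepoint in timepoints:
        for var in variables:
            col = f"{timepoint}_{var}"
            if n == 0:
                rows.append({
                    "variable": var, "timepoint": timepoint.upper(), "n": 0,
                    "n_missing": 0, "pct_missing": np.nan,
                    "n_structural": 0, "pct_structural": np.nan,
                    "undefined": True,
                })
                continue
            series = cohort.rows[col] if col in cohort.rows.columns else pd.Series(
                [pd.NA] * n, index=cohort.rows.index
            )
            is_missing = series.isna()
            structural_mask = cohort.rows["source_study"].map(
                lambda s: var in mapping.unavailable_vars(s)
            )
            n_missing = int(is_missing.sum())
            n_structural = int((is_missing & structural_mask).sum())
            rows.append({
                "variable": var, "timepoint": timepoint.upper(), "n": n,
                "n_missing": n_missing,
                "pct_missing": round(100.0 * n_missing / n, 1),
                "n_structural": n_structural,
                "pct_structural": round(100.0 * n_structural / n, 1),
                "undefined": False,
            })
    return pd.DataFrame(rows)


def _n_pct_block(series: pd.Series, block: str, categories: list[str],
                 n_total: int) -> list[dict]:
    out = []
    filled = series.fillna("missing") if series.dtype == object else series.astype(object).fillna("missing")
    for cat in categories + ["missing"]:
        count = int((filled == cat).sum())
        pct = round(100.0 * count / n_total, 1) if n_total else 0.0
        out.append({"block": block, "category": cat, "statistic": "n_pct",
                    "n": count, "pct": pct, "mean": np.nan, "sd": np.nan})
    return out


def _mean_sd_row(series: pd.Series, block: str) -> dict:
    values = pd.to_numeric(series, errors="coerce").dropna()
    return {
        "block": block, "category": "", "statistic": "mean_sd",
        "n": int(len(values)), "pct": np.nan,
        "mean": round(float(values.mean()), 1) if len(values) else np.nan,
        "sd": round(float(values.std(ddof=1)), 1) if len(values) > 1 else np.nan,
    }


def characteristics_table(cohort: CohortDataset) -> pd.DataFrame:
    """Key clinical characteristics: N (%) blocks and mean (SD) rows.

    Mirrors the layout of a registry characteristics table: gender,
    ethnicity, ILAR subtype and uveitis as counts with percentages of
    the cohort (missing as its own category), and age at symptom onset,
    baseline active and limited joint counts as mean (SD) over the
    non-missing values.
    """
    df = cohort.rows
    n = len(df)
    records: list[dict] = [{
        "block": "total", "category": "N", "statistic": "count",
        "n": n, "pct": np.nan, "mean": np.nan, "sd": np.nan,
    }]
    if n == 0:
        return pd.DataFrame(records)

    from .dialects import ILAR_SUBTYPES

    records += _n_pct_block(df["gender"], "gender", ["male", "female"], n)
    records += _n_pct_block(df["ethnicity"], "ethnicity",
                            ["Caucasian", "Non-Caucasian"], n)
    records += _n_pct_block(df["ilar_subtype"], "ilar_subtype",
                            list(ILAR_SUBTYPES), n)
    records += _n_pct_block(df["uveitis_ever"], "uveitis", ["yes", "no"], n)

    age_years = (
        pd.to_datetime(df["date_of_symptom_onset"]) - pd.to_datetime(df["date_of_birth"])
    ).dt.days / 365.25
    records.append(_mean_sd_row(age_years, "age_at_onset_years"))
    records.append(_mean_sd_row(df["t1_ajc"], "ajc_baseline"))
    records.append(_mean_sd_row(df["t1_ljc"], "ljc_baseline"))
    return pd.DataFrame(records)


def plot_missingness(report: pd.DataFrame, path) -> None:
    """Grouped bar chart of percentage missingness by variable and timepoint."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pivot = report.pivot(index="variable", columns="timepoint", values="pct_missing")
    ax = pivot.plot.bar(figsize=(9, 4.5), rot=45)
    ax.set_ylabel("% missing")
    ax.set_ylim(0, 100)
    ax.figure.tight_layout()
    ax.figure.savefig(path, dpi=150)
    plt.close(ax.figure)
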