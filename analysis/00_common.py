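"""Shared paths and run constants for the numbered analysis drivers.

Large intermediates (full study extracts, pooled CDM tables, per-person
cohort rows) live under ``scratch/``; the small summary tables each step
reports land under ``results/``.
"""

from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"

SEED = 20230713
SALT = b"cluster-analysis-salt"

EXTRACT_DIR = SCRATCH / "extracts"
LINKAGE_DIR = SCRATCH / "linkage"
CDM_DIR = SCRATCH / "cdm"
COHORT_DIR = SCRATCH / "cohorts"
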