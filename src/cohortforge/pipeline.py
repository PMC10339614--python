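"""Top-level pipeline: generate → link → harmonise → build cohorts → report.

A single :class:`RunConfig` drives an end-to-end run; every source of
randomness flows from its one seed, and every output file lands in the
run manifest with a SHA-256 hash and row count, so identical
(config, seed) pairs produce byte-identical artefacts and rerunning is a
hash comparison.
"""

from __future__ import annotations

import traceback
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, Field, field_validator

from . import io
from .cdm import attach_cluster_ids, map_to_cdm, pool_records
from .cohort import DEFAULT_PRECEDENCE, CohortConfig, build_cohort
from .dialects import MappingConfig, STUDIES
from .outcomes import characteristics_table, missingness_report, plot_missingness
from .pseudolink import assign_cluster_ids, cluster_map, summarise_duplication
from .synthetic import GeneratorConfig, generate_cohort


class RunConfig(BaseModel):
    """Validated configuration for one pipeline run."""

    outdir: str
    salt_file: str
    seed: int = 0
    generator: Optional[GeneratorConfig] = None
    input_dir: Optional[str] = None  # pre-existing extracts when no generator
    mapping_file: Optional[str] = None
    precedence: tuple[str, ...] = DEFAULT_PRECEDENCE
    t1_window: tuple[int, int] = (-91, 0)
    t2_window: tuple[int, int] = (91, 365)
    t2_target_day: int = Field(default=183, gt=0)
    make_plots: bool = False
    log_level: str = "INFO"

    @field_validator("t1_window", "t2_window")
    @classmethod
    def _ordered(cls, window):
        if window[0] > window[1]:
            raise ValueError(f"window not well-ordered: {window}")
        return window

    @field_validator("precedence")
    @classmethod
    def _full_precedence(cls, order):
        if set(order) != set(STUDIES):
            raise ValueError(f"precedence must rank all of {STUDIES}")
        return order

    def validate_paths(self) -> None:
        """All referenced input paths must exist before any stage runs."""
        if not Path(self.salt_file).exists():
            raise FileNotFoundError(f"salt file not found: {self.salt_file}")
        if self.mapping_file and not Path(self.mapping_file).exists():
            raise FileNotFoundError(f"mapping file not found: {self.mapping_file}")
        if self.generator is None:
            if not self.input_dir:
                raise ValueError("either a generator config or input_dir is required")
            if not Path(self.input_dir).exists():
                raise FileNotFoundError(f"input_dir not found: {self.input_dir}")

    def cohort_config(self) -> CohortConfig:
        return CohortConfig(
            precedence=tuple(self.precedence),
            t1_window=tuple(self.t1_window),
            t2_window=tuple(self.t2_window),
            t2_target_day=self.t2_target_day,
        )


def linkage_records(extracts: dict[str, dict[str, pd.DataFrame]]) -> pd.DataFrame:
    """One linkage record per treatment record, carrying the stored identifier."""
    mapping = MappingConfig.default()
    rows = []
    for study in STUDIES:
        pcols = mapping.columns(study, "patients")
        ecols = mapping.columns(study, "episodes")
        patients = extracts[study]["patients"]
        identifier = dict(
            zip(patients[pcols["local_id"]], patients[pcols["nhs_number"]])
        )
        episodes = extracts[study]["episodes"]
        for local_id, record_id in zip(
            episodes[ecols["local_id"]], episodes["record_id"]
        ):
            rows.append({
                "source_study": study,
                "local_id": str(local_id),
                "record_id": str(record_id),
                "identifier": identifier.get(str(local_id), ""),
            })
    return pd.DataFrame(rows, columns=["source_study", "local_id", "record_id", "identifier"])


def _manifest_entry(path: Path, n_rows: int | None = None) -> dict:
    entry = {"sha256": io.sha256_file(path)}
    if n_rows is not None:
        entry["rows"] = n_rows
    return entry


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; return the artefact manifest.

    Any stage failure leaves the partial outputs in place alongside a
    ``FAILED`` marker naming the stage, and re-raises.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "files": {}, "counts": {}}
    stage = "validate"
    try:
        config.validate_paths()
        salt = io.read_salt(config.salt_file)
        mapping = (
            MappingConfig.from_yaml(config.mapping_file)
            if config.mapping_file
            else MappingConfig.default()
        )
        manifest["config"] = config.model_dump(mode="json")

        stage = "generate"
        if config.generator is not None:
            gen_config = config.generator.model_copy(update={"seed": config.seed})
            extracts, truth = generate_cohort(gen_config, mapping)
            gen_dir = outdir / "generated"
            for path in io.write_extracts(extracts, gen_dir):
                manifest["files"][str(path.relative_to(outdir))] = _manifest_entry(path)
            truth_path = gen_dir / "planted_truth.json"
            truth_path.write_text(truth.to_json(), encoding="utf-8")
            manifest["files"]["generated/planted_truth.json"] = _manifest_entry(truth_path)
            echo = io.write_yaml(gen_config.model_dump(mode="json"), gen_dir / "config_echo.yaml")
            manifest["files"]["generated/config_echo.yaml"] = _manifest_entry(echo)
        else:
            extracts, sidecars = io.read_extracts(config.input_dir, mapping)
            for stem, sidecar in sidecars.items():
                path = io.write_csv(sidecar, outdir / "errors" / f"{stem}_errors.csv")
                manifest["files"][str(path.relative_to(outdir))] = _manifest_entry(
                    path, len(sidecar)
                )

        stage = "link"
        records = linkage_records(extracts)
        clusters, rejected = assign_cluster_ids(records, salt)
        summary = summarise_duplication(clusters)
        lookup = cluster_map(clusters)
        path = io.write_csv(lookup, outdir / "linkage" / "clusters.csv")
        manifest["files"]["linkage/clusters.csv"] = _manifest_entry(path, len(lookup))
        path = io.write_csv(rejected, outdir / "linkage" / "rejected.csv")
        manifest["files"]["linkage/rejected.csv"] = _manifest_entry(path, len(rejected))
        path = io.write_json(summary.as_dict(), outdir / "linkage" / "duplication_summary.json")
        manifest["files"]["linkage/duplication_summary.json"] = _manifest_entry(path)
        manifest["counts"]["linkage"] = summary.as_dict()

        stage = "harmonise"
        cdm = pool_records([map_to_cdm(extracts[s], s, mapping) for s in STUDIES])
        cdm = attach_cluster_ids(cdm, lookup)
        # pseudonymised outputs: cluster ID in place of the identifier
        cdm.patients = cdm.patients.drop(columns=["nhs_number"])
        for table in ("patients", "visits", "episodes"):
            df = getattr(cdm, table)
            path = io.write_csv(df, outdir / "cdm" / f"cdm_{table}.csv")
            manifest["files"][f"cdm/cdm_{table}.csv"] = _manifest_entry(path, len(df))
            manifest["counts"][f"cdm_{table}"] = len(df)

        stage = "build-cohort"
        cohorts = {}
        for drug_class, slug in (("MTX", "mtx"), ("TNFi", "tnfi")):
            cohort = build_cohort(cdm, drug_class, config.cohort_config())
            cohorts[slug] = cohort
            for name, df in (
                (f"cohort_{slug}", cohort.rows),
                (f"removed_{slug}", cohort.removed),
                (f"exclusions_{slug}", cohort.exclusions),
            ):
                path = io.write_csv(df, outdir / "cohorts" / f"{name}.csv")
                manifest["files"][f"cohorts/{name}.csv"] = _manifest_entry(path, len(df))
            manifest["counts"][f"cohort_{slug}"] = cohort.ledger

        stage = "report"
        for slug, cohort in cohorts.items():
            report = missingness_report(cohort, mapping=mapping)
            path = io.write_csv(report, outdir / "reports" / f"missingness_{slug}.csv")
            manifest["files"][f"reports/missingness_{slug}.csv"] = _manifest_entry(path, len(report))
            chars = characteristics_table(cohort)
            path = io.write_csv(chars, outdir / "reports" / f"characteristics_{slug}.csv")
            manifest["files"][f"reports/characteristics_{slug}.csv"] = _manifest_entry(path, len(chars))
            if config.make_plots:
                plot_missingness(report, outdir / "reports" / f"missingness_{slug}.png")

        stage = "manifest"
        io.write_json(manifest, outdir / "manifest.json")
        return manifest
    except Exception:
        (outdir / "FAILED").write_text(
            f"stage: {stage}\n{traceback.format_exc()}", encoding="utf-8"
        )
        raise
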