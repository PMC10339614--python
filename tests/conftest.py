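"""Shared fixtures: small synthetic cohorts reused across the suite."""

from __future__ import annotations

import pytest
from hypothesis import settings

import cohortforge as cf

settings.register_profile("suite", derandomize=True, max_examples=60)
settings.load_profile("suite")

SALT = b"test-salt"


def make_config(
    seed: int = 0,
    *,
    corruption: float = 0.0,
    id_missing: float = 0.0,
    extra: int = 3,
    **overrides,
) -> cf.GeneratorConfig:
    """A 60-person four-study cohort with planted overlap."""
    return cf.GeneratorConfig(
        mode="exact_count",
        n_individuals=60,
        membership=[
            {"count": 40, "n_studies": 1},
            {"count": 5, "n_studies": 1, "records": 2},
            {"count": 12, "n_studies": 2},
            {"count": 2, "n_studies": 3},
            {"count": 1, "n_studies": 4},
        ],
        extra_duplicate_records=extra,
        identifier_corruption_rate=corruption,
        identifier_missing_rate=id_missing,
        seed=seed,
        **overrides,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Uncorrupted 60-person fixture: (extracts, truth)."""
    return cf.generate_cohort(make_config(seed=3))


@pytest.fixture(scope="session")
def corrupted_cohort():
    """Fixture with mistyped and missing identifiers planted."""
    return cf.generate_cohort(make_config(seed=5, corruption=0.10, id_missing=0.05))


@pytest.fixture(scope="session")
def small_cdm(small_cohort):
    """The small fixture linked and pooled into the CDM."""
    from cohortforge.cdm import attach_cluster_ids, map_to_cdm, pool_records
    from cohortforge.pipeline import linkage_records
    from cohortforge.pseudolink import assign_cluster_ids, cluster_map

    extracts, truth = small_cohort
    clusters, _ = assign_cluster_ids(linkage_records(extracts), SALT)
    cdm = pool_records([map_to_cdm(extracts[s], s) for s in cf.STUDIES])
    cdm = attach_cluster_ids(cdm, cluster_map(clusters))
    return cdm, clusters, truth
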