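from types import SimpleNamespace

import numpy as np
import pytest

from datspect import (
    CohortConfig,
    build_template,
    define_vois,
    extract_striatum_mask,
    generate_cohort,
    voi_means_table,
)
from datspect.preprocess import standardize_to_reference


@pytest.fixture(scope="session")
def default_cohort():
    """The default three-group cohort (30 NMNC / 30 NMC / 18 PD, seed 42)."""
    return generate_cohort(CohortConfig(seed=42))


@pytest.fixture(scope="session")
def default_run(default_cohort):
    """Standardized scans, template, mask, VOIs and VOI means for seed 42."""
    cohort = default_cohort
    std = [standardize_to_reference(s.volume, cohort.reference_mask) for s in cohort.subjects]
    groups = cohort.manifest["group"]
    control = [s for s, g in zip(std, groups) if g == "NMNC"]
    template = extract_striatum_mask(build_template(control))
    vois = define_vois(std, template.striatum_mask, seed=42)
    means = voi_means_table(std, vois, list(cohort.manifest["subject_id"]))
    return SimpleNamespace(
        cohort=cohort,
        std=std,
        groups=groups,
        ages=cohort.manifest["age"].astype(float),
        template=template,
        vois=vois,
        means=means,
    )


@pytest.fixture
def small_config():
    """Desk-scale cohort for fast unit tests."""
    return CohortConfig(
        n_per_group={"PD": 4, "NMC": 5, "NMNC": 6},
        grid_shape=(32, 32, 24),
        seed=7,
    )
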