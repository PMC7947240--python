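import logging

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import brainmkl as bm

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

# fold-level selection warnings are expected on synthetic desk-scale cohorts
logging.getLogger("brainmkl").setLevel(logging.ERROR)


def make_planted_dataset(seed: int, **kw) -> tuple[bm.FeatureDataset, bm.CohortSpec]:
    spec = bm.planted_study_spec(seed, **kw)
    cohort = bm.generate_cohort(spec)
    return bm.build_feature_dataset(cohort), spec


@pytest.fixture(scope="session")
def planted_dataset() -> tuple[bm.FeatureDataset, bm.CohortSpec]:
    """30+30 subjects, 30 regions, 10 disjoint planted edges per modality at
    d=2.0 — the package's desk-scale study conditions."""
    return make_planted_dataset(7)


@pytest.fixture(scope="session")
def small_planted_dataset() -> tuple[bm.FeatureDataset, bm.CohortSpec]:
    """A faster 12+12-subject, 15-region variant for pipeline mechanics."""
    return make_planted_dataset(3, n_regions=15, n_per_group=12, n_effect_edges=5)


@pytest.fixture(scope="session")
def null_dataset() -> bm.FeatureDataset:
    """Zero-effect cohort: no edge differs between the groups."""
    spec = bm.CohortSpec(
        group_sizes={"control": 30, "patient": 30}, n_regions=30, seed=7
    )
    return bm.build_feature_dataset(bm.generate_cohort(spec))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
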