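import numpy as np
import pandas as pd
import pytest

from lipokine.cohort import GROUPS
from lipokine.synth import ClusterSpec, EffectSpec, GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """A compact cohort: 2 planted lipid clusters, 1 cytokine cluster."""
    return GeneratorConfig(
        n_per_group=10,
        n_lipids=12,
        n_cytokines=6,
        lipid_cluster_spec=[
            ClusterSpec(1, 4, {"NoDx-White": 1.0, "Dx-White": 1.0, "NoDx-AA": -1.0, "Dx-AA": -1.0}),
            ClusterSpec(2, 4, {"NoDx-White": -1.0, "Dx-White": 1.0, "NoDx-AA": -1.0, "Dx-AA": 1.0}),
        ],
        cytokine_cluster_spec=[
            ClusterSpec(1, 3, {"NoDx-White": -0.5, "Dx-White": 1.0, "NoDx-AA": -0.5, "Dx-AA": 0.0}),
        ],
        effect_table=[EffectSpec("clin_hba1c", "disease", 2.0)],
        seed=42,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    cohort, truth = generate_cohort(small_config)
    return cohort, truth


def balanced_design(n_per_cell: int):
    """(race, disease) factor arrays in canonical group order."""
    group = np.repeat(GROUPS, n_per_cell)
    disease = np.array([g.split("-")[0] for g in group])
    race = np.array([g.split("-")[1] for g in group])
    return race, disease


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
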