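import numpy as np
import pytest

from metconn import (
    Region,
    SyntheticCohortSpec,
    UptakeTable,
    VOIAtlas,
    compute_suvr,
    default_atlas,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def atlas53():
    return default_atlas()


@pytest.fixture
def tiny_atlas():
    """Two regions: one node and one reference."""
    return VOIAtlas((Region("A", "NA"), Region("medulla", "NA", True)))


@pytest.fixture
def small_atlas():
    """Six regions with a bilateral reference pool."""
    return VOIAtlas(
        (
            Region("cortex_L", "L"),
            Region("cortex_R", "R"),
            Region("thalamus_L", "L"),
            Region("thalamus_R", "R"),
            Region("medulla_L", "L", True),
            Region("medulla_R", "R", True),
        )
    )


@pytest.fixture
def small_cohort(small_atlas):
    """Simulated 7+7 null cohort on the six-region atlas."""
    spec = SyntheticCohortSpec(
        atlas=small_atlas, group_sizes={"KO": 7, "WT": 7}, seed=11
    )
    return simulate_cohort(spec)


@pytest.fixture
def small_suvr(small_cohort):
    return compute_suvr(small_cohort)


def make_table(atlas, values, groups=None):
    """Uptake table with auto subject ids for handwritten matrices."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    groups = list(groups) if groups is not None else ["G"] * n
    ids = [f"s{i:02d}" for i in range(n)]
    return UptakeTable(ids, groups, values, atlas)
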