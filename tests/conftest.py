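import numpy as np
import pytest

from ecograde.datasets import load_slope_sites, load_slope_standard
from ecograde.grade_model import (
    EvaluationObject,
    GradeStandard,
    IndexDefinition,
)
from ecograde.sampler import RandomSource


@pytest.fixture(scope="session")
def slope_standard():
    return load_slope_standard()


@pytest.fixture(scope="session")
def slope_sites(slope_standard):
    return load_slope_sites(slope_standard)


@pytest.fixture
def rng():
    return RandomSource(123)


@pytest.fixture
def two_index_standard():
    """Minimal all-quantitative standard with increasing intervals."""
    bounds = tuple((10.0 * g, 10.0 * (g + 1)) for g in range(5))
    return GradeStandard(
        indexes=(
            IndexDefinition(id="A", bounds=bounds),
            IndexDefinition(id="B", bounds=bounds),
        )
    )


@pytest.fixture
def separated_standard():
    """Thin, widely gapped grade intervals with alternating direction.

    The similarity is invariant under joint rescaling, so separation must
    come from the per-grade value *profile*: half the indexes increase with
    grade, half decrease, and each grade's interval is narrow relative to
    the gaps between grades.
    """
    thin = tuple((1000.0 * (g + 1), 1000.0 * (g + 1) + 1.0) for g in range(5))
    return GradeStandard(
        indexes=tuple(
            IndexDefinition(
                id=f"I{i}",
                bounds=thin if i % 2 == 0 else thin[::-1],
                allow_gaps=True,
            )
            for i in range(4)
        )
    )


@pytest.fixture
def degenerate_standard():
    """All five grades share (almost) the same interval for every index.

    Contiguity forces distinct intervals, so use negligibly thin adjacent
    slices of one range: similarities become indistinguishable in practice.
    """
    edges = [10.0, 10.0 + 1e-9, 10.0 + 2e-9, 10.0 + 3e-9, 10.0 + 4e-9, 10.0 + 5e-9]
    bounds = tuple((edges[g], edges[g + 1]) for g in range(5))
    return GradeStandard(indexes=(IndexDefinition(id="A", bounds=bounds),))


def make_object(values, object_id="obj"):
    return EvaluationObject(id=object_id, values=np.asarray(values, dtype=float))
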