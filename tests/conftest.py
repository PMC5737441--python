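import numpy as np
import pytest

from nerka.simulate import PopulationSpec, SimParams, simulate_panel
from nerka.types import ComparisonSpec, GenotypeMatrix, SampleTable

P = PopulationSpec


def two_pop_params(seed: int = 0, **overrides) -> SimParams:
    """One lake, shore vs stream kokanee pair — the workhorse panel."""
    base = dict(
        populations=[
            P("x_shore", "lk", "c1", "kokanee", "shore", 0.02, 36),
            P("x_stream", "lk", "c1", "kokanee", "stream", 0.02, 36),
        ],
        f_catch={"c1": 0.05},
        f_lake={"lk": 0.03},
        L_neutral=400,
        missing_rate=0.03,
        seed=seed,
    )
    base.update(overrides)
    return SimParams(**base)


@pytest.fixture(scope="session")
def small_panel():
    return simulate_panel(two_pop_params(seed=1))


@pytest.fixture
def shore_stream_cmp():
    return ComparisonSpec("shore_vs_stream", frozenset({"x_shore"}), frozenset({"x_stream"}))


@pytest.fixture
def handmade_matrix():
    """Four individuals x three loci with one missing genotype."""
    dosage = np.array(
        [[0, 1, 2], [1, 1, 0], [2, 0, -1], [0, 2, 1]], dtype=np.int8
    )
    gm = GenotypeMatrix(
        individual_ids=["a_1", "a_2", "b_1", "b_2"],
        locus_ids=["100_5", "100_84", "200_0"],
        dosage=dosage,
    )
    samples = SampleTable({"a_1": "a", "a_2": "a", "b_1": "b", "b_2": "b"})
    return gm, samples
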