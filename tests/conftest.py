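import numpy as np
import pytest

from mitoabc import HaplotypeAlignment
from mitoabc.demography import (
    ClockConfig,
    DemeSpec,
    DemographicModel,
    JoinEvent,
    ModelParams,
)

NO_PARAMS = ModelParams("constant")


def single_deme_model(n_samples, size, age=0.0, clock=None):
    """A one-deme constant model in generation units (1 gen/year)."""
    clock = clock or ClockConfig(1.0, 1e-9, 1000)
    return DemographicModel(
        "constant",
        demes=[DemeSpec("d0", "1", age, n_samples, size)],
        joins=[],
        bottlenecks=[],
        clock=clock,
    )


def two_deme_isolation_model(join_time, size, ages=(0.0, 0.0), n=(1, 1)):
    clock = ClockConfig(1.0, 1e-9, 1000)
    return DemographicModel(
        "constant",
        demes=[
            DemeSpec("a", "1", ages[0], n[0], size),
            DemeSpec("b", "1", ages[1], n[1], size),
        ],
        joins=[JoinEvent(join_time, "b", "a")],
        bottlenecks=[],
        clock=clock,
    )


def seeded_rng(*key):
    return np.random.default_rng(np.random.SeedSequence(list(key)))


@pytest.fixture
def toy_alignment():
    """The 4-sequence, 2-deme hand oracle: {AAA, AAT} vs {TTA, TTT}."""
    return HaplotypeAlignment(
        sample_ids=["s1", "s2", "s3", "s4"],
        deme_ids=["p1", "p1", "p2", "p2"],
        matrix=np.array(
            [[0, 0, 0], [0, 0, 1], [1, 1, 0], [1, 1, 1]], dtype=np.uint8
        ),
        seq_length=3,
    )
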