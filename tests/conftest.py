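import numpy as np
import pytest

import scmosaic as sm
from scmosaic import synthetic_data as sd


def small_config(seed: int = 11, **kw) -> sm.SimConfig:
    """A compact two-cell-type study used across test modules."""
    defaults = dict(
        seed=seed,
        genome_length=400_000,
        n_chromosomes=2,
        simulate_indels=True,
        cohort=[
            sd.CohortEntry("S1", 5.0, {"OL": 2, "neuron": 2}),
            sd.CohortEntry("S2", 30.0, {"OL": 2, "neuron": 2}),
            sd.CohortEntry("S3", 55.0, {"OL": 2, "neuron": 2}),
            sd.CohortEntry("S4", 80.0, {"OL": 2, "neuron": 2}),
        ],
    )
    defaults.update(kw)
    return sm.SimConfig(**defaults)


@pytest.fixture(scope="session")
def bundle_small():
    return sm.generate_reference(small_config())


@pytest.fixture(scope="session")
def cohort_small(bundle_small):
    return sm.generate_cohort_calls(small_config(), bundle_small)


@pytest.fixture(scope="session")
def reference_small(bundle_small):
    return bundle_small.reference


def make_reference(seq: str, name: str = "chr1") -> sm.Reference:
    return sm.Reference({name: np.frombuffer(seq.encode(), dtype=np.uint8).copy()})
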