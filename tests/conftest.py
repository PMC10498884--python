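import numpy as np
import pandas as pd
import pytest

from plaqueomics.io_core import AbundanceMatrix, Fraction, SampleMetadata
from plaqueomics.synthetic import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """One reduced cohort shared across tests (105 samples, ~140 proteins)."""
    cfg = SimulationConfig(seed=11,
                           n_proteins={"SDS": 60, "NaCl": 40, "GuHCl": 60},
                           markers_per_axis=8)
    return simulate_study(cfg)


@pytest.fixture()
def toy_matrix():
    data = pd.DataFrame(
        [[1.0, 2.0, 3.0],
         [4.0, np.nan, 6.0],
         [7.0, 8.0, 9.0]],
        index=["A", "B", "C"], columns=["s1", "s2", "s3"])
    return AbundanceMatrix(Fraction.GUHCL, data)


def minimal_metadata(n, **overrides):
    base = {
        "sample_id": [f"s{i}" for i in range(n)],
        "patient_id": [f"p{i}" for i in range(n)],
        "region": "core",
        "sex": "male",
        "calcified": False,
        "symptomatic": False,
        "statin": False,
        "age": 70.0,
        "ultrasound": "unknown",
        "follow_up": 1.0,
        "event": False,
    }
    base.update(overrides)
    return SampleMetadata(pd.DataFrame(base))
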