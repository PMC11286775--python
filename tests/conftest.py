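import numpy as np
import pandas as pd
import pytest

from resistnet.dataio import ExpressionMatrix, Regulon, RegulonSet
from resistnet.simulate import SimConfig, simulate_omics


@pytest.fixture
def tiny_counts():
    data = pd.DataFrame(
        {
            "s1": [10, 100, 0, 50],
            "s2": [12, 110, 0, 55],
            "s3": [20, 200, 0, 100],
            "s4": [22, 220, 0, 110],
        },
        index=["g1", "g2", "g3", "g4"],
        dtype=float,
    )
    cond = pd.Series(["A", "A", "B", "B"], index=data.columns)
    return ExpressionMatrix(data, cond, "count")


@pytest.fixture
def small_regulons():
    regs = RegulonSet()
    regs["R1"] = Regulon(["g1", "g2", "g3"], np.array([1.0, 1.0, -1.0]), np.ones(3))
    regs["R2"] = Regulon(["g4", "g5"], np.array([1.0, 1.0]), np.array([1.0, 0.5]))
    return regs


@pytest.fixture(scope="session")
def default_sim():
    """One default synthetic study, shared across tests that only read it."""
    cfg = SimConfig(rng_seed=7)
    counts, intensities, regulons, truth = simulate_omics(cfg)
    return cfg, counts, intensities, regulons, truth
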