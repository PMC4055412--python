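import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

import bowtievar as bv
from bowtievar.proteomics_features import IntensityMatrix

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_matrix(values, columns=None, index=None) -> IntensityMatrix:
    """Intensity matrix straight from an array, bypassing the
    non-negativity check (tests feed z-scored or signed data too)."""
    values = np.asarray(values, dtype=float)
    if columns is None:
        n_lines = values.shape[1] // 3
        columns = [f"L{l:02d}.rep{r}" for l in range(n_lines) for r in (1, 2, 3)]
    if index is None:
        index = [f"P{i:05d}" for i in range(values.shape[0])]
    m = IntensityMatrix.__new__(IntensityMatrix)
    m.values = pd.DataFrame(values, index=index, columns=list(columns))
    return m


@pytest.fixture(scope="session")
def small_world() -> bv.synthetic_data.World:
    """One modest synthetic world shared by read-only tests."""
    return bv.generate_world(bv.WorldConfig(n_proteins=800, seed=20240917 % 2**31))


@pytest.fixture(scope="session")
def small_features(small_world):
    return bv.compute_features(small_world.intensities)
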