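import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

import spatialcoloc as sc

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_cells(n=100, n_fovs=2, n_types=3, seed=0, fov_size=500.0, sample="S1"):
    """Random uniform cell table: n cells split over n_fovs FOVs."""
    r = np.random.default_rng(seed)
    types = [chr(ord("A") + i) for i in range(n_types)]
    df = pd.DataFrame({
        "cell_id": [f"c{i:05d}" for i in range(n)],
        "sample_id": sample,
        "fov_id": [f"F{i % n_fovs + 1}" for i in range(n)],
        "x_um": r.uniform(0, fov_size, n),
        "y_um": r.uniform(0, fov_size, n),
        "cell_type": r.choice(types, n),
    })
    return sc.CellTable(df, fov_size_um=fov_size)


@pytest.fixture
def small_cells():
    return make_cells(n=100, n_fovs=2, n_types=3, seed=1)


@pytest.fixture
def neutral_spec():
    def _make(seed=0, density=200, n_fovs=4, n_types=4, relations=()):
        types = [chr(ord("A") + i) for i in range(n_types)]
        return sc.SyntheticSpec(
            type_freqs={t: 1 / n_types for t in types},
            base_density=density,
            n_fovs_per_sample=n_fovs,
            relations=list(relations),
            seed=seed,
        )
    return _make
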