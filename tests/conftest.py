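from pathlib import Path

import numpy as np
import pytest

from hho_featsel.data_io import SyntheticSpec, generate_synthetic
from hho_featsel.hho import OptimizerConfig, SearchSpace

DATA_DIR = Path(__file__).parent / "data"


def sphere(x: np.ndarray) -> float:
    return float(np.sum(x * x))


@pytest.fixture
def fixture_arff() -> Path:
    return DATA_DIR / "fixture_3rows.arff"


@pytest.fixture
def small_table():
    """400-row synthetic table with the default planted signal."""
    return generate_synthetic(SyntheticSpec(n_rows=400, seed=7))


@pytest.fixture
def sphere_config():
    return OptimizerConfig(
        pop_size=30,
        max_iter=200,
        space=SearchSpace.cube(10, -10.0, 10.0),
        seed=11,
    )
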