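from pathlib import Path

import numpy as np
import pytest

from capdist import CodeTable, worked_example_set

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def table() -> CodeTable:
    return CodeTable.default()


@pytest.fixture(scope="session")
def worked_example():
    return worked_example_set()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20231005)
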