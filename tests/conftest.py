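import numpy as np
import pytest

from scassembly.cg_simulator import CGModelParams, build_tetramer_model


@pytest.fixture(scope="session")
def cg_params():
    return CGModelParams()


@pytest.fixture(scope="session")
def tetramer(cg_params):
    return build_tetramer_model(cg_params)


@pytest.fixture
def gentle_midline():
    """Midline polyline used for synthetic stacks: gentle sine across a 160-px frame."""
    return np.column_stack(
        [np.linspace(12, 148, 20), 32 + 4 * np.sin(np.linspace(0, 2.5, 20))]
    )
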