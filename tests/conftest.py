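import numpy as np
import pytest

from memadh.models import ElectrolyteModel, PlanarGap


@pytest.fixture(scope="session")
def water_010m() -> ElectrolyteModel:
    """Standard water parameter set at 0.1 M salt."""
    return ElectrolyteModel.from_molar(0.1)


@pytest.fixture(scope="session")
def water_001m() -> ElectrolyteModel:
    return ElectrolyteModel.from_molar(0.01)


@pytest.fixture(scope="session")
def weak_gap() -> PlanarGap:
    """Weak-charge antisymmetric pair, deep in the linear regime."""
    return PlanarGap.from_nm(6.0, 1e-3, -1e-3)


# moderate default grid for tests: full accuracy checks pass at 8001 nodes,
# everything else runs on 4001 to keep the suite fast
FAST_NODES = 4001
FULL_NODES = 8001
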