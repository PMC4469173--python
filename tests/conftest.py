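import numpy as np
import pytest

from ritdose.decay import load_radionuclide
from ritdose.geometry import build_tissue_model
from ritdose.synthetic import generate_material_tables
from ritdose.materials import MaterialTables


@pytest.fixture(scope="session")
def model05():
    """Reference 0.5 cm tumour with the full 4 cm lung shell."""
    return build_tissue_model(0.5)


@pytest.fixture(scope="session")
def material_tables():
    return MaterialTables(
        soft_tissue=generate_material_tables("soft_tissue"),
        lung=generate_material_tables("lung"),
    )


@pytest.fixture(scope="session")
def nuclides():
    return {name: load_radionuclide(name)
            for name in ("Y90", "Lu177", "I124", "I131", "Re188")}


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
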