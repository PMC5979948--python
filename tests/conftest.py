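import pytest

from oxmembrane import lipid_library
from oxmembrane.membrane_builder import MembraneComposition, build_bilayer


@pytest.fixture(scope="session")
def library():
    """Topologies for all bundled lipid species."""
    return lipid_library()


@pytest.fixture(scope="session")
def small_bilayer():
    """A small mixed bilayer built with a fixed seed."""
    comp = MembraneComposition({"DSPC": 0.75, "DOPC": 0.25})
    return build_bilayer(comp, n_per_leaflet=16, seed=7)
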