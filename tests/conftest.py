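import numpy as np
import pytest

from irdl.dockcore import build_grid, fragment_topology
from irdl.structures import PeptideModel
from irdl.synthetic import make_pocket_system


@pytest.fixture(scope="session")
def pocket():
    """A small certified pocket complex shared across tests."""
    return make_pocket_system("GAKDF", n_contacts=3, seed=1)


@pytest.fixture(scope="session")
def pocket_grid(pocket):
    return build_grid(pocket.receptor, pocket.planted_peptide, spacing=0.5)


@pytest.fixture(scope="session")
def seed_fragment(pocket):
    """The pocket's C-terminal segment model, topology and planted coords."""
    model = PeptideModel("DF")
    topo = fragment_topology(model)
    coords = np.array([
        pocket.planted_peptide.coords[
            pocket.model.atom_index(3 + model.atom_res[k],
                                    model.atom_names[k])]
        for k in range(model.n_atoms)])
    return model, topo, coords
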