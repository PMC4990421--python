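import numpy as np
import pytest

from mapfit import density_maps as dm
from mapfit.structures import (TopologyParams, assign_ss_restraints, build_topology,
                               ss_segments)
from mapfit.synthetic import ToySpec, make_fixture, make_toy_dimer


@pytest.fixture(scope="session")
def toy_spec():
    return ToySpec(residues_per_domain=60, hinge_angle=25.0, seed=1)


@pytest.fixture(scope="session")
def toy_structure(toy_spec):
    return make_toy_dimer(toy_spec)


@pytest.fixture(scope="session")
def toy_map(toy_structure):
    return dm.render_map(toy_structure, resolution=3.0, voxel=1.0, pad=14.0)


@pytest.fixture(scope="session")
def toy_topology(toy_structure):
    return build_topology(toy_structure)


@pytest.fixture(scope="session")
def toy_restraints(toy_structure):
    return assign_ss_restraints(toy_structure, ss_segments(toy_structure))


@pytest.fixture(scope="session")
def fitting_fixture():
    """The packaged two-domain fitting fixture (target, 7 A-displaced search, maps)."""
    return make_fixture(seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
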