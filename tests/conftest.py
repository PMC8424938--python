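import warnings

import numpy as np
import pytest

warnings.filterwarnings("ignore", module="MDAnalysis")

from pocketgrid.featurize import featurize_structure
from pocketgrid.fixtures import FixtureConfig, make_toy_protein
from pocketgrid.structio import structure_center
from pocketgrid.voxelize import GridSpec, voxelize_atoms, voxelize_site


@pytest.fixture(scope="session")
def toy():
    """A 20-residue single-chain helix with site and ligand clouds."""
    return make_toy_protein(FixtureConfig(n_residues=20, seed=3))


@pytest.fixture(scope="session")
def toy_two_chain():
    return make_toy_protein(FixtureConfig(n_residues=14, n_chains=2, seed=7))


@pytest.fixture(scope="session")
def toy_grid(toy):
    """(GridSpec, FeatureGrid, SiteMask) for the session toy protein."""
    spec = GridSpec(center=structure_center(toy.structure))
    grid = voxelize_atoms(featurize_structure(toy.structure), spec)
    mask = voxelize_site(toy.site, spec, dilation=2.0)
    return spec, grid, mask


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
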