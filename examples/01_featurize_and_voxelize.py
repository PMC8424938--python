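"""Featurize a synthetic protein and place it on the 36^3 voxel grid.

Builds a 20-residue helix, computes the 18-channel per-atom feature
vectors, and rasterizes them into the network's input tensor.
"""

import numpy as np

from pocketgrid.featurize import CHANNEL_NAMES, featurize_structure
from pocketgrid.fixtures import FixtureConfig, make_toy_protein
from pocketgrid.structio import structure_center
from pocketgrid.voxelize import GridSpec, voxelize_atoms

toy = make_toy_protein(FixtureConfig(n_residues=20, seed=1))
print(f"chain A sequence: {toy.sequences['A']}")

atoms = featurize_structure(toy.structure)
print(f"{len(atoms)} heavy atoms featurized, {len(CHANNEL_NAMES)} channels each")

spec = GridSpec(center=structure_center(toy.structure))
grid = voxelize_atoms(atoms, spec)
occupied = int((grid.tensor.sum(axis=-1) != 0).sum())
print(f"grid {grid.tensor.shape}: {occupied} of {spec.side**3} voxels occupied, "
      f"{grid.n_dropped} atoms outside the box")
# The occupied count is small relative to 36^3 = 46,656 — the extreme
# class imbalance that motivates the dice training loss.
charges = grid.tensor[..., 12]
print(f"partial-charge channel range: {charges.min():+.3f} .. {charges.max():+.3f} e")
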