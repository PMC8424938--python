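"""Scaled-down training: overfit one synthetic (grid, mask) pair.

A narrow-filter build of the network is trained with the dice loss on a
single voxelized helix + site pair, then the probability map is cut into
pockets and compared with the training mask.  Takes a couple of minutes
on one CPU.
"""

import numpy as np

from pocketgrid.featurize import featurize_structure
from pocketgrid.fixtures import FixtureConfig, make_toy_protein
from pocketgrid.metrics import dvo
from pocketgrid.model import (
    TrainConfig,
    build_puresnet,
    predict,
    reduced_schedule,
    train_scaled,
)
from pocketgrid.structio import structure_center
from pocketgrid.voxelize import GridSpec, extract_pockets, voxelize_atoms, voxelize_site

toy = make_toy_protein(FixtureConfig(n_residues=20, seed=3))
spec = GridSpec(center=structure_center(toy.structure))
grid = voxelize_atoms(featurize_structure(toy.structure), spec)
mask = voxelize_site(toy.site, spec, dilation=2.0)
print(f"training mask: {int(mask.tensor.sum())} positive voxels of {spec.side**3}")

net = build_puresnet(reduced_schedule(2), seed=0)
config = TrainConfig(learning_rate=3e-3, l2=1e-4, batch_size=1, seed=0, steps=200)
trace = train_scaled(
    net,
    [(grid.tensor.astype(float), mask.tensor.astype(float))],
    config,
    callback=lambda s, l: print(f"  step {s:>3}: dice loss {l:.4f}")
    if s % 50 == 0 else None,
)
print(f"final dice loss: {trace[-1]:.4f} (< 0.1 means the pair is memorized)")

prob = predict(net, grid)
pockets = extract_pockets(prob, spec)
print(f"pockets extracted from the prediction: {len(pockets)}")
print(f"overlap with the training mask (DVO): {dvo(pockets[0], mask):.3f}")
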