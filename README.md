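# pocketgrid

Voxel-grid prediction of protein–ligand binding sites: a residual 3D U-Net
over featurized protein structures, the structural-similarity data-cleaning
pipeline used to curate its training set, and the DCC/DVO/PLI/F1 evaluation
protocol — implemented as a tested library with a thin CLI, exercisable
end-to-end on synthetic structures (no external database or trained weights
required).

## The problem

A ligand binds a protein at a specific cavity (the *binding site*); finding
that site from structure alone is a first step in protein function
annotation and drug discovery.  The approach here treats the problem as 3D
image segmentation: a protein is placed in a cube of side ~70 Å centered on
its heavy-atom centroid and discretized into a 36×36×36 grid (2 Å voxels).
Each voxel accumulates an 18-channel chemical description of the atoms it
contains (element class one-hot over {B,C,N,O,P,S,Se,halogen,metal},
hybridization, heavy/hetero neighbour counts, Gasteiger partial charge, and
five SMARTS flags: hydrophobic, aromatic, acceptor, donor, ring).  A
residual encoder–decoder network maps this 36³×18 tensor to a 36³×1 grid of
per-voxel site probabilities, which are thresholded and cut into discrete
pockets by 26-connected component labelling.

Because binding-site voxels are ~0.1 % of the grid, training uses the soft
dice loss, `1 − (2Σpm + s)/(Σp + Σm + s)`, rather than cross-entropy.

**Data cleaning.**  Structure databases are heavily redundant.  The cleaning
pipeline groups structures by UniProt accession and measures within-cluster
similarity with a *k-mer fingerprint Tanimoto index*: a sequence of N
residues becomes N−2 overlapping 3-mers, each embodied as a tripeptide
molecule and fingerprinted with the 167-bit MACCS dictionary, giving an
(N−2)×167 bit matrix; equal-length matrices are pooled into single bit
vectors and compared with the Tanimoto index |A∩B|/|A∪B|, while unequal
lengths slide the shorter matrix along the longer and keep the maximum.
One representative (the longest sequence) is kept per cluster, only chains
in contact with the site (≤ 4 Å) are retained, and entries whose site lies
more than 70 Å from the protein center — unrepresentable in the voxel box —
are dropped.

**Evaluation.**  A predicted pocket is compared with the annotated site by
DCC (distance between centers; ≤ 4 Å is a hit), DVO (Jaccard overlap of the
voxelized volumes, for hits only) and PLI (fraction of ligand voxels inside
the predicted site).  Per structure: a hit is a TP, a miss an FP, no
prediction at all an FN, and `F1 = 2TP/(2TP+FP+FN)`.

## The network

Three residual block types (layer counts as graph nodes):

| block | layers | structure |
|---|---|---|
| convolution | 12 | bottleneck conv–BN–ReLU ×2 + conv–BN, projection shortcut conv–BN, add, ReLU |
| identity | 10 | same bottleneck path, raw-input shortcut |
| up-sampling | 14 | upsample + bottleneck path, upsample–conv–BN shortcut |

The default build has 5 convolution, 13 identity and 4 up-sampling blocks:
five encoder stages (conv + identity, spatial sizes 36→36→18→9→3→1), four
skip connections each passing through an identity block before joining the
decoder, and four decoder stages (up-sampling block + concatenation +
identity).  With the input node, 4 joins and the sigmoid head the graph has
252 layers, 13,840,903 trainable and 16,992 non-trainable parameters.

The network runs on a small NumPy computational-graph engine written for
this package (im2col 3D convolution, batch norm, nearest-neighbour
up-sampling, Adam, hand-derived backward passes) — no GPU framework is
needed for the scaled-down training the package targets.

## Worked example

```bash
python examples/03_build_network.py
```

```
blocks: 5 convolution (12 layers each), 13 identity (10), 4 up-sampling (14)
total layers: 252
trainable parameters:       13,840,903
non-trainable parameters:       16,992
```

```bash
python examples/02_cleaning_pipeline.py
```

```
dispositions (kept / deduplicated / dropped_parse / dropped_distance):
    broken -> dropped_parse
      dupA -> deduplicated
      dupB -> kept
   farsite -> dropped_distance
       okA -> kept
       okB -> kept

duplicate pair sliding Tanimoto: 1.000 (>= 0.8 marks structures as redundant copies)
retained for training: ['dupB', 'okA', 'okB']
```

The duplicate pair differs by one terminal residue, so the shorter
fingerprint matrix is a contiguous slice of the longer one and the sliding
Tanimoto is exactly 1; the longer member is kept.  `farsite` has its site
cloud 80 Å from the protein center — beyond the 70 Å representability
limit — and is dropped.

`examples/04_train_and_predict.py` overfits a narrow-filter build on one
synthetic (grid, mask) pair with the dice loss (~2 minutes on one CPU),
then recovers the site as a pocket: final dice loss ≈ 0.04, DVO with the
training mask ≈ 0.98.

The CLI wraps the same functionality: `pocketgrid fixtures | convert |
clean | voxelize | build | train | predict | pockets | eval` (see
`pocketgrid --help`).

## Layout

```
src/pocketgrid/
  structio.py    PDB/mol2 I/O, structure model, mol2 point-cloud export
  featurize.py   18-channel per-atom chemical features (RDKit)
  voxelize.py    grid placement, site masks, pocket extraction
  cleaner.py     k-mer MACCS fingerprints, sliding Tanimoto, cleaning flow
  nn.py          NumPy computational-graph engine
  model.py       residual U-Net builder, dice loss, training, k-fold groups
  metrics.py     DCC / success rate / DVO / PLI / F1
  fixtures.py    deterministic synthetic proteins, sites, probability grids
  serialize.py   weight persistence (HDF5)
  cli.py         the `pocketgrid` command
examples/        one narrative script per capability
docs/methods.md  model assumptions, parameter choices, limitations
```
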