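# Methods

This note records the model, the parameter choices that matter, what the
synthetic data does and does not emulate, and the numerically delicate
decisions, in enough detail that a maintainer can judge what a passing test
establishes.

## Data representation

A protein is treated as a 3D image: a cube centered on the unweighted mean
of the heavy-atom coordinates, extending `max_dist` (default 35 Å) in each
direction and discretized at `resolution` (default 2 Å), giving
`side = floor(2·max_dist/resolution) + 1 = 36` voxels per axis.  The voxel
index along an axis is `i = floor((x − center + max_dist)/resolution)`;
points with any index outside `[0, side)` are dropped (their count is
reported).  An atom at the exact center lands in voxel (17, 17, 17).

The per-atom feature vector has 18 frozen channels: a 9-class element
one-hot (B, C, N, O, P, S, Se, halogen = {F, Cl, Br, I}, metal = a fixed
atomic-number table), hybridization (1/2/3 for sp/sp²/sp³), heavy- and
heteroatom-neighbour counts, the Gasteiger partial charge (non-finite
values are clamped to 0 with a warning), and five SMARTS membership flags
(hydrophobic, aromatic, acceptor, donor, ring) evaluated on the whole
molecule.  The SMARTS strings are the published pattern set of the
featurizer this layout follows.  Hydrogens are never featurized; they are
retained at parse time only to flag `is_heavy`.  Atom features contain no
coordinate-dependent channel, so feature vectors are invariant under
rigid-body motion (voxel *placement* obviously is not).

Voxel aggregation on collision is channel-wise **sum**, chosen over max
because additivity over disjoint atom sets is a testable linearity.  Site
masks use raw point occupancy (voxel = 1 iff ≥ 1 site point maps to it)
with an optional spherical dilation radius for pipelines that prefer a
neighbourhood label; the training fixtures use a 2 Å dilation so a point
cloud produces a contiguous, learnable target.

The stated grid geometry is internally inconsistent in its source: 1 Å
voxels cannot give a 36-voxel side spanning 70 Å per direction.  We resolve
it as 2 Å voxels with `max_dist` 35 Å (≈70 Å total extent, 36³ grid) and
keep both knobs configurable.

## Cleaning pipeline

Order: parse-failure removal → UniProt clustering → representative
selection → site-chain retention → 70 Å site-distance filter.  Decisions:

* **Tanimoto over bit matrices.**  The index is defined on sets; a
  fingerprint here is an (N−2)×167 bit *matrix*.  We pool the matrix
  row-aligned into one long bit vector before the set computation — the
  simplest reading of "computed between A1 and A2".  Two all-zero vectors
  score 1 (identical objects).
* **Sliding form.**  Unequal lengths slide a window of the shorter length
  along the longer with stride 1 and keep the maximum pooled index.  A
  contiguous row-slice therefore scores exactly 1 — acceptable for the
  redundancy-detection purpose (a fragment *is* redundant with its parent).
* **3-mer embodiment.**  Each 3-mer becomes a neutral tripeptide molecule
  (free amine/acid termini, no zwitterion) before MACCS fingerprinting;
  rows are cached per 3-mer (20³ possible), which makes fingerprinting a
  500-residue sequence cheap.
* **Representative = longest sequence**, ties broken by lexicographically
  smallest id for determinism.  Clusters whose mean pairwise similarity
  falls below the 0.8 threshold still keep exactly one member but are
  flagged.
* **Chain retention** stands in for the original manual visual inspection:
  chains with ≥ 1 heavy atom within 4 Å of any site point are kept; if none
  qualifies the structure is flagged for review, never silently dropped.
* The 70 Å filter is strict (> 70 drops, exactly 70 keeps).

## Network

Blocks follow the standard residual bottleneck layout (1³–3³–1³ kernels,
BN after every convolution, ReLU after the add): convolution block = 12
graph nodes, identity block = 10, up-sampling block = 14 (nearest-neighbour
up-sampling; the projection shortcut also upsamples).  The build is 5
encoder stages (convolution + identity), 4 skip paths each with an identity
block, and 4 decoder stages (up-sampling block, concatenation with the skip
feature, identity block), then a 1³ sigmoid head: 252 graph nodes
including the input and the 4 joins.  Encoder strides are (1, 2, 2, 3, 3)
and decoder factors (3, 3, 2, 2), so spatial sizes run
36→36→18→9→3→1→3→9→18→36 and every up-sampled tensor aligns exactly with
its skip partner — no cropping or padding asymmetry.

**Filter schedule.**  The per-block width table of the reference
architecture is distributed in supplementary material that is not shipped
here; what survives in print are the block/layer counts and the parameter
totals (13,840,903 trainable, 16,992 non-trainable).  The default schedule
is therefore *calibrated*: bottleneck widths follow a doubling ladder —
encoder (24, 48, 96, 192, 384), decoder (96, 48, 24, 12) — with block
output widths equal to the bottleneck widths except three entries
(encoder stage 5 output 478, decoder outputs 84 and 126) solved exactly so
that the build reproduces the printed totals under the layouts above.  A
fully regular (all multiples of 8) schedule provably cannot meet the
printed totals in this layout family (a mod-4 parity obstruction), which is
why the calibration concentrates in as few widths as possible.  The
schedule is a plain dataclass; any other width table can be passed to the
builder, and the parameter accounting is always computed from the graph,
never asserted from constants.

**Engine.**  The graph runs on a purpose-built NumPy engine: explicit DAG
of layer nodes, im2col 3D convolution ('same' padding, output
`ceil(n/stride)`, He initialization), per-channel batch norm (ε = 10⁻³,
momentum 0.8 — a short memory suits runs of a few hundred steps; moving
statistics are the non-trainable parameters, 2 per channel each), nearest
up-sampling, additive shortcuts, channel concatenation, and Adam.  All
backward passes are hand-derived and verified against central finite
differences (relative error ≤ 10⁻⁵ in the test suite).  Tensors are
single-sample; batches average parameter gradients.  L2 regularization
(default 10⁻⁴) applies to convolution kernels only and enters through the
loss gradient.

**Loss.**  Soft dice with smoothing 1:
`1 − (2Σpm + 1)/(Σp + Σm + 1)`; its gradient is computed in closed form.
Binary cross-entropy is available behind `loss="bce"` for comparison.
Defaults follow the reference training recipe (learning rate 10⁻⁴, L2
10⁻⁴, batch 5, K = 4 folds); K-fold splitting is group-aware so all
structures of one protein family land in the same fold.  After the last
optimization step the trainer runs a short statistics-only pass (15
forward passes by default) to recalibrate the batch-norm moving statistics
against the final weights; without it, inference-mode predictions after a
short run can diverge badly from training-mode behaviour because the
moving averages lag the rapidly changing activations.

## Synthetic data

`fixtures.make_toy_protein` builds ideal α-helices (φ = −57°, ψ = −47°,
ω = 180°, standard bond lengths/angles via natural-extension placement)
from a five-residue template alphabet (G, A, S, C, F) with idealized CB and
side-chain geometry, including a planar aromatic PHE ring.  Bond orders for
backbone carbonyls and template side chains are restored before
sanitization so the cheminformatics backend perceives amides, aromaticity
and sensible charges.  The site is a ~30-point cloud anchored 3 Å outside a
mid-chain residue; a second chain, when requested, sits 30 Å away so
exactly one chain contacts the site.  All generators are pure functions of
their seed.

What this does *not* emulate: real side-chain rotamers and packing,
β-sheets and loops, real pocket concavity, crystallographic noise, hetero
atoms/cofactors, and the family composition of curated databases.  Passing
tests therefore establish the correctness of the machinery (featurization
contracts, grid arithmetic, cleaning logic, optimization behaviour), not
predictive performance on real proteins — the published success rates
require the original trained weights and external datasets and are out of
scope here.

## Scaled-down training

The learning smoke test overfits one (grid, mask) pair — a 20-residue
helix, 43 positive voxels of 46,656 — using a narrow schedule (all
bottlenecks 2, outputs 4), learning rate 3·10⁻³, 200 steps, ~3 minutes of
CPU.  A correct implementation reaches dice loss < 0.1 and recovers the
site as the top pocket (DVO > 0.7 against the training mask).  The same
configuration with every shortcut and skip join removed stalls near loss 1
at step 200 — the qualitative vanishing-gradient contrast the residual
design exists to fix.  Problem sizes here (one sample, width-2 filters,
200 steps) were chosen as the smallest at which these qualitative
contrasts are stable across seeds.

## Evaluation protocol

One record per structure: the annotated site is paired with the pocket of
minimum DCC (`policy="min_dcc"`, default) or with the top-ranked pocket by
mean probability (`policy="top_ranked"`); the printed per-fold counts are
consistent with one record per structure, but the source does not fully pin
the pairing policy, so both are exposed.  DCC ≤ 4 Å → TP (DVO and PLI are
then computed on the common 36³ grid); DCC > 4 Å → FP; no pockets → FN;
`F1 = 2TP/(2TP+FP+FN)`.  Table comparisons round F1 half-up to 2 decimals.
DVO/PLI are set arithmetic over voxel index sets — never continuous
volumes.

## Known limitations

* mol2 protein files carry no chain ids; structures read from mol2 are
  treated as single-chain.
* Bond-order restoration covers backbone carbonyls and the common
  side-chain patterns; exotic residues fall back to single bonds, which can
  shift hybridization/aromaticity channels for those residues.
* The engine is CPU-bound NumPy: suitable for the scaled-down training and
  inference this package targets, not for full-database training.
* The calibrated filter schedule reproduces the printed parameter totals
  but is not guaranteed to equal the unpublished reference width table.
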