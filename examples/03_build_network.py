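"""Build the residual 3D U-Net and print its accounting.

The default filter schedule reproduces the reference parameter totals;
the block census and per-block layer counts are structural invariants of
the architecture.
"""

from pocketgrid.model import (
    DEFAULT_SCHEDULE,
    block_census,
    build_puresnet,
    count_parameters,
)

net = build_puresnet(DEFAULT_SCHEDULE)
trainable, non_trainable, layers = count_parameters(net)
conv, ident, up = block_census(net)

print(f"blocks: {conv} convolution (12 layers each), "
      f"{ident} identity (10), {up} up-sampling (14)")
print(f"total layers: {layers}")
print(f"trainable parameters:     {trainable:>12,}")
print(f"non-trainable parameters: {non_trainable:>12,}")
# The non-trainable parameters are the batch-norm moving statistics; the
# count equals 2 x (sum of channels over all 75 normalization layers).
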