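"""The residual 3D U-Net: block builders, architecture, loss and training.

The network is an encoder-decoder segmentation model over the 36^3 x 18
feature grid, built from three residual block types:

* convolution block (12 layers) — bottleneck path conv-BN-ReLU x2 +
  conv-BN, a projection shortcut conv-BN, an addition and a final ReLU;
  downsamples when its stride exceeds 1,
* identity block (10 layers) — the same bottleneck path with the raw input
  as shortcut ("identity mapping by shortcuts"),
* up-sampling block (14 layers) — nearest-neighbour up-sampling followed by
  the bottleneck path, with an upsample-conv-BN projection shortcut.

The default build has 5 convolution blocks, 13 identity blocks and 4
up-sampling blocks: each of the five encoder stages is a convolution block
followed by an identity block; each of the four skip connections passes
through its own identity block before joining the decoder; each of the four
decoder stages is an up-sampling block whose output is concatenated with
the skip feature and refined by an identity block.  With the input node,
the four concatenations and the final sigmoid-activated 1x1x1 convolution
the graph has 252 layers.

Spatial sizes run 36 -> 36 -> 18 -> 9 -> 3 -> 1 through the encoder
(strides 1, 2, 2, 3, 3) and back up by factors 3, 3, 2, 2, so every
up-sampled tensor aligns exactly with its skip partner.

The default filter schedule is calibrated so that the builder reproduces
the reference parameter accounting — 13,840,903 trainable and 16,992
non-trainable parameters — see the packaged methods note.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (
    Activation,
    Adam,
    Add,
    BatchNorm,
    Concatenate,
    Conv3D,
    Input,
    Network,
    UpSampling3D,
)
from .voxelize import SiteMask

__all__ = [
    "BlockSpec",
    "FilterSchedule",
    "TrainConfig",
    "DEFAULT_SCHEDULE",
    "build_block",
    "build_puresnet",
    "count_parameters",
    "block_census",
    "dice_loss",
    "dice_loss_grad",
    "train_scaled",
    "predict",
    "group_kfold",
    "reduced_schedule",
]

ENCODER_STRIDES = (1, 2, 2, 3, 3)
DECODER_FACTORS = (3, 3, 2, 2)


@dataclass(frozen=True)
class BlockSpec:
    kind: str  # convolution | identity | upsampling
    filters: tuple[int, int]  # (bottleneck width, output channels)
    stride: int = 1  # stride for convolution blocks, factor for upsampling

    def __post_init__(self):
        if self.kind not in ("convolution", "identity", "upsampling"):
            raise ValueError(f"unknown block kind {self.kind!r}")
        if min(self.filters) < 1 or self.stride < 1:
            raise ValueError("filters and stride must be positive")


@dataclass(frozen=True)
class FilterSchedule:
    """Per-block channel widths.

    ``encoder[i] = (bottleneck, out)`` for encoder stage i (its convolution
    block and stage identity block share the pair); ``decoder[j]`` likewise
    for the j-th up-sampling block and its post-concatenation identity
    block.  Skip identity blocks reuse their encoder stage's pair.
    """

    encoder: tuple[tuple[int, int], ...]
    decoder: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if len(self.encoder) != 5 or len(self.decoder) != 4:
            raise ValueError(
                "schedule needs 5 encoder and 4 decoder width pairs, got "
                f"{len(self.encoder)} and {len(self.decoder)}"
            )


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    l2: float = 1e-4
    batch_size: int = 5
    k_folds: int = 4
    loss: str = "dice"
    seed: int = 0
    steps: int = 200

    def __post_init__(self):
        if min(self.learning_rate, self.batch_size, self.k_folds, self.steps) <= 0:
            raise ValueError("training hyperparameters must be positive")
        if self.l2 < 0:
            raise ValueError("l2 must be non-negative")
        if self.loss not in ("dice", "bce"):
            raise ValueError(f"unknown loss {self.loss!r}")


def _bottleneck_path(net, x_idx, cin, width, cout, stride, rng, prefix):
    """conv(1)-BN-ReLU, conv(3)-BN-ReLU, conv(1)-BN — returns the BN node."""
    i = net.add(
        Conv3D(cin, width, kernel=1, stride=stride, rng=rng, name=f"{prefix}_c1"),
        [x_idx],
    )
    i = net.add(BatchNorm(width, name=f"{prefix}_bn1"), [i])
    i = net.add(Activation("relu", name=f"{prefix}_relu1"), [i])
    i = net.add(Conv3D(width, width, kernel=3, rng=rng, name=f"{prefix}_c2"), [i])
    i = net.add(BatchNorm(width, name=f"{prefix}_bn2"), [i])
    i = net.add(Activation("relu", name=f"{prefix}_relu2"), [i])
    i = net.add(Conv3D(width, cout, kernel=1, rng=rng, name=f"{prefix}_c3"), [i])
    i = net.add(BatchNorm(cout, name=f"{prefix}_bn3"), [i])
    return i


def build_block(
    net: Network,
    x_idx: int,
    cin: int,
    spec: BlockSpec,
    rng: np.random.Generator,
    prefix: str = "block",
    shortcut: bool = True,
) -> int:
    """Append one residual block to the graph; returns the output node.

    Layer counts per kind are 12 (convolution), 10 (identity) and
    14 (up-sampling).  ``shortcut=False`` builds the ablated main-path-only
    variant used to demonstrate the vanishing-gradient problem.
    """
    width, cout = spec.filters
    if spec.kind == "identity":
        if cout != cin:
            raise ValueError(
                f"identity block requires cout == cin ({cout} != {cin})"
            )
        main = _bottleneck_path(net, x_idx, cin, width, cout, 1, rng, prefix)
        out = main
        if shortcut:
            out = net.add(Add(name=f"{prefix}_add"), [main, x_idx])
        return net.add(Activation("relu", name=f"{prefix}_out"), [out])

    if spec.kind == "convolution":
        main = _bottleneck_path(
            net, x_idx, cin, width, cout, spec.stride, rng, prefix
        )
        out = main
        if shortcut:
            sc = net.add(
                Conv3D(cin, cout, kernel=1, stride=spec.stride, rng=rng,
                       name=f"{prefix}_sc"),
                [x_idx],
            )
            sc = net.add(BatchNorm(cout, name=f"{prefix}_scbn"), [sc])
            out = net.add(Add(name=f"{prefix}_add"), [main, sc])
        return net.add(Activation("relu", name=f"{prefix}_out"), [out])

    # upsampling block
    up = net.add(UpSampling3D(spec.stride, name=f"{prefix}_up"), [x_idx])
    main = _bottleneck_path(net, up, cin, width, cout, 1, rng, prefix)
    out = main
    if shortcut:
        sc = net.add(UpSampling3D(spec.stride, name=f"{prefix}_scup"), [x_idx])
        sc = net.add(
            Conv3D(cin, cout, kernel=1, rng=rng, name=f"{prefix}_sc"), [sc]
        )
        sc = net.add(BatchNorm(cout, name=f"{prefix}_scbn"), [sc])
        out = net.add(Add(name=f"{prefix}_add"), [main, sc])
    return net.add(Activation("relu", name=f"{prefix}_out"), [out])


# Calibrated default: bottleneck widths follow a doubling ladder
# (24..384 down, 96..12 up); three output widths (478, 84, 126) are
# calibrated so the build reproduces the reference parameter accounting
# (see docs/methods.md).
DEFAULT_SCHEDULE = FilterSchedule(
    encoder=((24, 24), (48, 48), (96, 96), (192, 192), (384, 478)),
    decoder=((96, 84), (48, 48), (24, 24), (12, 126)),
)


def reduced_schedule(base: int = 2) -> FilterSchedule:
    """A narrow schedule for CPU-scale smoke training."""
    return FilterSchedule(
        encoder=tuple((base, 2 * base) for _ in range(5)),
        decoder=tuple((base, 2 * base) for _ in range(4)),
    )


def build_puresnet(
    schedule: FilterSchedule = DEFAULT_SCHEDULE,
    in_channels: int = 18,
    seed: int = 0,
    skip_connections: bool = True,
) -> Network:
    """Build the residual U-Net graph.

    ``skip_connections=False`` removes every residual shortcut and the
    encoder-decoder joins — the ablation whose training stalls on deep
    builds.
    """
    rng = np.random.default_rng(seed)
    net = Network()
    x = net.add(Input(name="input"), [])
    cin = in_channels
    skips: list[tuple[int, int]] = []  # (node, channels)
    for i, ((width, cout), stride) in enumerate(
        zip(schedule.encoder, ENCODER_STRIDES), start=1
    ):
        x = build_block(
            net, x, cin, BlockSpec("convolution", (width, cout), stride),
            rng, prefix=f"enc{i}_conv", shortcut=skip_connections,
        )
        x = build_block(
            net, x, cout, BlockSpec("identity", (width, cout)),
            rng, prefix=f"enc{i}_id", shortcut=skip_connections,
        )
        cin = cout
        if i < 5:
            skips.append((x, cout))
    for j, ((width, cout), factor) in enumerate(
        zip(schedule.decoder, DECODER_FACTORS), start=1
    ):
        x = build_block(
            net, x, cin, BlockSpec("upsampling", (width, cout), factor),
            rng, prefix=f"dec{j}_up", shortcut=skip_connections,
        )
        skip_node, skip_c = skips[4 - j]
        if skip_connections:
            s_width, s_cout = schedule.encoder[4 - j]
            s = build_block(
                net, skip_node, skip_c, BlockSpec("identity", (s_width, skip_c)),
                rng, prefix=f"skip{j}_id", shortcut=True,
            )
            x = net.add(Concatenate(name=f"join{j}"), [x, s])
            cin = cout + skip_c
        else:
            cin = cout
        x = build_block(
            net, x, cin, BlockSpec("identity", (width, cin)),
            rng, prefix=f"dec{j}_id", shortcut=skip_connections,
        )
    net.add(
        Conv3D(cin, 1, kernel=1, activation="sigmoid", rng=rng, name="head"),
        [x],
    )
    return net


def block_census(net: Network) -> tuple[int, int, int]:
    """(convolution, identity, upsampling) block counts, inferred from the
    layer naming convention of the builder."""
    prefixes = {
        l.name.rsplit("_", 1)[0]
        for l in net.layers
        if l.name.endswith("_out")
    }
    conv = sum(1 for p in prefixes if "_conv" in p)
    up = sum(1 for p in prefixes if "_up" in p)
    ident = sum(1 for p in prefixes if "_id" in p)
    return conv, ident, up


def count_parameters(net: Network) -> tuple[int, int, int]:
    """(trainable, non_trainable, layers) for a built graph."""
    return net.count_parameters()


def dice_loss(pred: np.ndarray, mask, smooth: float = 1.0) -> float:
    """Soft dice loss: 1 - (2 sum(p*m) + s) / (sum(p) + sum(m) + s)."""
    m = mask.tensor if isinstance(mask, SiteMask) else np.asarray(mask)
    p = np.asarray(pred)
    if p.squeeze().shape != m.squeeze().shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {m.shape}")
    p = p.reshape(m.squeeze().shape)
    m = m.squeeze()
    num = 2.0 * float((p * m).sum()) + smooth
    den = float(p.sum()) + float(m.sum()) + smooth
    return 1.0 - num / den


def dice_loss_grad(pred: np.ndarray, mask, smooth: float = 1.0) -> np.ndarray:
    """d(dice loss)/d(pred), same shape as ``pred``."""
    m = mask.tensor if isinstance(mask, SiteMask) else np.asarray(mask)
    shape = pred.shape
    p = pred.reshape(m.squeeze().shape)
    m = m.squeeze()
    num = 2.0 * float((p * m).sum()) + smooth
    den = float(p.sum()) + float(m.sum()) + smooth
    grad = (num / den**2) - 2.0 * m / den
    return grad.reshape(shape)


def _bce_loss_and_grad(p: np.ndarray, m: np.ndarray) -> tuple[float, np.ndarray]:
    eps = 1e-7
    pc = np.clip(p, eps, 1 - eps)
    loss = float(-(m * np.log(pc) + (1 - m) * np.log(1 - pc)).mean())
    grad = ((pc - m) / (pc * (1 - pc))) / m.size
    return loss, grad


def train_scaled(
    net: Network,
    dataset: list[tuple[np.ndarray, np.ndarray]],
    config: TrainConfig = TrainConfig(),
    callback=None,
    bn_refresh_passes: int = 15,
) -> list[float]:
    """Gradient-descent training, deterministic given the config seed.

    ``dataset`` holds (feature tensor, binary mask) pairs; each step runs
    over one shuffled mini-batch (gradient averaging).  Returns the loss
    trace, one value per step.  Raises on divergence (NaN loss), attaching
    the trace so the failure point is visible.  After the last step the
    batch-norm moving statistics are recalibrated with ``bn_refresh_passes``
    statistics-only forward passes.
    """
    if not dataset:
        raise ValueError("training dataset is empty")
    rng = np.random.default_rng(config.seed)
    optimizer = Adam(net, learning_rate=config.learning_rate)
    trace: list[float] = []
    n = len(dataset)
    for step in range(config.steps):
        picks = rng.choice(n, size=min(config.batch_size, n), replace=False)
        batch_loss = 0.0
        accum: dict[tuple[int, str], np.ndarray] = {}
        for pi in picks:
            grid, mask = dataset[pi]
            net.zero_grads()
            pred = net.forward(grid, training=True)
            if config.loss == "dice":
                loss = dice_loss(pred, mask)
                grad = dice_loss_grad(pred, mask)
            else:
                loss, grad = _bce_loss_and_grad(
                    pred.squeeze(), np.asarray(mask).squeeze()
                )
                grad = grad.reshape(pred.shape)
            batch_loss += loss
            net.backward(grad)
            for idx, layer in enumerate(net.layers):
                for name, g in layer.grads.items():
                    key = (idx, name)
                    accum[key] = accum.get(key, 0.0) + g
        batch_loss /= len(picks)
        for (idx, name), g in accum.items():
            layer = net.layers[idx]
            g = g / len(picks)
            if config.l2 > 0 and name in layer.regularized:
                g = g + 2.0 * config.l2 * layer.params[name]
                batch_loss += config.l2 * float(
                    (layer.params[name] ** 2).sum()
                ) / len(picks)
            layer.grads[name] = g
        if not np.isfinite(batch_loss):
            raise FloatingPointError(
                f"training diverged at step {step}; loss trace: {trace}"
            )
        optimizer.step()
        trace.append(batch_loss)
        if callback is not None:
            callback(step, batch_loss)
    # refresh the batch-norm moving statistics against the final weights so
    # inference-mode predictions match the trained behaviour
    for _ in range(bn_refresh_passes):
        for grid, _mask in dataset:
            net.forward(grid, training=True)
    return trace


def predict(net: Network, grid) -> np.ndarray:
    """Per-voxel site probabilities for one feature grid, shape side^3."""
    tensor = grid.tensor if hasattr(grid, "tensor") else np.asarray(grid)
    out = net.forward(tensor.astype(float), training=False)
    return out.squeeze(axis=-1)


def group_kfold(families: list[str], k: int = 4, seed: int = 0):
    """Fold assignments that keep every protein family in a single fold.

    Returns an integer array of fold labels aligned with ``families``.
    Thin wrapper over scikit-learn's GroupKFold.
    """
    from sklearn.model_selection import GroupKFold

    families = list(families)
    if k < 2:
        raise ValueError("need at least 2 folds")
    folds = np.full(len(families), -1, dtype=int)
    gkf = GroupKFold(n_splits=k)
    X = np.zeros((len(families), 1))
    for fold, (_, test_idx) in enumerate(
        gkf.split(X, groups=np.asarray(families))
    ):
        folds[test_idx] = fold
    return folds
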