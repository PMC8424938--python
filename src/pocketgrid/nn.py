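"""A small NumPy computational-graph engine for 3D volumetric networks.

Implements exactly the layer vocabulary the residual U-Net needs — 3D
convolution (im2col), batch normalization, ReLU/sigmoid activations,
nearest-neighbour up-sampling, additive shortcuts and channel
concatenation — with hand-derived backward passes and an Adam optimizer.
Tensors are single-sample ``(D, H, W, C)`` arrays; batches are handled by
gradient averaging in the training loop.

Every layer object is one node of a :class:`Network` DAG, mirroring the
"every graph node is one layer" accounting convention used when quoting
layer counts.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Input",
    "Conv3D",
    "BatchNorm",
    "Activation",
    "UpSampling3D",
    "Add",
    "Concatenate",
    "Network",
    "Adam",
]


class Layer:
    """Base node: ``params`` are trainable, ``state`` is non-trainable."""

    kind = "layer"

    def __init__(self, name: str = ""):
        self.name = name
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.state: dict[str, np.ndarray] = {}
        self.regularized: set[str] = set()  # params under L2 penalty

    def forward(self, inputs: list[np.ndarray], training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> list[np.ndarray]:
        raise NotImplementedError

    @property
    def n_trainable(self) -> int:
        return sum(p.size for p in self.params.values())

    @property
    def n_non_trainable(self) -> int:
        return sum(p.size for p in self.state.values())


class Input(Layer):
    kind = "input"

    def forward(self, inputs, training):
        return inputs[0]

    def backward(self, grad):
        return [grad]


class Conv3D(Layer):
    """3D convolution, 'same' padding, arbitrary stride, optional fused
    activation (the fused form counts as a single layer, as in common
    framework summaries)."""

    kind = "conv"

    def __init__(
        self,
        cin: int,
        cout: int,
        kernel: int = 3,
        stride: int = 1,
        activation: str | None = None,
        rng: np.random.Generator | None = None,
        name: str = "",
    ):
        super().__init__(name)
        self.cin, self.cout = cin, cout
        self.k, self.stride = kernel, stride
        self.activation = activation
        rng = rng or np.random.default_rng(0)
        fan_in = kernel**3 * cin
        scale = np.sqrt(2.0 / fan_in)  # He/variance-scaling init
        self.params["kernel"] = rng.normal(
            0.0, scale, size=(kernel, kernel, kernel, cin, cout)
        ).astype(np.float64)
        self.params["bias"] = np.zeros(cout)
        self.regularized = {"kernel"}

    def _pad_amounts(self, size: int) -> tuple[int, int, int]:
        out = -(-size // self.stride)  # ceil
        total = max((out - 1) * self.stride + self.k - size, 0)
        front = total // 2
        return out, front, total - front

    def forward(self, inputs, training):
        (x,) = inputs
        k, s = self.k, self.stride
        if k == 1:
            xs = x[::s, ::s, ::s, :]
            od, oh, ow, c = xs.shape
            wmat = self.params["kernel"].reshape(self.cin, self.cout)
            out = xs.reshape(-1, c) @ wmat + self.params["bias"]
            self._cache = (x.shape, xs.reshape(-1, c), (od, oh, ow))
            out = out.reshape(od, oh, ow, self.cout)
        else:
            d, h, w, c = x.shape
            od, pf_d, pb_d = self._pad_amounts(d)
            oh, pf_h, pb_h = self._pad_amounts(h)
            ow, pf_w, pb_w = self._pad_amounts(w)
            xp = np.pad(
                x, ((pf_d, pb_d), (pf_h, pb_h), (pf_w, pb_w), (0, 0))
            )
            win = np.lib.stride_tricks.sliding_window_view(
                xp, (k, k, k), axis=(0, 1, 2)
            )
            win = win[::s, ::s, ::s]  # (od, oh, ow, c, k, k, k)
            cols = np.ascontiguousarray(win).reshape(od * oh * ow, c * k**3)
            wmat = self.params["kernel"].transpose(3, 0, 1, 2, 4).reshape(
                c * k**3, self.cout
            )
            out = cols @ wmat + self.params["bias"]
            self._cache = (
                x.shape, xp.shape, (pf_d, pf_h, pf_w), (od, oh, ow), cols
            )
            out = out.reshape(od, oh, ow, self.cout)
        if self.activation == "sigmoid":
            out = 1.0 / (1.0 + np.exp(-out))
            self._act_cache = out
        elif self.activation is not None:
            raise ValueError(f"unsupported fused activation {self.activation!r}")
        return out

    def backward(self, grad):
        if self.activation == "sigmoid":
            y = self._act_cache
            grad = grad * y * (1.0 - y)
        k, s, c = self.k, self.stride, self.cin
        if k == 1:
            x_shape, xflat, (od, oh, ow) = self._cache
            gflat = grad.reshape(od * oh * ow, self.cout)
            wmat = self.params["kernel"].reshape(c, self.cout)
            self.grads["kernel"] = (xflat.T @ gflat).reshape(
                self.params["kernel"].shape
            )
            self.grads["bias"] = gflat.sum(axis=0)
            dxs = (gflat @ wmat.T).reshape(od, oh, ow, c)
            if s == 1:
                return [dxs]
            dx = np.zeros(x_shape)
            dx[::s, ::s, ::s, :] = dxs
            return [dx]
        x_shape, xp_shape, (pf_d, pf_h, pf_w), (od, oh, ow), cols = self._cache
        gflat = grad.reshape(od * oh * ow, self.cout)
        wmat = self.params["kernel"].transpose(3, 0, 1, 2, 4).reshape(
            c * k**3, self.cout
        )
        dw = cols.T @ gflat
        self.grads["kernel"] = (
            dw.reshape(c, k, k, k, self.cout).transpose(1, 2, 3, 0, 4)
        )
        self.grads["bias"] = gflat.sum(axis=0)
        dcols = (gflat @ wmat.T).reshape(od, oh, ow, c, k, k, k)
        dxp = np.zeros(xp_shape)
        for a in range(k):
            for b in range(k):
                for cc in range(k):
                    dxp[
                        a : a + s * od : s,
                        b : b + s * oh : s,
                        cc : cc + s * ow : s,
                        :,
                    ] += dcols[:, :, :, :, a, b, cc]
        d, h, w, _ = x_shape
        dx = dxp[pf_d : pf_d + d, pf_h : pf_h + h, pf_w : pf_w + w, :]
        return [dx]


class BatchNorm(Layer):
    """Per-channel normalization over the spatial axes.

    gamma/beta are trainable; the moving mean/variance are the
    non-trainable state (two arrays of the channel count each).
    """

    kind = "batchnorm"

    def __init__(self, channels: int, momentum: float = 0.8, eps: float = 1e-3,
                 name: str = ""):
        super().__init__(name)
        self.momentum, self.eps = momentum, eps
        self.params["gamma"] = np.ones(channels)
        self.params["beta"] = np.zeros(channels)
        self.state["moving_mean"] = np.zeros(channels)
        self.state["moving_var"] = np.ones(channels)

    def forward(self, inputs, training):
        (x,) = inputs
        axes = (0, 1, 2)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.state["moving_mean"] = m * self.state["moving_mean"] + (1 - m) * mean
            self.state["moving_var"] = m * self.state["moving_var"] + (1 - m) * var
        else:
            mean = self.state["moving_mean"]
            var = self.state["moving_var"]
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        self._cache = (xhat, inv_std, training, x.shape)
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, grad):
        xhat, inv_std, training, shape = self._cache
        n = shape[0] * shape[1] * shape[2]
        axes = (0, 1, 2)
        self.grads["gamma"] = (grad * xhat).sum(axis=axes)
        self.grads["beta"] = grad.sum(axis=axes)
        g = self.params["gamma"]
        if not training:
            return [grad * g * inv_std]
        dxhat = grad * g
        dx = (
            dxhat
            - dxhat.mean(axis=axes)
            - xhat * (dxhat * xhat).mean(axis=axes)
        ) * inv_std
        return [dx]


class Activation(Layer):
    kind = "activation"

    def __init__(self, fn: str = "relu", name: str = ""):
        super().__init__(name)
        if fn not in ("relu", "sigmoid"):
            raise ValueError(f"unsupported activation {fn!r}")
        self.fn = fn

    def forward(self, inputs, training):
        (x,) = inputs
        if self.fn == "relu":
            out = np.maximum(x, 0.0)
            self._cache = x > 0
        else:
            out = 1.0 / (1.0 + np.exp(-x))
            self._cache = out * (1.0 - out)
        return out

    def backward(self, grad):
        return [grad * self._cache]


class UpSampling3D(Layer):
    """Nearest-neighbour up-sampling by an integer factor per axis."""

    kind = "upsampling"

    def __init__(self, factor: int = 2, name: str = ""):
        super().__init__(name)
        self.factor = factor

    def forward(self, inputs, training):
        (x,) = inputs
        f = self.factor
        self._in_shape = x.shape
        return x.repeat(f, axis=0).repeat(f, axis=1).repeat(f, axis=2)

    def backward(self, grad):
        d, h, w, c = self._in_shape
        f = self.factor
        g = grad.reshape(d, f, h, f, w, f, c)
        return [g.sum(axis=(1, 3, 5))]


class Add(Layer):
    kind = "add"

    def forward(self, inputs, training):
        a, b = inputs
        if a.shape != b.shape:
            raise ValueError(
                f"additive shortcut shape mismatch: {a.shape} vs {b.shape}"
            )
        return a + b

    def backward(self, grad):
        return [grad, grad]


class Concatenate(Layer):
    kind = "concatenate"

    def forward(self, inputs, training):
        a, b = inputs
        self._split = a.shape[-1]
        return np.concatenate([a, b], axis=-1)

    def backward(self, grad):
        s = self._split
        return [grad[..., :s], grad[..., s:]]


class Network:
    """An explicit DAG of layers executed in insertion (topological) order."""

    def __init__(self):
        self.layers: list[Layer] = []
        self._inputs: list[list[int]] = []
        self.output_index: int | None = None

    def add(self, layer: Layer, inputs: list[int]) -> int:
        for i in inputs:
            if not 0 <= i < len(self.layers):
                raise ValueError(f"unknown input node {i}")
        self.layers.append(layer)
        self._inputs.append(list(inputs))
        self.output_index = len(self.layers) - 1
        return self.output_index

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        acts: list[np.ndarray] = [None] * len(self.layers)
        for idx, (layer, srcs) in enumerate(zip(self.layers, self._inputs)):
            ins = [x] if not srcs else [acts[s] for s in srcs]
            acts[idx] = layer.forward(ins, training)
        self._acts = acts
        return acts[self.output_index]

    def backward(self, grad_out: np.ndarray) -> None:
        """Accumulate parameter gradients from d(loss)/d(output)."""
        grads: dict[int, np.ndarray] = {self.output_index: grad_out}
        for idx in range(len(self.layers) - 1, -1, -1):
            if idx not in grads:
                continue
            in_grads = self.layers[idx].backward(grads[idx])
            for src, g in zip(self._inputs[idx], in_grads):
                if src in grads:
                    grads[src] = grads[src] + g
                else:
                    grads[src] = g

    def zero_grads(self) -> None:
        for layer in self.layers:
            layer.grads = {}

    def parameters(self):
        """Yield (layer, param_name, array) for every trainable parameter."""
        for layer in self.layers:
            for name in layer.params:
                yield layer, name

    def count_parameters(self) -> tuple[int, int, int]:
        """(trainable, non_trainable, layer_count)."""
        trainable = sum(l.n_trainable for l in self.layers)
        non_trainable = sum(l.n_non_trainable for l in self.layers)
        return trainable, non_trainable, len(self.layers)

    def get_weights(self) -> list[dict[str, np.ndarray]]:
        return [
            {**{k: v.copy() for k, v in l.params.items()},
             **{k: v.copy() for k, v in l.state.items()}}
            for l in self.layers
        ]

    def set_weights(self, weights: list[dict[str, np.ndarray]]) -> None:
        if len(weights) != len(self.layers):
            raise ValueError("weight list does not match layer count")
        for layer, w in zip(self.layers, weights):
            for k in layer.params:
                layer.params[k] = w[k].copy()
            for k in layer.state:
                layer.state[k] = w[k].copy()


class Adam:
    """Adam with optional decoupled L2 applied through the loss gradient."""

    def __init__(self, net: Network, learning_rate: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.net = net
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m: dict[tuple[int, str], np.ndarray] = {}
        self.v: dict[tuple[int, str], np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for idx, layer in enumerate(self.net.layers):
            for name, grad in layer.grads.items():
                key = (idx, name)
                if key not in self.m:
                    self.m[key] = np.zeros_like(grad)
                    self.v[key] = np.zeros_like(grad)
                self.m[key] = b1 * self.m[key] + (1 - b1) * grad
                self.v[key] = b2 * self.v[key] + (1 - b2) * grad**2
                mhat = self.m[key] / (1 - b1**self.t)
                vhat = self.v[key] / (1 - b2**self.t)
                layer.params[name] = layer.params[name] - self.lr * mhat / (
                    np.sqrt(vhat) + self.eps
                )
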