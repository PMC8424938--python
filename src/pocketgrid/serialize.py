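"""Weight persistence: networks round-trip through HDF5.

The file stores every layer's parameter and state arrays plus the filter
schedule and build flags, so ``load_weights`` can rebuild an identical
graph before restoring the arrays.
"""

from __future__ import annotations

import json

import h5py

from .model import FilterSchedule, build_puresnet
from .nn import Network

__all__ = ["save_weights", "load_weights"]


def save_weights(
    net: Network,
    path,
    schedule: FilterSchedule | None = None,
    seed: int = 0,
    skip_connections: bool = True,
) -> None:
    from .model import DEFAULT_SCHEDULE, reduced_schedule

    if schedule is None:
        # infer: match against the two canonical schedules by parameter count
        schedule = _infer_schedule(net)
    meta = {
        "encoder": [list(p) for p in schedule.encoder],
        "decoder": [list(p) for p in schedule.decoder],
        "seed": seed,
        "skip_connections": skip_connections,
    }
    with h5py.File(path, "w") as fh:
        fh.attrs["meta"] = json.dumps(meta)
        for idx, layer in enumerate(net.layers):
            grp = fh.create_group(f"layer{idx:04d}")
            for name, arr in layer.params.items():
                grp.create_dataset(f"param_{name}", data=arr)
            for name, arr in layer.state.items():
                grp.create_dataset(f"state_{name}", data=arr)


def _infer_schedule(net: Network) -> FilterSchedule:
    from .model import DEFAULT_SCHEDULE, reduced_schedule

    n = net.count_parameters()[0]
    for candidate in (DEFAULT_SCHEDULE, reduced_schedule()):
        probe = build_puresnet(candidate)
        if probe.count_parameters()[0] == n:
            return candidate
    raise ValueError(
        "cannot infer the filter schedule from the network; pass schedule="
    )


def load_weights(path) -> Network:
    with h5py.File(path, "r") as fh:
        meta = json.loads(fh.attrs["meta"])
        schedule = FilterSchedule(
            encoder=tuple(tuple(p) for p in meta["encoder"]),
            decoder=tuple(tuple(p) for p in meta["decoder"]),
        )
        net = build_puresnet(
            schedule,
            seed=int(meta.get("seed", 0)),
            skip_connections=bool(meta.get("skip_connections", True)),
        )
        for idx, layer in enumerate(net.layers):
            grp = fh[f"layer{idx:04d}"]
            for name in list(layer.params):
                layer.params[name] = grp[f"param_{name}"][...]
            for name in list(layer.state):
                layer.state[name] = grp[f"state_{name}"][...]
    return net
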