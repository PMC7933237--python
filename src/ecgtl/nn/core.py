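"""Minimal reverse-mode neural-network core on numpy arrays.

Layers cache forward activations on a LIFO stack, so a layer may be run
several times inside one training step (e.g. the shared frame encoder in
contrastive pretraining) as long as ``backward`` calls happen in reverse
order of the ``forward`` calls.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = "") -> None:
        self.data = np.asarray(data)
        self.grad = np.zeros_like(self.data)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    """Base class: subclasses implement forward/backward and list params."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return self.forward(x, train=train)

    # -- weight (de)serialisation ------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for i, p in enumerate(self.params()):
            key = p.name or f"param_{i}"
            state[f"{i:04d}:{key}"] = p.data
        for name, buf in self.buffers().items():
            state[f"buf:{name}"] = buf
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = self.params()
        param_keys = sorted(k for k in state if not k.startswith("buf:"))
        if len(param_keys) != len(own):
            raise ValueError(
                f"state has {len(param_keys)} params, layer expects {len(own)}"
            )
        for key, p in zip(param_keys, own):
            arr = state[key]
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {key}: {arr.shape} vs {p.data.shape}"
                )
            p.data = arr.astype(p.data.dtype, copy=True)
            p.grad = np.zeros_like(p.data)
        bufs = self.buffers()
        for name in bufs:
            key = f"buf:{name}"
            if key in state:
                bufs[name][...] = state[key]

    def buffers(self) -> dict[str, np.ndarray]:
        """Non-trainable state (e.g. batch-norm running moments)."""
        return {}

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()

    def n_params(self) -> int:
        return int(sum(p.data.size for p in self.params()))


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        self.layers = list(layers)

    def params(self) -> list[Param]:
        out: list[Param] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def buffers(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            for name, buf in layer.buffers().items():
                out[f"{i}.{name}"] = buf
        return out

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


def copy_weights(layer: Layer) -> dict[str, np.ndarray]:
    return {k: v.copy() for k, v in layer.state_dict().items()}


def numerical_gradient(f, x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    """Central-difference gradient of scalar ``f`` wrt array ``x`` (test helper)."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        fp = f()
        x[idx] = orig - eps
        fm = f()
        x[idx] = orig
        g[idx] = (fp - fm) / (2 * eps)
        it.iternext()
    return g
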