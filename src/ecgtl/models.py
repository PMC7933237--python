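"""Model surface: encoder specs, classifier heads, the contrastive
future-prediction model, lead-count adaptation and checkpointing.

The encoder is a 1D pre-activation residual network (depths 18/34/50,
stage kernels 7/5/5/3). The contrastive model shares the encoder across
context and candidate frames, pools the context with transformer
attention into a vector ``c``, and scores each candidate ``h_i`` by the
plain dot product ``c . h_i`` followed by a softmax.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn

__all__ = ["ModelSpec", "AttentionPoolSpec", "build_encoder", "ClassifierModel",
           "CpcModel", "classify", "attention_pool", "cpc_probabilities",
           "adapt_input_channels", "replace_head", "save_checkpoint",
           "load_checkpoint"]


@dataclass(frozen=True)
class ModelSpec:
    depth: int = 18
    in_channels: int = 1
    n_classes: int | None = None
    width_multiplier: float = 1.0
    stage_kernels: tuple[int, int, int, int] = (7, 5, 5, 3)
    stages_used: int = 4

    def __post_init__(self) -> None:
        if self.depth not in (18, 34, 50):
            raise ValueError(f"depth must be 18, 34 or 50, got {self.depth}")
        if self.in_channels < 1:
            raise ValueError("in_channels must be >= 1")
        if len(self.stage_kernels) != 4:
            raise ValueError("stage_kernels must have length 4")
        if self.width_multiplier <= 0:
            raise ValueError("width_multiplier must be positive")


@dataclass(frozen=True)
class AttentionPoolSpec:
    n_layers: int = 3
    d_model: int = 512
    n_heads: int = 8
    d_ff: int | None = None      # defaults to 2 * d_model
    dropout: float = 0.0
    max_len: int = 64
    use_positional: bool = True

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        if self.dropout != 0.0:
            raise ValueError("only dropout=0 is supported (as configured)")

    @property
    def inner_dim(self) -> int:
        return 2 * self.d_model if self.d_ff is None else self.d_ff


def build_encoder(spec: ModelSpec, rng: np.random.Generator | None = None
                  ) -> nn.ResNet1D:
    """Build the residual encoder; output is the global-average-pooled
    feature vector (size depends on depth, width and stages used)."""
    return nn.ResNet1D(depth=spec.depth, in_channels=spec.in_channels,
                       width_multiplier=spec.width_multiplier,
                       stage_kernels=spec.stage_kernels,
                       stages_used=spec.stages_used, rng=rng)


class ClassifierModel(nn.Layer):
    """Encoder plus a fully connected classification head."""

    def __init__(self, encoder: nn.ResNet1D, n_classes: int,
                 activation: str = "softmax",
                 rng: np.random.Generator | None = None) -> None:
        if n_classes < 2:
            raise ValueError("need at least two classes")
        if activation not in ("softmax", "sigmoid"):
            raise ValueError(f"unknown output activation {activation!r}")
        self.encoder = encoder
        self.head = nn.Dense(encoder.out_features, n_classes, rng=rng)
        self.n_classes = n_classes
        self.activation = activation

    def params(self) -> list[nn.Param]:
        return self.encoder.params() + self.head.params()

    def buffers(self) -> dict[str, np.ndarray]:
        return {f"enc.{k}": v for k, v in self.encoder.buffers().items()}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return self.head.forward(self.encoder.forward(x, train), train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.encoder.backward(self.head.backward(dy))

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        logits = self.forward(x, train=False)
        if self.activation == "softmax":
            return nn.softmax(logits)
        return nn.sigmoid(logits)


def classify(model: ClassifierModel, batch: np.ndarray) -> np.ndarray:
    """Class probabilities for a batch of frames (rows sum to 1 for
    single-label heads)."""
    return model.predict_proba(batch)


def attention_pool(encodings: np.ndarray, pool: nn.AttentionPool,
                   train: bool = False) -> np.ndarray:
    """Pool (batch, frames, d_model) encodings into (batch, d_model)."""
    return pool.forward(encodings, train=train)


def cpc_probabilities(c: np.ndarray, candidates: np.ndarray) -> np.ndarray:
    """Softmax over dot-product similarities between the context vector
    and candidate encodings.

    ``c``: (d,) or (batch, d); ``candidates``: (k, d) or (batch, k, d).
    """
    c = np.asarray(c, dtype=np.float64)
    h = np.asarray(candidates, dtype=np.float64)
    squeeze = c.ndim == 1
    if squeeze:
        c, h = c[None], h[None]
    if c.shape[-1] != h.shape[-1]:
        raise ValueError("context and candidate encodings differ in size")
    scores = np.einsum("bd,bkd->bk", c, h)
    p = nn.softmax(scores)
    return p[0] if squeeze else p


class CpcModel(nn.Layer):
    """Contrastive future-prediction model: shared encoder + attention
    pooling + dot-product scoring.

    Input is a batch of stacked frames (batch, K + 1 + ns, channels,
    frame_length); candidate 0 is the positive future frame.
    """

    def __init__(self, encoder: nn.ResNet1D, context_size: int,
                 pool_spec: AttentionPoolSpec | None = None,
                 rng: np.random.Generator | None = None) -> None:
        rng = rng or np.random.default_rng()
        self.encoder = encoder
        self.context_size = context_size
        d_model = encoder.out_features
        spec = pool_spec or AttentionPoolSpec(d_model=d_model)
        if spec.d_model != d_model:
            raise ValueError(f"pool d_model {spec.d_model} != encoder output {d_model}")
        self.pool_spec = spec
        self.pool = nn.AttentionPool(d_model, n_heads=spec.n_heads,
                                     n_layers=spec.n_layers, d_ff=spec.inner_dim,
                                     max_len=spec.max_len,
                                     use_positional=spec.use_positional, rng=rng)

    def params(self) -> list[nn.Param]:
        return self.encoder.params() + self.pool.params()

    def buffers(self) -> dict[str, np.ndarray]:
        return {f"enc.{k}": v for k, v in self.encoder.buffers().items()}

    def forward(self, frames: np.ndarray, train: bool = True) -> np.ndarray:
        b, m, ch, length = frames.shape
        k = self.context_size
        if m <= k:
            raise ValueError("need at least one candidate beyond the context")
        enc = self.encoder.forward(frames.reshape(b * m, ch, length), train)
        enc = enc.reshape(b, m, -1)
        c = self.pool.forward(enc[:, :k, :], train)
        cands = enc[:, k:, :]
        logits = np.einsum("bd,bkd->bk", c, cands, optimize=True)
        if train:
            self._fwd = (enc, c, cands, frames.shape)
        return logits

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        enc, c, cands, shape = self._fwd
        b, m, ch, length = shape
        k = self.context_size
        dc = np.einsum("bk,bkd->bd", dlogits, cands, optimize=True)
        dcands = np.einsum("bk,bd->bkd", dlogits, c, optimize=True)
        denc = np.zeros_like(enc)
        denc[:, k:, :] = dcands
        denc[:, :k, :] += self.pool.backward(dc.astype(enc.dtype))
        dx = self.encoder.backward(denc.reshape(b * m, -1).astype(np.float32))
        return dx.reshape(shape)


def adapt_input_channels(weights: np.ndarray, new_in_channels: int) -> np.ndarray:
    """Adapt single-channel first-layer filters to more input channels.

    Filters are duplicated across channels and every weight is scaled by
    the ratio of original to adjusted channel counts (1/new), so a
    signal replicated across all channels produces the original output.
    """
    w = np.asarray(weights)
    if w.ndim != 3 or w.shape[1] != 1:
        raise ValueError("expected (out_channels, 1, kernel) weights")
    if new_in_channels < 1:
        raise ValueError("new_in_channels must be >= 1")
    return np.tile(w, (1, new_in_channels, 1)) / new_in_channels


def adapt_encoder_channels(encoder: nn.ResNet1D, new_in_channels: int) -> None:
    """In-place lead-count adaptation of an encoder's stem convolution."""
    conv = encoder.stem_conv
    conv.w.data = adapt_input_channels(conv.w.data, new_in_channels).astype(
        conv.w.data.dtype)
    conv.w.grad = np.zeros_like(conv.w.data)
    conv.in_channels = new_in_channels
    encoder.in_channels = new_in_channels


def transfer_encoder_weights(src: nn.ResNet1D, dst: nn.ResNet1D) -> int:
    """Copy pretrained weights into a (possibly deeper) encoder.

    The stem and every stage present in both encoders are copied; stages
    beyond the source's (e.g. stage 4 when only the first 3 stages were
    pretrained) keep their fresh initialisation, as does the final norm
    when the source was truncated. Returns the number of stages copied.
    """
    if src.depth != dst.depth or src.width_multiplier != dst.width_multiplier:
        raise ValueError("encoders differ in depth or width")
    if src.in_channels != dst.in_channels:
        raise ValueError("encoders differ in input channels")
    shared = min(src.stages_used, dst.stages_used)

    def _copy(a: nn.Layer, b: nn.Layer) -> None:
        for ps, pd in zip(a.params(), b.params()):
            pd.data = ps.data.copy()
            pd.grad = np.zeros_like(pd.data)
        for name, buf in a.buffers().items():
            b.buffers()[name][...] = buf
    _copy(src.stem_conv, dst.stem_conv)
    for i in range(shared):
        for blk_s, blk_d in zip(src.stages[i], dst.stages[i]):
            _copy(blk_s, blk_d)
    if src.stages_used == dst.stages_used:
        _copy(src.final_bn, dst.final_bn)
    return shared


def replace_head(model: ClassifierModel | nn.ResNet1D, n_classes: int,
                 output_activation: str = "softmax",
                 rng: np.random.Generator | None = None) -> ClassifierModel:
    """Put a freshly initialised head on a (pre)trained encoder.

    Encoder weights are untouched; finetuning is end-to-end, nothing is
    frozen.
    """
    encoder = model.encoder if isinstance(model, ClassifierModel) else model
    return ClassifierModel(encoder, n_classes, activation=output_activation, rng=rng)


# ------------------------------------------------------------- checkpoints

def save_checkpoint(path: str | Path, model: nn.Layer,
                    spec: ModelSpec | None = None, extra: dict | None = None) -> None:
    """Weights as .npz plus a JSON sidecar describing the model spec."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.state_dict())
    meta = {"spec": asdict(spec) if spec else None, "extra": extra or {}}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(path: str | Path, model: nn.Layer,
                    expect_spec: ModelSpec | None = None) -> dict:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    if expect_spec is not None and meta.get("spec") is not None:
        saved = dict(meta["spec"])
        saved["stage_kernels"] = tuple(saved["stage_kernels"])
        if ModelSpec(**saved) != expect_spec:
            raise ValueError("checkpoint spec does not match the expected spec")
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return meta
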