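"""Segmentation network definitions: basic 3-D U-Net and a dual-attention
variant.

Both map an image patch of the configured window shape to a per-voxel
probability map over the three classes (background, cranial cavity,
extracranial arteries).  The dual-attention variant adds parallel
position- and channel-attention blocks at the bottleneck whose outputs
are summed into the bottleneck features; both attention residual gains
start at zero, so an untrained dual-attention network computes the same
function as its basic counterpart while carrying strictly more
parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

from .core import ValidationError
from . import nn

ARCHITECTURES = ("basic_unet", "dual_attention_unet")


@dataclass(frozen=True)
class ArchConfig:
    architecture: str = "dual_attention_unet"
    window_shape: Tuple[int, int, int] = (160, 160, 48)
    base_filters: int = 16
    depth: int = 4
    instance_norm: bool = True
    l2_strength: float = 2e-4
    class_count: int = 3

    def __post_init__(self):
        if self.architecture not in ARCHITECTURES:
            raise ValidationError(
                f"architecture: must be one of {ARCHITECTURES}, "
                f"got {self.architecture!r}"
            )
        ws = tuple(int(w) for w in self.window_shape)
        div = 2**self.depth
        if any(w % div for w in ws):
            raise ValidationError(
                f"window_shape {ws} must be divisible by 2^depth = {div} "
                "on every axis"
            )
        if self.l2_strength < 0:
            raise ValidationError(f"l2_strength must be >= 0, got {self.l2_strength}")
        if self.base_filters < 1 or self.depth < 1:
            raise ValidationError("base_filters and depth must be >= 1")
        if self.class_count != 3:
            raise ValidationError("class_count is fixed at 3")
        object.__setattr__(self, "window_shape", ws)

    def to_dict(self) -> Dict:
        return {
            "architecture": self.architecture,
            "window_shape": list(self.window_shape),
            "base_filters": self.base_filters,
            "depth": self.depth,
            "instance_norm": self.instance_norm,
            "l2_strength": self.l2_strength,
            "class_count": self.class_count,
        }

    @staticmethod
    def from_dict(d: Dict) -> "ArchConfig":
        return ArchConfig(
            architecture=d["architecture"],
            window_shape=tuple(d["window_shape"]),
            base_filters=int(d["base_filters"]),
            depth=int(d["depth"]),
            instance_norm=bool(d["instance_norm"]),
            l2_strength=float(d["l2_strength"]),
            class_count=int(d["class_count"]),
        )


class _ConvBlock:
    """conv3 -> [IN] -> ReLU, twice."""

    def __init__(self, cin, cout, use_in, rng):
        self.layers = []
        for i, (a, b) in enumerate([(cin, cout), (cout, cout)]):
            self.layers.append((f"conv{i}", nn.Conv3d(a, b, 3, rng)))
            if use_in:
                self.layers.append((f"in{i}", nn.InstanceNorm(b)))
            self.layers.append((f"relu{i}", nn.ReLU()))

    def forward(self, x, train=True):
        for _, l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, d):
        for _, l in reversed(self.layers):
            d = l.backward(d)
        return d


class UNet3D:
    """A 3-D U-Net over channels-first patches, with optional dual attention.

    ``forward`` accepts ``(N, 1, X, Y, Z)`` (or an unbatched patch via
    :meth:`predict_probs`) and returns per-voxel class probabilities that
    sum to one for arbitrary weights (softmax head).
    """

    def __init__(self, cfg: ArchConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        f, d, use_in = cfg.base_filters, cfg.depth, cfg.instance_norm
        self.enc: List[_ConvBlock] = []
        self.pools: List[nn.MaxPool2] = []
        cin = 1
        for i in range(d):
            self.enc.append(_ConvBlock(cin, f * 2**i, use_in, rng))
            self.pools.append(nn.MaxPool2())
            cin = f * 2**i
        cb = f * 2**d
        self.bottleneck = _ConvBlock(cin, cb, use_in, rng)
        self.dual = cfg.architecture == "dual_attention_unet"
        if self.dual:
            self.pos_att = nn.PositionAttention(cb, rng)
            self.chan_att = nn.ChannelAttention(cb)
        self.ups: List[nn.Upsample2] = []
        self.dec: List[_ConvBlock] = []
        cprev = cb
        for i in reversed(range(d)):
            self.ups.append(nn.Upsample2())
            self.dec.append(_ConvBlock(cprev + f * 2**i, f * 2**i, use_in, rng))
            cprev = f * 2**i
        self.head = nn.Conv3d(cprev, cfg.class_count, 1, rng)
        self.softmax = nn.SoftmaxC()

    # ---- plumbing -------------------------------------------------------
    def _named_layers(self):
        for i, blk in enumerate(self.enc):
            for n, l in blk.layers:
                yield f"enc{i}.{n}", l
        for n, l in self.bottleneck.layers:
            yield f"bottleneck.{n}", l
        if self.dual:
            yield "pos_att", self.pos_att
            yield "chan_att", self.chan_att
        for i, blk in enumerate(self.dec):
            for n, l in blk.layers:
                yield f"dec{i}.{n}", l
        yield "head", self.head

    def parameters(self) -> Dict[str, np.ndarray]:
        out = {}
        for ln, l in self._named_layers():
            for pn, p in l.params().items():
                out[f"{ln}.{pn}"] = p
        return out

    def gradients(self) -> Dict[str, np.ndarray]:
        out = {}
        for ln, l in self._named_layers():
            for pn, g in l.grads().items():
                out[f"{ln}.{pn}"] = g
        return out

    @property
    def param_count(self) -> int:
        return int(sum(p.size for p in self.parameters().values()))

    @property
    def window_shape(self) -> Tuple[int, int, int]:
        return self.cfg.window_shape

    def state_dict(self) -> Dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        params = self.parameters()
        missing = set(params) ^ set(state)
        if missing:
            raise ValidationError(f"state dict keys mismatch: {sorted(missing)}")
        for k, p in params.items():
            if p.shape != state[k].shape:
                raise ValidationError(
                    f"shape mismatch for {k}: {p.shape} vs {state[k].shape}"
                )
            p[...] = state[k]

    # ---- compute --------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        skips = []
        for blk, pool in zip(self.enc, self.pools):
            x = blk.forward(x, train=train)
            skips.append(x)
            x = pool.forward(x, train=train)
        x = self.bottleneck.forward(x, train=train)
        if self.dual:
            x = (
                self.pos_att.forward(x, train=train)
                + self.chan_att.forward(x, train=train)
                - x  # both blocks are residual; sum their increments once
            )
        self._skip_channels = []
        for up, blk, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x, train=train)
            self._skip_channels.append(skip.shape[1])
            x = np.concatenate([x, skip], axis=1)
            x = blk.forward(x, train=train)
        x = self.head.forward(x, train=train)
        return self.softmax.forward(x, train=train)

    def backward(self, dprobs: np.ndarray) -> None:
        d = self.softmax.backward(dprobs)
        d = self.head.backward(d)
        dskips = []
        for blk, up, cs in zip(
            reversed(self.dec), reversed(self.ups), reversed(self._skip_channels)
        ):
            d = blk.backward(d)
            dskips.append(d[:, -cs:])
            d = up.backward(np.ascontiguousarray(d[:, :-cs]))
        dskips.reverse()  # dskips[i] pairs with dec[i] (deepest skip first)
        if self.dual:
            d = self.pos_att.backward(d) + self.chan_att.backward(d) - d
        d = self.bottleneck.backward(d)
        for blk, pool, dskip in zip(
            reversed(self.enc), reversed(self.pools), dskips
        ):
            d = pool.backward(d)
            d = d + dskip
            d = blk.backward(d)

    def predict_probs(self, patch: np.ndarray) -> np.ndarray:
        """Inference on one unbatched patch -> (class_count, X, Y, Z)."""
        x = np.asarray(patch, dtype=np.float32)[None, None]
        return self.forward(x, train=False)[0]


def build_network(cfg: ArchConfig, seed: int = 0) -> UNet3D:
    """Instantiate a randomly initialized network for ``cfg``."""
    return UNet3D(cfg, seed=seed)
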