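"""A compact numpy encoder–decoder (U-Net) with hand-written backprop.

The network maps an (N, H, W, 3) image batch to (N, H, W) logits. Each
encoder level is two 3x3 conv + ReLU blocks followed by 2x2 max pooling; the
decoder mirrors it with nearest-neighbour upsampling, skip concatenation and
one 3x3 conv + ReLU per level; a final 1x1 conv produces the logit map.
Convolutions are stride-1, zero-padded ("same"), computed via im2col and a
single matmul, which keeps training on small fixture images practical on one
CPU. H and W must be divisible by 2**depth.

Two presets are exposed through :class:`ModelSpec`: ``tiny`` (~27k
parameters, for tests and fixture-scale pipelines) and ``base`` (~440k
parameters). The original study used an ImageNet-pretrained EfficientNet-B4
U-Net; the encoder here is deliberately configurable and self-contained —
no pretrained weights are bundled, so ``pretrained_init`` must stay off.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import as_strided

from .errors import InputError, ShapeError

PRESETS = {
    "tiny": {"widths": (8, 16), "bottleneck": 32},
    "base": {"widths": (16, 32, 64), "bottleneck": 128},
}


@dataclass
class ModelSpec:
    """Architecture configuration for :func:`build_model`."""

    encoder_name: str = "base"
    decoder_widths: tuple[int, ...] | None = None  # default: mirror encoder widths
    pretrained_init: bool = False
    widths: tuple[int, ...] | None = None  # explicit override of the preset
    bottleneck: int | None = None

    def resolve(self) -> tuple[tuple[int, ...], int, tuple[int, ...]]:
        if self.widths is not None:
            widths = tuple(self.widths)
            bottleneck = self.bottleneck or widths[-1] * 2
        elif self.encoder_name in PRESETS:
            preset = PRESETS[self.encoder_name]
            widths = preset["widths"]
            bottleneck = preset["bottleneck"]
        else:
            raise InputError(
                f"unknown encoder {self.encoder_name!r}; available: {sorted(PRESETS)}"
            )
        dec = tuple(self.decoder_widths) if self.decoder_widths else widths
        if len(dec) != len(widths):
            raise InputError("decoder_widths must have one entry per encoder level")
        return widths, bottleneck, dec

    @property
    def input_size_divisor(self) -> int:
        widths, _, _ = self.resolve()
        return 2 ** len(widths)


def _im2col3(xp: np.ndarray, H: int, W: int) -> np.ndarray:
    """(N, C, H+2, W+2) zero-padded input -> (N, H*W, C*9) patch matrix."""
    N, C = xp.shape[:2]
    s0, s1, s2, s3 = xp.strides
    v = as_strided(xp, (N, H, W, C, 3, 3), (s0, s2, s3, s1, s2, s3))
    return np.ascontiguousarray(v).reshape(N, H * W, C * 9)


class _Conv3x3:
    """Same-padded 3x3 convolution; weights (C*9, F), He-initialized."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (cin * 9))
        self.W = (rng.standard_normal((cin * 9, cout)) * scale).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols = None
        self._shape = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        N, C, H, W = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        cols = _im2col3(xp, H, W).reshape(N * H * W, C * 9)
        y = cols @ self.W + self.b
        if train:
            self._cols, self._shape = cols, (N, C, H, W)
        return y.reshape(N, H * W, -1).transpose(0, 2, 1).reshape(N, -1, H, W)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        N, C, H, W = self._shape
        F = self.W.shape[1]
        dym = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(N * H * W, F)
        self.dW += self._cols.T @ dym
        self.db += dym.sum(axis=0)
        # dX is the correlation of dY with the spatially flipped kernels
        # (transposed convolution), done as one im2col + matmul
        wk = self.W.reshape(C, 9, F)[:, ::-1]  # flip the 3x3 taps
        wback = np.ascontiguousarray(wk.transpose(2, 1, 0)).reshape(F * 9, C)
        dyp = np.pad(dy, ((0, 0), (0, 0), (1, 1), (1, 1)))
        dycols = _im2col3(dyp, H, W).reshape(N * H * W, F * 9)
        dx = (dycols @ wback).reshape(N, H, W, C).transpose(0, 3, 1, 2)
        self._cols = None
        return dx

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class _Conv1x1:
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / cin)
        self.W = (rng.standard_normal((cin, cout)) * scale).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        y = np.einsum("nchw,cf->nfhw", x, self.W) + self.b[None, :, None, None]
        if train:
            self._x = x
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW += np.einsum("nchw,nfhw->cf", self._x, dy)
        self.db += dy.sum(axis=(0, 2, 3))
        dx = np.einsum("nfhw,cf->nchw", dy, self.W)
        self._x = None
        return dx

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class _ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._mask
        self._mask = None
        return dx

    def params(self):
        return []


def _pool2_forward(x: np.ndarray):
    N, C, H, W = x.shape
    xr = (
        x.reshape(N, C, H // 2, 2, W // 2, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(N, C, H // 2, W // 2, 4)
    )
    idx = xr.argmax(axis=-1)
    y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return y, idx


def _pool2_backward(dy: np.ndarray, idx: np.ndarray, shape) -> np.ndarray:
    N, C, H, W = shape
    dxr = np.zeros((N, C, H // 2, W // 2, 4), dtype=dy.dtype)
    np.put_along_axis(dxr, idx[..., None], dy[..., None], axis=-1)
    return (
        dxr.reshape(N, C, H // 2, W // 2, 2, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(N, C, H, W)
    )


def _up2(x: np.ndarray) -> np.ndarray:
    return x.repeat(2, axis=2).repeat(2, axis=3)


def _up2_backward(dy: np.ndarray) -> np.ndarray:
    N, C, H, W = dy.shape
    return dy.reshape(N, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5))


class UNet:
    """Encoder–decoder producing one logit per pixel."""

    def __init__(self, spec: ModelSpec | None = None, seed: int = 0):
        self.spec = spec or ModelSpec()
        if self.spec.pretrained_init:
            raise InputError(
                "pretrained_init is not supported: no pretrained weights are "
                "bundled with this package; use seeded random initialization"
            )
        widths, bottleneck, dec_widths = self.spec.resolve()
        self.widths, self.bottleneck, self.dec_widths = widths, bottleneck, dec_widths
        self.divisor = 2 ** len(widths)
        rng = np.random.default_rng(seed)
        self.enc: list[tuple] = []
        cin = 3
        for wdt in widths:
            self.enc.append(
                (_Conv3x3(cin, wdt, rng), _ReLU(), _Conv3x3(wdt, wdt, rng), _ReLU())
            )
            cin = wdt
        self.mid = (
            _Conv3x3(cin, bottleneck, rng),
            _ReLU(),
            _Conv3x3(bottleneck, bottleneck, rng),
            _ReLU(),
        )
        self.dec: list[tuple] = []
        cin = bottleneck
        for wdt, skip in zip(reversed(dec_widths), reversed(widths)):
            self.dec.append((_Conv3x3(cin + skip, wdt, rng), _ReLU()))
            cin = wdt
        self.head = _Conv1x1(cin, 1, rng)
        self._cache = None

    # -- forward / backward -------------------------------------------------

    def forward(self, images: np.ndarray, train: bool = False) -> np.ndarray:
        """(N, H, W, 3) in [0,1] -> (N, H, W) logits."""
        images = np.asarray(images, dtype=self.head.W.dtype)
        if images.ndim == 3:
            images = images[None]
        N, H, W, C = images.shape
        if C != 3:
            raise ShapeError(f"expected 3 channels, got {C}")
        if H % self.divisor or W % self.divisor:
            raise ShapeError(
                f"input {H}x{W} not divisible by {self.divisor}; pad the image "
                f"to a multiple of {self.divisor}"
            )
        x = (images - 0.5).transpose(0, 3, 1, 2).copy()
        skips, pools = [], []
        for c1, r1, c2, r2 in self.enc:
            x = r2.forward(c2.forward(r1.forward(c1.forward(x, train), train), train), train)
            skips.append(x)
            y, idx = _pool2_forward(x)
            pools.append((idx, x.shape))
            x = y
        c1, r1, c2, r2 = self.mid
        x = r2.forward(c2.forward(r1.forward(c1.forward(x, train), train), train), train)
        splits = []
        for (conv, relu), skip in zip(self.dec, reversed(skips)):
            x = _up2(x)
            splits.append(x.shape[1])
            x = np.concatenate([x, skip], axis=1)
            x = relu.forward(conv.forward(x, train), train)
        logits = self.head.forward(x, train)[:, 0]
        if train:
            self._cache = (pools, splits)
        return logits

    def backward(self, dlogits: np.ndarray) -> None:
        """Accumulate parameter gradients from d(loss)/d(logits)."""
        pools, splits = self._cache
        dx = self.head.backward(np.asarray(dlogits, dtype=np.float32)[:, None])
        dskips = []  # gradients for skip tensors, outermost level first
        for (conv, relu), ch in zip(self.dec[::-1], splits[::-1]):
            dcat = conv.backward(relu.backward(dx))
            dup, dskip = dcat[:, :ch], dcat[:, ch:]
            dskips.append(dskip)
            dx = _up2_backward(dup)
        c1, r1, c2, r2 = self.mid
        dx = c1.backward(r1.backward(c2.backward(r2.backward(dx))))
        for (c1, r1, c2, r2), (idx, shape), dskip in zip(
            self.enc[::-1], pools[::-1], dskips[::-1]
        ):
            dx = _pool2_backward(dx, idx, shape) + dskip
            dx = c1.backward(r1.backward(c2.backward(r2.backward(dx))))
        self._cache = None

    # -- parameters ----------------------------------------------------------

    def _layers(self):
        out = []
        for block in self.enc:
            out.extend(block)
        out.extend(self.mid)
        for block in self.dec:
            out.extend(block)
        out.append(self.head)
        return out

    def parameters(self):
        pairs = []
        for layer in self._layers():
            pairs.extend(layer.params())
        return pairs

    def zero_grad(self) -> None:
        for _, g in self.parameters():
            g[...] = 0.0

    def n_parameters(self) -> int:
        return int(sum(p.size for p, _ in self.parameters()))

    def cast(self, dtype) -> "UNet":
        """Convert all parameters to ``dtype`` (e.g. float64 for grad checks)."""
        for layer in self._layers():
            if hasattr(layer, "W"):
                layer.W = layer.W.astype(dtype)
                layer.b = layer.b.astype(dtype)
                layer.dW = layer.dW.astype(dtype)
                layer.db = layer.db.astype(dtype)
        return self

    # -- (de)serialization -----------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.copy() for i, (p, _) in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise InputError(
                f"checkpoint has {len(state)} tensors, model expects {len(params)}"
            )
        for i, (p, _) in enumerate(params):
            src = state[f"p{i}"]
            if src.shape != p.shape:
                raise InputError(f"tensor p{i} shape {src.shape} != model {p.shape}")
            p[...] = src


class SGD:
    """Plain SGD with optional momentum."""

    def __init__(self, net: UNet, lr: float = 0.01, momentum: float = 0.9):
        self.net = net
        self.lr = lr
        self.momentum = momentum
        self._vel = [np.zeros_like(p) for p, _ in net.parameters()]

    def step(self) -> None:
        for v, (p, g) in zip(self._vel, self.net.parameters()):
            if self.momentum:
                v *= self.momentum
                v -= self.lr * g
                p += v
            else:
                p -= self.lr * g


def build_model(spec: ModelSpec | None = None, seed: int = 0) -> UNet:
    """Construct a seeded segmentation network from a spec."""
    return UNet(spec=spec, seed=seed)


def predict_probs(model: UNet, image: np.ndarray) -> np.ndarray:
    """Per-pixel head probability: elementwise sigmoid of the logits.

    Accepts one (H, W, 3) image with H, W divisible by the model stride;
    returns an (H, W) array with values in the open interval (0, 1).
    """
    from scipy.special import expit

    image = np.asarray(image)
    squeeze = image.ndim == 3
    logits = model.forward(image[None] if squeeze else image)
    probs = expit(logits[0] if squeeze else logits)
    return np.clip(probs, 1e-12, 1 - 1e-12)


def save_checkpoint(
    path: str | Path,
    model: UNet,
    meta: dict | None = None,
) -> Path:
    """Weights as .npz plus a sidecar JSON (spec, seed, epoch, val loss)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.state_dict())
    sidecar = {
        "encoder_name": model.spec.encoder_name,
        "widths": list(model.widths),
        "bottleneck": model.bottleneck,
        "decoder_widths": list(model.dec_widths),
    }
    sidecar.update(meta or {})
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def load_checkpoint(path: str | Path) -> tuple[UNet, dict]:
    path = Path(path)
    if not path.exists():
        raise InputError(f"checkpoint not found: {path}")
    meta = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    spec = ModelSpec(
        encoder_name=meta.get("encoder_name", "base"),
        widths=tuple(meta["widths"]) if "widths" in meta else None,
        bottleneck=meta.get("bottleneck"),
        decoder_widths=tuple(meta["decoder_widths"]) if "decoder_widths" in meta else None,
    )
    net = UNet(spec=spec)
    with np.load(path) as data:
        net.load_state_dict({k: data[k] for k in data.files})
    return net, meta
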