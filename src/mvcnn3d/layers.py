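"""Volumetric network primitives.

Tensors are channels-last throughout: a batch has shape ``(S, Z, M, N, K)``
with ``Z`` the slice (depth) axis, ``M``/``N`` the in-plane axes and ``K``
the channel axis.  One channel of one sample is a 3D feature volume.

The 3D convolution is the plain quadruple-sum cross-correlation

    y[z', i', j', k'] = sum_{z,i,j,k} w[z, i, j, k, k'] * x[z+z', i+i', j+j', k]

with stride 1; it is evaluated as a single GEMM over an im2col patch matrix.
Backward passes are analytic (col2im scatter for the input gradient), so the
whole stack trains with mini-batch SGD on a CPU with no autodiff dependency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FilterBank",
    "PoolSpec",
    "DropoutSpec",
    "conv3d",
    "relu",
    "pool3d",
    "Layer",
    "Conv3D",
    "ReLU",
    "MaxPool3D",
    "AvgPool3D",
    "Flatten",
    "Dense",
    "Dropout",
    "SpatialDropout",
    "Sequential",
    "ConcatBranches",
    "Residual",
    "softmax",
    "SGD",
]

DTYPE = np.float32


# ---------------------------------------------------------------------------
# declarative specs
# ---------------------------------------------------------------------------


@dataclass
class FilterBank:
    """A bank of 3D filters: ``weights`` has shape (Zf, Mf, Nf, K, K')."""

    weights: np.ndarray
    biases: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.weights.ndim != 5:
            raise ValueError("filter weights must be 5D (Zf, Mf, Nf, K, K')")
        if self.biases is None:
            self.biases = np.zeros(self.weights.shape[-1], dtype=self.weights.dtype)

    @property
    def kernel(self) -> tuple[int, int, int]:
        return self.weights.shape[:3]

    @property
    def in_channels(self) -> int:
        return self.weights.shape[3]

    @property
    def out_channels(self) -> int:
        return self.weights.shape[4]


@dataclass
class PoolSpec:
    sizes: tuple[int, int, int]
    mode: str = "max"  # "max" | "average"
    strides: tuple[int, int, int] | None = None  # default: stride = size

    def __post_init__(self) -> None:
        if any(p < 1 for p in self.sizes):
            raise ValueError("pool sizes must be >= 1")
        if self.mode not in ("max", "average"):
            raise ValueError(f"unknown pool mode {self.mode!r}")
        if self.strides is None:
            self.strides = tuple(self.sizes)


@dataclass
class DropoutSpec:
    rate: float
    kind: str = "unit"  # "unit" | "spatial"

    def __post_init__(self) -> None:
        if not 0.0 < self.rate < 1.0:
            raise ValueError("dropout rate must lie in (0, 1)")
        if self.kind not in ("unit", "spatial"):
            raise ValueError(f"unknown dropout kind {self.kind!r}")


# ---------------------------------------------------------------------------
# functional primitives
# ---------------------------------------------------------------------------


def _same_pad(k: int) -> tuple[int, int]:
    return ((k - 1) // 2, k - 1 - (k - 1) // 2)


def _im2col(x: np.ndarray, kernel: tuple[int, int, int]) -> np.ndarray:
    """Patch matrix of shape (S*P, Zf*Mf*Nf*K) for stride-1 windows."""
    s = x.shape[0]
    win = np.lib.stride_tricks.sliding_window_view(x, kernel, axis=(1, 2, 3))
    # win: (S, Zo, Mo, No, K, Zf, Mf, Nf) -> (S, Zo, Mo, No, Zf, Mf, Nf, K)
    win = np.moveaxis(win, 4, 7)
    out_sp = win.shape[1:4]
    cols = np.ascontiguousarray(win).reshape(s * int(np.prod(out_sp)), -1)
    return cols, out_sp


def conv3d(x: np.ndarray, f: FilterBank, padding: str = "valid") -> np.ndarray:
    """Stride-1 3D convolution of a (S, Z, M, N, K) batch with a filter bank."""
    if x.ndim != 5:
        raise ValueError("input must be 5D (S, Z, M, N, K)")
    if x.shape[-1] != f.in_channels:
        raise ValueError(
            f"channel mismatch: input has {x.shape[-1]}, filters expect {f.in_channels}"
        )
    if padding == "same":
        pads = [(0, 0)] + [_same_pad(k) for k in f.kernel] + [(0, 0)]
        x = np.pad(x, pads)
    elif padding != "valid":
        raise ValueError(f"unknown padding {padding!r}")
    if any(x.shape[1 + a] < f.kernel[a] for a in range(3)):
        raise ValueError("kernel larger than (padded) input")
    cols, out_sp = _im2col(x, f.kernel)
    wmat = f.weights.reshape(-1, f.out_channels)
    y = cols @ wmat + f.biases
    return y.reshape(x.shape[0], *out_sp, f.out_channels)


def relu(x: np.ndarray) -> np.ndarray:
    """Elementwise rectifier max(0, x)."""
    return np.maximum(x, 0)


def pool3d(x: np.ndarray, p: PoolSpec) -> np.ndarray:
    """Non-overlapping 3D pooling (stride = window) over a (S,Z,M,N,K) batch.

    Output spatial sizes floor to ``dim // size``; trailing remainders are
    dropped. A window larger than the input in any axis is an error.
    """
    if x.ndim != 5:
        raise ValueError("input must be 5D (S, Z, M, N, K)")
    if tuple(p.strides) != tuple(p.sizes):
        raise NotImplementedError("only stride == window pooling is provided")
    if any(x.shape[1 + a] < p.sizes[a] for a in range(3)):
        raise ValueError("pool window larger than input")
    blocks, _ = _pool_blocks(x, p.sizes)
    if p.mode == "max":
        return blocks.max(axis=(2, 4, 6))
    return blocks.mean(axis=(2, 4, 6))


def _pool_blocks(x: np.ndarray, sizes: tuple[int, int, int]):
    s, z, m, n, k = x.shape
    p1, p2, p3 = sizes
    zo, mo, no = z // p1, m // p2, n // p3
    xc = x[:, : zo * p1, : mo * p2, : no * p3, :]
    return xc.reshape(s, zo, p1, mo, p2, no, p3, k), (zo, mo, no)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# trainable layers
# ---------------------------------------------------------------------------


class Layer:
    """Base layer: stateless unless it owns parameters."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def iter_layers(self):
        yield self


class Conv3D(Layer):
    def __init__(
        self,
        kernel: tuple[int, int, int],
        in_channels: int,
        out_channels: int,
        padding: str = "same",
        rng: np.random.Generator | None = None,
        needs_input_grad: bool = True,
    ) -> None:
        super().__init__()
        self.kernel = tuple(kernel)
        self.padding = padding
        # first-layer convs can skip the (expensive) input-gradient pass
        self.needs_input_grad = needs_input_grad
        fan_in = int(np.prod(kernel)) * in_channels
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / fan_in)
        w = rng.normal(0.0, scale, size=(*self.kernel, in_channels, out_channels))
        self.w = w.astype(DTYPE)
        self.b = np.zeros(out_channels, dtype=DTYPE)
        self.params = [self.w, self.b]
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.grads = [self.dw, self.db]
        self._cache = None

    @property
    def in_channels(self) -> int:
        return self.w.shape[3]

    @property
    def out_channels(self) -> int:
        return self.w.shape[4]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.shape[-1] != self.in_channels:
            raise ValueError(
                f"channel mismatch: got {x.shape[-1]}, expected {self.in_channels}"
            )
        xp = x.astype(DTYPE, copy=False)
        if self.padding == "same":
            pads = [(0, 0)] + [_same_pad(k) for k in self.kernel] + [(0, 0)]
            xp = np.pad(xp, pads)
        cols, out_sp = _im2col(xp, self.kernel)
        wmat = self.w.reshape(-1, self.out_channels)
        y = cols @ wmat + self.b
        if training:
            self._cache = (cols, xp.shape, out_sp)
        else:
            self._cache = (None, xp.shape, out_sp)
        return y.reshape(x.shape[0], *out_sp, self.out_channels)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, padded_shape, out_sp = self._cache
        s = dy.shape[0]
        dym = dy.reshape(-1, self.out_channels).astype(DTYPE, copy=False)
        self.dw[...] = (cols.T @ dym).reshape(self.w.shape)
        self.db[...] = dym.sum(axis=0)
        if not self.needs_input_grad:
            self._cache = None
            return None
        # input gradient: scatter dcols back over the kernel offsets
        wmat = self.w.reshape(-1, self.out_channels)
        dcols = (dym @ wmat.T).reshape(s, *out_sp, *self.kernel, self.in_channels)
        dxp = np.zeros(padded_shape, dtype=DTYPE)
        zo, mo, no = out_sp
        for dz in range(self.kernel[0]):
            for dm in range(self.kernel[1]):
                for dn in range(self.kernel[2]):
                    dxp[:, dz : dz + zo, dm : dm + mo, dn : dn + no, :] += dcols[
                        :, :, :, :, dz, dm, dn, :
                    ]
        if self.padding == "same":
            sl = [slice(None)]
            for a, k in enumerate(self.kernel):
                lo, hi = _same_pad(k)
                sl.append(slice(lo, padded_shape[1 + a] - hi))
            sl.append(slice(None))
            dxp = dxp[tuple(sl)]
        self._cache = None
        return dxp


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class _Pool3D(Layer):
    mode = "max"

    def __init__(self, sizes: tuple[int, int, int], clip: bool = False) -> None:
        super().__init__()
        self.sizes = tuple(sizes)
        self.clip = clip

    def _effective(self, shape) -> tuple[int, int, int]:
        if not self.clip:
            return self.sizes
        return tuple(min(p, shape[1 + a]) for a, p in enumerate(self.sizes))

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        sizes = self._effective(x.shape)
        if any(x.shape[1 + a] < sizes[a] for a in range(3)):
            raise ValueError("pool window larger than input")
        blocks, out_sp = _pool_blocks(x, sizes)
        if self.mode == "max":
            y = blocks.max(axis=(2, 4, 6))
            self._cache = (x.shape, sizes, blocks, y)
        else:
            y = blocks.mean(axis=(2, 4, 6))
            self._cache = (x.shape, sizes, None, None)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        in_shape, sizes, blocks, y = self._cache
        s, _, _, _, k = in_shape
        p1, p2, p3 = sizes
        dyb = dy[:, :, None, :, None, :, None, :]
        if self.mode == "max":
            mask = blocks == y[:, :, None, :, None, :, None, :]
            counts = mask.sum(axis=(2, 4, 6), keepdims=True)
            dblocks = mask * (dyb / counts)
        else:
            dblocks = np.broadcast_to(dyb / (p1 * p2 * p3), blocks_shape(in_shape, sizes))
        dx = np.zeros(in_shape, dtype=DTYPE)
        zo, mo, no = dy.shape[1:4]
        dx[:, : zo * p1, : mo * p2, : no * p3, :] = dblocks.reshape(
            s, zo * p1, mo * p2, no * p3, k
        )
        self._cache = None
        return dx


def blocks_shape(in_shape, sizes):
    s, z, m, n, k = in_shape
    p1, p2, p3 = sizes
    return (s, z // p1, p1, m // p2, p2, n // p3, p3, k)


class MaxPool3D(_Pool3D):
    mode = "max"


class AvgPool3D(_Pool3D):
    mode = "average"


class Flatten(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(
        self,
        in_features: int,
        out_features: int,
        rng: np.random.Generator | None = None,
        is_softmax: bool = False,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / in_features)
        self.w = rng.normal(0.0, scale, size=(in_features, out_features)).astype(DTYPE)
        self.b = np.zeros(out_features, dtype=DTYPE)
        self.params = [self.w, self.b]
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.grads = [self.dw, self.db]
        # marks the classifier layer feeding the softmax (used by parameter accounting)
        self.is_softmax = is_softmax

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dw[...] = self._x.T @ dy
        self.db[...] = dy.sum(axis=0)
        return dy @ self.w.T


class Dropout(Layer):
    """Unit dropout with inverted scaling; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        if not 0.0 < rate < 1.0:
            raise ValueError("dropout rate must lie in (0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        return dy * self._mask


class SpatialDropout(Layer):
    """Channel dropout: one Bernoulli trial per feature volume, so a dropped
    channel is zeroed across all of its voxels (one trial per channel per
    sample, not per unit)."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        if not 0.0 < rate < 1.0:
            raise ValueError("dropout rate must lie in (0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random((x.shape[0], 1, 1, 1, x.shape[-1])) < keep) / keep
        self._mask = mask.astype(DTYPE)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        return dy * self._mask


# ---------------------------------------------------------------------------
# composites
# ---------------------------------------------------------------------------


class Sequential(Layer):
    def __init__(self, layers: list[Layer], name: str = "") -> None:
        super().__init__()
        self.layers = list(layers)
        self.name = name

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def iter_layers(self):
        for layer in self.layers:
            yield from layer.iter_layers()

    # -- convenience for classifiers ------------------------------------
    def predict_logits(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x, training=False)

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        out = []
        for i in range(0, x.shape[0], batch_size):
            out.append(softmax(self.forward(x[i : i + batch_size], training=False)))
        return np.concatenate(out, axis=0)

    def parameters(self):
        for layer in self.iter_layers():
            yield from zip(layer.params, layer.grads)

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for layer in self.iter_layers() for p in layer.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        flat = [p for layer in self.iter_layers() for p in layer.params]
        if len(flat) != len(weights):
            raise ValueError("weight list length mismatch")
        for p, w in zip(flat, weights):
            p[...] = w


class ConcatBranches(Layer):
    """Parallel branches whose outputs share spatial dims and are concatenated
    on the channel axis (the Inception join)."""

    def __init__(self, branches: list[Sequential]) -> None:
        super().__init__()
        self.branches = list(branches)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        outs = [b.forward(x, training=training) for b in self.branches]
        spatial = {o.shape[1:4] for o in outs}
        if len(spatial) != 1:
            raise ValueError(f"branch spatial dims disagree: {sorted(spatial)}")
        self._splits = np.cumsum([o.shape[-1] for o in outs])[:-1]
        return np.concatenate(outs, axis=-1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        parts = np.split(dy, self._splits, axis=-1)
        dx = None
        for branch, part in zip(self.branches, parts):
            g = branch.backward(np.ascontiguousarray(part))
            dx = g if dx is None else dx + g
        return dx

    def iter_layers(self):
        for b in self.branches:
            yield from b.iter_layers()


class Residual(Layer):
    """y = ReLU(x + scale * body(x)).

    The body ends with a 1x1x1 projection when its width differs from the
    shortcut, so the elementwise add is always well defined.
    """

    def __init__(self, body: Sequential, scale: float = 0.1) -> None:
        super().__init__()
        self.body = body
        self.scale = float(scale)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        b = self.body.forward(x, training=training)
        if b.shape != x.shape:
            raise ValueError(
                f"residual branch shape {b.shape} does not match shortcut {x.shape}"
            )
        pre = x + self.scale * b
        self._mask = pre > 0
        return np.maximum(pre, 0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dpre = dy * self._mask
        return dpre + self.body.backward(self.scale * dpre)

    def iter_layers(self):
        yield from self.body.iter_layers()


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------


@dataclass
class SGD:
    """Mini-batch SGD with classical momentum and L2 weight decay."""

    lr: float = 0.001
    momentum: float = 0.9
    weight_decay: float = 5e-4
    _velocity: dict = field(default_factory=dict)

    def step(self, parameters) -> None:
        for i, (p, g) in enumerate(parameters):
            v = self._velocity.get(i)
            if v is None:
                v = np.zeros_like(p)
                self._velocity[i] = v
            v *= self.momentum
            v -= self.lr * (g + self.weight_decay * p)
            p += v
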