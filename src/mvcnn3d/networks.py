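"""Network family builders and parameter accounting.

Two topology families are provided, all operating on standardized multi-view
nodule volumes of shape ``(Z, M, N, K)`` = ``(6, 50, 50, n_views)``:

* **chain** nets: ``m * (MaxPool(ReLU(conv(x, w)))) + fc + softmax`` with
  depth ``m`` in {0..3} (``m = 0`` is a bare softmax classifier on the
  flattened volume).  Filter sizes and channel widths follow the standard
  configuration: CNN1 = conv 3x5x5 (20 ch); CNN2 adds conv 3x3x3 (50 ch);
  CNN3 uses convs 3x5x5 (20), 3x5x5 (50), 2x3x3 (50); the hidden fc layer has
  128 units. Max-pool 2x2x2 after every conv; dropout 0.5 on the fc layer and
  spatial dropout 0.5 after every conv activation.

* **DAG** nets: a single 3D Inception module (variant 1 uses 1x1x1 / 3x3x3 /
  5x5x5 conv branches; variant 2 factorizes each nxnxn filter into 1x1xn,
  1xnx1 and nx1x1 stacks), with the fully connected layer replaced by a
  1x1x1 convolution (32 channels for the binary task, 64 for the ternary)
  followed by 2x3x3 average pooling.  The Inception-ResNet wraps the same
  module in a residual connection whose branch is scaled by 0.1 before the
  add.  Stem and branch channel widths are recorded in
  ``configs/inception_figure.yaml`` and exposed through ``figure_config()``.

All convolutions are stride 1 with 'same' padding; pooling strides equal the
pool window.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from importlib import resources

import numpy as np
import yaml

from .layers import (
    AvgPool3D,
    ConcatBranches,
    Conv3D,
    Dense,
    Dropout,
    Flatten,
    MaxPool3D,
    Residual,
    ReLU,
    Sequential,
    SpatialDropout,
)

__all__ = [
    "ArchitectureSpec",
    "ParamReport",
    "figure_config",
    "build_network",
    "build_chain",
    "build_inception",
    "build_inception_resnet",
    "build_one_view_ensemble",
    "inception_module",
    "OneViewEnsemble",
    "count_parameters",
]

CHAIN_FAMILIES = ("softmax", "chain")
DAG_FAMILIES = ("inception1", "inception2", "inception_resnet")

# Table-1 chain configuration: (kernel, out_channels) per conv layer.
CHAIN_CONVS = {
    1: [((3, 5, 5), 20)],
    2: [((3, 5, 5), 20), ((3, 3, 3), 50)],
    3: [((3, 5, 5), 20), ((3, 5, 5), 50), ((2, 3, 3), 50)],
}
FC_UNITS = 128


@dataclass
class ArchitectureSpec:
    """Declarative description of one network of the family."""

    family: str = "chain"
    depth_m: int = 1  # chain depth m in {0,1,2,3}; ignored for DAG families
    n_views: int = 3
    n_classes: int = 2
    input_shape: tuple[int, int, int] = (6, 50, 50)
    head_channels: int | None = None  # DAG 1x1x1 head; None -> 32 (binary) / 64 (ternary)
    avgpool_size: tuple[int, int, int] = (2, 3, 3)
    chain_pool_size: tuple[int, int, int] = (2, 2, 2)
    residual_scale: float = 0.1
    stem_channels: int | None = None  # None -> figure config
    branch_widths: tuple[int, int, int] | None = None  # (w1, w3, w5); None -> figure config
    dropout_rate: float = 0.5

    def __post_init__(self) -> None:
        if self.family not in CHAIN_FAMILIES + DAG_FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "softmax":
            self.depth_m = 0
        if self.family == "chain" and self.depth_m not in (0, 1, 2, 3):
            raise ValueError("chain depth m must be in {0, 1, 2, 3}")
        if self.n_views not in (1, 3):
            raise ValueError("n_views must be 1 or 3")
        if self.n_classes not in (2, 3):
            raise ValueError("n_classes must be 2 (binary) or 3 (ternary)")
        self.input_shape = tuple(self.input_shape)
        self.avgpool_size = tuple(self.avgpool_size)
        self.chain_pool_size = tuple(self.chain_pool_size)
        if self.branch_widths is not None:
            self.branch_widths = tuple(self.branch_widths)

    @property
    def task(self) -> str:
        return "binary" if self.n_classes == 2 else "ternary"

    def resolved_head_channels(self) -> int:
        if self.head_channels is not None:
            return self.head_channels
        return 32 if self.n_classes == 2 else 64

    # -- YAML round trip -------------------------------------------------
    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "ArchitectureSpec":
        """Load a spec from a file-like object, a path, or a YAML string."""
        import os

        if hasattr(source, "read"):
            data = yaml.safe_load(source.read())
        elif isinstance(source, (str, os.PathLike)) and os.path.exists(source):
            with open(source) as fh:
                data = yaml.safe_load(fh)
        else:
            data = yaml.safe_load(str(source))
        for key in ("input_shape", "avgpool_size", "chain_pool_size", "branch_widths"):
            if data.get(key) is not None:
                data[key] = tuple(data[key])
        return cls(**data)


def figure_config() -> dict:
    """Stem / branch / head channel widths of the Inception nets, per task.

    These widths are the package's documented reading of the published
    architecture diagrams (which state per-layer output sizes separately for
    the binary and the ternary network); they reproduce the published
    parameter totals of the multi-view Inception1 nets, 0.47e5 (binary) and
    1.49e5 (ternary), at two significant figures.
    """
    with resources.files("mvcnn3d").joinpath("configs/inception_figure.yaml").open() as fh:
        return yaml.safe_load(fh)


def _resolve_dag_widths(spec: ArchitectureSpec) -> tuple[int, tuple[int, int, int]]:
    cfg = figure_config()[spec.task]
    stem = spec.stem_channels if spec.stem_channels is not None else cfg["stem_channels"]
    widths = (
        spec.branch_widths
        if spec.branch_widths is not None
        else tuple(cfg["branch_widths"])
    )
    return stem, widths


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------


def _rngs(seed: int):
    ss = np.random.SeedSequence(seed)
    while True:
        yield np.random.default_rng(ss.spawn(1)[0])


def _finalize(net: Sequential, spec: ArchitectureSpec) -> Sequential:
    """Attach the spec and mark the input conv, which never needs an input
    gradient (there is no layer below it)."""
    first = net.layers[0]
    if isinstance(first, Conv3D):
        first.needs_input_grad = False
    net.spec = spec
    return net


def build_chain(spec: ArchitectureSpec, seed: int = 0) -> Sequential:
    """Chain net per Eq-5 structure; ``depth_m = 0`` is the softmax classifier."""
    if spec.family not in CHAIN_FAMILIES:
        raise ValueError(f"build_chain expects a chain family, got {spec.family!r}")
    rngs = _rngs(seed)
    layers: list = []
    in_ch = spec.n_views
    feat_shape = spec.input_shape
    for kernel, out_ch in CHAIN_CONVS.get(spec.depth_m, []):
        layers += [
            Conv3D(kernel, in_ch, out_ch, padding="same", rng=next(rngs)),
            ReLU(),
            SpatialDropout(spec.dropout_rate, rng=next(rngs)),
            MaxPool3D(spec.chain_pool_size, clip=True),
        ]
        p = spec.chain_pool_size
        feat_shape = tuple(
            max(1, feat_shape[a] // min(p[a], feat_shape[a])) for a in range(3)
        )
        in_ch = out_ch
    layers.append(Flatten())
    n_feat = int(np.prod(feat_shape)) * in_ch
    if spec.depth_m > 0:
        layers += [
            Dense(n_feat, FC_UNITS, rng=next(rngs)),
            ReLU(),
            Dropout(spec.dropout_rate, rng=next(rngs)),
        ]
        n_feat = FC_UNITS
    layers.append(Dense(n_feat, spec.n_classes, rng=next(rngs), is_softmax=True))
    net = Sequential(layers, name=f"CNN{spec.depth_m}" if spec.depth_m else "Softmax")
    return _finalize(net, spec)


def inception_module(
    in_channels: int,
    branch_widths: tuple[int, int, int],
    variant: int = 1,
    rngs=None,
) -> ConcatBranches:
    """One 3D Inception module.

    Variant 1 runs 1x1x1, 3x3x3 and 5x5x5 conv branches in parallel (same
    padding) and concatenates them on the channel axis.  Variant 2 replaces
    each nxnxn filter (n = 3, 5) with a stack of three factorized filters
    1x1xn, 1xnx1 and nx1x1 of the same width.
    """
    if variant not in (1, 2):
        raise ValueError("inception variant must be 1 or 2")
    if rngs is None:
        rngs = _rngs(0)
    w1, w3, w5 = branch_widths
    branches = [
        Sequential(
            [Conv3D((1, 1, 1), in_channels, w1, padding="same", rng=next(rngs)), ReLU()],
            name="branch1",
        )
    ]
    for n, w in ((3, w3), (5, w5)):
        if variant == 1:
            convs = [Conv3D((n, n, n), in_channels, w, padding="same", rng=next(rngs))]
        else:
            convs = [
                Conv3D((1, 1, n), in_channels, w, padding="same", rng=next(rngs)),
                Conv3D((1, n, 1), w, w, padding="same", rng=next(rngs)),
                Conv3D((n, 1, 1), w, w, padding="same", rng=next(rngs)),
            ]
        branches.append(Sequential([*convs, ReLU()], name=f"branch{n}"))
    return ConcatBranches(branches)


def _dag_head(spec: ArchitectureSpec, in_channels: int, rngs) -> list:
    head_ch = spec.resolved_head_channels()
    return [
        Conv3D((1, 1, 1), in_channels, head_ch, padding="same", rng=next(rngs)),
        ReLU(),
        AvgPool3D(spec.avgpool_size),
        Flatten(),
    ]


def _dag_feat_count(spec: ArchitectureSpec) -> int:
    # stem max-pool then head average pool, both with stride = window
    shape = spec.input_shape
    for pool in (spec.avgpool_size, spec.avgpool_size):
        shape = tuple(shape[a] // pool[a] for a in range(3))
    return int(np.prod(shape)) * spec.resolved_head_channels()


def build_inception(spec: ArchitectureSpec, seed: int = 0) -> Sequential:
    """Stem conv + one Inception module + 1x1x1-conv/avg-pool head + softmax.

    There is no fully connected layer; the 1x1x1 convolution (32 channels
    binary / 64 ternary) and the 2x3x3 average pooling stand in for it.
    """
    if spec.family not in ("inception1", "inception2"):
        raise ValueError(f"build_inception expects inception1|2, got {spec.family!r}")
    variant = 1 if spec.family == "inception1" else 2
    rngs = _rngs(seed)
    stem_ch, widths = _resolve_dag_widths(spec)
    layers = [
        Conv3D((3, 3, 3), spec.n_views, stem_ch, padding="same", rng=next(rngs)),
        ReLU(),
        MaxPool3D(spec.avgpool_size),
        inception_module(stem_ch, widths, variant=variant, rngs=rngs),
        SpatialDropout(spec.dropout_rate, rng=next(rngs)),
        *_dag_head(spec, sum(widths), rngs),
        Dense(_dag_feat_count(spec), spec.n_classes, rng=next(rngs), is_softmax=True),
    ]
    net = Sequential(layers, name=f"Inception{variant}")
    return _finalize(net, spec)


def build_inception_resnet(spec: ArchitectureSpec, seed: int = 0) -> Sequential:
    """Inception-ResNet: the Inception1 module sits on a residual branch whose
    output is projected back to the stem width by a 1x1x1 convolution, scaled
    by ``residual_scale`` (default 0.1) and added to the shortcut before ReLU.
    """
    if spec.family != "inception_resnet":
        raise ValueError(
            f"build_inception_resnet expects inception_resnet, got {spec.family!r}"
        )
    rngs = _rngs(seed)
    stem_ch, widths = _resolve_dag_widths(spec)
    body = Sequential(
        [
            inception_module(stem_ch, widths, variant=1, rngs=rngs),
            Conv3D((1, 1, 1), sum(widths), stem_ch, padding="same", rng=next(rngs)),
        ],
        name="residual_branch",
    )
    layers = [
        Conv3D((3, 3, 3), spec.n_views, stem_ch, padding="same", rng=next(rngs)),
        ReLU(),
        MaxPool3D(spec.avgpool_size),
        Residual(body, scale=spec.residual_scale),
        SpatialDropout(spec.dropout_rate, rng=next(rngs)),
        *_dag_head(spec, stem_ch, rngs),
        Dense(_dag_feat_count(spec), spec.n_classes, rng=next(rngs), is_softmax=True),
    ]
    net = Sequential(layers, name="InceptionResNet")
    return _finalize(net, spec)


def build_network(spec: ArchitectureSpec, seed: int = 0) -> Sequential:
    if spec.family in CHAIN_FAMILIES:
        return build_chain(spec, seed=seed)
    if spec.family in ("inception1", "inception2"):
        return build_inception(spec, seed=seed)
    return build_inception_resnet(spec, seed=seed)


# ---------------------------------------------------------------------------
# one-view-one-network ensembles
# ---------------------------------------------------------------------------


class OneViewEnsemble:
    """A separate single-view network per crop size; the per-view softmax
    outputs are fused by averaging."""

    def __init__(self, networks: list[Sequential], spec: ArchitectureSpec) -> None:
        self.networks = networks
        self.spec = spec

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        probs = [
            net.predict_proba(x[..., v : v + 1], batch_size=batch_size)
            for v, net in enumerate(self.networks)
        ]
        return np.mean(probs, axis=0)

    def iter_layers(self):
        for net in self.networks:
            yield from net.iter_layers()

    def parameters(self):
        for net in self.networks:
            yield from net.parameters()


def build_one_view_ensemble(
    spec: ArchitectureSpec, reduced_channels: bool = False, seed: int = 0
) -> OneViewEnsemble:
    """One single-view network per view.

    Variant 1 (``reduced_channels=False``) keeps every sub-network's hidden
    structure identical to the multi-view network, so total parameters come
    out close to ``n_views`` times the multi-view conv stack.  Variant 2
    scales channel widths by 1/sqrt(n_views) so the ensemble total roughly
    matches the multi-view network's.
    """
    if spec.n_views < 2:
        return OneViewEnsemble([build_network(spec, seed=seed)], spec)
    nets = []
    for v in range(spec.n_views):
        sub = ArchitectureSpec(**{**asdict(spec), "n_views": 1})
        if reduced_channels and sub.family in DAG_FAMILIES:
            stem, widths = _resolve_dag_widths(spec)
            f = 1.0 / np.sqrt(spec.n_views)
            sub.stem_channels = max(1, round(stem * f))
            sub.branch_widths = tuple(max(1, round(w * f)) for w in widths)
            sub.head_channels = max(1, round(spec.resolved_head_channels() * f))
        nets.append(build_network(sub, seed=seed + v))
    return OneViewEnsemble(nets, spec)


# ---------------------------------------------------------------------------
# parameter accounting
# ---------------------------------------------------------------------------


@dataclass
class ParamReport:
    """Parameter accounting mirroring the published comparison table.

    ``conv_params`` and ``softmax_params`` exclude biases; ``r_p`` is their
    ratio (conv : softmax) and ``r_f`` the number of filters feeding each
    first-hidden-layer channel (= input view channels: ``n_views`` for the
    multi-view-one-network strategy, 1 for one-view sub-networks).
    """

    total_params: int
    conv_params: int
    softmax_params: int
    r_p: float
    r_f: int
    breakdown: list = field(default_factory=list)

    def format_table(self) -> str:
        lines = [
            f"{'layer':<28}{'kind':<10}{'weights':>10}{'biases':>8}",
        ]
        for name, kind, w, b in self.breakdown:
            lines.append(f"{name:<28}{kind:<10}{w:>10}{b:>8}")
        lines += [
            f"total parameters      {self.total_params}",
            f"total (x 1e5)         {self.total_params / 1e5:.2f}",
            f"conv weights          {self.conv_params}",
            f"softmax weights       {self.softmax_params}",
            f"R_p (conv:softmax)    {self.r_p:.1f}:1",
            f"R_f                   {self.r_f}:1",
        ]
        return "\n".join(lines)


def count_parameters(network) -> ParamReport:
    """Closed-form parameter accounting: every conv layer contributes
    Zf*Mf*Nf*K*K' weights + K' biases, every dense layer in*out + out."""
    total = 0
    conv_w = 0
    softmax_w = 0
    breakdown = []
    first_conv_in = None
    for i, layer in enumerate(network.iter_layers()):
        if isinstance(layer, Conv3D):
            w = int(np.prod(layer.w.shape))
            b = layer.b.size
            total += w + b
            conv_w += w
            if first_conv_in is None:
                first_conv_in = layer.in_channels
            breakdown.append((f"conv3d_{i}{layer.kernel}", "conv", w, b))
        elif isinstance(layer, Dense):
            w = int(np.prod(layer.w.shape))
            b = layer.b.size
            total += w + b
            kind = "softmax" if layer.is_softmax else "fc"
            if layer.is_softmax:
                softmax_w += w
            breakdown.append((f"dense_{i}", kind, w, b))
    if first_conv_in is None:
        # softmax-only model: the flattened input feeds the classifier directly
        spec = getattr(network, "spec", None)
        first_conv_in = spec.n_views if spec is not None else 1
    if isinstance(network, OneViewEnsemble):
        first_conv_in = 1
    r_p = conv_w / softmax_w if softmax_w else float("inf")
    return ParamReport(
        total_params=total,
        conv_params=conv_w,
        softmax_params=softmax_w,
        r_p=r_p,
        r_f=int(first_conv_in),
        breakdown=breakdown,
    )
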