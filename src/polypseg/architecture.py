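"""Dilated ResFCN: residual feature extraction, multi-resolution dilated
classification paths, and bilinear fusion — plus receptive-field design
analysis (effective kernel spans, valid-weight histograms, polyp coverage).

The network has three sub-networks:

* **feature extraction** — a ResNet-style bottleneck backbone partitioned into
  stages Res1..Res5.  Res1 is a 7x7/2 convolution + BN + ReLU + 2x2/2 max
  pool; Res2..Res5 are bottleneck stages with 256/512/1024/2048 output
  channels and (for depth 50) 9/12/18/9 convolutional layers (projection
  shortcuts not counted).  Spatial strides relative to the input are
  4/8/16/32.
* **multi-resolution classification** — four parallel paths tap the outputs
  of Res2..Res5.  Each path is a dilated 3x3 convolution (rates 16/8/4/2 from
  the finest to the coarsest path), dropout, and a 1x1 per-pixel classifier.
  Dilation widens the receptive field without adding parameters, matching
  the span of the kernels to the distribution of polyp sizes.
* **fusion** — each path's class scores are bilinearly upsampled (fixed, not
  learned) to the input size and summed.

Setting ``use_dilation=False`` yields the ResFCN ablation variant: the same
graph with all path dilation rates forced to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn

BOTTLENECK_BLOCKS = {50: (3, 4, 6, 3), 101: (3, 4, 23, 3), 152: (3, 8, 36, 3)}
STAGE_MID_CHANNELS = (64, 128, 256, 512)
STAGE_OUT_CHANNELS = (256, 512, 1024, 2048)
STAGE_STRIDES = (4, 8, 16, 32)  # Res2..Res5 relative to input
STAGE_NAMES = ("Res2", "Res3", "Res4", "Res5")


@dataclass
class ArchitectureSpec:
    """Configuration of the segmentation network."""

    backbone_depth: int = 50
    path_dilation_rates: tuple[int, int, int, int] = (16, 8, 4, 2)  # Res2..Res5
    classifier_kernel: int = 3
    path_channels: int = 64
    dropout_rate: float = 0.5
    n_classes: int = 2
    input_size: tuple[int, int] = (250, 287)
    use_dilation: bool = True
    pretrained_init: str | None = None

    def __post_init__(self):
        if self.backbone_depth not in BOTTLENECK_BLOCKS:
            raise ValueError(f"backbone_depth must be one of {sorted(BOTTLENECK_BLOCKS)}")
        rates = tuple(int(r) for r in self.path_dilation_rates)
        if len(rates) != 4 or any(r < 1 for r in rates):
            raise ValueError("path_dilation_rates must be four integers >= 1")
        if self.use_dilation:
            if not all(a > b for a, b in zip(rates, rates[1:])):
                raise ValueError("dilation rates must strictly decrease from Res2 to Res5")
        else:
            rates = (1, 1, 1, 1)
        self.path_dilation_rates = rates
        if self.classifier_kernel % 2 == 0 or self.classifier_kernel < 1:
            raise ValueError("classifier_kernel must be odd and >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        self.input_size = (int(self.input_size[0]), int(self.input_size[1]))
        if min(self.input_size) < 32:
            raise ValueError("input_size must be at least 32 pixels per side")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["path_dilation_rates"] = list(self.path_dilation_rates)
        d["input_size"] = list(self.input_size)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureSpec":
        return cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in d.items()})


# ---------------------------------------------------------------------------
# Backbone stage arithmetic (no tensors involved)


def _stem_output_size(h: int, w: int) -> tuple[int, int]:
    # 7x7/2 pad 3 conv, then 2x2/2 floor max pool
    ch = (h + 2 * 3 - 7) // 2 + 1
    cw = (w + 2 * 3 - 7) // 2 + 1
    return ch // 2, cw // 2


def stage_output_size(stage: str, input_size: tuple[int, int]) -> tuple[int, int]:
    """Spatial size of a backbone stage's output for a given input size."""
    h, w = _stem_output_size(*input_size)
    sizes = {"Res2": (h, w)}
    for name in STAGE_NAMES[1:]:
        h, w = -(-h // 2), -(-w // 2)  # ceil(n/2): stride-2 same-ish conv
        sizes[name] = (h, w)
    return sizes[stage]


@dataclass
class BackboneStage:
    """Summary of one backbone stage for a given spec/input size."""

    name: str
    stride: int
    n_conv_layers: int
    n_output_channels: int
    output_size: tuple[int, int]


def backbone_stages(spec: ArchitectureSpec) -> list[BackboneStage]:
    blocks = BOTTLENECK_BLOCKS[spec.backbone_depth]
    out = []
    for i, name in enumerate(STAGE_NAMES):
        out.append(BackboneStage(
            name=name,
            stride=STAGE_STRIDES[i],
            n_conv_layers=3 * blocks[i],
            n_output_channels=STAGE_OUT_CHANNELS[i],
            output_size=stage_output_size(name, spec.input_size),
        ))
    return out


# ---------------------------------------------------------------------------
# Network modules


class Bottleneck(nn.Layer):
    """1x1 -> 3x3 (optionally strided) -> 1x1 residual block with BN."""

    def __init__(self, in_ch, mid_ch, out_ch, stride, rng):
        self.conv1 = nn.Conv2d(in_ch, mid_ch, 1, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(mid_ch)
        self.conv2 = nn.Conv2d(mid_ch, mid_ch, 3, stride=stride, pad=1, bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(mid_ch)
        self.conv3 = nn.Conv2d(mid_ch, out_ch, 1, bias=False, rng=rng)
        self.bn3 = nn.BatchNorm2d(out_ch)
        self.relu1, self.relu2, self.relu_out = nn.ReLU(), nn.ReLU(), nn.ReLU()
        if stride != 1 or in_ch != out_ch:
            self.proj = nn.Conv2d(in_ch, out_ch, 1, stride=stride, bias=False, rng=rng)
            self.proj_bn = nn.BatchNorm2d(out_ch)
        else:
            self.proj = None

    def params(self):
        ps = (self.conv1.params() + self.bn1.params() + self.conv2.params()
              + self.bn2.params() + self.conv3.params() + self.bn3.params())
        if self.proj is not None:
            ps += self.proj.params() + self.proj_bn.params()
        return ps

    def forward(self, x, training=False):
        y = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, training), training))
        y = self.relu2.forward(self.bn2.forward(self.conv2.forward(y, training), training))
        y = self.bn3.forward(self.conv3.forward(y, training), training)
        if self.proj is not None:
            sc = self.proj_bn.forward(self.proj.forward(x, training), training)
        else:
            sc = x
        return self.relu_out.forward(y + sc)

    def backward(self, grad):
        grad = self.relu_out.backward(grad)
        g_main, g_skip = grad, grad
        g_main = self.conv3.backward(self.bn3.backward(g_main))
        g_main = self.conv2.backward(self.bn2.backward(self.relu2.backward(g_main)))
        g_main = self.conv1.backward(self.bn1.backward(self.relu1.backward(g_main)))
        if self.proj is not None:
            g_skip = self.proj.backward(self.proj_bn.backward(g_skip))
        return g_main + g_skip


class ClassificationPath(nn.Layer):
    """Dilated conv -> dropout -> 1x1 pixel classifier -> bilinear upsample."""

    def __init__(self, in_ch, path_ch, n_classes, kernel, rate, dropout_rate,
                 out_size, rng):
        self.rate = rate
        self.conv = nn.Conv2d.same(in_ch, path_ch, kernel, dilation=rate,
                                   rng=rng, init="xavier")
        self.relu = nn.ReLU()
        self.dropout = nn.Dropout(dropout_rate)
        self.classifier = nn.Conv2d(path_ch, n_classes, 1, rng=rng, init="xavier")
        self.upsample = nn.BilinearUpsample(*out_size)

    def params(self):
        return self.conv.params() + self.classifier.params()

    def forward(self, x, training=False):
        y = self.relu.forward(self.conv.forward(x, training))
        y = self.dropout.forward(y, training)
        y = self.classifier.forward(y, training)
        return self.upsample.forward(y, training)

    def backward(self, grad):
        g = self.upsample.backward(grad)
        g = self.classifier.backward(g)
        g = self.dropout.backward(g)
        return self.conv.backward(self.relu.backward(g))


class DilatedResFCN(nn.Layer):
    """The full segmentation network.

    ``forward`` maps a (N, 3, H, W) float input to (N, n_classes, H, W)
    scores.  The network is fully convolutional, so inputs of sizes other
    than ``spec.input_size`` (e.g. the padded squares used by rotation
    test-time augmentation) are accepted; the output always matches the
    input's spatial size.
    """

    def __init__(self, spec: ArchitectureSpec, seed: int = 0):
        self.spec = spec
        self.input_stats = None  # (mean, std) per channel, set by training
        rng = np.random.default_rng(seed)
        blocks = BOTTLENECK_BLOCKS[spec.backbone_depth]

        self.stem_conv = nn.Conv2d(3, 64, 7, stride=2, pad=3, bias=False, rng=rng)
        self.stem_bn = nn.BatchNorm2d(64)
        self.stem_relu = nn.ReLU()
        self.stem_pool = nn.MaxPool2x2()

        self.stages: list[list[Bottleneck]] = []
        in_ch = 64
        for i in range(4):
            mid, out = STAGE_MID_CHANNELS[i], STAGE_OUT_CHANNELS[i]
            stride = 1 if i == 0 else 2
            stage = [Bottleneck(in_ch, mid, out, stride, rng)]
            for _ in range(blocks[i] - 1):
                stage.append(Bottleneck(out, mid, out, 1, rng))
            self.stages.append(stage)
            in_ch = out

        self.paths = [
            ClassificationPath(STAGE_OUT_CHANNELS[i], spec.path_channels,
                               spec.n_classes, spec.classifier_kernel,
                               spec.path_dilation_rates[i], spec.dropout_rate,
                               spec.input_size, rng)
            for i in range(4)
        ]
        if spec.pretrained_init:
            self.load_weights(spec.pretrained_init)

    # -- parameter access ---------------------------------------------------

    def params(self):
        ps = self.stem_conv.params() + self.stem_bn.params()
        for stage in self.stages:
            for block in stage:
                ps += block.params()
        for path in self.paths:
            ps += path.params()
        return ps

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params())

    def conv_layer_count(self, stage: str) -> int:
        """Convolutions in a Res2..Res5 stage (projection shortcuts excluded)."""
        i = STAGE_NAMES.index(stage)
        return sum(1 for block in self.stages[i]
                   for conv in (block.conv1, block.conv2, block.conv3)
                   if isinstance(conv, nn.Conv2d))

    # -- forward / backward -------------------------------------------------

    def forward(self, x, training=False):
        h, w = x.shape[2], x.shape[3]
        for path in self.paths:
            path.upsample.out_h, path.upsample.out_w = h, w
            path.upsample._mats.clear()
        y = self.stem_pool.forward(
            self.stem_relu.forward(self.stem_bn.forward(self.stem_conv.forward(x, training), training)))
        self._taps = []
        for stage in self.stages:
            for block in stage:
                y = block.forward(y, training)
            self._taps.append(y)
        out = None
        for path, tap in zip(self.paths, self._taps):
            s = path.forward(tap, training)
            out = s if out is None else out + s
        return out

    def backward(self, grad):
        g_taps = [path.backward(grad) for path in self.paths]
        g = None
        for stage, gt in zip(reversed(self.stages), reversed(g_taps)):
            g = gt if g is None else g + gt
            for block in reversed(stage):
                g = block.backward(g)
        g = self.stem_pool.backward(g)
        g = self.stem_conv.backward(self.stem_bn.backward(self.stem_relu.backward(g)))
        self._taps = None
        return g

    def stage_outputs(self, x):
        """Forward the backbone only; return {stage name: output array}."""
        y = self.stem_pool.forward(
            self.stem_relu.forward(self.stem_bn.forward(self.stem_conv.forward(x))))
        out = {}
        for name, stage in zip(STAGE_NAMES, self.stages):
            for block in stage:
                y = block.forward(y)
            out[name] = y
        return out

    # -- (de)serialization --------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        arrs = {}
        for i, p in enumerate(self.params()):
            arrs[f"param_{i:04d}"] = p.data
        j = 0
        for layer in self._bn_layers():
            arrs[f"bn_{j:04d}_mean"] = layer.running_mean
            arrs[f"bn_{j:04d}_var"] = layer.running_var
            j += 1
        if self.input_stats is not None:
            arrs["input_mean"], arrs["input_std"] = self.input_stats
        return arrs

    def _bn_layers(self):
        yield self.stem_bn
        for stage in self.stages:
            for b in stage:
                yield b.bn1
                yield b.bn2
                yield b.bn3
                if b.proj is not None:
                    yield b.proj_bn

    def save_weights(self, path):
        np.savez(path, **self.state_arrays())

    def load_weights(self, path):
        with np.load(path) as data:
            for i, p in enumerate(self.params()):
                arr = data[f"param_{i:04d}"]
                if arr.shape != p.data.shape:
                    raise ValueError(f"checkpoint shape mismatch at param {i}")
                p.data = arr.astype(p.data.dtype)
            for j, layer in enumerate(self._bn_layers()):
                layer.running_mean = data[f"bn_{j:04d}_mean"].astype(layer.running_mean.dtype)
                layer.running_var = data[f"bn_{j:04d}_var"].astype(layer.running_var.dtype)
            if "input_mean" in data:
                self.input_stats = (data["input_mean"].copy(), data["input_std"].copy())


def build_network(spec: ArchitectureSpec, seed: int = 0) -> DilatedResFCN:
    """Construct the segmentation network from its specification."""
    return DilatedResFCN(spec, seed=seed)


# ---------------------------------------------------------------------------
# Receptive-field design analysis


def effective_kernel_span(kernel: int, rate: int) -> int:
    """Spatial extent (k - 1) * r + 1 covered by a k x k kernel at rate r."""
    if kernel % 2 == 0 or kernel < 1:
        raise ValueError("kernel must be odd and >= 1")
    if rate < 1:
        raise ValueError("rate must be >= 1")
    return (kernel - 1) * rate + 1


def valid_weight_histogram(map_size: tuple[int, int], kernel: int, rate: int) -> dict[int, int]:
    """Histogram of valid-weight counts over all output positions.

    With same-padding, a dilated kernel tap falls on zero padding whenever its
    offset leaves the feature map; the number of taps landing inside the map
    ("valid weights") varies per output position and collapses toward 1 when
    the rate is large relative to the map.  Returns {valid count: positions}.
    """
    h, w = map_size
    if h < 1 or w < 1:
        raise ValueError("map size must be positive")
    if kernel % 2 == 0:
        raise ValueError("kernel must be odd")
    half = kernel // 2
    offs = np.arange(-half, half + 1) * rate
    rows = np.arange(h)[:, None] + offs[None, :]   # (h, k)
    cols = np.arange(w)[:, None] + offs[None, :]
    vrows = ((rows >= 0) & (rows < h)).sum(axis=1)  # valid taps per row
    vcols = ((cols >= 0) & (cols < w)).sum(axis=1)
    counts = vrows[:, None] * vcols[None, :]
    hist: dict[int, int] = {}
    for v, c in zip(*np.unique(counts, return_counts=True)):
        hist[int(v)] = int(c)
    return hist


@dataclass
class ReceptiveFieldReport:
    """Per-path receptive-field analysis for a network specification."""

    stage: str
    dilation_rate: int
    effective_span: int
    map_size: tuple[int, int]
    valid_weight_hist: dict[int, int] = field(default_factory=dict)

    @property
    def n_positions(self) -> int:
        return sum(self.valid_weight_hist.values())

    @property
    def fraction_with_4_or_more(self) -> float:
        total = self.n_positions
        good = sum(c for v, c in self.valid_weight_hist.items() if v >= 4)
        return good / total if total else 0.0


def receptive_field_report(spec: ArchitectureSpec) -> list[ReceptiveFieldReport]:
    out = []
    for i, stage in enumerate(STAGE_NAMES):
        rate = spec.path_dilation_rates[i]
        size = stage_output_size(stage, spec.input_size)
        out.append(ReceptiveFieldReport(
            stage=stage,
            dilation_rate=rate,
            effective_span=effective_kernel_span(spec.classifier_kernel, rate),
            map_size=size,
            valid_weight_hist=valid_weight_histogram(size, spec.classifier_kernel, rate),
        ))
    return out


def coverage_fraction(polyp_sizes, span: int, stride: int) -> float:
    """Fraction of polyps whose extent fits the path's receptive span.

    ``polyp_sizes`` are linear extents in input pixels; at a path whose
    feature map is subsampled by ``stride``, a polyp of extent ``e`` occupies
    ``e / stride`` feature-map pixels and is covered when that fits within
    the effective kernel span.  This is the design statistic used to pick
    the coarsest path's dilation rate.
    """
    sizes = np.asarray(list(polyp_sizes), dtype=float)
    if sizes.size == 0:
        raise ValueError("polyp size collection is empty")
    if span < 1 or stride < 1:
        raise ValueError("span and stride must be >= 1")
    return float(np.mean(sizes / stride <= span))
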