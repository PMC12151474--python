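"""Attention U-Net with a Dense Atrous Convolution (DAC) bottleneck.

The segmentation backbone is a U-Net encoder-decoder: each encoder stage is
two 3x3 conv + BatchNorm + ReLU units, refined by a CBAM attention block
(channel attention, then spatial attention) and downsampled by 2x2 max
pooling.  The bottleneck is widened to ``base_width * 2**depth`` channels
and, on the decoder side, passes through a DAC module — four parallel
cascades of dilated 3x3 convolutions with receptive fields 3/7/9/19,
residual-summed onto the input — before the first 2x2 stride-2 transposed
convolution.  CBAM precedes the remaining up-samplings; every up-sampling
is followed by skip-concatenation with the matching encoder stage and two
further conv+BN+ReLU units; a final 1x1 convolution maps to two output
channels (background / plaque).

With the default configuration (512x512 input, depth 4, base width 64) the
spatial size shrinks 512 -> 32 while channels grow 3 -> 1024, and the
decoder restores the full 512x512 resolution.

Also provided: analytic receptive-field and parameter-count calculators,
an analytic per-stage shape summary, and single-file checkpoints.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .autodiff import (Tensor, concat, conv2d, conv_transpose2x2, edge_pad2d,
                       maxpool2x2, relu, sigmoid)

__all__ = [
    "NetworkConfig", "DilationSpec", "receptive_field",
    "cascade_receptive_field", "branch_receptive_fields", "DACNet",
    "count_parameters", "stage_shapes", "save_checkpoint", "load_checkpoint",
    "dac_parameter_count", "plain_stack_parameter_count",
]

# default DAC cascade plan: dilation rates of the 3x3 convs on each branch,
# and whether the branch ends in a 1x1 convolution
DEFAULT_DAC_DILATIONS: tuple[tuple[int, ...], ...] = ((1,), (3,), (1, 3), (1, 3, 5))
DEFAULT_DAC_FINAL_1X1: tuple[bool, ...] = (False, True, True, True)


@dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    The defaults describe the full-scale model (512x512 input, bottleneck
    1024 channels at 32x32); tests use the same code with a small
    ``input_size`` and ``base_width``.
    """

    input_size: int = 512
    input_channels: int = 3
    depth: int = 4
    base_width: int = 64
    out_channels: int = 2
    cbam_reduction: int = 16
    cbam_spatial_kernel: int = 7
    dac_dilations: tuple[tuple[int, ...], ...] = DEFAULT_DAC_DILATIONS
    dac_final_1x1: tuple[bool, ...] = DEFAULT_DAC_FINAL_1X1
    seed: int = 0

    def __post_init__(self):
        if self.input_size % (2 ** self.depth) != 0:
            raise ValueError(
                f"input_size {self.input_size} not divisible by 2^depth "
                f"= {2 ** self.depth}")
        if self.out_channels < 2:
            raise ValueError("out_channels must be >= 2")
        if self.cbam_spatial_kernel % 2 == 0:
            raise ValueError("cbam_spatial_kernel must be odd")
        self.dac_dilations = tuple(tuple(b) for b in self.dac_dilations)
        self.dac_final_1x1 = tuple(bool(f) for f in self.dac_final_1x1)
        if len(self.dac_final_1x1) != len(self.dac_dilations):
            raise ValueError("dac_final_1x1 must match dac_dilations length")

    @property
    def stage_widths(self) -> list[int]:
        """Channel widths of the encoder stages plus the bottleneck."""
        return [self.base_width * 2 ** i for i in range(self.depth + 1)]

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        return cls(**d)


# ---------------------------------------------------------------------------
# receptive-field arithmetic
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DilationSpec:
    """A k x k convolution with dilation rate r."""
    k: int
    r: int = 1

    def __post_init__(self):
        if self.k < 1 or self.k % 2 == 0:
            raise ValueError("kernel size must be odd and >= 1")
        if self.r < 1:
            raise ValueError("dilation rate must be >= 1")


def receptive_field(spec: DilationSpec) -> int:
    """Receptive field F = (r - 1)(k - 1) + k of one dilated convolution.

    With r = 1 this reduces to the kernel size (standard convolution); a
    3x3 kernel at r = 2 covers the 5-pixel extent of a 5x5 kernel.
    """
    return (spec.r - 1) * (spec.k - 1) + spec.k


def cascade_receptive_field(specs: Sequence[DilationSpec]) -> int:
    """Receptive field of stacked stride-1 convolutions.

    Composition rule: RF_total = sum(RF_i - 1) + 1.
    """
    specs = list(specs)
    if not specs:
        raise ValueError("cascade_receptive_field requires at least one layer")
    return sum(receptive_field(s) - 1 for s in specs) + 1


def branch_receptive_fields(config: NetworkConfig | None = None) -> tuple[int, ...]:
    """Per-branch receptive fields of the DAC cascade plan (default 3/7/9/19).

    The final 1x1 convolutions contribute nothing to the receptive field.
    """
    config = config or NetworkConfig()
    return tuple(
        cascade_receptive_field([DilationSpec(3, r) for r in branch])
        for branch in config.dac_dilations)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Module:
    """Base class: parameter collection and train/eval mode propagation."""

    def modules(self):
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
            elif isinstance(v, (list, tuple)):
                for m in v:
                    if isinstance(m, Module):
                        yield m

    def named_parameters(self, prefix: str = ""):
        for name, v in self.__dict__.items():
            if isinstance(v, Tensor) and v.requires_grad:
                yield f"{prefix}{name}", v
        for name, v in self.__dict__.items():
            if isinstance(v, Module):
                yield from v.named_parameters(f"{prefix}{name}.")
            elif isinstance(v, (list, tuple)):
                for i, m in enumerate(v):
                    if isinstance(m, Module):
                        yield from m.named_parameters(f"{prefix}{name}.{i}.")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def set_training(self, mode: bool) -> None:
        if hasattr(self, "training"):
            self.training = mode
        for m in self.modules():
            m.set_training(mode)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _kaiming(rng: np.random.Generator, shape: tuple[int, ...],
             fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 dilation: int = 1, pad: int | None = None):
        self.dilation = dilation
        self.pad = pad
        self.weight = Tensor(_kaiming(rng, (cout, cin, k, k), cin * k * k),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(cout, np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, dilation=self.dilation,
                      pad=self.pad)


class ConvTranspose2x2(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.weight = Tensor(_kaiming(rng, (cin, cout, 2, 2), cin * 4),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(cout, np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return conv_transpose2x2(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        self.eps = eps
        self.momentum = momentum
        self.training = True
        self.gamma = Tensor(np.ones((1, c, 1, 1), np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros((1, c, 1, 1), np.float32), requires_grad=True)
        self.running_mean = np.zeros((1, c, 1, 1), np.float32)
        self.running_var = np.ones((1, c, 1, 1), np.float32)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data
            self.running_var = (1 - m) * self.running_var + m * var.data
            xhat = (x - mu) * ((var + self.eps) ** -0.5)
        else:
            xhat = (x - Tensor(self.running_mean)) * \
                Tensor(1.0 / np.sqrt(self.running_var + self.eps))
        return xhat * self.gamma + self.beta


class DoubleConv(Module):
    """Two (3x3 conv -> BN -> ReLU) units, the basic U-Net stage."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.conv1 = Conv2d(cin, cout, 3, rng)
        self.bn1 = BatchNorm2d(cout)
        self.conv2 = Conv2d(cout, cout, 3, rng)
        self.bn2 = BatchNorm2d(cout)

    def forward(self, x: Tensor) -> Tensor:
        x = relu(self.bn1(self.conv1(x)))
        return relu(self.bn2(self.conv2(x)))


class CBAM(Module):
    """Convolutional Block Attention Module.

    Channel attention: Mc = sigmoid(MLP(avgpool(F)) + MLP(maxpool(F))),
    shared two-layer MLP with hidden width C / reduction.  Spatial
    attention: Ms = sigmoid(conv_kxk(concat(channel-max, channel-mean))).
    The refined map is F'' = Ms(F') * F' with F' = Mc(F) * F.
    """

    def __init__(self, c: int, reduction: int, spatial_kernel: int,
                 rng: np.random.Generator):
        hidden = max(c // reduction, 1)
        self.w1 = Tensor(_kaiming(rng, (c, hidden), c), requires_grad=True)
        self.b1 = Tensor(np.zeros(hidden, np.float32), requires_grad=True)
        self.w2 = Tensor(_kaiming(rng, (hidden, c), hidden), requires_grad=True)
        self.b2 = Tensor(np.zeros(c, np.float32), requires_grad=True)
        self.spatial_pad = spatial_kernel // 2
        self.spatial_conv = Conv2d(2, 1, spatial_kernel, rng, pad=0)

    def _mlp(self, v: Tensor) -> Tensor:
        return relu(v.matmul(self.w1) + self.b1).matmul(self.w2) + self.b2

    def channel_map(self, x: Tensor) -> Tensor:
        """Mc, shape (N, C, 1, 1), entries in (0, 1)."""
        n, c, h, w = x.shape
        flat = x.reshape(n, c, h * w)
        avg = flat.mean(axis=2)
        mx = flat.max(axis=2)
        mc = sigmoid(self._mlp(avg) + self._mlp(mx))
        return mc.reshape(n, c, 1, 1)

    def spatial_map(self, x: Tensor) -> Tensor:
        """Ms, shape (N, 1, H, W), entries in (0, 1).

        The pooled 2-channel map is edge-replicated before the k x k
        convolution, so a spatially constant input yields a spatially
        constant attention map (zero padding would break this at borders).
        """
        mx = x.max(axis=1, keepdims=True)
        avg = x.mean(axis=1, keepdims=True)
        pooled = edge_pad2d(concat([mx, avg], axis=1), self.spatial_pad)
        return sigmoid(self.spatial_conv(pooled))

    def forward(self, x: Tensor) -> Tensor:
        xp = self.channel_map(x) * x        # F'  = Mc(F) (x) F
        return self.spatial_map(xp) * xp    # F'' = Ms(F') (x) F'


class DACBlock(Module):
    """Dense Atrous Convolution bottleneck block.

    Four parallel branches of cascaded dilated 3x3 convolutions (ReLU after
    each), most ending in a 1x1 convolution, summed residually onto the
    input: out = F + sum_b branch_b(F).  Channel width and spatial size are
    preserved; with the default plan the branch receptive fields are
    3, 7, 9 and 19 pixels.
    """

    def __init__(self, c: int, config: NetworkConfig, rng: np.random.Generator):
        self.branches = []
        for dilations, final_1x1 in zip(config.dac_dilations,
                                        config.dac_final_1x1):
            layers = [Conv2d(c, c, 3, rng, dilation=r) for r in dilations]
            if final_1x1:
                layers.append(Conv2d(c, c, 1, rng))
            self.branches.append(layers)

    def modules(self):
        for branch in self.branches:
            yield from branch

    def named_parameters(self, prefix: str = ""):
        for i, branch in enumerate(self.branches):
            for j, layer in enumerate(branch):
                yield from layer.named_parameters(f"{prefix}branches.{i}.{j}.")

    def forward(self, x: Tensor) -> Tensor:
        out = x
        for branch in self.branches:
            y = x
            for layer in branch:
                y = relu(layer(y))
            out = out + y
        return out


# ---------------------------------------------------------------------------
# the full network
# ---------------------------------------------------------------------------

class DACNet(Module):
    """U-Net with CBAM attention and a DAC bottleneck (see module docstring)."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        w = config.stage_widths                      # e.g. [64,128,256,512,1024]
        cin = config.input_channels

        self.enc_convs, self.enc_cbams = [], []
        for i in range(config.depth):
            self.enc_convs.append(DoubleConv(cin, w[i], rng))
            self.enc_cbams.append(CBAM(w[i], config.cbam_reduction,
                                       config.cbam_spatial_kernel, rng))
            cin = w[i]
        self.bottleneck = DoubleConv(w[config.depth - 1], w[config.depth], rng)
        self.dac = DACBlock(w[config.depth], config, rng)

        self.dec_cbams = [CBAM(w[i + 1], config.cbam_reduction,
                               config.cbam_spatial_kernel, rng)
                          for i in reversed(range(config.depth - 1))]
        self.upconvs = [ConvTranspose2x2(w[i + 1], w[i], rng)
                        for i in reversed(range(config.depth))]
        self.dec_convs = [DoubleConv(2 * w[i], w[i], rng)
                          for i in reversed(range(config.depth))]
        self.head = Conv2d(w[0], config.out_channels, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        """Map (N, C_in, H, W) images to (N, out_channels, H, W) logits."""
        n, c, h, wdt = x.shape
        if h != wdt or h % (2 ** self.config.depth) != 0:
            raise ValueError(
                f"input {h}x{wdt} incompatible with depth {self.config.depth}")
        skips = []
        for conv, cbam in zip(self.enc_convs, self.enc_cbams):
            x = cbam(conv(x))
            skips.append(x)
            x = maxpool2x2(x)
        x = self.dac(self.bottleneck(x))             # DAC before up-sampling 1
        for i in range(self.config.depth):
            if i > 0:                                 # CBAM before up 2..depth
                x = self.dec_cbams[i - 1](x)
            x = self.upconvs[i](x)
            x = concat([skips[-(i + 1)], x], axis=1)
            x = self.dec_convs[i](x)
        return self.head(x)

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """Foreground (plaque) probability maps, shape (N, H, W).

        Softmax over the two output channels; runs in eval mode (BatchNorm
        uses running statistics) with no gradient tape.
        """
        self.set_training(False)
        logits = self.forward(Tensor(images)).data
        d = logits[:, 1] - logits[:, 0]
        return 1.0 / (1.0 + np.exp(-np.clip(d, -60.0, 60.0)))


# ---------------------------------------------------------------------------
# analytic bookkeeping: shapes and parameter counts
# ---------------------------------------------------------------------------

def stage_shapes(config: NetworkConfig) -> list[tuple[str, int, int]]:
    """Per-stage (name, channels, spatial size), computed analytically.

    Mirrors the tensor shapes ``DACNet.forward`` produces without building
    the model, so the 512-scale plan can be inspected instantly.
    """
    s, w = config.input_size, config.stage_widths
    shapes = [("input", config.input_channels, s)]
    for i in range(config.depth):
        shapes.append((f"encoder{i + 1}", w[i], s))
        s //= 2
        shapes.append((f"pool{i + 1}", w[i], s))
    shapes.append(("bottleneck", w[config.depth], s))
    shapes.append(("dac", w[config.depth], s))
    for i in range(config.depth):
        s *= 2
        shapes.append((f"decoder{i + 1}", w[config.depth - 1 - i], s))
    shapes.append(("output", config.out_channels, s))
    return shapes


def _double_conv_params(cin: int, cout: int) -> int:
    conv = cin * cout * 9 + cout + cout * cout * 9 + cout
    return conv + 4 * cout                           # two BN (gamma, beta)


def _cbam_params(c: int, reduction: int, k: int) -> int:
    h = max(c // reduction, 1)
    mlp = c * h + h + h * c + c
    return mlp + 2 * k * k + 1


def dac_parameter_count(c: int,
                        dilations: Sequence[Sequence[int]] = DEFAULT_DAC_DILATIONS,
                        final_1x1: Sequence[bool] = DEFAULT_DAC_FINAL_1X1) -> int:
    """Trainable parameters of a DAC block at width ``c``.

    Dilation never changes a kernel's parameter count, so only the number
    of 3x3 and 1x1 convolutions matters.
    """
    total = 0
    for branch, f in zip(dilations, final_1x1):
        total += len(branch) * (c * c * 9 + c)
        if f:
            total += c * c + c
    return total


def plain_stack_parameter_count(c: int, rf: int = 19) -> int:
    """Parameters of a plain 3x3 stack matched to receptive field ``rf``.

    Replacing every dilated convolution by standard 3x3 convolutions, a
    stack of (rf - 1) / 2 layers at equal width reaches the same receptive
    field; this is the undilated equivalent the DAC block economises over.
    """
    n_layers = (rf - 1) // 2
    return n_layers * (c * c * 9 + c)


def count_parameters(config: NetworkConfig) -> int:
    """Total trainable parameter count, summed analytically layer by layer.

    Equals ``DACNet(config).num_parameters()`` for every valid config.
    """
    w = config.stage_widths
    total = 0
    cin = config.input_channels
    for i in range(config.depth):
        total += _double_conv_params(cin, w[i])
        total += _cbam_params(w[i], config.cbam_reduction,
                              config.cbam_spatial_kernel)
        cin = w[i]
    total += _double_conv_params(w[config.depth - 1], w[config.depth])
    total += dac_parameter_count(w[config.depth], config.dac_dilations,
                                 config.dac_final_1x1)
    for i in reversed(range(config.depth - 1)):
        total += _cbam_params(w[i + 1], config.cbam_reduction,
                              config.cbam_spatial_kernel)
    for i in reversed(range(config.depth)):
        total += w[i + 1] * w[i] * 4 + w[i]          # 2x2 transposed conv
        total += _double_conv_params(2 * w[i], w[i])
    total += w[0] * config.out_channels + config.out_channels
    return total


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: DACNet, path) -> None:
    """Serialise weights, BatchNorm running stats and the config to one file."""
    arrays = {f"param:{n}": p.data for n, p in model.named_parameters()}
    for i, m in enumerate(_all_bn(model)):
        arrays[f"bn:{i}:mean"] = m.running_mean
        arrays[f"bn:{i}:var"] = m.running_var
    arrays["config_json"] = np.frombuffer(
        json.dumps(model.config.to_dict()).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path, expected_config: NetworkConfig | None = None) -> DACNet:
    """Rebuild a model from :func:`save_checkpoint` output.

    Raises ``ValueError`` if ``expected_config`` disagrees with the stored
    config, or if any stored array does not fit the rebuilt model.
    """
    with np.load(path) as data:
        stored = NetworkConfig.from_dict(
            json.loads(bytes(data["config_json"]).decode()))
        if expected_config is not None and \
                expected_config.to_dict() != stored.to_dict():
            raise ValueError("checkpoint config does not match expected config")
        model = DACNet(stored)
        params = dict(model.named_parameters())
        for key in data.files:
            if key.startswith("param:"):
                name = key[len("param:"):]
                if name not in params or params[name].data.shape != data[key].shape:
                    raise ValueError(f"checkpoint parameter mismatch: {name}")
                params[name].data = data[key].astype(np.float32)
        bns = _all_bn(model)
        for i, m in enumerate(bns):
            m.running_mean = data[f"bn:{i}:mean"].astype(np.float32)
            m.running_var = data[f"bn:{i}:var"].astype(np.float32)
    return model


def _all_bn(module: Module) -> list[BatchNorm2d]:
    found = []
    for m in module.modules():
        if isinstance(m, BatchNorm2d):
            found.append(m)
        found.extend(_all_bn(m))
    return found
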