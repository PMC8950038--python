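"""The cascade W-shaped segmentation networks.

ASW-Net is a lightweight "simplified W" encoder-decoder for 3-class
nucleus segmentation: two down-samplings, one up-sampling (re-entering
only the features generated before the second down-sampling), one more
down-sampling and two final up-samplings -- three of each in total,
tracing a W.  Additive attention gates modulate every skip connection in
the decoding phases, and the original input is concatenated back in
before the 1x1 classification head (the first up-sampling deliberately
does not receive the raw input).  SW-Net is the identical graph with the
attention gates replaced by plain skips; a standard 3-scale U-Net is
included as a baseline.

All variants map a batch of single-channel images to a per-pixel softmax
over {background, interior, boundary} at the input resolution.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .errors import ShapeError, UnknownLayer
from .io import ProbMap

__all__ = [
    "NetworkConfig",
    "ModelHandle",
    "build_asw_net",
    "build_sw_net",
    "build_u_net",
    "build_model",
    "attention_gate",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class NetworkConfig:
    """Architecture hyper-parameters.

    Channel widths follow the U-Net convention ``base_filters x {1,2,4}``
    across the three scales.  Input dimensions must be divisible by 8
    (three 2x down-samplings in the deepest path).
    """

    base_filters: int = 16
    kernel_size: int = 3
    depth_downsamples: int = 3
    use_attention: bool = True
    use_batchnorm: bool = True
    n_classes: int = 3
    padding_mode: str = "zeros"  # "wrap" gives exact shift equivariance
    init_seed: int = 0

    def __post_init__(self):
        if self.base_filters < 1:
            raise ValueError("base_filters must be >= 1")
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd")
        if self.depth_downsamples != 3:
            raise ValueError("the W topology is defined for 3 down-samplings")
        if self.padding_mode not in ("zeros", "wrap"):
            raise ValueError("padding_mode must be 'zeros' or 'wrap'")


def _check_input_shape(x: np.ndarray):
    if x.ndim != 4 or x.shape[1] != 1:
        raise ShapeError("expected input of shape (N, 1, H, W)")
    if x.shape[2] % 8 != 0 or x.shape[3] % 8 != 0:
        raise ShapeError("input height and width must be divisible by 8")


class _Module:
    def parameters(self) -> dict[str, Tensor]:
        raise NotImplementedError


class Conv2d(_Module):
    """k x k same convolution with Glorot-uniform init."""

    def __init__(self, c_in, c_out, k, rng, padding_mode="zeros"):
        limit = np.sqrt(6.0 / (c_in * k * k + c_out * k * k))
        self.w = Tensor(rng.uniform(-limit, limit, (c_out, c_in, k, k)
                                    ).astype(np.float32), requires_grad=True)
        self.b = Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True)
        self.padding_mode = padding_mode

    def __call__(self, x):
        return ad.conv2d(x, self.w, self.b, padding_mode=self.padding_mode)

    def parameters(self):
        return {"w": self.w, "b": self.b}


class ConvTranspose2d(_Module):
    """2x2, stride-2 transposed convolution (learned 2x up-sampling)."""

    def __init__(self, c_in, c_out, rng):
        limit = np.sqrt(6.0 / (c_in * 4 + c_out * 4))
        self.w = Tensor(rng.uniform(-limit, limit, (c_in, c_out, 2, 2)
                                    ).astype(np.float32), requires_grad=True)
        self.b = Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True)

    def __call__(self, x):
        return ad.conv_transpose2x2(x, self.w, self.b)

    def parameters(self):
        return {"w": self.w, "b": self.b}


class BatchNorm2d(_Module):
    def __init__(self, c):
        self.gamma = Tensor(np.ones(c, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(c, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def __call__(self, x, training):
        return ad.batchnorm(x, self.gamma, self.beta,
                            self.running_mean, self.running_var, training)

    def parameters(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def buffers(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}


class ConvBlock(_Module):
    """Two k x k convolutions, each followed by (BN and) ReLU."""

    def __init__(self, c_in, c_out, k, rng, use_bn, padding_mode):
        self.conv1 = Conv2d(c_in, c_out, k, rng, padding_mode)
        self.conv2 = Conv2d(c_out, c_out, k, rng, padding_mode)
        self.bn1 = BatchNorm2d(c_out) if use_bn else None
        self.bn2 = BatchNorm2d(c_out) if use_bn else None

    def __call__(self, x, training):
        h = self.conv1(x)
        if self.bn1 is not None:
            h = self.bn1(h, training)
        h = ad.relu(h)
        h = self.conv2(h)
        if self.bn2 is not None:
            h = self.bn2(h, training)
        return ad.relu(h)

    def parameters(self):
        out = {}
        for name, mod in (("conv1", self.conv1), ("conv2", self.conv2),
                          ("bn1", self.bn1), ("bn2", self.bn2)):
            if mod is not None:
                for k, v in mod.parameters().items():
                    out[f"{name}.{k}"] = v
        return out


class AttentionGate(_Module):
    """Additive attention gate over a skip connection.

    The skip features and the (up-sampled) gating signal are each
    projected by 1x1 convolutions to an intermediate width, summed,
    passed through ReLU, projected to a single channel and squashed by a
    sigmoid; the resulting coefficient map in (0, 1) multiplies the skip
    features elementwise.  The coefficient map is kept for visualization.
    """

    def __init__(self, c_skip, c_gate, rng, c_inter=None):
        c_inter = c_inter or max(c_skip // 2, 1)
        self.theta_x = Conv2d(c_skip, c_inter, 1, rng)
        self.theta_g = Conv2d(c_gate, c_inter, 1, rng)
        self.psi = Conv2d(c_inter, 1, 1, rng)
        self.last_coefficients: np.ndarray | None = None

    def __call__(self, skip: Tensor, gate: Tensor):
        while gate.data.shape[2] < skip.data.shape[2]:
            gate = ad.upsample2_nearest(gate)
        if gate.data.shape[2:] != skip.data.shape[2:]:
            raise ShapeError("gating signal cannot be matched to skip resolution")
        a = ad.relu(ad.add(self.theta_x(skip), self.theta_g(gate)))
        coeff = ad.sigmoid(self.psi(a))          # (N, 1, H, W) in (0, 1)
        self.last_coefficients = coeff.data
        return ad.mul(skip, coeff), coeff

    def parameters(self):
        out = {}
        for name, mod in (("theta_x", self.theta_x), ("theta_g", self.theta_g),
                          ("psi", self.psi)):
            for k, v in mod.parameters().items():
                out[f"{name}.{k}"] = v
        return out


def attention_gate(skip_features, gating_features, rng_seed: int = 0):
    """Standalone functional form of the additive attention gate.

    Returns ``(gated skip features, coefficient map)`` as arrays; mainly
    for experimentation and tests -- the builders embed
    :class:`AttentionGate` modules directly.
    """
    skip = np.asarray(skip_features, dtype=np.float32)
    gate = np.asarray(gating_features, dtype=np.float32)
    if gate.shape[2] > skip.shape[2] or gate.shape[3] > skip.shape[3]:
        raise ShapeError("gating spatial dims must not exceed skip dims")
    rng = np.random.default_rng(rng_seed)
    module = AttentionGate(skip.shape[1], gate.shape[1], rng)
    gated, coeff = module(Tensor(skip), Tensor(gate))
    return gated.data, coeff.data


class ModelHandle:
    """A built network: forward function, parameters and metadata."""

    def __init__(self, variant: str, config: NetworkConfig):
        self.variant = variant
        self.config = config
        self.modules: dict[str, _Module] = {}
        self.activations: dict[str, np.ndarray] = {}
        #: names of the feature blocks at the five characteristic depths
        #: (first block, pre-first-upsample, middle, pre-second-upsample, last)
        self.feature_blocks: list[str] = []
        self.gate_names: list[str] = []

    # -- parameter bookkeeping ------------------------------------------
    def parameters(self) -> dict[str, Tensor]:
        out = {}
        for mname, mod in self.modules.items():
            for pname, t in mod.parameters().items():
                out[f"{mname}.{pname}"] = t
        return out

    def buffers(self) -> dict[str, np.ndarray]:
        out = {}
        for mname, mod in self.modules.items():
            stack = [(mname, mod)]
            for sub in ("bn1", "bn2"):
                m = getattr(mod, sub, None)
                if isinstance(m, BatchNorm2d):
                    stack.append((f"{mname}.{sub}", m))
            for name, m in stack:
                if isinstance(m, BatchNorm2d):
                    for k, v in m.buffers().items():
                        out[f"{name}.{k}"] = v
        return out

    @property
    def parameter_count(self) -> int:
        return int(sum(t.data.size for t in self.parameters().values()))

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: t.data.copy() for k, t in self.parameters().items()}
        state.update({k: v.copy() for k, v in self.buffers().items()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = self.parameters()
        buffers = self.buffers()
        for k, v in state.items():
            if k in params:
                params[k].data = np.array(v, dtype=np.float32)
            elif k in buffers:
                buffers[k][...] = v
            else:
                raise UnknownLayer(k)

    def zero_grad(self):
        for t in self.parameters().values():
            t.zero_grad()

    # -- forward --------------------------------------------------------
    def forward_logits(self, x: np.ndarray, training: bool = False,
                       capture: bool = False) -> Tensor:
        raise NotImplementedError  # attached by the builder

    def forward(self, batch) -> np.ndarray:
        """Normalized-image batch (N, H, W) or (N, 1, H, W) -> probs (N, 3, H, W)."""
        x = np.asarray(batch, dtype=np.float32)
        if x.ndim == 2:
            x = x[None]
        if x.ndim == 3:
            x = x[:, None]
        _check_input_shape(x)
        logits = self.forward_logits(x, training=False)
        return ad.softmax(logits.data, axis=1)

    def predict_prob_map(self, image2d: np.ndarray) -> ProbMap:
        probs = self.forward(np.asarray(image2d)[None])[0]
        return ProbMap(probs=probs)

    def attention_maps(self) -> dict[str, np.ndarray]:
        if not self.gate_names:
            raise UnknownLayer(f"variant {self.variant!r} has no attention gates")
        out = {}
        for name in self.gate_names:
            gate = self.modules[name]
            if gate.last_coefficients is None:
                raise RuntimeError("run a forward pass before requesting gates")
            out[name] = gate.last_coefficients
        return out


def _merge(skip: Tensor, up: Tensor, gate_mod, gating: Tensor,
           handle: ModelHandle, capture: bool, gate_name: str):
    """Concatenate decoder features with the (possibly gated) skip."""
    if gate_mod is not None:
        gated, coeff = gate_mod(skip, gating)
        if capture:
            handle.activations[f"{gate_name}_coefficients"] = coeff.data
        skip = gated
    return ad.concat([up, skip], axis=1)


def build_asw_net(config: NetworkConfig | None = None) -> ModelHandle:
    """Build ASW-Net (attention-gated simplified W network)."""
    return _build_w(config or NetworkConfig(), attention=True)


def build_sw_net(config: NetworkConfig | None = None) -> ModelHandle:
    """Build SW-Net: ASW-Net with plain skips instead of attention gates."""
    cfg = (dataclasses.replace(config, use_attention=False)
           if config else NetworkConfig(use_attention=False))
    return _build_w(cfg, attention=False)


def _build_w(config: NetworkConfig, attention: bool) -> ModelHandle:
    f = config.base_filters
    k = config.kernel_size
    rng = np.random.default_rng(config.init_seed)
    bn = config.use_batchnorm
    pm = config.padding_mode
    h = ModelHandle("asw" if attention else "sw", config)
    m = h.modules
    m["c0"] = ConvBlock(1, f, k, rng, bn, pm)
    m["c1"] = ConvBlock(f, 2 * f, k, rng, bn, pm)
    m["c2"] = ConvBlock(2 * f, 4 * f, k, rng, bn, pm)
    m["u1"] = ConvTranspose2d(4 * f, 2 * f, rng)
    m["c3"] = ConvBlock(4 * f, 2 * f, k, rng, bn, pm)
    m["c4"] = ConvBlock(2 * f, 4 * f, k, rng, bn, pm)
    m["u2"] = ConvTranspose2d(4 * f, 2 * f, rng)
    m["c5"] = ConvBlock(4 * f, 2 * f, k, rng, bn, pm)
    m["u3"] = ConvTranspose2d(2 * f, f, rng)
    m["c6"] = ConvBlock(2 * f, f, k, rng, bn, pm)
    m["head"] = Conv2d(f + 1, config.n_classes, 1, rng)
    if attention:
        m["ag1"] = AttentionGate(2 * f, 4 * f, rng)
        m["ag2"] = AttentionGate(2 * f, 4 * f, rng)
        m["ag3"] = AttentionGate(f, 2 * f, rng)
        h.gate_names = ["ag1", "ag2", "ag3"]
    h.feature_blocks = ["c0", "c2", "c3", "c4", "c6"]

    def forward_logits(x: np.ndarray, training: bool = False,
                       capture: bool = False) -> Tensor:
        _check_input_shape(np.asarray(x))
        xin = Tensor(np.asarray(x, dtype=np.float32))
        act: dict[str, np.ndarray] = {}
        c0 = m["c0"](xin, training)                      # H
        c1 = m["c1"](ad.maxpool2x2(c0), training)        # H/2
        c2 = m["c2"](ad.maxpool2x2(c1), training)        # H/4
        u1 = m["u1"](c2)                                 # H/2
        # first decoding phase: only features generated before the second
        # down-sampling (c1) are re-entered -- never the raw input
        g1 = m.get("ag1")
        c3 = m["c3"](_merge(c1, u1, g1, c2, h, capture, "ag1"), training)
        c4 = m["c4"](ad.maxpool2x2(c3), training)        # H/4
        u2 = m["u2"](c4)                                 # H/2
        c5 = m["c5"](_merge(c3, u2, m.get("ag2"), c4, h, capture, "ag2"), training)
        u3 = m["u3"](c5)                                 # H
        c6 = m["c6"](_merge(c0, u3, m.get("ag3"), c5, h, capture, "ag3"), training)
        # merge the deep result with the original input before classifying
        logits = m["head"](ad.concat([c6, xin], axis=1))
        if capture:
            for name, t in (("c0", c0), ("c1", c1), ("c2", c2), ("c3", c3),
                            ("c4", c4), ("c5", c5), ("c6", c6)):
                act[name] = t.data
            h.activations = act | {k: v for k, v in h.activations.items()
                                   if k.endswith("coefficients")}
        return logits

    h.forward_logits = forward_logits
    return h


def build_u_net(config: NetworkConfig | None = None) -> ModelHandle:
    """Standard symmetric 3-scale U-Net baseline with a 3-class head."""
    config = config or NetworkConfig(use_attention=False)
    f = config.base_filters
    k = config.kernel_size
    rng = np.random.default_rng(config.init_seed)
    bn = config.use_batchnorm
    pm = config.padding_mode
    h = ModelHandle("unet", config)
    m = h.modules
    m["e0"] = ConvBlock(1, f, k, rng, bn, pm)
    m["e1"] = ConvBlock(f, 2 * f, k, rng, bn, pm)
    m["e2"] = ConvBlock(2 * f, 4 * f, k, rng, bn, pm)
    m["bottleneck"] = ConvBlock(4 * f, 8 * f, k, rng, bn, pm)
    m["u2"] = ConvTranspose2d(8 * f, 4 * f, rng)
    m["d2"] = ConvBlock(8 * f, 4 * f, k, rng, bn, pm)
    m["u1"] = ConvTranspose2d(4 * f, 2 * f, rng)
    m["d1"] = ConvBlock(4 * f, 2 * f, k, rng, bn, pm)
    m["u0"] = ConvTranspose2d(2 * f, f, rng)
    m["d0"] = ConvBlock(2 * f, f, k, rng, bn, pm)
    m["head"] = Conv2d(f, config.n_classes, 1, rng)
    h.feature_blocks = ["e0", "e2", "bottleneck", "d2", "d0"]

    def forward_logits(x: np.ndarray, training: bool = False,
                       capture: bool = False) -> Tensor:
        _check_input_shape(np.asarray(x))
        xin = Tensor(np.asarray(x, dtype=np.float32))
        e0 = m["e0"](xin, training)
        e1 = m["e1"](ad.maxpool2x2(e0), training)
        e2 = m["e2"](ad.maxpool2x2(e1), training)
        bott = m["bottleneck"](ad.maxpool2x2(e2), training)
        d2 = m["d2"](ad.concat([m["u2"](bott), e2], axis=1), training)
        d1 = m["d1"](ad.concat([m["u1"](d2), e1], axis=1), training)
        d0 = m["d0"](ad.concat([m["u0"](d1), e0], axis=1), training)
        logits = m["head"](d0)
        if capture:
            h.activations = {name: t.data for name, t in
                             (("e0", e0), ("e1", e1), ("e2", e2),
                              ("bottleneck", bott), ("d2", d2), ("d1", d1),
                              ("d0", d0))}
        return logits

    h.forward_logits = forward_logits
    return h


_BUILDERS = {"asw": build_asw_net, "sw": build_sw_net, "unet": build_u_net}


def build_model(variant: str, config: NetworkConfig | None = None) -> ModelHandle:
    if variant not in _BUILDERS:
        raise ValueError(f"unknown variant {variant!r}; choose from {sorted(_BUILDERS)}")
    return _BUILDERS[variant](config)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: ModelHandle, path) -> None:
    """Write weights (.npz) plus a JSON sidecar with the architecture."""
    path = Path(path)
    with open(path, "wb") as fh:
        np.savez(fh, **model.state_dict())
    sidecar = {
        "variant": model.variant,
        "parameter_count": model.parameter_count,
        "config": {k: v for k, v in vars(model.config).items()},
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path) -> ModelHandle:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    config = NetworkConfig(**sidecar["config"])
    model = build_model(sidecar["variant"], config)
    with np.load(path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model
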