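"""The siamese pyramid fusion network.

Two weight-sharing encoder branches (a 3x3 convolutional stem, a
channel-coupling gate driven by global average/max pooling through a shared
MLP, and a spatial-pyramid coupling block pooling onto 16/4/2/1 grids) map
the CT and PET slices to feature stacks; a parameter-free cross-correlation
layer matches 3x3 patches between the two stacks over a small displacement
window (stride 3 per displacement step); and a three-stage deconvolutional
decoder reconstructs the fused slice through a sigmoid, so the output lives
in [0, 1] like its normalized sources.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .autodiff import (
    Tensor,
    adaptive_avg_pool2d,
    bilinear_upsample,
    concat,
    conv2d,
    conv_transpose2d,
    global_max_pool,
)
from .preprocessing import Image2D, ImagePair

__all__ = [
    "ModelConfig",
    "ModelParams",
    "init_parameters",
    "conv_stem",
    "channel_coupling",
    "channel_gate",
    "spatial_pyramid_coupling",
    "encode",
    "cross_correlation_fuse",
    "decode",
    "fuse",
    "fuse_tensor",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    The pyramid scales (16, 4, 2, 1) and the correlation stride o = 3 are
    fixed by the method; channel widths, the MLP bottleneck, patch size and
    displacement radius are implementation defaults.
    """

    stem_channels: int = 16
    stem_kernel: int = 3
    mlp_reduction: int = 4
    spp_scales: tuple[int, ...] = (16, 4, 2, 1)
    spp_branch_channels: int = 8
    corr_patch: tuple[int, int] = (3, 3)
    corr_stride: int = 3
    corr_window_radius: int = 1
    decoder_channels: tuple[int, int] = (16, 16)
    decoder_kernels: tuple[int, int, int] = (3, 3, 3)
    decoder_strides: tuple[int, int, int] = (1, 1, 1)
    activation: str = "relu"
    untied: bool = False

    def __post_init__(self):
        if list(self.spp_scales) != sorted(self.spp_scales, reverse=True) or len(
            set(self.spp_scales)
        ) != len(self.spp_scales):
            raise ValueError("spp_scales must be strictly decreasing")
        if self.spp_scales[-1] != 1:
            raise ValueError("spp_scales must end at 1")
        if self.corr_stride < 1 or min(self.corr_patch) < 1:
            raise ValueError("correlation patch dims and stride must be >= 1")
        if self.corr_window_radius < 0:
            raise ValueError("corr_window_radius must be >= 0")
        if not (len(self.decoder_kernels) == len(self.decoder_strides) == 3):
            raise ValueError("the decoder has exactly three stages")
        if len(self.decoder_channels) != 2:
            raise ValueError("decoder_channels specifies the two hidden widths")
        if self.activation != "relu":
            raise ValueError("only the relu activation is implemented")

    @property
    def corr_channels(self) -> int:
        return (2 * self.corr_window_radius + 1) ** 2

    @property
    def encoder_out_channels(self) -> int:
        return (
            self.stem_channels
            + len(self.spp_scales) * self.spp_branch_channels
            + 1
        )


class ModelParams:
    """Named parameter tensors; both siamese branches read the same set
    unless the configuration unties them."""

    def __init__(self, tensors: dict[str, Tensor]):
        self.tensors = tensors

    def __getitem__(self, name: str) -> Tensor:
        return self.tensors[name]

    def __contains__(self, name: str) -> bool:
        return name in self.tensors

    def items(self):
        return self.tensors.items()

    def n_entries(self) -> int:
        return sum(t.data.size for t in self.tensors.values())

    def l1_norm(self) -> float:
        return float(sum(np.abs(t.data).sum() for t in self.tensors.values()))

    def l1_tensor(self) -> Tensor:
        total = Tensor(0.0)
        for t in self.tensors.values():
            total = total + t.abs().sum()
        return total

    def zero_grad(self) -> None:
        for t in self.tensors.values():
            t.grad = None

    def copy(self) -> "ModelParams":
        out = {}
        for k, t in self.tensors.items():
            nt = Tensor(t.data.copy(), requires_grad=t.requires_grad)
            out[k] = nt
        return ModelParams(out)

    def all_finite(self) -> bool:
        return all(np.all(np.isfinite(t.data)) for t in self.tensors.values())


def _xavier(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


def _zeros(shape) -> Tensor:
    return Tensor(np.zeros(shape), requires_grad=True)


def _encoder_param_specs(cfg: ModelConfig):
    c = cfg.stem_channels
    k = cfg.stem_kernel
    hidden = max(1, c // cfg.mlp_reduction)
    b = cfg.spp_branch_channels
    specs = [
        ("stem.w", (c, 1, k, k), 1 * k * k, c * k * k),
        ("stem.b", (c,), None, None),
        ("gate.w1", (hidden, c), c, hidden),
        ("gate.b1", (hidden, 1), None, None),
        ("gate.w2", (c, hidden), hidden, c),
        ("gate.b2", (c, 1), None, None),
        ("spp.inner.w", (c, c, 3, 3), c * 9, c * 9),
        ("spp.inner.b", (c,), None, None),
    ]
    for g in cfg.spp_scales:
        specs.append((f"spp.scale{g}.w", (b, c, 3, 3), c * 9, b * 9))
        specs.append((f"spp.scale{g}.b", (b,), None, None))
    return specs


def init_parameters(cfg: ModelConfig, seed: int) -> ModelParams:
    """Glorot-uniform weights, zero biases, reproducible from the seed."""
    rng = np.random.default_rng(seed)
    tensors: dict[str, Tensor] = {}

    prefixes = [""] if not cfg.untied else ["", "pet."]
    for prefix in prefixes:
        for name, shape, fan_in, fan_out in _encoder_param_specs(cfg):
            if fan_in is None:
                tensors[prefix + name] = _zeros(shape)
            else:
                tensors[prefix + name] = _xavier(rng, shape, fan_in, fan_out)

    dec_in = (cfg.corr_channels, *cfg.decoder_channels)
    dec_out = (*cfg.decoder_channels, 1)
    for i, (ci, co, k) in enumerate(zip(dec_in, dec_out, cfg.decoder_kernels), start=1):
        tensors[f"dec{i}.w"] = _xavier(rng, (ci, co, k, k), ci * k * k, co * k * k)
        tensors[f"dec{i}.b"] = _zeros((co,))
    return ModelParams(tensors)


# ---------------------------------------------------------------------------
# Encoder stages
# ---------------------------------------------------------------------------


def _as_tensor(img) -> Tensor:
    if isinstance(img, Tensor):
        return img
    if isinstance(img, Image2D):
        if not img.normalized:
            raise ValueError("the encoder requires a normalized image")
        return Tensor(img.values[None])  # (1, H, W)
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim == 2:
        arr = arr[None]
    return Tensor(arr)


def conv_stem(img, params: ModelParams, cfg: ModelConfig = ModelConfig(), branch: str = "") -> Tensor:
    """3x3 convolutional stem extracting the low-level feature stack F."""
    x = _as_tensor(img)
    return conv2d(x, params[branch + "stem.w"], params[branch + "stem.b"]).relu()


def channel_gate(f: Tensor, params: ModelParams, cfg: ModelConfig = ModelConfig(), branch: str = "") -> Tensor:
    """The per-channel sigmoid gate: Sig(MLP(AvgPool(F)) + MLP(MaxPool(F))).

    The same two-layer MLP (bottleneck = channels / mlp_reduction) is
    applied to both pooled descriptors.
    """
    c = f.shape[0]
    avg = f.mean(axis=(1, 2)).reshape(c, 1)
    mx = global_max_pool(f).reshape(c, 1)

    def mlp(v: Tensor) -> Tensor:
        h = (params[branch + "gate.w1"] @ v + params[branch + "gate.b1"]).relu()
        return params[branch + "gate.w2"] @ h + params[branch + "gate.b2"]

    return (mlp(avg) + mlp(mx)).sigmoid()


def channel_coupling(f: Tensor, params: ModelParams, cfg: ModelConfig = ModelConfig(), branch: str = "") -> Tensor:
    """Rescale each channel of F by its gate: F' = g (x) F."""
    c = f.shape[0]
    gate = channel_gate(f, params, cfg, branch).reshape(c, 1, 1)
    return gate * f


def spatial_pyramid_coupling(
    f_c: Tensor, params: ModelParams, cfg: ModelConfig = ModelConfig(), branch: str = ""
) -> Tensor:
    """Multi-scale block: Concat_g(Conv_g(SPP_g(Conv(F')))) upsampled to full size.

    Each pyramid scale g pools the inner convolution onto a g x g grid,
    refines it with a per-scale 3x3 convolution, and is resampled back to
    the input resolution before channel concatenation.
    """
    _, h, w = f_c.shape
    largest = cfg.spp_scales[0]
    if h < largest or w < largest:
        raise ValueError(
            f"spatial size {h}x{w} is smaller than the largest pyramid scale "
            f"{largest}; configure a smaller spp_scales set"
        )
    inner = conv2d(f_c, params[branch + "spp.inner.w"], params[branch + "spp.inner.b"]).relu()
    branches = []
    for g in cfg.spp_scales:
        pooled = adaptive_avg_pool2d(inner, g)
        refined = conv2d(
            pooled, params[branch + f"spp.scale{g}.w"], params[branch + f"spp.scale{g}.b"]
        ).relu()
        branches.append(bilinear_upsample(refined, h, w))
    return concat(branches, axis=0)


def encode(img, params: ModelParams, cfg: ModelConfig = ModelConfig(), branch: str = "") -> Tensor:
    """One siamese branch: stem, channel coupling, pyramid coupling, then
    superimposition (channel concatenation) of F', F'' and the original image."""
    x = _as_tensor(img)
    f = conv_stem(x, params, cfg, branch)
    f_c = channel_coupling(f, params, cfg, branch)
    f_s = spatial_pyramid_coupling(f_c, params, cfg, branch)
    return concat([f_c, f_s, x], axis=0)


# ---------------------------------------------------------------------------
# Cross-correlation fusion (parameter-free)
# ---------------------------------------------------------------------------


def _shift2d(x: Tensor, dy: int, dx: int) -> Tensor:
    """shifted[c, i, j] = x[c, i + dy, j + dx], zero outside the raster."""
    _, h, w = x.shape
    pt, pb = max(dy, 0), max(-dy, 0)
    pl, pr = max(dx, 0), max(-dx, 0)
    padded = x.pad2d(pb, pt, pr, pl)
    return padded[:, pt : pt + h, pl : pl + w]


def cross_correlation_fuse(f_ct: Tensor, f_pet: Tensor, cfg: ModelConfig = ModelConfig()) -> Tensor:
    """Patch cross-correlation between the two encoded stacks.

    At every site the m x n patch of the CT stack is inner-producted with
    the PET-stack patch displaced by multiples of the stride o (within
    corr_window_radius steps per axis), SAME zero padding, responses
    averaged over input channels: one output channel per displacement,
    (2r + 1)^2 in total. The layer holds no trainable weight.
    """
    if f_ct.shape != f_pet.shape:
        raise ValueError(f"feature shapes differ: {f_ct.shape} vs {f_pet.shape}")
    m, n = cfg.corr_patch
    o = cfg.corr_stride
    r = cfg.corr_window_radius
    box = Tensor(np.ones((1, 1, m, n)))  # constant patch-summation kernel
    responses = []
    for dy in range(-r * o, r * o + 1, o):
        for dx in range(-r * o, r * o + 1, o):
            prod = f_ct * _shift2d(f_pet, dy, dx)
            chan_mean = prod.mean(axis=0, keepdims=True)
            responses.append(conv2d(chan_mean, box, padding="same"))
    return concat(responses, axis=0)


# ---------------------------------------------------------------------------
# Decoder and end-to-end fusion
# ---------------------------------------------------------------------------


def decode(f_pc: Tensor, params: ModelParams, cfg: ModelConfig = ModelConfig()) -> Tensor:
    """Three transposed convolutions; the last maps through a sigmoid so the
    reconstruction lies in [0, 1]. Returns a (1, H, W) tensor."""
    x = f_pc
    for i, stride in enumerate(cfg.decoder_strides, start=1):
        x = conv_transpose2d(x, params[f"dec{i}.w"], params[f"dec{i}.b"], stride=stride)
        x = x.relu() if i < 3 else x.sigmoid()
    return x


def fuse_tensor(pair: ImagePair, params: ModelParams, cfg: ModelConfig = ModelConfig()) -> Tensor:
    """Full differentiable forward pass; used by the training loop."""
    pet_branch = "pet." if cfg.untied else ""
    f_ct = encode(pair.ct, params, cfg, branch="")
    f_pet = encode(pair.pet, params, cfg, branch=pet_branch)
    f_pc = cross_correlation_fuse(f_ct, f_pet, cfg)
    return decode(f_pc, params, cfg)


def fuse(pair: ImagePair, params: ModelParams, cfg: ModelConfig = ModelConfig()) -> Image2D:
    """Fuse a registered pair into a single [0, 1] image."""
    out = fuse_tensor(pair, params, cfg)
    return Image2D(out.data[0], modality="FUSED", normalized=True)


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

_CHECKPOINT_VERSION = 1


def save_checkpoint(path, params: ModelParams, cfg: ModelConfig) -> None:
    """Single-file archive: named parameter tensors + config echo + version."""
    meta = {"version": _CHECKPOINT_VERSION, "config": asdict(cfg)}
    arrays = {f"param::{k}": t.data for k, t in params.items()}
    np.savez(Path(path), __meta__=np.array(json.dumps(meta)), **arrays)


def load_checkpoint(path) -> tuple[ModelParams, ModelConfig]:
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such checkpoint: {path}")
    with np.load(path) as z:
        meta = json.loads(str(z["__meta__"]))
        if meta.get("version") != _CHECKPOINT_VERSION:
            raise IOError(f"unsupported checkpoint version in {path}")
        raw = dict(meta["config"])
        for key in ("spp_scales", "corr_patch", "decoder_channels", "decoder_kernels", "decoder_strides"):
            raw[key] = tuple(raw[key])
        cfg = ModelConfig(**raw)
        tensors = {
            k[len("param::") :]: Tensor(z[k].copy(), requires_grad=True)
            for k in z.files
            if k.startswith("param::")
        }
    return ModelParams(tensors), cfg
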