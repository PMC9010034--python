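"""Self-supervised training objective: structural similarity plus weight L1.

The fused slice is scored against each source by SSIM; the loss is
(1 - SSIM(ct, fused)) + (1 - SSIM(pet, fused)) + lambda * sum|omega|, where
omega collects every network weight. With normalized inputs the dynamic
range L is 1, so the stabilizers are C1 = (0.01)^2 and C2 = (0.03)^2.

By default SSIM is computed from whole-image moments (global mode); a
windowed mode (11 x 11 Gaussian, sigma 1.5, valid support) is available
since local SSIM is the more common training signal in the fusion
literature. Both are differentiable through the autodiff engine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, conv2d
from .model import ModelParams
from .preprocessing import Image2D

__all__ = ["SSIMConfig", "LossValue", "ssim", "ssim_loss", "fusion_loss"]


@dataclass(frozen=True)
class SSIMConfig:
    k1: float = 0.01
    k2: float = 0.03
    dynamic_range: float = 1.0  # L; normalized images span [0, 1]
    mode: str = "global"  # or "windowed"
    window_size: int = 11
    window_sigma: float = 1.5

    def __post_init__(self):
        if self.k1 <= 0 or self.k2 <= 0 or self.dynamic_range <= 0:
            raise ValueError("k1, k2 and the dynamic range must be positive")
        if self.mode not in ("global", "windowed"):
            raise ValueError(f"unknown SSIM mode {self.mode!r}")
        if self.mode == "windowed" and self.window_size < 2:
            raise ValueError("window_size must be >= 2")

    @property
    def c1(self) -> float:
        return (self.k1 * self.dynamic_range) ** 2

    @property
    def c2(self) -> float:
        return (self.k2 * self.dynamic_range) ** 2


@dataclass(frozen=True)
class LossValue:
    """Components of one loss evaluation (floats; the graph root is internal)."""

    total: float
    ssim_ct: float
    ssim_pet: float
    l1_term: float
    lam: float


def _to_tensor(img) -> Tensor:
    if isinstance(img, Tensor):
        return img
    if isinstance(img, Image2D):
        return Tensor(img.values)
    return Tensor(np.asarray(img, dtype=np.float64))


def _flatten2d(t: Tensor) -> Tensor:
    if t.ndim == 3:
        if t.shape[0] != 1:
            raise ValueError("expected a single-channel map")
        t = t.reshape(t.shape[1], t.shape[2])
    return t


def _gaussian_window(size: int, sigma: float) -> np.ndarray:
    ax = np.arange(size) - (size - 1) / 2.0
    g = np.exp(-(ax**2) / (2.0 * sigma**2))
    k = np.outer(g, g)
    return k / k.sum()


def ssim_tensor(x: Tensor, y: Tensor, cfg: SSIMConfig = SSIMConfig()) -> Tensor:
    """Differentiable SSIM; returns a scalar tensor."""
    x = _flatten2d(x)
    y = _flatten2d(y)
    if x.shape != y.shape:
        raise ValueError(f"ssim: shapes differ {x.shape} vs {y.shape}")
    c1, c2 = cfg.c1, cfg.c2
    if cfg.mode == "global":
        mx = x.mean()
        my = y.mean()
        vx = ((x - mx) ** 2).mean()
        vy = ((y - my) ** 2).mean()
        cov = ((x - mx) * (y - my)).mean()
        lum = (2.0 * mx * my + c1) / (mx**2 + my**2 + c1)
        struct = (2.0 * cov + c2) / (vx + vy + c2)
        return lum * struct
    # windowed: local Gaussian moments over valid support
    h, w = x.shape
    if h < cfg.window_size or w < cfg.window_size:
        raise ValueError("image smaller than the SSIM window")
    win = Tensor(_gaussian_window(cfg.window_size, cfg.window_sigma)[None, None])
    x3 = x.reshape(1, h, w)
    y3 = y.reshape(1, h, w)
    mx = conv2d(x3, win, padding="valid")
    my = conv2d(y3, win, padding="valid")
    vx = conv2d(x3 * x3, win, padding="valid") - mx * mx
    vy = conv2d(y3 * y3, win, padding="valid") - my * my
    cov = conv2d(x3 * y3, win, padding="valid") - mx * my
    ssim_map = ((2.0 * mx * my + c1) * (2.0 * cov + c2)) / (
        (mx * mx + my * my + c1) * (vx + vy + c2)
    )
    return ssim_map.mean()


def ssim(x, y, cfg: SSIMConfig = SSIMConfig()) -> float:
    """Structural similarity between two same-shape images, in [-1, 1]."""
    return float(ssim_tensor(_to_tensor(x), _to_tensor(y), cfg).data)


def ssim_loss(x, y, cfg: SSIMConfig = SSIMConfig()) -> float:
    """1 - SSIM(x, y); zero iff the two images are structurally identical."""
    return 1.0 - ssim(x, y, cfg)


def fusion_loss_tensor(
    ct,
    pet,
    fused: Tensor,
    params: ModelParams | None = None,
    lam: float = 1e-4,
    cfg: SSIMConfig = SSIMConfig(),
) -> tuple[Tensor, dict]:
    """Graph-building form of the objective; returns (total tensor, components)."""
    s_ct = ssim_tensor(_to_tensor(ct), fused, cfg)
    s_pet = ssim_tensor(_to_tensor(pet), fused, cfg)
    total = (1.0 - s_ct) + (1.0 - s_pet)
    if params is not None and lam != 0.0:
        l1 = params.l1_tensor()
        total = total + lam * l1
        l1_val = float(l1.data)
    else:
        l1_val = params.l1_norm() if params is not None else 0.0
    parts = {"ssim_ct": float(s_ct.data), "ssim_pet": float(s_pet.data), "l1_term": l1_val}
    return total, parts


def fusion_loss(
    ct,
    pet,
    fused,
    params: ModelParams | None = None,
    lam: float = 1e-4,
    cfg: SSIMConfig = SSIMConfig(),
) -> LossValue:
    """Evaluate the full objective on (ct, pet, fused) and report components."""
    total, parts = fusion_loss_tensor(ct, pet, _to_tensor(fused), params, lam, cfg)
    return LossValue(
        total=float(total.data),
        ssim_ct=parts["ssim_ct"],
        ssim_pet=parts["ssim_pet"],
        l1_term=parts["l1_term"],
        lam=lam,
    )
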