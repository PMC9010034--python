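"""Synthetic thorax phantoms: registered CT-like / PET-like slice pairs.

The generator emulates the statistical structure of a registered clinical
PET/CT slice pair without any real data: the CT channel is a piecewise
anatomy (body ellipse, two darker lung fields, a bright spine/rib
structure) with fine additive texture and sharp boundaries; the PET channel
shares the same geometry but is a heavily smoothed low-resolution map whose
only salient content is a small number of high-uptake "hotspots" placed
inside the lung fields — the synthetic stand-in for FDG-avid lesions.

The anatomy is a fixed parametric ellipse layout with seeded jitter
(centers and axes perturbed by up to 10%), so every pair is reproducible
from its integer seed alone, and the lesion geometry is returned as a
binary mask for downstream checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .preprocessing import Image2D

__all__ = [
    "PhantomConfig",
    "PhantomPair",
    "PhantomError",
    "generate_ct_phantom",
    "generate_pet_phantom",
    "generate_phantom_pair",
    "generate_dataset",
]


class PhantomError(ValueError):
    """Configuration or generation failure in the phantom simulator."""


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and noise settings for one phantom pair.

    The default 128 px CT / 32 px native PET mirrors the 4x resolution gap
    of the clinical acquisition (512 px CT vs 128 px PET) at a scale where
    the whole pipeline runs in seconds; the full-scale geometry is reached
    with ct_size=512.
    """

    ct_size: int = 128
    pet_native_size: int | None = None  # defaults to ct_size // 4
    n_hotspots: int = 2
    hotspot_radius_range: tuple[float, float] | None = None  # defaults scale with ct_size
    hotspot_peak_range: tuple[float, float] = (0.7, 1.0)
    pet_blur_sigma: float = 2.0
    ct_noise_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.pet_native_size is None:
            object.__setattr__(self, "pet_native_size", self.ct_size // 4)
        if self.hotspot_radius_range is None:
            # lesions span ~2-5% of the slice width, as at the 128-px default
            object.__setattr__(
                self,
                "hotspot_radius_range",
                (3.0 * self.ct_size / 128.0, 7.0 * self.ct_size / 128.0),
            )
        if self.ct_size < 8 or self.pet_native_size < 1:
            raise PhantomError(f"invalid sizes: ct {self.ct_size}, pet {self.pet_native_size}")
        if self.ct_size % self.pet_native_size != 0:
            raise PhantomError(
                f"ct_size {self.ct_size} must be a multiple of pet_native_size {self.pet_native_size}"
            )
        if self.n_hotspots < 0:
            raise PhantomError("n_hotspots must be >= 0")
        lo, hi = self.hotspot_peak_range
        if not (0.0 < lo <= hi <= 1.0):
            raise PhantomError("hotspot peaks must lie in (0, 1]")
        if not (0.0 <= self.ct_noise_sigma <= 1.0):
            raise PhantomError("ct_noise_sigma must lie in [0, 1]")
        rlo, rhi = self.hotspot_radius_range
        if not (0.0 < rlo <= rhi):
            raise PhantomError("hotspot radii must be positive and ordered")

    @property
    def downsample_factor(self) -> int:
        return self.ct_size // self.pet_native_size


@dataclass(frozen=True)
class PhantomPair:
    """One registered phantom: CT raster, native-resolution PET, lesion mask."""

    ct: Image2D
    pet_native: Image2D
    lesion_mask: np.ndarray
    seed_used: int

    def __post_init__(self):
        if self.ct.shape != self.lesion_mask.shape:
            raise PhantomError("ct and lesion_mask dimensions differ")


# -- anatomy ---------------------------------------------------------------

# base layout on the unit square: (cy, cx, ry, rx, intensity)
_BODY = (0.52, 0.50, 0.40, 0.44)
_LUNG_L = (0.48, 0.32, 0.24, 0.14)
_LUNG_R = (0.48, 0.68, 0.24, 0.14)
_SPINE = (0.80, 0.50, 0.075, 0.055)


def _jitter(rng: np.random.Generator, params: tuple, frac: float = 0.1) -> tuple:
    return tuple(p * (1.0 + rng.uniform(-frac, frac)) for p in params)


def _ellipse_mask(size: int, cy: float, cx: float, ry: float, rx: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    y = (yy + 0.5) / size
    x = (xx + 0.5) / size
    return ((y - cy) / ry) ** 2 + ((x - cx) / rx) ** 2 <= 1.0


def _anatomy(cfg: PhantomConfig):
    """Seeded jittered layout shared by the CT and PET channels of one pair."""
    rng = np.random.default_rng(cfg.seed)
    size = cfg.ct_size
    body = _jitter(rng, _BODY)
    lung_l = _jitter(rng, _LUNG_L)
    lung_r = _jitter(rng, _LUNG_R)
    spine = _jitter(rng, _SPINE)
    masks = {
        "body": _ellipse_mask(size, *body),
        "lung_l": _ellipse_mask(size, *lung_l),
        "lung_r": _ellipse_mask(size, *lung_r),
        "spine": _ellipse_mask(size, *spine),
    }
    # a few bright rib cross-sections along the body outline
    n_ribs = 6
    angles = np.linspace(0.35, 0.65, n_ribs) * 2 * np.pi + rng.uniform(-0.05, 0.05, n_ribs)
    rib = np.zeros((size, size), dtype=bool)
    cy, cx, ry, rx = body
    for a in angles:
        rcy = cy + 0.88 * ry * np.sin(a)
        rcx = cx + 0.88 * rx * np.cos(a)
        rib |= _ellipse_mask(size, rcy, rcx, 0.02, 0.02)
    masks["ribs"] = rib & masks["body"]
    # noise stream is drawn after geometry so the layout is stable
    return masks, rng


def generate_ct_phantom(cfg: PhantomConfig) -> Image2D:
    """Render the CT-like channel: sharp piecewise anatomy plus fine texture."""
    masks, rng = _anatomy(cfg)
    img = np.zeros((cfg.ct_size, cfg.ct_size))
    img[masks["body"]] = 0.55
    img[masks["lung_l"]] = 0.15
    img[masks["lung_r"]] = 0.15
    img[masks["spine"]] = 0.95
    img[masks["ribs"]] = 0.90
    if cfg.ct_noise_sigma > 0:
        img = img + rng.normal(0.0, cfg.ct_noise_sigma, img.shape)
    return Image2D(np.clip(img, 0.0, 1.0), modality="CT")


def _place_hotspots(cfg: PhantomConfig, masks, rng: np.random.Generator):
    """Draw hotspot centers inside the lung fields by rejection sampling."""
    lungs = masks["lung_l"] | masks["lung_r"]
    coords = np.argwhere(lungs)
    if cfg.n_hotspots > 0 and len(coords) < 4 * cfg.n_hotspots:
        raise PhantomError(
            f"lung fields ({len(coords)} px) too small to place {cfg.n_hotspots} hotspots"
        )
    spots = []
    min_sep = 2.5 * cfg.hotspot_radius_range[1]
    for _ in range(cfg.n_hotspots):
        for _attempt in range(200):
            cy, cx = coords[rng.integers(len(coords))]
            if all(np.hypot(cy - sy, cx - sx) >= min_sep for sy, sx, *_ in spots):
                break
        else:
            raise PhantomError("could not place non-overlapping hotspots in the lung fields")
        radius = rng.uniform(*cfg.hotspot_radius_range)
        peak = rng.uniform(*cfg.hotspot_peak_range)
        spots.append((float(cy), float(cx), radius, peak))
    return spots


def generate_pet_phantom(ct: Image2D, cfg: PhantomConfig) -> tuple[Image2D, np.ndarray]:
    """Render the PET-like channel registered to `ct`.

    A low smooth background follows the body outline; Gaussian-profile
    hotspots (sigma = radius / 2) are added inside the lung fields; the
    whole map is blurred with pet_blur_sigma and block-averaged down to the
    native PET grid. Returns the native-resolution PET and a full-resolution
    binary lesion mask (the hotspot support disks).
    """
    if ct.shape != (cfg.ct_size, cfg.ct_size):
        raise PhantomError(f"ct shape {ct.shape} does not match cfg.ct_size {cfg.ct_size}")
    masks, rng = _anatomy(cfg)
    size = cfg.ct_size
    yy, xx = np.mgrid[0:size, 0:size]

    background = np.where(masks["body"], 0.12, 0.0) + np.where(
        masks["lung_l"] | masks["lung_r"], -0.04, 0.0
    )
    background = ndimage.gaussian_filter(background, sigma=size / 32)

    pet = background.copy()
    lesion_mask = np.zeros((size, size), dtype=bool)
    for cy, cx, radius, peak in _place_hotspots(cfg, masks, rng):
        r2 = (yy - cy) ** 2 + (xx - cx) ** 2
        pet += peak * np.exp(-r2 / (2.0 * (radius / 2.0) ** 2))
        lesion_mask |= r2 <= radius**2
    if cfg.pet_blur_sigma > 0:
        pet = ndimage.gaussian_filter(pet, sigma=cfg.pet_blur_sigma)
    pet = np.clip(pet, 0.0, 1.0)

    f = cfg.downsample_factor
    native = pet.reshape(cfg.pet_native_size, f, cfg.pet_native_size, f).mean(axis=(1, 3))
    return Image2D(native, modality="PET"), lesion_mask


def generate_phantom_pair(cfg: PhantomConfig) -> PhantomPair:
    ct = generate_ct_phantom(cfg)
    pet, mask = generate_pet_phantom(ct, cfg)
    return PhantomPair(ct=ct, pet_native=pet, lesion_mask=mask, seed_used=cfg.seed)


def generate_dataset(n: int, cfg: PhantomConfig) -> list[PhantomPair]:
    """Generate n pairs with per-pair seeds derived deterministically from cfg.seed."""
    if n < 1:
        raise PhantomError("n must be >= 1")
    pairs = []
    for i in range(n):
        seed_i = (cfg.seed * 1_000_003 + 7919 * i + 1) % (2**31)
        cfg_i = PhantomConfig(
            ct_size=cfg.ct_size,
            pet_native_size=cfg.pet_native_size,
            n_hotspots=cfg.n_hotspots,
            hotspot_radius_range=cfg.hotspot_radius_range,
            hotspot_peak_range=cfg.hotspot_peak_range,
            pet_blur_sigma=cfg.pet_blur_sigma,
            ct_noise_sigma=cfg.ct_noise_sigma,
            seed=seed_i,
        )
        pairs.append(generate_phantom_pair(cfg_i))
    return pairs
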