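"""Image containers, file I/O, resampling, and min-max normalization.

PET slices arrive at a coarser native grid than CT (128 x 128 vs 512 x 512
in the clinical protocol this package follows); before fusion the PET slice
is zoomed up to the CT grid and both modalities are min-max normalized
image-wise, since Hounsfield units and tracer uptake live on unrelated
physical scales.

Coordinate convention (used everywhere in the package): row-major rasters,
origin at the top-left, pixel-center alignment for resampling.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .autodiff import Tensor, bilinear_upsample

__all__ = [
    "Image2D",
    "ImagePair",
    "ImageIOError",
    "load_image",
    "save_image",
    "save_archive",
    "load_archive",
    "resample_to",
    "minmax_normalize",
    "make_pair",
]

Modality = str  # one of "CT", "PET", "FUSED", "OTHER"
_MODALITIES = {"CT", "PET", "FUSED", "OTHER"}


class ImageIOError(IOError):
    """Raised when an image file cannot be read or written."""


@dataclass(frozen=True)
class Image2D:
    """A single-channel raster with a modality tag.

    `values` is a (height, width) float array. `normalized` asserts that
    intensities lie in [0, 1] (checked on construction).
    """

    values: np.ndarray
    modality: Modality = "OTHER"
    normalized: bool = False

    def __post_init__(self):
        arr = np.asarray(self.values, dtype=np.float64)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError(f"Image2D requires a 2-D raster, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("Image2D values must be finite")
        if self.modality not in _MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.normalized and (arr.min() < 0.0 or arr.max() > 1.0):
            raise ValueError("normalized image has values outside [0, 1]")
        object.__setattr__(self, "values", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class ImagePair:
    """A registered, normalized (CT, PET) pair at identical resolution."""

    ct: Image2D
    pet: Image2D
    identifier: str = ""
    lesion_mask: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self):
        if self.ct.shape != self.pet.shape:
            raise ValueError(
                f"pair dimensions differ: ct {self.ct.shape} vs pet {self.pet.shape}"
            )
        if not (self.ct.normalized and self.pet.normalized):
            raise ValueError("both images of a pair must be normalized")

    @property
    def shape(self) -> tuple[int, int]:
        return self.ct.shape


# ---------------------------------------------------------------------------
# Reading and writing
# ---------------------------------------------------------------------------


def load_image(path: str | os.PathLike, format_hint: str | None = None, modality: Modality = "OTHER") -> Image2D:
    """Read a single-slice image from DICOM, NIfTI, or PNG/TIFF.

    Values are returned in native units (HU for CT DICOMs once the rescale
    slope/intercept have been applied); the normalized flag is False.
    """
    path = Path(path)
    if not path.exists():
        raise ImageIOError(f"no such image file: {path}")
    fmt = (format_hint or "").lower() or _sniff_format(path)
    try:
        if fmt == "dicom":
            arr = _read_dicom(path)
        elif fmt == "nifti":
            arr = _read_nifti(path)
        elif fmt in ("png", "tiff"):
            import imageio.v3 as iio

            arr = np.asarray(iio.imread(path), dtype=np.float64)
            if arr.ndim == 3:  # collapse RGB(A) to luminance
                arr = arr[..., :3].mean(axis=-1)
        elif fmt == "npz":
            return load_archive(path)
        else:
            raise ImageIOError(f"unrecognized image format for {path}")
    except ImageIOError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-raise with path context
        raise ImageIOError(f"failed to read {path} as {fmt}: {exc}") from exc
    if arr.ndim != 2:
        raise ImageIOError(f"{path}: expected a single 2-D slice, got shape {arr.shape}")
    return Image2D(arr, modality=modality, normalized=False)


def _sniff_format(path: Path) -> str:
    suffix = path.suffix.lower()
    name = path.name.lower()
    if suffix in (".dcm", ".dicom"):
        return "dicom"
    if suffix in (".nii",) or name.endswith(".nii.gz"):
        return "nifti"
    if suffix == ".png":
        return "png"
    if suffix in (".tif", ".tiff"):
        return "tiff"
    if suffix == ".npz":
        return "npz"
    return "dicom"  # DICOM files frequently carry no extension


def _read_dicom(path: Path) -> np.ndarray:
    import pydicom

    ds = pydicom.dcmread(path)
    arr = ds.pixel_array.astype(np.float64)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    return arr * slope + intercept


def _read_nifti(path: Path) -> np.ndarray:
    import nibabel as nib

    img = nib.load(str(path))
    arr = np.asarray(img.dataobj, dtype=np.float64)
    arr = np.squeeze(arr)
    if arr.ndim != 2:
        raise ImageIOError(f"{path}: NIfTI volume is {arr.ndim}-D; a single slice is required")
    return arr


def save_image(img: Image2D, path: str | os.PathLike) -> None:
    """Write an 8-bit PNG (intensities rescaled from [0, 1] if normalized)."""
    import imageio.v3 as iio

    arr = img.values
    if img.normalized:
        out = np.round(arr * 255.0)
    else:
        lo, hi = arr.min(), arr.max()
        out = np.zeros_like(arr) if hi == lo else np.round((arr - lo) / (hi - lo) * 255.0)
    iio.imwrite(Path(path), out.astype(np.uint8))


def save_archive(img: Image2D, path: str | os.PathLike) -> None:
    """Lossless float64 archive (npz) preserving values and metadata bitwise."""
    np.savez(
        Path(path),
        values=img.values,
        modality=np.array(img.modality),
        normalized=np.array(img.normalized),
    )


def load_archive(path: str | os.PathLike) -> Image2D:
    path = Path(path)
    if not path.exists():
        raise ImageIOError(f"no such archive: {path}")
    with np.load(path) as z:
        return Image2D(
            z["values"],
            modality=str(z["modality"]),
            normalized=bool(z["normalized"]),
        )


# ---------------------------------------------------------------------------
# Resampling and normalization
# ---------------------------------------------------------------------------


def resample_to(
    img: Image2D, target_height: int, target_width: int, method: str = "bilinear"
) -> Image2D:
    """Zoom an image to the target grid (bilinear by default, bicubic optional).

    Bilinear output never leaves the input's value envelope; bicubic may
    overshoot, so normalized inputs are re-clipped to [0, 1] in that case.
    """
    if target_height < 1 or target_width < 1:
        raise ValueError("target dimensions must be >= 1")
    if method == "bilinear":
        out = bilinear_upsample(
            Tensor(img.values[None]), target_height, target_width
        ).data[0]
    elif method == "bicubic":
        from scipy import ndimage

        h, w = img.shape
        out = ndimage.zoom(
            img.values,
            (target_height / h, target_width / w),
            order=3,
            mode="nearest",
            grid_mode=True,
        )
        if img.normalized:
            out = np.clip(out, 0.0, 1.0)
    else:
        raise ValueError(f"unknown resampling method {method!r}")
    return replace(img, values=out)


def minmax_normalize(img: Image2D) -> Image2D:
    """Affine rescale to [0, 1]; a constant image maps to all zeros."""
    lo = img.values.min()
    hi = img.values.max()
    if hi == lo:
        out = np.zeros_like(img.values)
    else:
        out = (img.values - lo) / (hi - lo)
    return replace(img, values=out, normalized=True)


def make_pair(
    ct: Image2D, pet: Image2D, method: str = "bilinear", identifier: str = ""
) -> ImagePair:
    """Resample PET to the CT grid and normalize both, yielding a fusion-ready pair."""
    h, w = ct.shape
    if pet.shape != (h, w):
        pet = resample_to(pet, h, w, method=method)
    ct_n = minmax_normalize(replace(ct, modality="CT"))
    pet_n = minmax_normalize(replace(pet, modality="PET"))
    if ct_n.shape != pet_n.shape:
        raise RuntimeError("internal error: pair dimensions diverged after resampling")
    return ImagePair(ct=ct_n, pet=pet_n, identifier=identifier)
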