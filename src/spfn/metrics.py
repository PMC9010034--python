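"""Fusion-quality metrics: mean, std, average gradient, entropy, RMSE,
normalized mutual information, and pixel-domain visual information fidelity.

Single-image statistics (mean, std, AG, entropy) describe the fused slice
alone; reference statistics (RMSE, NMI, VIF) relate it to both sources and
are averaged over the two, except NMI whose definition already combines
them. Histograms use 256 uniform bins on [0, 1] and natural logarithms.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage

from .preprocessing import Image2D, ImagePair

__all__ = [
    "HistogramConfig",
    "MetricReport",
    "mean_value",
    "std_value",
    "average_gradient",
    "entropy",
    "joint_entropy",
    "rmse",
    "nmi",
    "vif",
    "evaluate_pair",
    "reports_to_frame",
]


@dataclass(frozen=True)
class HistogramConfig:
    n_bins: int = 256
    value_range: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self):
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")


@dataclass(frozen=True)
class MetricReport:
    """The seven quality statistics for one fused image against its sources."""

    mean: float
    std: float
    avg_gradient: float
    entropy: float
    rmse: float
    nmi: float
    vif: float
    rmse_ct: float = float("nan")
    rmse_pet: float = float("nan")
    vif_ct: float = float("nan")
    vif_pet: float = float("nan")

    def as_dict(self) -> dict:
        return asdict(self)


def _values(img) -> np.ndarray:
    if isinstance(img, Image2D):
        return img.values
    return np.asarray(img, dtype=np.float64)


def mean_value(img) -> float:
    """Arithmetic mean of the pixel intensities (image brightness)."""
    return float(_values(img).mean())


def std_value(img) -> float:
    """Population standard deviation (image contrast)."""
    return float(_values(img).std())


def average_gradient(img) -> float:
    """Mean of sqrt((dI/dx^2 + dI/dy^2) / 2) over the interior grid.

    Forward differences; the last row and column carry no forward neighbor
    and are excluded from the average.
    """
    arr = _values(img)
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("average gradient requires at least a 2x2 image")
    dx = arr[:-1, 1:] - arr[:-1, :-1]
    dy = arr[1:, :-1] - arr[:-1, :-1]
    return float(np.sqrt((dx**2 + dy**2) / 2.0).mean())


def _histogram(arr: np.ndarray, cfg: HistogramConfig) -> np.ndarray:
    hist, _ = np.histogram(arr, bins=cfg.n_bins, range=cfg.value_range)
    return hist / arr.size


def entropy(img, cfg: HistogramConfig = HistogramConfig()) -> float:
    """Shannon entropy (nats) of the binned intensity distribution."""
    p = _histogram(_values(img), cfg)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def joint_entropy(a, b, cfg: HistogramConfig = HistogramConfig()) -> float:
    """Shannon entropy (nats) of the joint binned distribution of two images."""
    x = _values(a).ravel()
    y = _values(b).ravel()
    if x.size != y.size:
        raise ValueError("joint entropy requires same-size images")
    hist, _, _ = np.histogram2d(x, y, bins=cfg.n_bins, range=[cfg.value_range] * 2)
    p = hist.ravel() / x.size
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def rmse(x, y) -> float:
    """Root mean squared pixel difference between two same-shape images."""
    a, b = _values(x), _values(y)
    if a.shape != b.shape:
        raise ValueError(f"rmse: shapes differ {a.shape} vs {b.shape}")
    return float(np.sqrt(((a - b) ** 2).mean()))


def nmi(i1, i2, fused, cfg: HistogramConfig = HistogramConfig()) -> float:
    """Normalized mutual information of the fused image with both sources.

    2 * [H(I1, F) / (H(I1) + H(F)) + H(I2, F) / (H(I2) + H(F))], bounded in
    [2, 4]: each joint-entropy ratio is 1/2 for identical images and tends
    to 1 for independent ones. Degenerate (zero-entropy) operands pin their
    ratio at the identical-image value 1/2.
    """
    h_f = entropy(fused, cfg)
    total = 0.0
    for src in (i1, i2):
        h_s = entropy(src, cfg)
        denom = h_s + h_f
        total += joint_entropy(src, fused, cfg) / denom if denom > 0 else 0.5
    return 2.0 * total


# ---------------------------------------------------------------------------
# Visual information fidelity (pixel domain, scalar GSM, 4 dyadic scales)
# ---------------------------------------------------------------------------

_VIF_EPS = 1e-10


def _gaussian_kernel(size: int, sigma: float) -> np.ndarray:
    ax = np.arange(size) - (size - 1) / 2.0
    g = np.exp(-(ax**2) / (2.0 * sigma**2))
    k = np.outer(g, g)
    return k / k.sum()


def vif(reference, distorted, sigma_nsq: float = 2.0, n_scales: int = 4) -> float:
    """Pixel-domain visual information fidelity of `distorted` w.r.t. `reference`.

    At each dyadic scale the images are modeled as a scalar Gaussian scale
    mixture observed through additive noise (variance sigma_nsq); the score
    is the ratio of the information the distorted and reference channels
    preserve, 1 for identical images and tending to 0 with degradation.
    """
    ref = _values(reference).astype(np.float64)
    dist = _values(distorted).astype(np.float64)
    if ref.shape != dist.shape:
        raise ValueError(f"vif: shapes differ {ref.shape} vs {dist.shape}")
    num = 0.0
    den = 0.0
    for scale in range(1, n_scales + 1):
        size = 2 ** (n_scales - scale + 1) + 1
        kernel = _gaussian_kernel(size, size / 5.0)
        if scale > 1:
            ref = ndimage.convolve(ref, kernel, mode="nearest")[::2, ::2]
            dist = ndimage.convolve(dist, kernel, mode="nearest")[::2, ::2]
        if min(ref.shape) < size:
            raise ValueError(
                f"image too small for VIF scale {scale} (needs >= {size} px, has {min(ref.shape)})"
            )
        mu1 = ndimage.convolve(ref, kernel, mode="nearest")
        mu2 = ndimage.convolve(dist, kernel, mode="nearest")
        s11 = ndimage.convolve(ref * ref, kernel, mode="nearest") - mu1 * mu1
        s22 = ndimage.convolve(dist * dist, kernel, mode="nearest") - mu2 * mu2
        s12 = ndimage.convolve(ref * dist, kernel, mode="nearest") - mu1 * mu2
        s11 = np.maximum(s11, 0.0)
        s22 = np.maximum(s22, 0.0)

        g = s12 / (s11 + _VIF_EPS)
        sv_sq = s22 - g * s12
        g = np.where(s11 < _VIF_EPS, 0.0, g)
        sv_sq = np.where(s11 < _VIF_EPS, s22, sv_sq)
        sv_sq = np.maximum(sv_sq, _VIF_EPS)

        num += np.log(1.0 + g * g * s11 / (sv_sq + sigma_nsq)).sum()
        den += np.log(1.0 + s11 / sigma_nsq).sum()
    if den <= 0.0:
        raise ValueError("vif is undefined for a degenerate (constant) reference")
    return float(num / den)


def evaluate_pair(pair: ImagePair, fused: Image2D, cfg: HistogramConfig = HistogramConfig()) -> MetricReport:
    """Compute the full seven-metric report for one fused slice.

    RMSE and VIF against each source are averaged into the headline value
    (and reported per source); NMI combines both sources by definition.
    """
    r_ct = rmse(fused, pair.ct)
    r_pet = rmse(fused, pair.pet)
    v_ct = vif(pair.ct, fused)
    v_pet = vif(pair.pet, fused)
    return MetricReport(
        mean=mean_value(fused),
        std=std_value(fused),
        avg_gradient=average_gradient(fused),
        entropy=entropy(fused, cfg),
        rmse=0.5 * (r_ct + r_pet),
        nmi=nmi(pair.ct, pair.pet, fused, cfg),
        vif=0.5 * (v_ct + v_pet),
        rmse_ct=r_ct,
        rmse_pet=r_pet,
        vif_ct=v_ct,
        vif_pet=v_pet,
    )


def reports_to_frame(reports: dict[str, MetricReport]):
    """Tabulate {identifier: report} as a pandas DataFrame (id, mean, std, ag, ...)."""
    import pandas as pd

    rows = []
    for ident, rep in reports.items():
        rows.append(
            {
                "id": ident,
                "mean": rep.mean,
                "std": rep.std,
                "ag": rep.avg_gradient,
                "ent": rep.entropy,
                "rmse": rep.rmse,
                "nmi": rep.nmi,
                "vif": rep.vif,
            }
        )
    return pd.DataFrame(rows, columns=["id", "mean", "std", "ag", "ent", "rmse", "nmi", "vif"])
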