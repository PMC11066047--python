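"""Quantification of two-channel fluorescence microscopy images.

Implements the measurement chain used for co-localization and membrane
recruitment readouts in yeast imaging: rolling-ball background
subtraction, Otsu thresholding on a 256-bin histogram, Manders M1/M2
overlap coefficients on the thresholded images, line-profile extraction
with per-channel min–max normalization, vacuole-membrane/cytosol
intensity ratios, and marker-defined region intensities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "ImageChannel",
    "ColocalizationResult",
    "LineProfile",
    "subtract_background",
    "otsu_value",
    "otsu_threshold",
    "manders",
    "line_profile",
    "membrane_cytosol_ratio",
    "marker_region_intensity",
]


@dataclass
class ImageChannel:
    """One fluorescence channel: non-negative intensities plus metadata."""

    pixels: np.ndarray
    pixel_size: float = 1.0  # µm per pixel
    label: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image intensities must be finite")
        if np.any(self.pixels < 0):
            raise ValueError("image intensities must be non-negative")


@dataclass
class ColocalizationResult:
    cell_id: str
    m1: float | None
    m2: float | None
    n_mask_a: int
    n_mask_b: int


@dataclass
class LineProfile:
    positions: np.ndarray  # µm along the polyline
    intensities: dict[str, np.ndarray]  # per channel, min–max normalized to [0,1]


def _pixels(channel) -> np.ndarray:
    return channel.pixels if isinstance(channel, ImageChannel) else np.asarray(
        channel, dtype=float
    )


def subtract_background(channel: ImageChannel, radius: int = 50) -> ImageChannel:
    """Rolling-ball background subtraction, clipped at zero.

    The rolling-ball estimate is the upper envelope a ball of the given
    radius can reach from below; subtracting it removes smooth background
    while preserving features narrower than the ball.  A flat image maps
    to all zeros.
    """
    from skimage import restoration

    if radius < 1:
        raise ValueError("radius must be >= 1")
    pixels = _pixels(channel)
    if radius > min(pixels.shape):
        raise ValueError(
            f"rolling-ball radius {radius} exceeds image extent {pixels.shape}"
        )
    background = restoration.rolling_ball(pixels, radius=radius)
    cleaned = np.clip(pixels - background, 0.0, None)
    return ImageChannel(
        cleaned,
        pixel_size=getattr(channel, "pixel_size", 1.0),
        label=getattr(channel, "label", ""),
    )


def otsu_value(pixels: np.ndarray, nbins: int = 256) -> float:
    """Otsu threshold: maximize between-class variance over an
    ``nbins``-bin histogram scaled to the image min–max.

    Returns the bin-center threshold; foreground is strictly above it.
    Raises on constant images (no threshold separates one value).
    """
    pixels = np.asarray(pixels, dtype=float).ravel()
    lo, hi = pixels.min(), pixels.max()
    if lo == hi:
        raise ValueError("constant image: Otsu threshold undefined")
    counts, edges = np.histogram(pixels, bins=nbins, range=(lo, hi))
    centers = (edges[:-1] + edges[1:]) / 2.0
    counts = counts.astype(float)
    # cumulative class weights and means; candidate split after each bin
    w0 = np.cumsum(counts)
    w1 = w0[-1] - w0
    cum_mean = np.cumsum(counts * centers)
    total_mean = cum_mean[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = cum_mean / w0
        mu1 = (total_mean - cum_mean) / w1
        between = w0 * w1 * (mu0 - mu1) ** 2
    between[~np.isfinite(between)] = -np.inf
    return float(centers[int(np.argmax(between))])


def otsu_threshold(channel: ImageChannel, nbins: int = 256) -> np.ndarray:
    """Binary foreground mask: pixels strictly above the Otsu threshold."""
    pixels = _pixels(channel)
    return pixels > otsu_value(pixels, nbins=nbins)


def manders(
    channel_a,
    mask_a: np.ndarray,
    channel_b,
    mask_b: np.ndarray,
    variant: str = "thresholded",
    cell_id: str = "",
) -> ColocalizationResult:
    """Manders overlap coefficients M1/M2 between two thresholded channels.

    In the thresholded variant (plugin-style), M1 is the fraction of
    channel A's above-threshold intensity that falls inside channel B's
    mask: ``M1 = Σ A[mask_a ∧ mask_b] / Σ A[mask_a]`` and symmetrically
    for M2.  The plain variant uses unmasked denominators
    (``M1 = Σ A[mask_b] / Σ A``).  An empty own-mask leaves that
    coefficient undefined (None).
    """
    a = _pixels(channel_a)
    b = _pixels(channel_b)
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if mask_a.shape != a.shape or mask_b.shape != b.shape:
        raise ValueError("masks must match channel shapes")
    if variant == "thresholded":
        denom_a = a[mask_a].sum()
        denom_b = b[mask_b].sum()
        num_a = a[mask_a & mask_b].sum()
        num_b = b[mask_a & mask_b].sum()
    elif variant == "plain":
        denom_a = a.sum()
        denom_b = b.sum()
        num_a = a[mask_b].sum()
        num_b = b[mask_a].sum()
    else:
        raise ValueError(f"unknown Manders variant {variant!r}")
    m1 = float(num_a / denom_a) if denom_a > 0 else None
    m2 = float(num_b / denom_b) if denom_b > 0 else None
    return ColocalizationResult(
        cell_id=cell_id,
        m1=m1,
        m2=m2,
        n_mask_a=int(mask_a.sum()),
        n_mask_b=int(mask_b.sum()),
    )


def _polyline_samples(
    polyline: Sequence[Sequence[float]], step: float
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform arc-length sample points ((row, col) array) along a polyline."""
    points = np.asarray(polyline, dtype=float)
    if points.ndim != 2 or points.shape[0] < 2 or points.shape[1] != 2:
        raise ValueError("polyline must be an ordered list of >=2 (row, col) points")
    seg = np.diff(points, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    total = float(seg_len.sum())
    if total == 0:
        raise ValueError("zero-length polyline")
    cumulative = np.concatenate([[0.0], np.cumsum(seg_len)])
    n_samples = max(int(round(total / step)), 1) + 1
    arc = np.linspace(0.0, total, n_samples)
    rows = np.interp(arc, cumulative, points[:, 0])
    cols = np.interp(arc, cumulative, points[:, 1])
    return arc, np.stack([rows, cols])


def line_profile(
    channels: Mapping[str, ImageChannel],
    polyline: Sequence[Sequence[float]],
    step: float = 1.0,
) -> LineProfile:
    """Per-channel normalized intensity along a polyline.

    Intensities are sampled by bilinear interpolation at uniform
    arc-length spacing and min–max normalized per channel to [0, 1]
    (a constant trace degenerates to all zeros).  Positions are reported
    in µm using each channel's pixel size (they must agree).
    """
    if not channels:
        raise ValueError("at least one channel required")
    arc, coords = _polyline_samples(polyline, step)
    pixel_sizes = {getattr(c, "pixel_size", 1.0) for c in channels.values()}
    if len(pixel_sizes) != 1:
        raise ValueError("channels have inconsistent pixel sizes")
    pixel_size = pixel_sizes.pop()
    profiles = {}
    for label, channel in channels.items():
        pixels = _pixels(channel)
        values = ndimage.map_coordinates(pixels, coords, order=1, mode="nearest")
        span = values.max() - values.min()
        profiles[label] = (
            (values - values.min()) / span if span > 0 else np.zeros_like(values)
        )
    return LineProfile(positions=arc * pixel_size, intensities=profiles)


def _disk_mask(shape: tuple[int, ...], center: Sequence[float], radius: float):
    rows, cols = np.ogrid[: shape[0], : shape[1]]
    return (rows - center[0]) ** 2 + (cols - center[1]) ** 2 <= radius**2


def membrane_cytosol_ratio(
    channel: ImageChannel,
    membrane_polyline: Sequence[Sequence[float]],
    cytosol_disks: Sequence[tuple[Sequence[float], float]],
    step: float = 0.5,
) -> float:
    """Membrane-to-cytosol intensity ratio for one cell.

    Ratio of the mean interpolated intensity along the membrane polyline
    to the average of the mean intensities inside exactly three circular
    cytosolic regions (center, radius in pixels).
    """
    if len(cytosol_disks) != 3:
        raise ValueError("exactly 3 cytosol disks are required")
    pixels = _pixels(channel)
    _, coords = _polyline_samples(membrane_polyline, step)
    membrane_mean = float(
        ndimage.map_coordinates(pixels, coords, order=1, mode="nearest").mean()
    )
    disk_means = []
    for center, radius in cytosol_disks:
        mask = _disk_mask(pixels.shape, center, radius)
        if not mask.any():
            raise ValueError("cytosol disk lies outside the image")
        disk_means.append(float(pixels[mask].mean()))
    cytosol_mean = float(np.mean(disk_means))
    if cytosol_mean == 0:
        raise ValueError("cytosol mean intensity is zero; ratio undefined")
    return membrane_mean / cytosol_mean


def marker_region_intensity(
    signal: ImageChannel,
    marker: ImageChannel,
    min_size: int = 5,
) -> list[dict]:
    """Mean signal intensity inside marker-defined regions.

    The marker channel is Otsu-thresholded and its connected components
    (8-connectivity in 2-D, 26-connectivity in 3-D) of at least
    ``min_size`` pixels become regions; the mean of the signal channel is
    reported per region, sorted by region size descending.  Returns an
    empty list when no region survives.
    """
    marker_pixels = _pixels(marker)
    signal_pixels = _pixels(signal)
    if marker_pixels.shape != signal_pixels.shape:
        raise ValueError("signal and marker shapes differ")
    mask = marker_pixels > otsu_value(marker_pixels)
    structure = ndimage.generate_binary_structure(marker_pixels.ndim, marker_pixels.ndim)
    labels, n_labels = ndimage.label(mask, structure=structure)
    regions = []
    for label_id in range(1, n_labels + 1):
        region = labels == label_id
        size = int(region.sum())
        if size < min_size:
            continue
        regions.append(
            {
                "region_id": label_id,
                "size": size,
                "mean_intensity": float(signal_pixels[region].mean()),
            }
        )
    regions.sort(key=lambda r: (-r["size"], r["region_id"]))
    return regions
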