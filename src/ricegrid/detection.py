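"""Rice-cluster recognition in nadir RGB field images.

Five to eight days after transplanting, rice seedlings stand upright with a
consistent light-yellow colour on dark wet soil, which makes a simple colour
rule a reliable foreground detector: a pixel is seedling if the mean of its
red and green channels exceeds ``rg_threshold`` while its blue channel stays
below ``b_threshold`` (water bubbles are bright too, but with a high blue
channel, so the second clause rejects them).

The full pipeline is

    binarize -> remove_noise -> dilate_disk -> label_components
             -> split_and_refine

Dilation (disk, radius 11 px by default) merges the separate shoots of one
hill into a single blob; blobs whose area is at or below the 85th percentile
are accepted directly and their centroids reported, while the oversized
remainder — typically two or more hills fused by the dilation — is eroded
(disk, radius 5), relabelled, and each surviving fragment larger than 400 px
with a major axis above 40 px contributes its own centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage import measure, morphology

from .errors import InvalidInputError, InvalidParameterError

__all__ = [
    "DetectionParams",
    "RGBImage",
    "Component",
    "ClusterSet",
    "disk_footprint",
    "binarize",
    "remove_noise",
    "dilate_disk",
    "erode_disk",
    "label_components",
    "split_and_refine",
    "detect_clusters",
    "pixel_to_ground",
]


@dataclass(frozen=True)
class DetectionParams:
    """Tunable constants of the recognition pipeline (all in pixel units).

    Defaults are calibrated for ~0.2 cm/px nadir imagery of freshly
    transplanted paddies.
    """

    rg_threshold: int = 220
    b_threshold: int = 200
    min_denoise_major_axis: float = 3.0
    dilation_radius: int = 11
    split_quantile: float = 0.85
    erosion_radius: int = 5
    refine_min_area: int = 400
    refine_min_major_axis: float = 40.0
    connectivity: int = 8

    def __post_init__(self):
        if not (0 <= self.rg_threshold <= 255 and 0 <= self.b_threshold <= 255):
            raise InvalidParameterError("intensity thresholds must lie in [0, 255]")
        if self.dilation_radius < 1 or self.erosion_radius < 1:
            raise InvalidParameterError("structuring-element radii must be >= 1")
        if not (0.0 < self.split_quantile < 1.0):
            raise InvalidParameterError("split_quantile must lie in (0, 1)")
        if self.refine_min_area < 0 or self.refine_min_major_axis < 0:
            raise InvalidParameterError("refinement minima must be >= 0")
        if self.connectivity not in (4, 8):
            raise InvalidParameterError("connectivity must be 4 or 8")

    @property
    def skimage_connectivity(self) -> int:
        return 1 if self.connectivity == 4 else 2


@dataclass(frozen=True)
class RGBImage:
    """An 8-bit RGB raster with optional ground-sampling distance (cm/px)."""

    pixels: np.ndarray
    gsd: float | None = None

    def __post_init__(self):
        _validate_rgb(self.pixels)
        if self.gsd is not None and self.gsd <= 0:
            raise InvalidParameterError("gsd must be positive")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def _validate_rgb(pixels: np.ndarray) -> None:
    if not isinstance(pixels, np.ndarray) or pixels.ndim != 3 or pixels.shape[2] != 3:
        raise InvalidInputError("expected an H x W x 3 RGB array")
    if pixels.dtype != np.uint8:
        raise InvalidInputError(f"expected 8-bit channels (uint8), got {pixels.dtype}")
    if pixels.shape[0] < 1 or pixels.shape[1] < 1:
        raise InvalidInputError("image must be at least 1 x 1")


def _as_pixels(image: RGBImage | np.ndarray) -> np.ndarray:
    if isinstance(image, RGBImage):
        return image.pixels
    _validate_rgb(image)
    return image


@dataclass(frozen=True)
class Component:
    """A labelled connected component of a binary mask."""

    label: int
    area: int
    major_axis_length: float
    centroid: tuple[float, float]  # (row, col), 0-based pixel centres
    bbox: tuple[int, int, int, int]  # min_row, min_col, max_row, max_col (exclusive)
    touches_border: bool


@dataclass(frozen=True)
class ClusterSet:
    """Detected, ground-truth or simulated cluster positions.

    ``positions`` is an (n, 2) float array of (row, col) coordinates in the
    units named by ``units`` ("px" or "cm").
    """

    positions: np.ndarray
    gsd: float | None = None
    provenance: str = "detected"
    units: str = "px"
    stages: tuple[str, ...] | None = None
    on_border: np.ndarray | None = None

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "positions", pos)
        if self.stages is not None and len(self.stages) != len(pos):
            raise InvalidInputError("stages must align with positions")

    def __len__(self) -> int:
        return len(self.positions)


def disk_footprint(radius: int) -> np.ndarray:
    """Discrete disk: offset (dr, dc) belongs iff dr^2 + dc^2 <= radius^2."""
    if radius < 1:
        raise InvalidParameterError("radius must be >= 1")
    r = int(radius)
    dr, dc = np.mgrid[-r : r + 1, -r : r + 1]
    return (dr * dr + dc * dc) <= r * r


def binarize(image: RGBImage | np.ndarray, params: DetectionParams | None = None) -> np.ndarray:
    """Pixel-wise colour rule: foreground iff (R+G)/2 > rg_threshold and B < b_threshold."""
    params = params or DetectionParams()
    px = _as_pixels(image)
    rg = px[..., 0].astype(np.int32) + px[..., 1].astype(np.int32)
    # (R+G)/2 > t  <=>  R+G > 2t for integer channels; avoids float rounding
    return (rg > 2 * params.rg_threshold) & (px[..., 2] < params.b_threshold)


def _check_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise InvalidInputError("mask must be 2-D")
    return mask.astype(bool)


def remove_noise(mask: np.ndarray, params: DetectionParams | None = None) -> np.ndarray:
    """Drop connected components whose second-moment major axis is below the cutoff.

    Isolated pixels and tiny specks (major axis < 3 px by default) are
    sensor/water noise, not seedlings. No foreground pixel is ever added.
    """
    params = params or DetectionParams()
    mask = _check_mask(mask)
    labels = measure.label(mask, connectivity=params.skimage_connectivity)
    if labels.max() == 0:
        return mask.copy()
    keep = np.zeros(labels.max() + 1, dtype=bool)
    for rp in measure.regionprops(labels):
        keep[rp.label] = rp.axis_major_length >= params.min_denoise_major_axis
    return keep[labels]


def dilate_disk(mask: np.ndarray, radius: int) -> np.ndarray:
    """Binary dilation with the discrete disk; merges a hill's shoots into one blob."""
    mask = _check_mask(mask)
    # the disk footprint is symmetric, so grayscale dilation on bool == binary
    return morphology.dilation(mask, disk_footprint(radius)).astype(bool)


def erode_disk(mask: np.ndarray, radius: int) -> np.ndarray:
    """Binary erosion with the discrete disk; splits hills fused by dilation."""
    mask = _check_mask(mask)
    return morphology.erosion(mask, disk_footprint(radius)).astype(bool)


def label_components(mask: np.ndarray, connectivity: int = 8) -> list[Component]:
    """Label the foreground and measure area, major axis and centroid per component."""
    if connectivity not in (4, 8):
        raise InvalidParameterError("connectivity must be 4 or 8")
    mask = _check_mask(mask)
    labels = measure.label(mask, connectivity=1 if connectivity == 4 else 2)
    h, w = mask.shape
    comps = []
    for rp in measure.regionprops(labels):
        minr, minc, maxr, maxc = rp.bbox
        comps.append(
            Component(
                label=rp.label,
                area=int(rp.area),
                major_axis_length=float(rp.axis_major_length),
                centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
                bbox=(minr, minc, maxr, maxc),
                touches_border=(minr == 0 or minc == 0 or maxr == h or maxc == w),
            )
        )
    return comps


def split_and_refine(
    components: list[Component],
    mask: np.ndarray,
    params: DetectionParams | None = None,
) -> ClusterSet:
    """Quantile-split the dilated components and refine the oversized ones.

    Components with area at or below the ``split_quantile`` area percentile
    (linear-interpolation estimator) are single hills: their centroids are
    reported directly.  Larger components are candidate merges: each is eroded
    with the radius-``erosion_radius`` disk, relabelled, and every fragment
    with area > ``refine_min_area`` and major axis > ``refine_min_major_axis``
    contributes its centroid.
    """
    params = params or DetectionParams()
    mask = _check_mask(mask)
    if not components:
        return ClusterSet(np.empty((0, 2)), provenance="detected", stages=())

    labels = measure.label(mask, connectivity=params.skimage_connectivity)
    areas = np.array([c.area for c in components], dtype=float)
    q = float(np.quantile(areas, params.split_quantile, method="linear"))

    positions: list[tuple[float, float]] = []
    stages: list[str] = []
    border: list[bool] = []
    for comp in components:
        if comp.area <= q:
            positions.append(comp.centroid)
            stages.append("direct")
            border.append(comp.touches_border)
        else:
            minr, minc, maxr, maxc = comp.bbox
            sub = labels[minr:maxr, minc:maxc] == comp.label
            eroded = erode_disk(sub, params.erosion_radius)
            for rp in measure.regionprops(
                measure.label(eroded, connectivity=params.skimage_connectivity)
            ):
                if (
                    rp.area > params.refine_min_area
                    and rp.axis_major_length > params.refine_min_major_axis
                ):
                    positions.append((rp.centroid[0] + minr, rp.centroid[1] + minc))
                    stages.append("refined")
                    border.append(comp.touches_border)

    pos = np.array(positions, dtype=float).reshape(-1, 2)
    return ClusterSet(
        pos,
        provenance="detected",
        stages=tuple(stages),
        on_border=np.array(border, dtype=bool),
    )


def detect_clusters(
    image: RGBImage | np.ndarray, params: DetectionParams | None = None
) -> ClusterSet:
    """Run the full recognition pipeline and return cluster positions in pixels."""
    params = params or DetectionParams()
    mask = binarize(image, params)
    mask = remove_noise(mask, params)
    mask = dilate_disk(mask, params.dilation_radius)
    comps = label_components(mask, params.connectivity)
    out = split_and_refine(comps, mask, params)
    gsd = image.gsd if isinstance(image, RGBImage) else None
    return replace(out, gsd=gsd)


def pixel_to_ground(clusters: ClusterSet, gsd: float | None = None) -> ClusterSet:
    """Convert pixel coordinates to ground centimetres by the image scale."""
    gsd = gsd if gsd is not None else clusters.gsd
    if gsd is None or gsd <= 0:
        raise InvalidParameterError("gsd must be positive")
    if clusters.units == "cm":
        raise InvalidInputError("cluster set is already in cm")
    return replace(clusters, positions=clusters.positions * gsd, gsd=gsd, units="cm")
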