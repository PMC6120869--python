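"""Core-image standardization and tiling.

Stain/intensity normalization maps every core to a common reference
appearance: RGB is converted to optical density (Beer–Lambert), the two
dominant stain directions (hematoxylin-like and eosin-like) are
estimated from the singular plane of the tissue OD cloud with
percentile-robust extreme angles, per-pixel concentrations are solved by
least squares, rescaled so their robust maxima match the reference
profile, and the image is reconstructed with the reference stain colors.
Tissue is then detected by thresholding total optical density, and the
core is tiled into square regions that contain at least a minimum
fraction of tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.morphology import remove_small_objects

#: optical density below which a pixel is treated as glass/background
OD_FLOOR = 0.15

#: connected components smaller than this (pixels) are dropped from masks
MIN_OBJECT_PX = 64


class NoTissueError(ValueError):
    """Raised when an image contains no pixels above the OD floor."""


@dataclass(frozen=True)
class StainReference:
    """Reference stain profile: unit OD vectors (rows) and robust
    maximum concentrations for the hematoxylin- and eosin-like stains."""

    stain_vectors: np.ndarray = field(
        default_factory=lambda: np.array(
            [[0.65, 0.70, 0.29], [0.07, 0.99, 0.11]], dtype=float
        )
    )
    max_concentrations: np.ndarray = field(
        default_factory=lambda: np.array([1.9705, 1.0308], dtype=float)
    )
    reference_id: str = "he-default"


@dataclass
class StainNormalizedImage:
    rgb: np.ndarray  # (H, W, 3) uint8, reference appearance
    stain_channels: np.ndarray  # (H, W, 2) float, concentrations >= 0
    reference_id: str

    def __post_init__(self) -> None:
        if self.rgb.shape[:2] != self.stain_channels.shape[:2]:
            raise ValueError("rgb and stain_channels disagree on spatial dimensions")
        if np.any(self.stain_channels < 0):
            raise ValueError("optical-density concentrations must be >= 0")


def rgb_to_od(rgb: np.ndarray) -> np.ndarray:
    """Beer–Lambert optical density; 8-bit white (255) maps to OD 0."""
    arr = np.asarray(rgb, dtype=np.float64)
    return -np.log10(np.clip(arr, 1.0, None) / 255.0)


def od_to_rgb(od: np.ndarray) -> np.ndarray:
    return np.clip(255.0 * np.power(10.0, -od), 0, 255).astype(np.uint8)


def estimate_stain_vectors(
    image: np.ndarray, od_floor: float = OD_FLOOR, angle_percentile: float = 1.0
) -> np.ndarray:
    """Estimate the two dominant stain OD unit vectors (Macenko-style).

    Tissue OD pixels are projected onto their leading singular plane; the
    stain vectors are the directions at the robust extreme angles of the
    projected cloud.  Rows are ordered hematoxylin-like first (larger
    blue/red OD ratio).
    """
    od = rgb_to_od(image).reshape(-1, 3)
    tissue = od[od.sum(axis=1) > od_floor]
    if tissue.shape[0] < 10:
        raise NoTissueError("no pixels above the optical-density floor")

    # leading eigenplane of the OD covariance; project the (uncentered)
    # OD cloud onto it and take the robust extreme angles
    _, eigvec = np.linalg.eigh(np.cov(tissue.T))
    plane = eigvec[:, [2, 1]]
    for k in range(2):  # orient so projections are predominantly positive
        if np.median(tissue @ plane[:, k]) < 0:
            plane[:, k] = -plane[:, k]
    proj = tissue @ plane
    ang = np.arctan2(proj[:, 1], proj[:, 0])
    lo, hi = np.percentile(ang, [angle_percentile, 100 - angle_percentile])
    v1 = plane @ np.array([np.cos(lo), np.sin(lo)])
    v2 = plane @ np.array([np.cos(hi), np.sin(hi)])
    vectors = np.abs(np.stack([v1, v2]))  # stain ODs are non-negative
    vectors /= np.linalg.norm(vectors, axis=1, keepdims=True)
    # hematoxylin absorbs red strongly; eosin barely at all
    if vectors[0, 0] < vectors[1, 0]:
        vectors = vectors[::-1]
    return vectors


def stain_concentrations(
    image: np.ndarray, stain_vectors: np.ndarray, od_floor: float | None = None
) -> np.ndarray:
    """Per-pixel non-negative stain concentrations by least squares.

    With an ``od_floor``, glass pixels (total OD at or below the floor)
    get zero concentration so they reconstruct to pure white.
    """
    od = rgb_to_od(image).reshape(-1, 3)
    conc, *_ = np.linalg.lstsq(stain_vectors.T, od.T, rcond=None)
    conc = np.clip(conc.T, 0.0, None)
    if od_floor is not None:
        conc[od.sum(axis=1) <= od_floor] = 0.0
    return conc.reshape(image.shape[0], image.shape[1], 2)


def normalize_stains(
    image: np.ndarray, reference: StainReference | None = None
) -> StainNormalizedImage:
    """Map an H&E image to the reference stain appearance.

    Raises :class:`NoTissueError` for blank glass (no pixel above the OD
    floor), mirroring the upstream exclusion of empty cores.
    """
    reference = reference or StainReference()
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    if image.size == 0:
        raise ValueError("empty image")

    vectors = estimate_stain_vectors(image)
    conc = stain_concentrations(image, vectors, od_floor=OD_FLOOR)

    flat = conc.reshape(-1, 2)
    tissue = rgb_to_od(image).reshape(-1, 3).sum(axis=1) > OD_FLOOR
    robust_max = np.percentile(flat[tissue], 99, axis=0)
    robust_max = np.where(robust_max < 1e-8, 1.0, robust_max)
    scaled = conc * (reference.max_concentrations / robust_max)

    od_norm = scaled.reshape(-1, 2) @ reference.stain_vectors
    rgb = od_to_rgb(od_norm.reshape(image.shape))
    return StainNormalizedImage(
        rgb=rgb, stain_channels=scaled, reference_id=reference.reference_id
    )


def tissue_mask(
    image: StainNormalizedImage,
    od_threshold: float = OD_FLOOR,
    min_object_px: int = MIN_OBJECT_PX,
) -> np.ndarray:
    """Binary tissue raster: total stain OD above threshold, small
    speckles removed."""
    total = image.stain_channels.sum(axis=2)
    mask = total > od_threshold
    if mask.any() and min_object_px > 1:
        mask = remove_small_objects(mask, max_size=min_object_px - 1)
    return mask


@dataclass
class RegionGrid:
    """Kept tile offsets for one core.

    Regions are addressed by their top-left (row, col) pixel offset,
    0-based, enumerated row-major on multiples of ``stride_px``.
    """

    region_size_px: int = 800
    stride_px: int = 400
    min_tissue_fraction: float = 0.5
    regions: list[tuple[int, int]] = field(default_factory=list)
    tissue_fractions: list[float] = field(default_factory=list)


def extract_regions(
    image_shape: tuple[int, int],
    mask: np.ndarray,
    region_size_px: int = 800,
    stride_px: int = 400,
    min_tissue_fraction: float = 0.5,
) -> RegionGrid:
    """Enumerate tiles fully inside the image whose tissue fraction meets
    ``min_tissue_fraction``.

    An image smaller than the region size yields an empty grid (the core
    is skipped, as with insufficient-cellularity cores upstream).
    """
    if stride_px < 1:
        raise ValueError("stride_px must be >= 1")
    h, w = image_shape[:2]
    grid = RegionGrid(region_size_px, stride_px, min_tissue_fraction)
    if region_size_px > h or region_size_px > w:
        return grid

    mask = np.asarray(mask, dtype=bool)
    if mask.shape[:2] != (h, w):
        raise ValueError("mask dimensions must equal image dimensions")
    # summed-area table for O(1) per-tile tissue fractions
    integral = np.zeros((h + 1, w + 1), dtype=np.int64)
    integral[1:, 1:] = np.cumsum(np.cumsum(mask, axis=0), axis=1)

    s = region_size_px
    area = float(s * s)
    for r in range(0, h - s + 1, stride_px):
        for c in range(0, w - s + 1, stride_px):
            count = (
                integral[r + s, c + s]
                - integral[r, c + s]
                - integral[r + s, c]
                + integral[r, c]
            )
            frac = count / area
            if frac >= min_tissue_fraction:
                grid.regions.append((r, c))
                grid.tissue_fractions.append(float(frac))
    return grid
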