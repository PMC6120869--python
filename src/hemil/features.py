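"""Region feature extraction.

Each normalized core is mapped to a spatial grid of d-dimensional
feature vectors at 1/8 the pixel resolution, and each kept tile becomes
one pooled vector — the arithmetic mean of the grid vectors its
footprint covers.  Two backends share this contract:

``cnn_intermediate``
    Intermediate activations of a transferred VGG16 (output of the
    fourth convolutional block, before max pooling; 512 channels, total
    downsampling factor 8).  Requires torch + torchvision weights.

``filterbank``
    A deterministic bank of isotropic multi-scale filters applied to the
    two stain-concentration channels and total optical density: Gaussian
    intensities, gradient-magnitude energies and Laplacian-of-Gaussian
    blob responses at three scales, plus second moments.  Needs no
    external weights, so the whole pipeline runs self-contained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.stats import skew

from .preprocess import StainNormalizedImage
from .synthetic_cohort import FeatureBag

#: total spatial downsampling factor of both backends
DOWNSAMPLE = 8


class ExtractorUnavailableError(RuntimeError):
    pass


@dataclass(frozen=True)
class ExtractorSpec:
    backend: str = "filterbank"  # or "cnn_intermediate"
    layer_tag: str = "block4_conv3"
    d: int = 512
    weights_source: str | None = None

    def __post_init__(self) -> None:
        if self.backend not in ("filterbank", "cnn_intermediate"):
            raise ValueError(f"unknown backend {self.backend!r}")


def _filter_channels(image: StainNormalizedImage) -> np.ndarray:
    h_conc = image.stain_channels[..., 0]
    e_conc = image.stain_channels[..., 1]
    return np.stack([h_conc, e_conc, h_conc + e_conc])


def _response_maps(channels: np.ndarray) -> np.ndarray:
    """(K, H, W) isotropic filter responses; K = 10 per input channel."""
    maps = []
    for ch in channels:
        for sigma in (1, 2, 4):
            maps.append(ndimage.gaussian_filter(ch, sigma))
        for sigma in (1, 2, 4):
            maps.append(ndimage.gaussian_gradient_magnitude(ch, sigma))
        for sigma in (2, 4, 8):
            maps.append(np.abs(ndimage.gaussian_laplace(ch, sigma)) * sigma**2)
        maps.append(ndimage.gaussian_filter(ch**2, 2))
    return np.stack(maps)


def _block_mean(arr: np.ndarray, factor: int) -> np.ndarray:
    h, w = arr.shape[-2:]
    gh, gw = h // factor, w // factor
    trimmed = arr[..., : gh * factor, : gw * factor]
    return trimmed.reshape(*arr.shape[:-2], gh, factor, gw, factor).mean(axis=(-3, -1))


def _pad_to_d(vectors: np.ndarray, d: int) -> np.ndarray:
    k = vectors.shape[-1]
    if k >= d:
        return vectors[..., :d]
    pad = [(0, 0)] * (vectors.ndim - 1) + [(0, d - k)]
    return np.pad(vectors, pad)


def extract_feature_map(image: StainNormalizedImage, spec: ExtractorSpec) -> np.ndarray:
    """(⌊H/8⌋, ⌊W/8⌋, d) feature grid for a normalized core."""
    if spec.backend == "cnn_intermediate":
        return _cnn_feature_map(image, spec)
    grid = _block_mean(_response_maps(_filter_channels(image)), DOWNSAMPLE)
    grid = np.moveaxis(grid, 0, -1)
    return _pad_to_d(grid, spec.d)


def _cnn_feature_map(image: StainNormalizedImage, spec: ExtractorSpec) -> np.ndarray:
    try:
        import torch
        from torchvision.models import VGG16_Weights, vgg16
    except ImportError as exc:  # pragma: no cover - torch not installed here
        raise ExtractorUnavailableError(
            "cnn_intermediate backend requires torch/torchvision with VGG16 "
            "weights; use ExtractorSpec(backend='filterbank') instead"
        ) from exc
    model = vgg16(weights=VGG16_Weights.IMAGENET1K_V1).features[:23].eval()
    arr = image.rgb.astype(np.float32) / 255.0
    mean = np.array([0.485, 0.456, 0.406], dtype=np.float32)
    std = np.array([0.229, 0.224, 0.225], dtype=np.float32)
    x = torch.from_numpy(((arr - mean) / std).transpose(2, 0, 1)[None])
    with torch.no_grad():
        out = model(x)[0].numpy()
    return _pad_to_d(np.moveaxis(out, 0, -1), spec.d)


def pool_region_features(
    feature_map: np.ndarray,
    grid,
    patient_id: str = "",
    core_id: int = 0,
    downsample: int = DOWNSAMPLE,
) -> FeatureBag:
    """Mean-pool the feature grid over every kept tile of a RegionGrid.

    Pixel offsets map to grid cells by flooring the start and ceiling
    the end of the footprint, so every contributing cell is covered.
    """
    if not grid.regions:
        raise ValueError(f"empty region grid for core {core_id} of {patient_id!r}")
    gh, gw, _ = feature_map.shape
    s = grid.region_size_px
    vectors, offsets = [], []
    for r, c in grid.regions:
        r0, c0 = r // downsample, c // downsample
        r1 = min(gh, -((r + s) // -downsample))  # ceil division
        c1 = min(gw, -((c + s) // -downsample))
        if r0 >= gh or c0 >= gw:
            raise ValueError(f"region offset ({r}, {c}) maps outside the feature grid")
        vectors.append(feature_map[r0:r1, c0:c1].mean(axis=(0, 1)))
        offsets.append((r, c))
    return FeatureBag(
        patient_id=patient_id,
        core_ids=np.full(len(vectors), core_id),
        offsets=np.asarray(offsets),
        vectors=np.asarray(vectors),
    )


def filterbank_features(region: np.ndarray, d: int = 512) -> np.ndarray:
    """Direct d-dim descriptor of one region raster (n_channels, H, W) or
    (H, W): per-channel moments, gradient energies and blob responses at
    three scales.  Deterministic; all statistics are zero on a zero region.
    """
    region = np.asarray(region, dtype=np.float64)
    if region.ndim == 2:
        region = region[None]
    stats: list[float] = []
    for ch in region:
        mu = ch.mean()
        sd = ch.std()
        stats += [mu, sd, float(skew(ch, axis=None)) if sd > 1e-12 else 0.0]
        for sigma in (1, 2, 4):
            stats.append(float(ndimage.gaussian_gradient_magnitude(ch, sigma).mean()))
        for sigma in (2, 4, 8):
            stats.append(float(np.abs(ndimage.gaussian_laplace(ch, sigma)).mean()) * sigma**2)
    return _pad_to_d(np.asarray(stats), d)
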