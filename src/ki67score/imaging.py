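"""Brightfield IHC image analysis: optical density, stain unmixing, nucleus detection.

A Ki67 immunohistochemistry slide carries two chromogens: DAB (brown) marking
Ki67-positive nuclei and hematoxylin (blue) counterstaining all nuclei. In
optical-density space the two stains mix linearly (Beer-Lambert), so per-pixel
stain concentrations are recovered by solving a 3x3 linear system against a
basis of stain OD direction vectors. Nuclei are then segmented on the combined
nuclear-stain map and classified positive/negative by their mean DAB signal.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian
from skimage.measure import label as cc_label, regionprops
from skimage.segmentation import watershed

from .errors import ConfigurationError, InvalidInputError

__all__ = [
    "SlideImage",
    "StainBasis",
    "NucleusDetection",
    "DetectionParams",
    "rgb_to_od",
    "deconvolve_stains",
    "detect_nuclei",
    "classify_detections",
]

#: Guard intensity in the log transform; pixels at 0 are treated as 1 so the
#: optical density stays finite (max OD = -log10(1/255) ~ 2.407).
OD_EPSILON = 1.0

# Ruifrok & Johnston H-DAB stain OD direction vectors (unnormalized published
# values; normalized to unit length at basis construction).
_RUIFROK_HEMATOXYLIN = (0.650, 0.704, 0.286)
_RUIFROK_DAB = (0.268, 0.570, 0.776)


@dataclass(frozen=True)
class SlideImage:
    """An RGB brightfield image plus its physical scale.

    Parameters
    ----------
    pixels
        ``(H, W, 3)`` uint8 array, row-major, origin top-left, y-down.
    mpp
        Microns per pixel, isotropic. Anisotropic inputs are rejected upstream.
    """

    pixels: np.ndarray
    mpp: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3 or px.shape[0] < 1 or px.shape[1] < 1:
            raise InvalidInputError(
                f"expected an (H, W, 3) RGB array, got shape {px.shape}"
            )
        if px.dtype != np.uint8:
            raise InvalidInputError(f"expected 8-bit RGB pixels, got dtype {px.dtype}")
        if not (np.isfinite(self.mpp) and self.mpp > 0):
            raise InvalidInputError(f"mpp must be a positive scalar, got {self.mpp}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass(frozen=True)
class StainBasis:
    """Three unit OD direction vectors spanning RGB-OD space.

    Rows are hematoxylin, DAB and a residual channel completing the basis.
    """

    hematoxylin: tuple[float, float, float]
    dab: tuple[float, float, float]
    residual: tuple[float, float, float]

    def __post_init__(self) -> None:
        m = self.matrix
        for name, row in zip(("hematoxylin", "dab", "residual"), m):
            if not np.isclose(np.linalg.norm(row), 1.0, atol=1e-6):
                raise ConfigurationError(f"{name} stain vector is not unit length")
        if np.linalg.cond(m) > 1e8:
            raise ConfigurationError("stain basis is singular or near-singular")

    @property
    def matrix(self) -> np.ndarray:
        """3x3 array with one stain OD vector per row."""
        return np.array([self.hematoxylin, self.dab, self.residual], dtype=float)

    @classmethod
    def hdab_default(cls) -> "StainBasis":
        """Standard H-DAB basis (Ruifrok-Johnston vectors, unit-normalized).

        The residual vector is the unit cross product of the two stain
        vectors, so the basis is always invertible.
        """
        h = np.asarray(_RUIFROK_HEMATOXYLIN, dtype=float)
        d = np.asarray(_RUIFROK_DAB, dtype=float)
        h /= np.linalg.norm(h)
        d /= np.linalg.norm(d)
        r = np.cross(h, d)
        r /= np.linalg.norm(r)
        return cls(tuple(h), tuple(d), tuple(r))


@dataclass(frozen=True)
class NucleusDetection:
    """One segmented nucleus: centroid (0-based px), area and stain summary."""

    centroid_x: float
    centroid_y: float
    area_px2: float
    mean_dab_od: float
    mean_hema_od: float
    label: str | None = None  # "positive" | "negative" | None (unclassified)


@dataclass(frozen=True)
class DetectionParams:
    """Tunables for nucleus segmentation.

    smoothing_sigma
        Gaussian scale (px) applied to the nuclear-stain map before
        thresholding.
    nuclear_od_threshold
        Minimum combined hematoxylin+DAB concentration for nuclear pixels.
    min_area_um2
        Components smaller than this physical area are discarded.
    split_touching
        When true, touching components are split with a distance-transform
        watershed.
    peak_min_distance_px
        Minimum separation of watershed seed peaks.
    """

    smoothing_sigma: float = 1.0
    nuclear_od_threshold: float = 0.15
    min_area_um2: float = 10.0
    split_touching: bool = True
    peak_min_distance_px: int = 4

    def __post_init__(self) -> None:
        if self.smoothing_sigma < 0 or self.nuclear_od_threshold <= 0:
            raise ConfigurationError("smoothing and threshold must be positive")
        if self.min_area_um2 < 0:
            raise ConfigurationError("min_area_um2 must be >= 0")


def rgb_to_od(image: SlideImage) -> np.ndarray:
    """Beer-Lambert transform: OD = -log10(max(I, eps) / 255) per channel.

    Returns a float array of the same grid shape with 3 channels; zero exactly
    where the source channel is 255 (white background absorbs nothing).
    """
    if not isinstance(image, SlideImage):
        raise InvalidInputError("rgb_to_od expects a SlideImage")
    intensity = np.maximum(image.pixels.astype(np.float32), OD_EPSILON)
    return -np.log10(intensity / 255.0)


def deconvolve_stains(
    od: np.ndarray, basis: StainBasis | None = None, *, clip_negative: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unmix an OD image into per-pixel (hematoxylin, DAB, residual) concentrations.

    Solves ``od = c @ M`` per pixel, where M stacks the basis vectors as rows.
    Negative concentrations are physically meaningless (noise pushing a pixel
    outside the stain cone) and are clamped to 0 unless ``clip_negative`` is
    false (the pre-clamp solution exactly reconstructs the OD vector).
    """
    basis = basis or StainBasis.hdab_default()
    od = np.asarray(od)
    if od.dtype not in (np.float32, np.float64):  # keep float32 images cheap
        od = od.astype(np.float64)
    if od.ndim != 3 or od.shape[2] != 3:
        raise InvalidInputError(f"expected an (H, W, 3) OD array, got {od.shape}")
    inv = np.linalg.inv(basis.matrix).astype(od.dtype)
    conc = od @ inv
    if clip_negative:
        conc = np.maximum(conc, 0.0)
    return conc[..., 0], conc[..., 1], conc[..., 2]


def detect_nuclei(
    hema: np.ndarray,
    dab: np.ndarray,
    mpp: float,
    params: DetectionParams | None = None,
) -> list[NucleusDetection]:
    """Segment nuclei on the combined nuclear-stain concentration map.

    Pipeline: Gaussian smoothing -> threshold -> connected components ->
    optional distance-transform watershed split -> area filter. Per-detection
    stain means are taken over the (unsmoothed) concentration maps on the
    component mask. Returns unlabeled detections.
    """
    params = params or DetectionParams()
    hema = np.asarray(hema, dtype=np.float32)
    dab = np.asarray(dab, dtype=np.float32)
    if hema.shape != dab.shape or hema.ndim != 2:
        raise InvalidInputError("hema and dab maps must be matching 2-D arrays")
    if hema.size == 0:
        return []

    nuclear = hema + dab
    smoothed = (
        gaussian(nuclear, sigma=params.smoothing_sigma, preserve_range=True)
        if params.smoothing_sigma > 0
        else nuclear
    )
    mask = smoothed > params.nuclear_od_threshold
    if not mask.any():
        return []

    if params.split_touching:
        distance = ndi.distance_transform_edt(mask)
        peaks = peak_local_max(
            distance,
            min_distance=params.peak_min_distance_px,
            labels=mask,
            exclude_border=False,
        )
        markers = np.zeros(mask.shape, dtype=np.int32)
        markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
        markers = ndi.grey_dilation(markers, size=3)  # merge adjacent plateau peaks
        labels = watershed(-distance, markers, mask=mask)
    else:
        labels = cc_label(mask, connectivity=2)

    min_area_px = params.min_area_um2 / (mpp * mpp)
    detections: list[NucleusDetection] = []
    for region in regionprops(labels):
        if region.area < min_area_px:
            continue
        rows, cols = region.coords[:, 0], region.coords[:, 1]
        cy, cx = region.centroid
        detections.append(
            NucleusDetection(
                centroid_x=float(cx),
                centroid_y=float(cy),
                area_px2=float(region.area),
                mean_dab_od=float(dab[rows, cols].mean()),
                mean_hema_od=float(hema[rows, cols].mean()),
            )
        )
    return detections


def classify_detections(
    detections: list[NucleusDetection], dab_positivity_threshold: float = 0.3
) -> list[NucleusDetection]:
    """Label each detection Ki67-positive iff mean DAB OD strictly exceeds the threshold.

    Ties go to negative (strict inequality), so raising the threshold can only
    reduce the positive count. Detection count and geometry are unchanged.
    """
    if dab_positivity_threshold < 0:
        raise ConfigurationError("DAB positivity threshold must be >= 0")
    return [
        dataclasses.replace(
            d,
            label="positive" if d.mean_dab_od > dab_positivity_threshold else "negative",
        )
        for d in detections
    ]
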