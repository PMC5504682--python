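"""Disk-diffusion inhibition-halo quantification.

A plate photographed over a red background shows the clearing (halo) around
the antibiotic disk as a high-red region inside the darker lawn.  The
pipeline: keep the red channel, threshold at the isodata level, smooth the
binary mask with a dilate/erode/dilate cycle (defaults 3/73/70) that erases
specks and fills pinholes while leaving a large disk's boundary in place,
fit a moment-based ellipse to the largest remaining component, and report

    D = (major + minor) / 2  -  disk filter diameter,

the halo diameter net of the disk.  Sensitivity is the squared halo radius,
S = (D/2)**2, which is linear in the amount of antibiotic loaded on the disk
(the basis of the dose-linearity validation in :mod:`rodquant.stats`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation, binary_erosion
from skimage.filters import threshold_isodata
from skimage.measure import label as sk_label
from skimage.measure import regionprops

__all__ = [
    "HaloParams",
    "Ellipse",
    "HaloMeasurement",
    "HaloNotFoundError",
    "UnitMismatchError",
    "red_channel",
    "binarize_default",
    "smooth_mask",
    "fit_ellipse",
    "halo_diameter",
    "measure_plate",
]

_SQUARE3 = np.ones((3, 3), dtype=bool)


class HaloNotFoundError(RuntimeError):
    """The smoothed mask contains no foreground component."""


class UnitMismatchError(ValueError):
    """A physical disk diameter was given without a pixel calibration."""


@dataclass(frozen=True)
class HaloParams:
    """Smoothing cycle counts and plate calibration.

    Each dilation/erosion cycle applies a 3x3 square structuring element
    once, with the image border treated as background.  The default 3/73/70
    sequence removes foreground objects of radius up to ~(erosions -
    dilations_pre) px and fills gaps up to ~dilations_pre px; the net count
    3 - 73 + 70 = 0 leaves the boundary of a large disk in place up to
    discretization.

    ``disk_diameter`` is in physical units (mm for a standard antibiogram
    disk) when ``pixel_size`` (units/px) is given, otherwise in pixels.
    """

    dilations_pre: int = 3
    erosions: int = 73
    dilations_post: int = 70
    disk_diameter: float = 6.0
    pixel_size: float | None = None  # physical units per pixel; None = uncalibrated
    unit: str = "mm"

    def __post_init__(self) -> None:
        if min(self.dilations_pre, self.erosions, self.dilations_post) < 0:
            raise ValueError("cycle counts must be >= 0")
        if self.disk_diameter < 0:
            raise ValueError("disk_diameter must be >= 0")
        if self.pixel_size is not None and self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")


@dataclass(frozen=True)
class Ellipse:
    """Moment-equivalent ellipse of a region; axes are full lengths in px."""

    center: tuple[float, float]  # (x, y)
    major: float
    minor: float
    orientation: float  # degrees from x axis (y down), in [0, 180)

    def __post_init__(self) -> None:
        if self.major < self.minor:
            raise ValueError("major axis must be >= minor axis")


@dataclass(frozen=True)
class HaloMeasurement:
    ellipse: Ellipse
    diameter: float  # D, net of the disk, physical units (or px if uncalibrated)
    radius: float  # D / 2
    sensitivity: float  # (D / 2)**2
    unit: str  # "mm", "px", ...


def red_channel(image: np.ndarray) -> np.ndarray:
    """Return the red plane of an RGB(A) image; green and blue are discarded."""
    img = np.asarray(image)
    if img.ndim == 2:
        warnings.warn("grayscale input: returning image unchanged", stacklevel=2)
        return img
    if img.ndim == 3 and img.shape[-1] in (3, 4):
        return img[..., 0]
    raise ValueError(f"expected an RGB(A) image, got shape {img.shape}")


def binarize_default(gray: np.ndarray, invert: bool = False) -> np.ndarray:
    """Threshold at the isodata (iterative intermeans) level.

    Foreground is the clearing: red values above the threshold, or below it
    when ``invert`` is set (lawn/clearing contrast can flip with the
    photographic background).
    """
    img = np.asarray(gray, dtype=float)
    if img.max() == img.min():
        raise ValueError("constant image has no threshold")
    thr = threshold_isodata(img)
    return img < thr if invert else img > thr


def smooth_mask(mask: np.ndarray, params: HaloParams) -> np.ndarray:
    """Apply the dilate / erode / dilate smoothing cycle to a binary mask.

    The image border is padded as background throughout, so halos touching
    the border shrink (a documented limitation; the synthetic generator never
    places halos at borders).  An emptied mask is a valid result.
    """
    out = np.asarray(mask, dtype=bool)
    for n, op in (
        (params.dilations_pre, binary_dilation),
        (params.erosions, binary_erosion),
        (params.dilations_post, binary_dilation),
    ):
        if n > 0:
            out = op(out, structure=_SQUARE3, iterations=n, border_value=0)
    return out


def fit_ellipse(mask: np.ndarray) -> Ellipse:
    """Fit the moment-equivalent ellipse to the largest foreground component.

    The ellipse shares the component's centroid and normalized second central
    moments; for a solid disk of radius r both axes equal 2r.
    """
    labeled = sk_label(np.asarray(mask, dtype=bool), connectivity=2)
    regions = regionprops(labeled)
    if not regions:
        raise HaloNotFoundError("no halo detected: empty mask")
    largest = max(regions, key=lambda r: r.area)
    cy, cx = largest.centroid
    # skimage orientation: angle between the row axis and the major axis,
    # in (-pi/2, pi/2]; convert to degrees from the x axis with y down.
    angle = (90.0 - np.degrees(largest.orientation)) % 180.0
    return Ellipse(
        center=(float(cx), float(cy)),
        major=float(largest.axis_major_length),
        minor=float(largest.axis_minor_length),
        orientation=float(angle),
    )


def halo_diameter(ellipse: Ellipse, params: HaloParams) -> HaloMeasurement:
    """Halo diameter, radius and squared-radius sensitivity from the ellipse.

    D = mean(major, minor) x pixel_size - disk_diameter.  A negative D (halo
    smaller than the disk, i.e. no inhibition) is clamped to 0 with a
    warning.  Without a pixel calibration the result is in pixels and a
    physical disk diameter cannot be subtracted meaningfully.
    """
    if params.pixel_size is None:
        if params.disk_diameter > 0 and params.unit != "px":
            raise UnitMismatchError(
                "disk_diameter is in physical units but no pixel_size was given"
            )
        scale, unit = 1.0, "px"
    else:
        scale, unit = params.pixel_size, params.unit
    d = (ellipse.major + ellipse.minor) / 2.0 * scale - params.disk_diameter
    if d < 0:
        warnings.warn(
            f"halo smaller than the disk (D = {d:.3g} {unit}); clamping to 0 "
            "(no inhibition)",
            stacklevel=2,
        )
        d = 0.0
    r = d / 2.0
    return HaloMeasurement(
        ellipse=ellipse, diameter=d, radius=r, sensitivity=r * r, unit=unit
    )


def measure_plate(
    image: np.ndarray,
    params: HaloParams | None = None,
    invert: bool = False,
) -> HaloMeasurement:
    """Full plate pipeline: red channel, isodata threshold, 3/73/70 smoothing,
    ellipse fit, halo diameter and sensitivity."""
    if params is None:
        params = HaloParams()
    gray = red_channel(image)
    mask = binarize_default(gray, invert=invert)
    mask = smooth_mask(mask, params)
    ellipse = fit_ellipse(mask)
    return halo_diameter(ellipse, params)
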