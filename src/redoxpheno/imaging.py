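"""Circular-ROI fluorescence quantification on single- and two-channel images.

Mirrors a manual microscopy workflow: ROIs (in micrometers) are supplied by
the user — a 50 µm-radius circle in the root proximal meristem or a 150 µm
circle mid-leaf for dye stains — and per-ROI background-corrected mean
intensities are extracted.  For the two-excitation roGFP2 channels the
405/488 ratio is formed from background-corrected ROI means (ratio of means,
robust at low 488 signal; a per-pixel mode exists for comparison).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .biosensor import BiosensorMeasurement

__all__ = [
    "ImageStack",
    "CircularROI",
    "IntensityResult",
    "roi_mean",
    "ratio_measurement",
    "percent_of_control",
    "read_tiff_stack",
    "write_tiff_stack",
    "read_roi_table",
]


class GeometryError(ValueError):
    """ROI does not intersect the image or contains no pixels."""


class SignalError(ValueError):
    """Background-corrected signal unusable (e.g. mean I488 <= 0)."""


@dataclass
class ImageStack:
    """Named 2-D intensity channels sharing one pixel grid.

    Attributes
    ----------
    channels : dict[str, np.ndarray]
        Channel name -> 2-D nonnegative intensity array; all same shape.
    pixel_size : float
        Micrometers per pixel (square pixels).
    """

    channels: dict[str, np.ndarray]
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("at least one channel required")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels have differing shapes: {shapes}")
        for name, arr in self.channels.items():
            arr = np.asarray(arr)
            if arr.ndim != 2:
                raise ValueError(f"channel {name!r} is not 2-D")
            if np.any(arr < 0):
                raise ValueError(f"channel {name!r} has negative intensities")
            self.channels[name] = arr

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass(frozen=True)
class CircularROI:
    """Circle in physical coordinates: center (x, y) and radius in µm."""

    cx: float
    cy: float
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")

    def mask(self, shape: tuple[int, int], pixel_size: float) -> np.ndarray:
        """Boolean pixel mask: a pixel belongs iff its center lies inside."""
        ny, nx = shape
        # pixel (row i, col j) has center ((j + 0.5) * s, (i + 0.5) * s) in µm
        ys = (np.arange(ny) + 0.5) * pixel_size
        xs = (np.arange(nx) + 0.5) * pixel_size
        dy = ys[:, None] - self.cy
        dx = xs[None, :] - self.cx
        return dx * dx + dy * dy <= self.radius * self.radius


@dataclass(frozen=True)
class IntensityResult:
    """Background-corrected mean over an ROI."""

    mean_intensity: float
    background: float
    n_pixels: int
    flags: tuple[str, ...] = ()


def roi_mean(
    image: np.ndarray,
    roi: CircularROI,
    background: float = 0.0,
    *,
    pixel_size: float = 1.0,
    saturation_level: float | None = None,
) -> IntensityResult:
    """Background-subtracted mean intensity over a circular ROI.

    The corrected mean is floored at 0.  Pixels at ``saturation_level``
    (typically the dtype maximum) are excluded and flagged, since saturated
    pixels bias ratio measurements.
    """
    image = np.asarray(image, dtype=float)
    mask = roi.mask(image.shape, pixel_size)
    if not mask.any():
        raise GeometryError(
            f"ROI (cx={roi.cx}, cy={roi.cy}, r={roi.radius} µm) contains no pixels"
        )
    values = image[mask]
    flags: tuple[str, ...] = ()
    if saturation_level is not None:
        sat = values >= saturation_level
        if sat.any():
            flags = ("saturated_pixels_excluded",)
            values = values[~sat]
            if values.size == 0:
                raise SignalError("all ROI pixels saturated")
    mean = float(values.mean()) - float(background)
    if mean < 0:
        mean = 0.0
        flags = flags + ("floored_at_zero",)
    return IntensityResult(
        mean_intensity=mean,
        background=float(background),
        n_pixels=int(values.size),
        flags=flags,
    )


def ratio_measurement(
    stack: ImageStack,
    roi: CircularROI,
    backgrounds: dict[str, float] | None = None,
    *,
    ch405: str = "exc405",
    ch488: str = "exc488",
    per_pixel: bool = False,
    saturation_level: float | None = None,
) -> BiosensorMeasurement:
    """405/488 biosensor measurement for one ROI.

    Default mode forms the ratio of background-corrected ROI means.  With
    ``per_pixel=True`` the per-pixel ratio field is averaged instead; the two
    agree exactly on spatially uniform fields and diverge on gradients.
    """
    backgrounds = backgrounds or {}
    for ch in (ch405, ch488):
        if ch not in stack.channels:
            raise KeyError(f"channel {ch!r} missing from stack {list(stack.channels)}")
    b405 = float(backgrounds.get(ch405, 0.0))
    b488 = float(backgrounds.get(ch488, 0.0))
    r405 = roi_mean(
        stack.channels[ch405], roi, b405,
        pixel_size=stack.pixel_size, saturation_level=saturation_level,
    )
    r488 = roi_mean(
        stack.channels[ch488], roi, b488,
        pixel_size=stack.pixel_size, saturation_level=saturation_level,
    )
    if r488.mean_intensity <= 0:
        raise SignalError("mean I488 is non-positive after background correction")
    flags = tuple(sorted(set(r405.flags + r488.flags)))
    if per_pixel:
        mask = roi.mask(stack.shape, stack.pixel_size)
        p405 = stack.channels[ch405][mask].astype(float) - b405
        p488 = stack.channels[ch488][mask].astype(float) - b488
        valid = p488 > 0
        if not valid.any():
            raise SignalError("no pixels with positive corrected I488")
        ratio = float(np.mean(p405[valid] / p488[valid]))
        # encode via intensities whose quotient is the mean per-pixel ratio
        return BiosensorMeasurement(
            i405=ratio * r488.mean_intensity,
            i488=r488.mean_intensity,
            flags=flags + ("per_pixel_ratio",),
        )
    return BiosensorMeasurement(
        i405=r405.mean_intensity, i488=r488.mean_intensity, flags=flags
    )


def percent_of_control(values, control_values) -> np.ndarray:
    """Scale intensities to percent of the control-group mean.

    The control group's mean maps to exactly 100%; this is the "control%"
    normalization used for dye-intensity reporting where the control is the
    untreated wild type.
    """
    values = np.asarray(values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if control.size == 0:
        raise ValueError("control group is empty")
    cmean = control.mean()
    if cmean <= 0:
        raise ValueError("control mean must be positive")
    return values * (100.0 / cmean)


# ---------------------------------------------------------------------------
# File I/O: multi-page grayscale TIFF and ROI definition tables

def write_tiff_stack(path, stack: ImageStack, *, dtype=np.float32) -> None:
    """Write a stack as a multi-page grayscale TIFF, one page per channel.

    Channel names and pixel size are stored in the ImageJ-style metadata so a
    round trip through :func:`read_tiff_stack` is lossless.
    """
    pages = np.stack([np.asarray(stack.channels[name], dtype=dtype)
                      for name in stack.channels])
    tifffile.imwrite(
        str(path),
        pages,
        metadata={
            "axes": "CYX",
            "channel_names": list(stack.channels),
            "pixel_size_um": stack.pixel_size,
        },
    )


def read_tiff_stack(
    path, channel_names: list[str] | None = None, pixel_size: float | None = None
) -> ImageStack:
    """Read a single- or multi-page grayscale TIFF as an ImageStack.

    Channel names / pixel size fall back to metadata written by
    :func:`write_tiff_stack`, then to ``ch0..chN`` and 1 µm/px.
    """
    with tifffile.TiffFile(str(path)) as tif:
        arr = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"expected a 2-D or 3-D grayscale TIFF, got shape {arr.shape}")
    if channel_names is None:
        channel_names = meta.get("channel_names") or [f"ch{i}" for i in range(arr.shape[0])]
    if pixel_size is None:
        pixel_size = float(meta.get("pixel_size_um", 1.0))
    if len(channel_names) != arr.shape[0]:
        raise ValueError("channel_names length does not match page count")
    return ImageStack(
        channels={name: arr[i].astype(float) for i, name in enumerate(channel_names)},
        pixel_size=pixel_size,
    )


ROI_COLUMNS = ["image_id", "channel", "cx_um", "cy_um", "radius_um", "role"]


def read_roi_table(path) -> pd.DataFrame:
    """Read an ROI definition CSV (image_id, channel, cx_um, cy_um, radius_um, role)."""
    df = pd.read_csv(path)
    missing = set(ROI_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"ROI table missing columns: {sorted(missing)}")
    bad_roles = set(df["role"].unique()) - {"sample", "background"}
    if bad_roles:
        raise ValueError(f"unknown ROI roles: {sorted(bad_roles)}")
    return df
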