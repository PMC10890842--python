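"""Image input/output with physical calibration, and dark-count subtraction.

Every downstream operation consumes a :class:`CalibratedImage`: a 2-D grid of
non-negative camera counts plus the physical pixel pitch in µm/pixel. The
pitch is load-bearing — the band-pass radii are expressed in cycles/µm, so a
wrong or defaulted pixel size silently shifts the pass-band. For that reason
the pixel size is resolved strictly as: explicit override, else TIFF
resolution metadata, else a hard error. There is no silent default.

Camera dark counts are subtracted before any scoring. Both a full dark frame
and a scalar mean dark level are supported; the result is clamped at zero
because luminescence counts are physically non-negative.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import tifffile

from .errors import PixelSizeError, ShapeMismatchError, UCNPScoreError

__all__ = [
    "Channel",
    "CalibratedImage",
    "DarkFrame",
    "read_image",
    "write_image",
    "subtract_dark",
]


class Channel(enum.Enum):
    """Acquisition channel of a calibrated image."""

    UCNP = "UCNP"
    DAPI = "DAPI"
    DAB = "DAB"
    BRIGHTFIELD = "BRIGHTFIELD"


@dataclass(frozen=True)
class CalibratedImage:
    """A single-channel image with physical pixel calibration.

    Parameters
    ----------
    pixels
        2-D array of finite, non-negative intensities (camera counts).
    pixel_size
        Physical pixel pitch in µm/pixel, > 0.
    channel
        Which acquisition channel the image came from.
    dark_subtracted
        Whether camera dark counts have already been removed.
    """

    pixels: np.ndarray
    pixel_size: float
    channel: Channel = Channel.UCNP
    dark_subtracted: bool = False

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.size == 0:
            raise UCNPScoreError("image must be a non-empty 2-D grid")
        if not np.all(np.isfinite(px)):
            raise UCNPScoreError("image contains non-finite values")
        if px.min() < 0:
            raise UCNPScoreError("image contains negative intensities")
        if not (np.isscalar(self.pixel_size) or np.ndim(self.pixel_size) == 0):
            raise PixelSizeError("pixel_size must be a scalar")
        if not np.isfinite(self.pixel_size) or self.pixel_size <= 0:
            raise PixelSizeError(f"pixel_size must be > 0, got {self.pixel_size}")
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "pixel_size", float(self.pixel_size))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class DarkFrame:
    """Camera dark counts: a full frame or a scalar mean dark level."""

    data: np.ndarray | float

    def __post_init__(self) -> None:
        if np.ndim(self.data) == 0:
            val = float(self.data)
            if not np.isfinite(val) or val < 0:
                raise UCNPScoreError("scalar dark level must be finite and >= 0")
            object.__setattr__(self, "data", val)
        else:
            arr = np.asarray(self.data, dtype=float)
            if arr.ndim != 2:
                raise UCNPScoreError("dark frame must be 2-D or scalar")
            if not np.all(np.isfinite(arr)) or arr.min() < 0:
                raise UCNPScoreError("dark frame must be finite and >= 0")
            object.__setattr__(self, "data", arr)


_UNIT_TO_UM = {2: 25400.0, 3: 10000.0}  # RESUNIT: 2 = inch, 3 = centimeter


def _pixel_size_from_tiff(tif: tifffile.TiffFile) -> float | None:
    """Extract µm/pixel from TIFF resolution tags, if derivable."""
    page = tif.pages[0]
    tags = page.tags
    xres = tags.get("XResolution")
    unit_tag = tags.get("ResolutionUnit")
    if xres is None:
        return None
    num, den = xres.value
    if num == 0 or den == 0:
        return None
    px_per_unit = num / den
    unit = int(getattr(unit_tag.value, "value", unit_tag.value)) if unit_tag else 1
    if unit in _UNIT_TO_UM:
        return _UNIT_TO_UM[unit] / px_per_unit
    # ImageJ-style TIFFs carry the unit name in metadata with RESUNIT none
    ij = tif.imagej_metadata or {}
    if ij.get("unit") in {"um", "micron", "µm", "μm"}:
        return 1.0 / px_per_unit
    return None


def read_image(
    path: str | Path,
    pixel_size_override: float | None = None,
    channel: Channel = Channel.UCNP,
    extract_channel: int | None = None,
) -> CalibratedImage:
    """Read a grayscale TIFF as a :class:`CalibratedImage`.

    Pixel size resolution order: ``pixel_size_override`` if given, else the
    TIFF XResolution/ResolutionUnit tags, else :class:`PixelSizeError`.
    Multi-channel (RGB) TIFFs are rejected unless ``extract_channel`` names
    the plane to keep.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            data = tif.pages[0].asarray()
            meta_px = _pixel_size_from_tiff(tif)
    except (OSError, tifffile.TiffFileError) as exc:
        raise UCNPScoreError(f"cannot read TIFF {path}: {exc}") from exc

    if data.ndim == 3:
        if extract_channel is None:
            raise UCNPScoreError(
                f"{path} is multi-channel; pass extract_channel to select a plane"
            )
        data = data[..., extract_channel]
    elif data.ndim != 2:
        raise UCNPScoreError(f"{path}: expected a 2-D image, got ndim={data.ndim}")

    pixel_size = pixel_size_override if pixel_size_override is not None else meta_px
    if pixel_size is None:
        raise PixelSizeError(
            f"{path}: no pixel size available — pass pixel_size_override or "
            "embed TIFF resolution metadata"
        )
    return CalibratedImage(
        pixels=np.asarray(data, dtype=float),
        pixel_size=float(pixel_size),
        channel=channel,
        dark_subtracted=False,
    )


def write_image(
    image: CalibratedImage, path: str | Path, dtype: np.dtype | str | None = None
) -> None:
    """Write a calibrated image as TIFF with resolution metadata (px/cm).

    If ``dtype`` is omitted, integer-valued images within the 16-bit range are
    written as uint16 (bit-exact round trip), everything else as float32.
    """
    px = image.pixels
    if dtype is None:
        integral = np.all(px == np.round(px)) and px.max() <= np.iinfo(np.uint16).max
        dtype = np.uint16 if integral else np.float32
    px_per_cm = 10000.0 / image.pixel_size
    dtype = np.dtype(dtype)
    data = np.round(px) if np.issubdtype(dtype, np.integer) else px
    tifffile.imwrite(
        Path(path),
        data.astype(dtype),
        resolution=(px_per_cm, px_per_cm),
        resolutionunit="CENTIMETER",
    )


def subtract_dark(image: CalibratedImage, dark: DarkFrame | np.ndarray | float) -> CalibratedImage:
    """Subtract camera dark counts, clamping negative residuals to zero.

    Guarded against double subtraction: applying to an image whose
    ``dark_subtracted`` flag is already set raises rather than silently
    re-subtracting.
    """
    if image.dark_subtracted:
        raise UCNPScoreError("image is already dark-subtracted")
    if not isinstance(dark, DarkFrame):
        dark = DarkFrame(dark)
    data = dark.data
    if not np.isscalar(data) and np.shape(data) != image.shape:
        raise ShapeMismatchError(
            f"dark frame shape {np.shape(data)} != image shape {image.shape}"
        )
    corrected = np.maximum(image.pixels - data, 0.0)
    return replace(image, pixels=corrected, dark_subtracted=True)
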