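"""Photograph and mask I/O, including EXIF capture metadata.

Reads JPEG/PNG canopy photographs into an :class:`RGBImage`, pulling the
capture timestamp, GPS position and scene brightness out of EXIF when the
tags exist.  Masks are stored as two-valued PNGs (sky=255, canopy=0) and
round-trip bit-exactly.

The EXIF orientation tag is applied on load so that the analysed raster
matches what the camera preview showed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import numpy as np
from PIL import ExifTags, Image, ImageOps, UnidentifiedImageError

from .masks import BinaryCanopyMask

__all__ = [
    "CaptureMeta",
    "RGBImage",
    "load_image",
    "write_mask",
    "read_mask",
    "SKY_PIXEL_VALUE",
    "CANOPY_PIXEL_VALUE",
]

#: Pixel values used in stored mask PNGs (fixed, documented contract).
SKY_PIXEL_VALUE = 255
CANOPY_PIXEL_VALUE = 0

#: EXIF tag read as scene luminance by default: BrightnessValue (APEX),
#: the standard scene-brightness field written by phone/tablet cameras.
DEFAULT_LUMINANCE_TAG = "BrightnessValue"

_EXIF_TAG_IDS = {name: tag for tag, name in ExifTags.TAGS.items()}


@dataclass(frozen=True)
class CaptureMeta:
    """Capture metadata; every field is optional and ``None`` when the
    corresponding EXIF tag is absent.  Absence is never encoded as 0 —
    0 is a legal luminance."""

    timestamp: datetime | None = None
    latitude: float | None = None
    longitude: float | None = None
    luminance_I: float | None = None

    def __post_init__(self) -> None:
        if self.latitude is not None and not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude out of range: {self.latitude}")
        if self.longitude is not None and not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude out of range: {self.longitude}")
        if self.luminance_I is not None and self.luminance_I < 0.0:
            raise ValueError(f"luminance must be >= 0: {self.luminance_I}")


@dataclass(frozen=True)
class RGBImage:
    """Decoded photograph: H x W x 3 uint8 raster plus capture metadata."""

    pixels: np.ndarray
    meta: CaptureMeta = field(default_factory=CaptureMeta)
    source: str | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"pixels must be H x W x 3, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError(f"image must be non-empty, got shape {px.shape}")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("channel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def blue(self) -> np.ndarray:
        """Blue channel (the segmentation channel), shape (H, W)."""
        return self.pixels[:, :, 2]


def _dms_to_degrees(dms, ref: str | None) -> float:
    deg, minutes, seconds = (float(v) for v in dms)
    value = deg + minutes / 60.0 + seconds / 3600.0
    if ref in ("S", "W"):
        value = -value
    return value


def _parse_timestamp(raw: str | None) -> datetime | None:
    if not raw:
        return None
    try:
        return datetime.strptime(str(raw).strip("\x00 "), "%Y:%m:%d %H:%M:%S")
    except ValueError:
        return None


def _extract_meta(exif: Image.Exif, luminance_tag: str) -> CaptureMeta:
    exif_ifd = exif.get_ifd(ExifTags.IFD.Exif)
    gps_ifd = exif.get_ifd(ExifTags.IFD.GPSInfo)

    timestamp = _parse_timestamp(
        exif_ifd.get(_EXIF_TAG_IDS["DateTimeOriginal"]) or exif.get(306)
    )

    latitude = longitude = None
    lat_dms = gps_ifd.get(2)  # GPSLatitude
    lon_dms = gps_ifd.get(4)  # GPSLongitude
    if lat_dms is not None and lon_dms is not None:
        try:
            latitude = _dms_to_degrees(lat_dms, gps_ifd.get(1))
            longitude = _dms_to_degrees(lon_dms, gps_ifd.get(3))
        except (TypeError, ValueError, ZeroDivisionError):
            latitude = longitude = None

    luminance = None
    tag_id = _EXIF_TAG_IDS.get(luminance_tag)
    if tag_id is not None:
        raw = exif_ifd.get(tag_id, exif.get(tag_id))
        if raw is not None:
            try:
                luminance = max(float(raw), 0.0)
            except (TypeError, ValueError, ZeroDivisionError):
                luminance = None

    return CaptureMeta(
        timestamp=timestamp,
        latitude=latitude,
        longitude=longitude,
        luminance_I=luminance,
    )


def load_image(path: str | Path, luminance_tag: str = DEFAULT_LUMINANCE_TAG) -> RGBImage:
    """Load a JPEG/PNG photograph with its capture metadata.

    Grayscale inputs are replicated across three channels; the EXIF
    orientation tag is applied before any analysis.

    Parameters
    ----------
    path : path-like
    luminance_tag : str
        Name of the numeric EXIF tag read as scene luminance
        (default ``BrightnessValue``).

    Raises
    ------
    OSError
        If the file is missing, unreadable or not a decodable image.
    ValueError
        If the decoded image has zero pixels.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            exif = im.getexif()
            im = ImageOps.exif_transpose(im)
            rgb = im.convert("RGB")
            pixels = np.asarray(rgb, dtype=np.uint8)
    except (UnidentifiedImageError, OSError) as exc:
        raise OSError(f"cannot read image file {path}: {exc}") from exc
    if pixels.size == 0:
        raise ValueError(f"image {path} has zero pixels")
    meta = _extract_meta(exif, luminance_tag)
    return RGBImage(pixels=pixels, meta=meta, source=str(path))


def write_mask(mask: BinaryCanopyMask, path: str | Path) -> None:
    """Store a mask as a two-valued PNG (sky=255, canopy=0)."""
    path = Path(path)
    raster = np.where(mask.sky, SKY_PIXEL_VALUE, CANOPY_PIXEL_VALUE).astype(np.uint8)
    Image.fromarray(raster, mode="L").save(path, format="PNG")


def read_mask(path: str | Path) -> BinaryCanopyMask:
    """Read a mask PNG written by :func:`write_mask`.

    The file must contain at most the two pixel values 0 (canopy) and
    255 (sky); anything else is rejected.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            raster = np.asarray(im.convert("L"))
    except (UnidentifiedImageError, OSError) as exc:
        raise OSError(f"cannot read mask file {path}: {exc}") from exc
    values = np.unique(raster)
    if not np.isin(values, (CANOPY_PIXEL_VALUE, SKY_PIXEL_VALUE)).all():
        raise ValueError(
            f"mask {path} is not two-valued (0/255): found values "
            f"{values.tolist()}"
        )
    return BinaryCanopyMask(sky=raster == SKY_PIXEL_VALUE, source=str(path))
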