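from __future__ import annotations

import numpy as np
import pytest
from PIL import ExifTags, Image
from PIL.TiffImagePlugin import IFDRational

from canopycover import BinaryCanopyMask


@pytest.fixture
def rng():
    return np.random.default_rng(20160423)


def random_mask(rng: np.random.Generator, height: int, width: int, p: float = 0.5):
    return BinaryCanopyMask(sky=rng.random((height, width)) < p)


def _to_dms(value: float) -> tuple[IFDRational, IFDRational, IFDRational]:
    value = abs(value)
    deg = int(value)
    minutes_f = (value - deg) * 60.0
    minutes = int(minutes_f)
    # store seconds as a rational with 1e4 denominator (~0.03 m precision)
    seconds = round((minutes_f - minutes) * 60.0 * 10000)
    return (IFDRational(deg, 1), IFDRational(minutes, 1), IFDRational(seconds, 10000))


def write_image_with_exif(
    path,
    pixels: np.ndarray,
    latitude: float | None = None,
    longitude: float | None = None,
    brightness: float | None = None,
    timestamp: str | None = None,
    fmt: str = "JPEG",
) -> None:
    """Encode an image with EXIF GPS/brightness/datetime tags for tests."""
    img = Image.fromarray(pixels)
    exif = Image.Exif()
    if latitude is not None and longitude is not None:
        gps = exif.get_ifd(ExifTags.IFD.GPSInfo)
        gps[1] = "S" if latitude < 0 else "N"
        gps[2] = _to_dms(latitude)
        gps[3] = "W" if longitude < 0 else "E"
        gps[4] = _to_dms(longitude)
    ex = exif.get_ifd(ExifTags.IFD.Exif)
    if brightness is not None:
        ex[0x9203] = IFDRational(round(brightness * 1000), 1000)  # BrightnessValue
    if timestamp is not None:
        ex[0x9003] = timestamp  # DateTimeOriginal
        exif[306] = timestamp
    img.save(path, format=fmt, exif=exif, quality=95)
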