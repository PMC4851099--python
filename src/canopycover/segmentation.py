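"""Sky/canopy segmentation by blue-channel thresholding.

Against a clear or overcast sky, canopy material is dark in the blue
channel while sky is bright, so a single histogram threshold separates the
two classes.  Automatic mode picks the threshold from the blue-channel
histogram (Otsu's between-class-variance criterion by default, the
Ridler–Calvard isodata iteration as an alternative); manual mode applies a
user-supplied threshold, the remedy when over-illuminated leaves or bright
sky sections defeat the automatic split.

Pixels with blue value strictly greater than the threshold are labelled
sky; the comparison direction and the recorded ``threshold_used`` make any
mask bit-reproducible.
"""

from __future__ import annotations

import numpy as np
from skimage.filters import threshold_isodata, threshold_otsu

from .imaging_io import RGBImage
from .masks import BinaryCanopyMask

__all__ = ["segment", "DegenerateImageError", "BinaryCanopyMask"]


class DegenerateImageError(ValueError):
    """Raised when automatic thresholding cannot work (flat histogram)."""


_AUTO_ALGORITHMS = {
    "otsu": threshold_otsu,
    "isodata": threshold_isodata,
}


def segment(
    image: RGBImage,
    method: str = "automatic",
    manual_threshold: int | None = None,
    algorithm: str = "otsu",
) -> BinaryCanopyMask:
    """Binarize a photograph into a sky/canopy mask.

    Parameters
    ----------
    image : RGBImage
    method : {"automatic", "manual"}
        Automatic selects the threshold from the blue-channel histogram;
        manual uses ``manual_threshold``.
    manual_threshold : int, optional
        Threshold in [0, 255]; required for manual mode.  Pixels with blue
        value strictly greater than it become sky, so 255 labels the whole
        frame canopy.
    algorithm : {"otsu", "isodata"}
        Histogram splitter for automatic mode.

    Raises
    ------
    DegenerateImageError
        In automatic mode when the blue channel is constant (no
        bimodality to split); use a manual threshold instead.
    """
    blue = image.blue
    if method == "manual":
        if manual_threshold is None:
            raise ValueError("manual mode requires manual_threshold")
        if not 0 <= manual_threshold <= 255:
            raise ValueError(
                f"manual_threshold must be in [0, 255], got {manual_threshold}"
            )
        threshold = int(manual_threshold)
    elif method == "automatic":
        try:
            splitter = _AUTO_ALGORITHMS[algorithm]
        except KeyError:
            raise ValueError(
                f"unknown algorithm {algorithm!r}; choose from "
                f"{sorted(_AUTO_ALGORITHMS)}"
            ) from None
        if blue.min() == blue.max():
            raise DegenerateImageError(
                f"blue channel is constant (value {int(blue.min())}): automatic "
                "thresholding is undefined; supply a manual threshold"
            )
        threshold = int(splitter(blue))
    else:
        raise ValueError(f"method must be 'automatic' or 'manual', got {method!r}")

    return BinaryCanopyMask(
        sky=blue > threshold,
        threshold_used=threshold,
        source=image.source,
    )
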