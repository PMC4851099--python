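"""Binary canopy/sky mask container.

A cover photograph, once segmented, reduces to a two-valued raster: every
pixel is either canopy material (leaves, shoots, cordon) or sky.  All of the
downstream canopy-architecture math consumes only this raster, so the mask is
the package's central exchange type.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["BinaryCanopyMask"]


@dataclass(frozen=True)
class BinaryCanopyMask:
    """Two-class raster separating sky from canopy.

    Parameters
    ----------
    sky : numpy.ndarray of bool, shape (H, W)
        True where the pixel is sky (a gap), False where it is canopy.
    threshold_used : int, optional
        Blue-channel threshold that produced this mask, when it came from
        segmentation.  Recorded for reproducibility.
    source : str, optional
        Path of the photograph the mask was derived from.
    """

    sky: np.ndarray
    threshold_used: int | None = None
    source: str | None = None

    def __post_init__(self) -> None:
        sky = np.asarray(self.sky)
        if sky.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {sky.shape}")
        if sky.shape[0] < 1 or sky.shape[1] < 1:
            raise ValueError(f"mask must be non-empty, got shape {sky.shape}")
        if sky.dtype != bool:
            uniq = np.unique(sky)
            if not np.isin(uniq, (0, 1)).all():
                raise ValueError(
                    f"mask values must be two-valued (0/1), found {uniq.tolist()}"
                )
            sky = sky.astype(bool)
        object.__setattr__(self, "sky", sky)

    @property
    def height(self) -> int:
        return int(self.sky.shape[0])

    @property
    def width(self) -> int:
        return int(self.sky.shape[1])

    @property
    def sky_count(self) -> int:
        """Number of gap (sky) pixels."""
        return int(self.sky.sum())

    @property
    def canopy_count(self) -> int:
        """Number of canopy pixels; sky_count + canopy_count == H*W."""
        return self.sky.size - self.sky_count

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinaryCanopyMask):
            return NotImplemented
        return (
            self.sky.shape == other.sky.shape
            and bool(np.array_equal(self.sky, other.sky))
        )

    __hash__ = None  # type: ignore[assignment]  # mutable payload
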