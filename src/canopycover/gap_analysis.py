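"""Gap counting with the 5x5 sub-image large-gap rule.

Cover photography distinguishes two kinds of gap in an upward-looking canopy
image.  *Within-crown* gaps are the small holes between leaves inside a
crown; *between-crown* ("large") gaps are open sky between crowns.  The
separation is done by tiling the binary mask into ``grid_n x grid_n``
rectangular sub-images (5x5 by default) and declaring a sub-image a large
gap when at least a fraction ``tau`` (default 0.75) of its pixels are sky.

The resulting triple of pixel counts —

* ``tp``  total pixels in the image,
* ``tg``  total sky (gap) pixels,
* ``lg``  sky pixels lying inside large-gap sub-images,

— is the sole input to all canopy-architecture metrics.

``lg`` counts the *sky pixels inside* qualifying sub-images, not the whole
sub-image area.  This guarantees ``lg <= tg`` and therefore keeps crown
cover >= foliage cover and crown porosity inside [0, 1] downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .masks import BinaryCanopyMask

__all__ = [
    "GapSettings",
    "GapCounts",
    "count_gaps",
    "count_gaps_bruteforce",
]


@dataclass(frozen=True)
class GapSettings:
    """Tiling and qualification settings for large-gap detection.

    Attributes
    ----------
    grid_n : int
        Number of sub-images per side; the image is tiled into
        ``grid_n ** 2`` near-equal rectangles.  Default 5 (25 sub-images).
    gap_fraction_threshold : float
        Sky fraction ``tau`` at or above which a sub-image counts as a
        large gap.  Default 0.75.
    """

    grid_n: int = 5
    gap_fraction_threshold: float = 0.75

    def __post_init__(self) -> None:
        if int(self.grid_n) != self.grid_n or self.grid_n < 1:
            raise ValueError(f"grid_n must be an integer >= 1, got {self.grid_n}")
        if not 0.0 <= self.gap_fraction_threshold <= 1.0:
            raise ValueError(
                "gap_fraction_threshold must be in [0, 1], got "
                f"{self.gap_fraction_threshold}"
            )


@dataclass(frozen=True)
class GapCounts:
    """Pixel-count triple (tp, tg, lg) plus the settings that produced it."""

    tp: int
    tg: int
    lg: int
    settings: GapSettings = field(default_factory=GapSettings)

    def __post_init__(self) -> None:
        if not 0 <= self.lg <= self.tg <= self.tp:
            raise ValueError(
                f"gap counts must satisfy 0 <= lg <= tg <= tp, got "
                f"lg={self.lg}, tg={self.tg}, tp={self.tp}"
            )


def _boundary(i: int, extent: int, grid_n: int) -> int:
    # floor(i * extent / grid_n + 1/2) in exact integer arithmetic, so the
    # vectorized and brute-force paths can never disagree on tiling.
    return (2 * i * extent + grid_n) // (2 * grid_n)


def _check(mask: BinaryCanopyMask, settings: GapSettings) -> None:
    if mask.height < settings.grid_n or mask.width < settings.grid_n:
        raise ValueError(
            f"image of shape ({mask.height}, {mask.width}) cannot be tiled "
            f"into {settings.grid_n}x{settings.grid_n} non-empty sub-images"
        )


def count_gaps(
    mask: BinaryCanopyMask, settings: GapSettings | None = None
) -> GapCounts:
    """Count total, gap and large-gap pixels of a binary mask.

    The mask is partitioned into ``grid_n x grid_n`` contiguous rectangles
    with boundaries at ``round(i * H / grid_n)`` / ``round(j * W / grid_n)``
    (half-up), covering every pixel exactly once even when the dimensions
    are not divisible by ``grid_n``.  A sub-image qualifies as a large gap
    iff its sky fraction is >= ``gap_fraction_threshold``; ``lg`` sums the
    sky pixels of qualifying sub-images.

    Parameters
    ----------
    mask : BinaryCanopyMask
    settings : GapSettings, optional
        Defaults to a 5x5 grid with threshold 0.75.

    Returns
    -------
    GapCounts
    """
    if settings is None:
        settings = GapSettings()
    _check(mask, settings)
    sky = mask.sky
    h, w = sky.shape
    n = settings.grid_n
    tau = settings.gap_fraction_threshold

    rows = [_boundary(i, h, n) for i in range(n + 1)]
    cols = [_boundary(j, w, n) for j in range(n + 1)]

    lg = 0
    for i in range(n):
        for j in range(n):
            tile = sky[rows[i] : rows[i + 1], cols[j] : cols[j + 1]]
            sky_px = int(tile.sum())
            if sky_px >= tau * tile.size:
                lg += sky_px
    return GapCounts(tp=h * w, tg=int(sky.sum()), lg=lg, settings=settings)


def count_gaps_bruteforce(
    mask: BinaryCanopyMask, settings: GapSettings | None = None
) -> GapCounts:
    """Reference implementation of :func:`count_gaps` by explicit loops.

    Same contract as :func:`count_gaps`, computed pixel by pixel with no
    array shortcuts.  Kept as an independent oracle for testing; use
    :func:`count_gaps` in production code.
    """
    if settings is None:
        settings = GapSettings()
    _check(mask, settings)
    sky = mask.sky
    h, w = sky.shape
    n = settings.grid_n
    tau = settings.gap_fraction_threshold

    tg = 0
    for r in range(h):
        for c in range(w):
            if sky[r, c]:
                tg += 1

    lg = 0
    for i in range(n):
        r0 = (2 * i * h + n) // (2 * n)
        r1 = (2 * (i + 1) * h + n) // (2 * n)
        for j in range(n):
            c0 = (2 * j * w + n) // (2 * n)
            c1 = (2 * (j + 1) * w + n) // (2 * n)
            sky_px = 0
            total = 0
            for r in range(r0, r1):
                for c in range(c0, c1):
                    total += 1
                    if sky[r, c]:
                        sky_px += 1
            if sky_px >= tau * total:
                lg += sky_px
    return GapCounts(tp=h * w, tg=tg, lg=lg, settings=settings)
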