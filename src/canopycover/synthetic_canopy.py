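"""Synthetic canopy image generation with exact ground truth.

Field validation of cover photography requires destructive leaf stripping;
this module replaces that with generated two-class images whose true mask,
gap counts and LAI are known by construction, so every stage of the
pipeline (segmentation, gap counting, Beer's-law inversion, k estimation)
can be tested end to end.

Three generators are provided:

* :func:`generate_bernoulli` — each pixel is independently sky with
  probability ``sky_prob``: a randomly dispersed canopy.
* :func:`generate_blocky` — designated rectangles are fully sky on top of
  a Bernoulli background: a clumped canopy with between-crown gaps that
  exercises the large-gap rule.
* :func:`generate_defoliation_series` — a sequence of images in which the
  canopy is progressively thinned (e.g. ~30% of the remaining canopy
  removed per step, down to a bare-cordon analogue), each image carrying
  an assigned true LAI consistent with a chosen true extinction
  coefficient, so that Beer's-law inversion recovers that coefficient
  exactly.

Pixels are rendered with class-conditional Gaussian channel statistics
clipped to [0, 255]; the default blue means (canopy 40, sky 220, sd 10)
are separable by any histogram splitter, emulating photographs taken with
the sun out of frame.  All generation is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .canopy_math import compute_metrics
from .gap_analysis import GapCounts, GapSettings, count_gaps
from .imaging_io import CaptureMeta, RGBImage
from .masks import BinaryCanopyMask

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate_bernoulli",
    "generate_blocky",
    "generate_defoliation_series",
]

# Red/green class means for rendering; only the blue channel drives
# segmentation, these just make the images look plausibly leaf/sky like.
_CANOPY_RG = (55.0, 95.0)
_SKY_RG = (205.0, 215.0)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic canopy scene.

    ``block_layout`` lists fully-sky rectangles as (row, col, height,
    width) tuples; they model between-crown gaps.  Channel statistics are
    per-class Gaussian means/sds for the blue channel, clipped to
    [0, 255] after sampling.
    """

    width: int = 200
    height: int = 200
    sky_prob: float = 0.2
    block_layout: tuple[tuple[int, int, int, int], ...] = ()
    canopy_blue_mean: float = 40.0
    canopy_blue_sd: float = 10.0
    sky_blue_mean: float = 220.0
    sky_blue_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError(f"image must be non-empty: {self.height}x{self.width}")
        if not 0.0 <= self.sky_prob <= 1.0:
            raise ValueError(f"sky_prob must be in [0, 1], got {self.sky_prob}")
        if self.canopy_blue_sd < 0 or self.sky_blue_sd < 0:
            raise ValueError("channel standard deviations must be >= 0")
        for rect in self.block_layout:
            r, c, bh, bw = rect
            if bh < 1 or bw < 1 or r < 0 or c < 0:
                raise ValueError(f"invalid block {rect}")
            if r + bh > self.height or c + bw > self.width:
                raise ValueError(f"block {rect} exceeds image bounds")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator knows: true mask, true counts, assigned LAI."""

    true_mask: BinaryCanopyMask
    true_counts: GapCounts
    true_lai: float | None = None


def _render(sky: np.ndarray, spec: SyntheticSpec, rng: np.random.Generator) -> RGBImage:
    h, w = sky.shape
    pixels = np.empty((h, w, 3), dtype=float)
    canopy = ~sky
    for ch, (c_mean, s_mean) in enumerate(
        [
            (_CANOPY_RG[0], _SKY_RG[0]),
            (_CANOPY_RG[1], _SKY_RG[1]),
            (spec.canopy_blue_mean, spec.sky_blue_mean),
        ]
    ):
        plane = np.empty((h, w), dtype=float)
        plane[canopy] = rng.normal(c_mean, spec.canopy_blue_sd, int(canopy.sum()))
        plane[sky] = rng.normal(s_mean, spec.sky_blue_sd, int(sky.sum()))
        pixels[:, :, ch] = plane
    pixels = np.clip(np.rint(pixels), 0, 255).astype(np.uint8)
    return RGBImage(pixels=pixels, meta=CaptureMeta())


def _truth(
    sky: np.ndarray, settings: GapSettings | None
) -> GroundTruth:
    mask = BinaryCanopyMask(sky=sky)
    counts = count_gaps(mask, settings)
    return GroundTruth(true_mask=mask, true_counts=counts)


def generate_bernoulli(
    spec: SyntheticSpec, settings: GapSettings | None = None
) -> tuple[RGBImage, GroundTruth]:
    """Randomly dispersed canopy: each pixel independently sky.

    Returns the rendered photograph and its ground truth (true mask and
    gap counts under ``settings``, default 5x5 grid / 0.75 threshold).
    """
    rng = np.random.default_rng(spec.seed)
    sky = rng.random((spec.height, spec.width)) < spec.sky_prob
    return _render(sky, spec, rng), _truth(sky, settings)


def generate_blocky(
    spec: SyntheticSpec, settings: GapSettings | None = None
) -> tuple[RGBImage, GroundTruth]:
    """Clumped canopy: fully-sky rectangles over a Bernoulli background.

    Blocks must not overlap; they create contiguous large gaps that the
    sub-image rule classifies as between-crown sky.
    """
    occupancy = np.zeros((spec.height, spec.width), dtype=np.int16)
    for r, c, bh, bw in spec.block_layout:
        occupancy[r : r + bh, c : c + bw] += 1
    if (occupancy > 1).any():
        raise ValueError("block_layout rectangles overlap")
    rng = np.random.default_rng(spec.seed)
    sky = rng.random((spec.height, spec.width)) < spec.sky_prob
    sky |= occupancy.astype(bool)
    return _render(sky, spec, rng), _truth(sky, settings)


def generate_defoliation_series(
    spec: SyntheticSpec,
    retention_fractions: Sequence[float],
    true_k: float = 0.7,
    settings: GapSettings | None = None,
) -> list[tuple[RGBImage, GroundTruth]]:
    """Progressive leaf-stripping series with assigned true LAI.

    Starts from a maximal canopy (Bernoulli gaps with ``spec.sky_prob``,
    which models the small within-crown holes present even at full
    canopy) and, for each retention fraction r, keeps a random subset of
    ``floor(r * n0)`` of the original canopy pixels, converting the rest
    to sky.  Each image's true LAI is assigned by applying Beer's law to
    its own exact gap counts with ``true_k``, so inverting the law
    against that LAI returns ``true_k`` to machine precision.

    Parameters
    ----------
    spec : SyntheticSpec
    retention_fractions : sequence of float
        Strictly decreasing values in (0, 1], e.g. ``[1.0, 0.7, 0.49,
        0.343]`` for ~30% canopy removal per stripping step.
    true_k : float
        The generating extinction coefficient, in (0, 1].
    """
    fracs = list(retention_fractions)
    if not fracs:
        raise ValueError("retention_fractions must be non-empty")
    if any(not 0.0 < f <= 1.0 for f in fracs):
        raise ValueError(f"retention fractions must lie in (0, 1]: {fracs}")
    if any(b >= a for a, b in zip(fracs, fracs[1:])):
        raise ValueError(f"retention fractions must strictly decrease: {fracs}")
    if not 0.0 < true_k <= 1.0:
        raise ValueError(f"true_k must be in (0, 1], got {true_k}")

    rng = np.random.default_rng(spec.seed)
    base_sky = rng.random((spec.height, spec.width)) < spec.sky_prob
    canopy_idx = np.flatnonzero(~base_sky.ravel())
    n0 = canopy_idx.size
    if n0 == 0:
        raise ValueError("base scene has no canopy pixels; lower sky_prob")
    order = rng.permutation(canopy_idx)  # stripping order, fixed once

    series: list[tuple[RGBImage, GroundTruth]] = []
    for frac in fracs:
        keep = int(frac * n0)
        sky = np.ones(base_sky.size, dtype=bool)
        sky[order[:keep]] = False
        sky = sky.reshape(base_sky.shape)
        image = _render(sky, spec, rng)
        mask = BinaryCanopyMask(sky=sky)
        counts = count_gaps(mask, settings)
        true_lai = compute_metrics(counts, k=true_k).lai
        series.append(
            (image, GroundTruth(true_mask=mask, true_counts=counts, true_lai=true_lai))
        )
    return series
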