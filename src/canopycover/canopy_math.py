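"""Canopy-architecture metrics from gap counts.

Given the pixel-count triple (tp, tg, lg) of an upward-looking image taken
at 0 degrees zenith, the cover-photography method computes:

    f_f    = 1 - tg/tp                    foliage projective cover
    f_c    = 1 - lg/tp                    crown cover
    Phi    = 1 - f_f/f_c                  crown porosity
    LAI    = -f_c * ln(Phi) / k           Beer's-law inversion
    Omega0 = (1 - Phi) ln(1 - f_f) / (ln(Phi) * f_f)   clumping index
    LAI_e  = LAI * Omega0                 effective LAI

where k is the light extinction coefficient (0.7 by default, the accepted
value for grapevine canopies).  Omega0 = 1 means randomly dispersed
foliage; Omega0 < 1 means a clumped canopy.  When there are no large gaps
(lg = 0) the algebra gives Omega0 = 1 identically, so LAI_e = LAI.

Degenerate inputs (fully open sky, fully closed canopy, porosity at its
bounds) are mapped to documented conventions and flagged rather than
raising, because they occur routinely in defoliation series and bare-cordon
baseline images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .gap_analysis import GapCounts

__all__ = [
    "CanopyMetrics",
    "DEFAULT_K",
    "PHI_FLOOR",
    "foliage_cover",
    "crown_cover",
    "crown_porosity",
    "lai_beer",
    "clumping_index",
    "effective_lai",
    "compute_metrics",
    "subtract_baseline",
]

#: Default light extinction coefficient for grapevine canopies.
DEFAULT_K = 0.7

#: Porosity floor substituted for Phi <= PHI_FLOOR in the Beer's-law
#: inversion, which diverges as Phi -> 0 (fully closed crowns).
PHI_FLOOR = 1e-4


@dataclass(frozen=True)
class CanopyMetrics:
    """All canopy metrics for one image.

    ``omega0_raw`` keeps the unclamped clumping index; ``omega0`` is
    ``min(raw, 1)`` and is what multiplies LAI.  ``flags`` records which
    degeneracy conventions fired (e.g. ``empty_crown``,
    ``porosity_floored``, ``omega_clamped``).
    """

    ff: float
    fc: float
    phi: float
    omega0: float
    omega0_raw: float
    lai: float
    lai_e: float
    k: float
    flags: frozenset[str] = field(default_factory=frozenset)


def _validate_k(k: float) -> None:
    if not 0.0 < k <= 1.0:
        raise ValueError(f"extinction coefficient k must be in (0, 1], got {k}")


def foliage_cover(counts: GapCounts) -> float:
    """Fraction of the frame covered by foliage and branches: 1 - tg/tp."""
    if counts.tp <= 0:
        raise ValueError("total pixel count must be positive")
    return 1.0 - counts.tg / counts.tp


def crown_cover(counts: GapCounts) -> float:
    """Fraction of the frame covered by crown envelopes: 1 - lg/tp."""
    if counts.tp <= 0:
        raise ValueError("total pixel count must be positive")
    return 1.0 - counts.lg / counts.tp


def crown_porosity(ff: float, fc: float, flags: set[str] | None = None) -> float:
    """Within-crown gap fraction: 1 - ff/fc.

    ``fc = 0`` (fully open sky, no crowns at all) returns 1.0 and flags
    ``empty_crown``: an absent crown is all gap by convention.
    """
    if not 0.0 <= ff <= 1.0 or not 0.0 <= fc <= 1.0:
        raise ValueError(f"cover fractions must be in [0, 1], got ff={ff}, fc={fc}")
    if ff > fc:
        raise ValueError(
            f"foliage cover ({ff}) cannot exceed crown cover ({fc}); "
            "check that lg <= tg upstream"
        )
    if fc == 0.0:
        if flags is not None:
            flags.add("empty_crown")
        return 1.0
    return 1.0 - ff / fc


def lai_beer(
    fc: float,
    phi: float,
    k: float = DEFAULT_K,
    phi_floor: float = PHI_FLOOR,
    flags: set[str] | None = None,
) -> float:
    """Invert Beer's law for LAI: -fc * ln(phi) / k.

    Parameters
    ----------
    fc : float
        Crown cover fraction.
    phi : float
        Crown porosity in [0, 1].  ``phi = 1`` (no foliage inside crowns)
        gives LAI 0.  ``phi <= phi_floor`` is floored to ``phi_floor``
        (flagged ``porosity_floored``) because the logarithm diverges for
        a perfectly closed crown.
    k : float
        Light extinction coefficient in (0, 1].
    """
    _validate_k(k)
    if not 0.0 <= phi <= 1.0:
        raise ValueError(f"porosity must be in [0, 1], got {phi}")
    if phi >= 1.0:
        return 0.0
    if phi <= phi_floor:
        if flags is not None:
            flags.add("porosity_floored")
        phi = phi_floor
    return -fc * math.log(phi) / k


def clumping_index(ff: float, phi: float, flags: set[str] | None = None) -> float:
    """Clumping index at 0 degrees zenith.

    Omega0 = (1 - phi) * ln(1 - ff) / (ln(phi) * ff).

    Degenerate inputs — no foliage (ff = 0), closed frame (ff = 1) or
    porosity at either bound — return 1.0 (random dispersion) and flag
    ``omega_degenerate``.  The returned value is the *raw* index and may
    exceed 1 for some (ff, phi); callers clamp for downstream use.
    """
    if not 0.0 <= ff <= 1.0 or not 0.0 <= phi <= 1.0:
        raise ValueError(f"inputs must be in [0, 1], got ff={ff}, phi={phi}")
    if ff == 0.0 or ff == 1.0 or phi == 0.0 or phi == 1.0:
        if flags is not None:
            flags.add("omega_degenerate")
        return 1.0
    return (1.0 - phi) * math.log(1.0 - ff) / (math.log(phi) * ff)


def effective_lai(lai: float, omega0: float) -> float:
    """Effective LAI: the product LAI * Omega0."""
    if lai < 0.0:
        raise ValueError(f"LAI must be non-negative, got {lai}")
    if omega0 <= 0.0:
        raise ValueError(f"clumping index must be positive, got {omega0}")
    return lai * omega0


def compute_metrics(
    counts: GapCounts,
    k: float = DEFAULT_K,
    phi_floor: float = PHI_FLOOR,
    clamp_omega: bool = True,
) -> CanopyMetrics:
    """Full metric chain for one image's gap counts.

    Composes foliage cover, crown cover, porosity, Beer's-law LAI,
    clumping index and effective LAI; all intermediate fractions are kept
    in double precision, never rounded.
    """
    _validate_k(k)
    flags: set[str] = set()
    ff = foliage_cover(counts)
    fc = crown_cover(counts)
    phi = crown_porosity(ff, fc, flags)
    lai = lai_beer(fc, phi, k, phi_floor, flags)
    omega_raw = clumping_index(ff, phi, flags)
    if clamp_omega and omega_raw > 1.0:
        flags.add("omega_clamped")
        omega = 1.0
    else:
        omega = omega_raw
    lai_e = effective_lai(lai, omega)
    return CanopyMetrics(
        ff=ff,
        fc=fc,
        phi=phi,
        omega0=omega,
        omega0_raw=omega_raw,
        lai=lai,
        lai_e=lai_e,
        k=k,
        flags=frozenset(flags),
    )


def subtract_baseline(metrics: CanopyMetrics, baseline_lai_e: float) -> float:
    """Remove the woody-structure contribution from effective LAI.

    Bare-cordon images (all leaves stripped) still register a non-zero
    effective LAI; subtracting that baseline converts the plant-area
    estimate toward a leaf-area estimate.  The result is floored at 0.
    """
    if baseline_lai_e < 0.0:
        raise ValueError(f"baseline must be non-negative, got {baseline_lai_e}")
    return max(metrics.lai_e - baseline_lai_e, 0.0)
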