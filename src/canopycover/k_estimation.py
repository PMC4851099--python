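"""Light extinction coefficient (k) estimation strategies.

Beer's-law LAI inversion needs an extinction coefficient k.  Five
strategies are implemented, mirroring how k is obtained in practice:

``fixed``
    The literature value for grapevine canopies, k = 0.7.
``inverted``
    The *real* per-image k, obtained by inverting Beer's law against a
    ground-truth LAI (planimetric/gravimetric in the field, assigned by
    the synthetic generator here): k_r = -f_c ln(Phi) / LAI_r.
``lowess``
    A proxy k from a locally weighted scatterplot smoother (LOWESS) of
    k_r against a cover predictor (crown porosity Phi by default, crown
    cover f_c as an alternative), calibrated on samples with known LAI_r.
``biggap``
    A proxy k from an ordinary least-squares line of k_r against the
    normalized large-gap fraction lg/tp — larger between-crown gaps mean
    higher light transmission.
``luminance``
    A proxy k from scene brightness: the ratio I / Io between the image's
    metadata luminance and the maximum luminance of open-sky images
    (Io = 12).  A ``complement`` switch returns 1 - I/Io instead, the
    convention used for discontinuous orchard canopies.

All proxy outputs are clamped into [K_MIN, 1] because Beer's law divides
by k.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .canopy_math import (
    DEFAULT_K,
    PHI_FLOOR,
    CanopyMetrics,
    compute_metrics,
    crown_cover,
    crown_porosity,
    foliage_cover,
)
from .gap_analysis import GapCounts

__all__ = [
    "K_MIN",
    "DEFAULT_IO",
    "CalibrationSample",
    "KEstimate",
    "LowessKModel",
    "BigGapKModel",
    "fixed_k",
    "invert_k",
    "fit_lowess_k",
    "fit_biggap_k",
    "luminance_k",
    "estimate_lai_with_method",
    "read_calibration_csv",
    "write_calibration_csv",
]

#: Lower clamp for proxy k values (Beer's law divides by k).
K_MIN = 0.05

#: Maximum luminance of open-sky images (metadata units).
DEFAULT_IO = 12.0

#: Columns of a calibration CSV (header required).
CALIBRATION_COLUMNS = ["fc", "phi", "lg", "tp", "luminance_I", "lai_r"]


def _clamp_k(k: float, flags: set[str] | None = None, k_min: float = K_MIN) -> float:
    if k < k_min:
        if flags is not None:
            flags.add("k_clamped_low")
        return k_min
    if k > 1.0:
        if flags is not None:
            flags.add("k_clamped_high")
        return 1.0
    return k


@dataclass(frozen=True)
class CalibrationSample:
    """One calibration image: covers, gap counts, luminance and true LAI.

    ``k_r`` is the real extinction coefficient implied by the sample,
    computed by inverting Beer's law unless supplied explicitly.
    """

    fc: float
    phi: float
    lg: int
    tp: int
    lai_r: float
    luminance_I: float | None = None
    k_r: float | None = None

    def __post_init__(self) -> None:
        if self.lai_r <= 0.0:
            raise ValueError(f"ground-truth LAI must be positive, got {self.lai_r}")
        if self.tp <= 0 or not 0 <= self.lg <= self.tp:
            raise ValueError(f"invalid pixel counts lg={self.lg}, tp={self.tp}")
        if self.k_r is None:
            object.__setattr__(self, "k_r", invert_k(self.fc, self.phi, self.lai_r))
        elif self.k_r <= 0.0:
            raise ValueError(f"k_r must be positive, got {self.k_r}")

    @property
    def lg_fraction(self) -> float:
        """Normalized large-gap fraction lg/tp (image-size invariant)."""
        return self.lg / self.tp


@dataclass(frozen=True)
class KEstimate:
    """A resolved extinction coefficient with its provenance."""

    method: str
    k: float
    model_params: dict = field(default_factory=dict)
    flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not 0.0 < self.k <= 1.0:
            raise ValueError(f"k must be in (0, 1], got {self.k}")


def fixed_k(value: float = DEFAULT_K) -> KEstimate:
    """Strategy (fixed): the literature constant, configurable."""
    if not 0.0 < value <= 1.0:
        raise ValueError(f"fixed k must be in (0, 1], got {value}")
    return KEstimate(method="fixed", k=value)


def invert_k(fc: float, phi: float, lai_r: float, phi_floor: float = PHI_FLOOR) -> float:
    """Strategy (inverted): real per-image k from ground-truth LAI.

    k_r = -fc * ln(phi) / lai_r.  Porosity at its bounds is floored the
    same way as in the forward Beer's-law computation so that inverting
    and re-applying the law round-trips exactly.
    """
    if lai_r <= 0.0:
        raise ValueError(f"ground-truth LAI must be positive, got {lai_r}")
    if not 0.0 <= phi <= 1.0:
        raise ValueError(f"porosity must be in [0, 1], got {phi}")
    if phi >= 1.0:
        raise ValueError("porosity 1 (no foliage) admits no finite k inversion")
    if phi <= phi_floor:
        phi = phi_floor
    return -fc * math.log(phi) / lai_r


@dataclass(frozen=True)
class LowessKModel:
    """Fitted LOWESS curve of k_r against a cover predictor."""

    predictor: str  # "phi" or "fc"
    x_smooth: np.ndarray
    k_smooth: np.ndarray
    window_frac: float
    n_samples: int

    def predict(self, x: float, flags: set[str] | None = None) -> float:
        """Interpolate the smoothed curve; extrapolation holds the ends."""
        k = float(np.interp(x, self.x_smooth, self.k_smooth))
        return _clamp_k(k, flags)

    def predict_for(self, counts: GapCounts, flags: set[str] | None = None) -> float:
        ff = foliage_cover(counts)
        fc = crown_cover(counts)
        phi = crown_porosity(ff, fc)
        return self.predict(phi if self.predictor == "phi" else fc, flags)


def fit_lowess_k(
    samples: Sequence[CalibrationSample],
    window_frac: float = 0.05,
    predictor: str = "phi",
) -> LowessKModel:
    """Strategy (lowess): smooth k_r against a cover predictor.

    Parameters
    ----------
    samples : sequence of CalibrationSample
        At least 5 samples with defined k_r.
    window_frac : float
        LOWESS window as a fraction of the sample count (default 5%);
        at least 3 points are always used.
    predictor : {"phi", "fc"}
        Which cover variable drives the smoother.
    """
    if len(samples) < 5:
        raise ValueError(f"LOWESS calibration needs >= 5 samples, got {len(samples)}")
    if predictor not in ("phi", "fc"):
        raise ValueError(f"predictor must be 'phi' or 'fc', got {predictor!r}")
    x = np.array([getattr(s, predictor) for s in samples], dtype=float)
    y = np.array([s.k_r for s in samples], dtype=float)
    if np.ptp(x) == 0.0:
        raise ValueError(f"predictor {predictor!r} is constant; cannot smooth")
    frac = max(window_frac, 3.0 / len(samples))
    smoothed = sm.nonparametric.lowess(y, x, frac=frac, return_sorted=True)
    # collapse duplicate abscissae so np.interp sees a strictly sorted grid
    xs, idx = np.unique(smoothed[:, 0], return_index=True)
    return LowessKModel(
        predictor=predictor,
        x_smooth=xs,
        k_smooth=smoothed[idx, 1],
        window_frac=frac,
        n_samples=len(samples),
    )


@dataclass(frozen=True)
class BigGapKModel:
    """OLS line k = a + b * (lg/tp) fitted on calibration samples."""

    intercept: float
    slope: float
    n_samples: int

    def predict(self, lg_fraction: float, flags: set[str] | None = None) -> float:
        return _clamp_k(self.intercept + self.slope * lg_fraction, flags)

    def predict_for(self, counts: GapCounts, flags: set[str] | None = None) -> float:
        return self.predict(counts.lg / counts.tp, flags)


def fit_biggap_k(samples: Sequence[CalibrationSample]) -> BigGapKModel:
    """Strategy (biggap): regress k_r on the normalized large-gap fraction.

    Larger between-crown gaps transmit more light to the acquisition
    point; the fitted line converts an image's lg/tp into a proxy k.
    """
    if len(samples) < 3:
        raise ValueError(f"large-gap regression needs >= 3 samples, got {len(samples)}")
    x = np.array([s.lg_fraction for s in samples], dtype=float)
    y = np.array([s.k_r for s in samples], dtype=float)
    if np.ptp(x) == 0.0:
        raise ValueError("large-gap fractions are all equal; cannot regress")
    slope, intercept = np.polyfit(x, y, 1)
    return BigGapKModel(intercept=float(intercept), slope=float(slope), n_samples=len(x))


def luminance_k(
    I: float,
    Io: float = DEFAULT_IO,
    complement: bool = False,
    k_min: float = K_MIN,
    flags: set[str] | None = None,
) -> float:
    """Strategy (luminance): proxy k from scene brightness.

    Default is the plain ratio I/Io; ``complement=True`` returns
    1 - I/Io (the below/above-canopy radiation convention used for
    orchard canopies).  Either way the result is clamped into
    [k_min, 1], flagged when clamping fires.
    """
    if Io <= 0.0:
        raise ValueError(f"maximum luminance Io must be positive, got {Io}")
    if I < 0.0:
        raise ValueError(f"luminance must be non-negative, got {I}")
    ratio = I / Io
    k = 1.0 - ratio if complement else ratio
    return _clamp_k(k, flags, k_min)


def estimate_lai_with_method(
    counts: GapCounts,
    method: str | KEstimate | LowessKModel | BigGapKModel,
    *,
    lai_r: float | None = None,
    luminance_I: float | None = None,
    k: float = DEFAULT_K,
    Io: float = DEFAULT_IO,
    complement: bool = False,
    phi_floor: float = PHI_FLOOR,
) -> CanopyMetrics:
    """Resolve a per-image k by the chosen strategy, then compute metrics.

    Parameters
    ----------
    counts : GapCounts
    method : str or fitted model
        One of ``"fixed"``, ``"inverted"``, ``"luminance"``, a
        :class:`KEstimate`, or a fitted :class:`LowessKModel` /
        :class:`BigGapKModel`.
    lai_r : float, required for ``"inverted"``
    luminance_I : float, required for ``"luminance"``
        Falls back to nothing: an absent luminance is an error.
    """
    flags: set[str] = set()
    if isinstance(method, KEstimate):
        k_value = method.k
    elif isinstance(method, (LowessKModel, BigGapKModel)):
        k_value = method.predict_for(counts, flags)
    elif method == "fixed":
        k_value = fixed_k(k).k
    elif method == "inverted":
        if lai_r is None:
            raise ValueError("method 'inverted' requires lai_r (ground-truth LAI)")
        ff = foliage_cover(counts)
        fc = crown_cover(counts)
        phi = crown_porosity(ff, fc)
        k_value = _clamp_k(invert_k(fc, phi, lai_r, phi_floor), flags)
    elif method == "luminance":
        if luminance_I is None:
            raise ValueError("method 'luminance' requires luminance_I (image metadata)")
        k_value = luminance_k(luminance_I, Io, complement, flags=flags)
    else:
        raise ValueError(
            f"unknown k method {method!r}; expected 'fixed', 'inverted', "
            "'luminance' or a fitted model"
        )
    metrics = compute_metrics(counts, k=k_value, phi_floor=phi_floor)
    return CanopyMetrics(
        ff=metrics.ff,
        fc=metrics.fc,
        phi=metrics.phi,
        omega0=metrics.omega0,
        omega0_raw=metrics.omega0_raw,
        lai=metrics.lai,
        lai_e=metrics.lai_e,
        k=metrics.k,
        flags=metrics.flags | frozenset(flags),
    )


def read_calibration_csv(path: str | Path) -> list[CalibrationSample]:
    """Read calibration samples from a CSV with the documented header.

    Required columns: fc, phi, lg, tp, luminance_I, lai_r.  An empty
    luminance cell means "not recorded".
    """
    df = pd.read_csv(path)
    missing = [c for c in CALIBRATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"calibration CSV {path} lacks columns: {missing}")
    samples = []
    for row in df.itertuples(index=False):
        lum = getattr(row, "luminance_I")
        samples.append(
            CalibrationSample(
                fc=float(row.fc),
                phi=float(row.phi),
                lg=int(row.lg),
                tp=int(row.tp),
                lai_r=float(row.lai_r),
                luminance_I=None if pd.isna(lum) else float(lum),
            )
        )
    return samples


def write_calibration_csv(samples: Sequence[CalibrationSample], path: str | Path) -> None:
    """Write calibration samples in the documented CSV schema."""
    df = pd.DataFrame(
        {
            "fc": [s.fc for s in samples],
            "phi": [s.phi for s in samples],
            "lg": [s.lg for s in samples],
            "tp": [s.tp for s in samples],
            "luminance_I": [s.luminance_I for s in samples],
            "lai_r": [s.lai_r for s in samples],
        }
    )
    df.to_csv(path, index=False)
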