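"""Extinction-coefficient strategies: inversion, smoothing, regression, luminance."""

from __future__ import annotations

import math

import numpy as np
import pytest

from canopycover import (
    CalibrationSample,
    GapCounts,
    compute_metrics,
    estimate_lai_with_method,
    fit_biggap_k,
    fit_lowess_k,
    fixed_k,
    invert_k,
    lai_beer,
    luminance_k,
)
from canopycover.k_estimation import (
    K_MIN,
    read_calibration_csv,
    write_calibration_csv,
)


def make_sample(phi: float, lg_frac: float = 0.02, k_r: float | None = None,
                fc: float = 0.95, lai_r: float | None = None,
                luminance: float | None = None) -> CalibrationSample:
    """Build a sample whose implied k_r is exactly the requested value."""
    if k_r is not None:
        lai_r = -fc * math.log(phi) / k_r
    assert lai_r is not None
    tp = 10_000
    return CalibrationSample(
        fc=fc, phi=phi, lg=round(lg_frac * tp), tp=tp, lai_r=lai_r,
        luminance_I=luminance,
    )


# ---------------------------------------------------------------- fixed (i)

def test_fixed_k_default_and_override():
    assert fixed_k().k == 0.7
    assert fixed_k().method == "fixed"
    assert fixed_k(0.5).k == 0.5
    with pytest.raises(ValueError):
        fixed_k(1.5)
    with pytest.raises(ValueError):
        fixed_k(0.0)


# ------------------------------------------------------------- inverted (ii)

def test_invert_k_hand_value():
    assert invert_k(0.96, 0.166667, 2.0) == pytest.approx(0.8601, abs=5e-4)


def test_invert_k_closed_form():
    assert invert_k(1.0, math.exp(-0.7), 1.0) == pytest.approx(0.7, rel=1e-12)


def test_invert_then_forward_round_trips(rng):
    for _ in range(200):
        fc = float(rng.uniform(0.3, 1.0))
        phi = float(rng.uniform(0.01, 0.99))
        L = float(rng.uniform(0.1, 6.0))
        k = invert_k(fc, phi, L)
        if k <= 1.0:  # forward model only accepts physical k
            assert lai_beer(fc, phi, k) == pytest.approx(L, rel=1e-12)


def test_invert_k_rejects_bad_inputs():
    with pytest.raises(ValueError):
        invert_k(0.9, 0.5, 0.0)
    with pytest.raises(ValueError):
        invert_k(0.9, 1.0, 2.0)
    with pytest.raises(ValueError):
        invert_k(0.9, 1.2, 2.0)


# --------------------------------------------------------------- lowess (iii)

def test_lowess_recovers_exact_linear_k_function(rng):
    phis = rng.uniform(0.05, 0.95, 200)
    samples = [make_sample(float(p), k_r=0.5 + 0.3 * float(p)) for p in phis]
    model = fit_lowess_k(samples, window_frac=0.05)
    interior = np.linspace(0.15, 0.85, 30)
    for p in interior:
        assert model.predict(float(p)) == pytest.approx(0.5 + 0.3 * p, abs=0.01)


def test_lowess_smooths_constant_to_constant(rng):
    phis = rng.uniform(0.1, 0.9, 50)
    samples = [make_sample(float(p), k_r=0.7) for p in phis]
    model = fit_lowess_k(samples)
    for p in (0.2, 0.5, 0.8):
        assert model.predict(p) == pytest.approx(0.7, abs=1e-9)


def test_lowess_needs_five_samples(rng):
    samples = [make_sample(p, k_r=0.7) for p in (0.2, 0.4, 0.6, 0.8)]
    with pytest.raises(ValueError, match=">= 5"):
        fit_lowess_k(samples)


def test_lowess_rejects_constant_predictor():
    samples = [make_sample(0.5, k_r=0.6 + 0.01 * i) for i in range(6)]
    with pytest.raises(ValueError, match="constant"):
        fit_lowess_k(samples)


def test_lowess_fc_predictor(rng):
    fcs = rng.uniform(0.5, 1.0, 100)
    samples = [make_sample(0.3, fc=float(f), k_r=0.4 + 0.3 * float(f)) for f in fcs]
    model = fit_lowess_k(samples, predictor="fc")
    assert model.predict(0.75) == pytest.approx(0.4 + 0.3 * 0.75, abs=0.01)


# --------------------------------------------------------------- biggap (iv)

def test_biggap_recovers_exact_line(rng):
    # quantize to whole pixels out of tp=10000 so lg/tp is exact
    lg_fracs = np.round(rng.uniform(0.0, 0.5, 40), 4)
    samples = [make_sample(0.3, lg_frac=float(g), k_r=0.6 + 0.2 * float(g))
               for g in lg_fracs]
    model = fit_biggap_k(samples)
    assert model.intercept == pytest.approx(0.6, abs=1e-9)
    assert model.slope == pytest.approx(0.2, abs=1e-9)


def test_biggap_rejects_degenerate_predictor():
    samples = [make_sample(0.3, lg_frac=0.1, k_r=0.6 + 0.01 * i) for i in range(5)]
    with pytest.raises(ValueError, match="equal"):
        fit_biggap_k(samples)
    with pytest.raises(ValueError, match=">= 3"):
        fit_biggap_k(samples[:2])


def test_biggap_prediction_clamps_to_unit_interval(rng):
    lg_fracs = np.linspace(0.0, 0.4, 20)
    samples = [make_sample(0.3, lg_frac=float(g), k_r=min(0.5 + 2.0 * float(g), 1.0 - 1e-9))
               for g in lg_fracs[:10]]
    # steep synthetic line: prediction beyond the data can exceed 1
    model = fit_biggap_k(
        [make_sample(0.3, lg_frac=float(g), k_r=0.5 + 1.2 * float(g)) for g in lg_fracs]
    )
    flags: set[str] = set()
    assert model.predict(0.9, flags) == 1.0
    assert "k_clamped_high" in flags


# ------------------------------------------------------------ luminance (v)

def test_luminance_ratio_and_bounds():
    assert luminance_k(8.4, 12.0) == pytest.approx(0.7, rel=1e-12)
    assert luminance_k(12.0, 12.0) == 1.0
    flags: set[str] = set()
    assert luminance_k(0.0, 12.0, flags=flags) == K_MIN
    assert "k_clamped_low" in flags
    flags.clear()
    assert luminance_k(30.0, 12.0, flags=flags) == 1.0
    assert "k_clamped_high" in flags


def test_luminance_complement_switch():
    assert luminance_k(3.6, 12.0, complement=True) == pytest.approx(0.7, rel=1e-12)


def test_luminance_rejects_bad_io():
    with pytest.raises(ValueError):
        luminance_k(5.0, 0.0)
    with pytest.raises(ValueError):
        luminance_k(-1.0, 12.0)


# --------------------------------------------------- per-image LAI dispatch

def test_fixed_method_delegates_to_compute_metrics():
    counts = GapCounts(tp=100, tg=20, lg=4)
    direct = compute_metrics(counts, k=0.7)
    via = estimate_lai_with_method(counts, "fixed")
    assert via.lai == direct.lai
    assert via.k == 0.7


def test_inverted_method_reproduces_ground_truth_exactly():
    counts = GapCounts(tp=100, tg=20, lg=4)
    lai_r = compute_metrics(counts, k=0.63).lai
    m = estimate_lai_with_method(counts, "inverted", lai_r=lai_r)
    assert m.lai == pytest.approx(lai_r, rel=1e-12)


def test_luminance_method_matches_fixed_default():
    counts = GapCounts(tp=100, tg=20, lg=4)
    assert estimate_lai_with_method(
        counts, "luminance", luminance_I=8.4
    ).lai == pytest.approx(estimate_lai_with_method(counts, "fixed").lai, rel=1e-12)


def test_missing_extras_raise_descriptive_errors():
    counts = GapCounts(tp=100, tg=20, lg=4)
    with pytest.raises(ValueError, match="inverted"):
        estimate_lai_with_method(counts, "inverted")
    with pytest.raises(ValueError, match="luminance"):
        estimate_lai_with_method(counts, "luminance")
    with pytest.raises(ValueError, match="unknown"):
        estimate_lai_with_method(counts, "bogus")


def test_fitted_models_resolve_per_image_k(rng):
    lg_fracs = np.round(rng.uniform(0.0, 0.4, 30), 4)
    samples = [make_sample(0.3, lg_frac=float(g), k_r=0.6 + 0.2 * float(g))
               for g in lg_fracs]
    model = fit_biggap_k(samples)
    counts = GapCounts(tp=10_000, tg=3_000, lg=1_000)
    m = estimate_lai_with_method(counts, model)
    assert m.k == pytest.approx(0.6 + 0.2 * 0.1, abs=1e-9)


# ------------------------------------------------------------ CSV plumbing

def test_calibration_csv_round_trip(tmp_path, rng):
    samples = [
        make_sample(float(p), lg_frac=float(g), k_r=float(k), luminance=float(l))
        for p, g, k, l in zip(
            rng.uniform(0.1, 0.9, 10),
            rng.uniform(0.0, 0.3, 10),
            rng.uniform(0.4, 0.9, 10),
            rng.uniform(0.0, 12.0, 10),
        )
    ]
    path = tmp_path / "calib.csv"
    write_calibration_csv(samples, path)
    back = read_calibration_csv(path)
    assert len(back) == len(samples)
    for a, b in zip(samples, back):
        assert b.fc == pytest.approx(a.fc)
        assert b.phi == pytest.approx(a.phi)
        assert b.lg == a.lg
        assert b.lai_r == pytest.approx(a.lai_r)
        assert b.k_r == pytest.approx(a.k_r, rel=1e-12)


def test_calibration_csv_requires_header(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("a,b,c\n1,2,3\n")
    with pytest.raises(ValueError, match="lacks columns"):
        read_calibration_csv(path)
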