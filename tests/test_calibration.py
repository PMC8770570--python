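"""Ratio <-> pH / [Ca2+] conversions, curve fits and reference adjustment."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from marrowquant import calibration as cal
from marrowquant import synthetic_data as sd


PH = cal.PHCalibration()
CA = cal.CaCalibration()


# ---------------------------------------------------------------------------
# conversions
# ---------------------------------------------------------------------------

def test_ph_midpoint_is_pka():
    r = (PH.r0 + PH.rm) / 2
    assert cal.ph_from_ratio(r, PH) == pytest.approx(PH.pka, abs=1e-12)


def test_spectral_term_shifts_ph_by_one_unit():
    r = 0.9
    base = cal.ph_from_ratio(r, PH)
    shifted = cal.ph_from_ratio(
        r, cal.PHCalibration(s_basic_over_s_acid=10.0))
    assert shifted - base == pytest.approx(1.0, abs=1e-12)


def test_ca_trivial_points():
    assert cal.ca_from_ratio(CA.r0, CA) == pytest.approx(0.0, abs=1e-12)
    mid = (CA.r0 + CA.rm) / 2  # (R-R0)/(RM-R) = 1
    assert cal.ca_from_ratio(mid, CA) == pytest.approx(CA.keff, abs=1e-12)


@settings(max_examples=60, deadline=None)
@given(st.floats(0.01, 0.99), st.floats(0.3, 3.0))
def test_round_trips_exact(u, hill):
    r = PH.r0 + u * (PH.rm - PH.r0)
    ph = cal.ph_from_ratio(r, PH)
    assert cal.ratio_from_ph(ph, PH) == pytest.approx(r, abs=1e-12)
    ca_cal = cal.CaCalibration(hill_slope=hill)
    if r > ca_cal.r0:
        c = cal.ca_from_ratio(r, ca_cal)
        assert cal.ratio_from_ca(c, ca_cal) == pytest.approx(r, abs=1e-12)


def test_monotonicity_of_conversions():
    rs = np.linspace(PH.r0 + 1e-6, PH.rm - 1e-6, 200)
    assert np.all(np.diff(cal.ph_from_ratio(rs, PH)) > 0)
    assert np.all(np.diff(cal.ca_from_ratio(rs, CA)) > 0)


def test_out_of_range_signalling():
    with pytest.raises(cal.RatioDomainError) as e:
        cal.ph_from_ratio(PH.rm + 0.1, PH)
    assert e.value.boundary == "high"
    with pytest.raises(cal.RatioDomainError) as e:
        cal.ca_from_ratio(CA.r0 - 0.01, CA)
    assert e.value.boundary == "low"
    out = cal.ca_from_ratio(np.array([CA.rm + 1.0]), CA, out_of_range="nan")
    assert np.isnan(out[0])


# ---------------------------------------------------------------------------
# fits
# ---------------------------------------------------------------------------

def test_ph_fit_recovers_noise_free_parameters():
    table = sd.generate_calibration_series("ph", cal=PH, noise_sd=0.0, seed=0)
    fit = cal.fit_ph_calibration(table)
    assert fit.pka == pytest.approx(PH.pka, rel=1e-6)
    assert fit.r0 == pytest.approx(PH.r0, rel=1e-6)
    assert fit.rm == pytest.approx(PH.rm, rel=1e-6)


def test_ph_fit_noisy_recovers_pka_within_tolerance():
    table = sd.generate_calibration_series("ph", cal=PH, noise_sd=0.02,
                                           replicates=3, seed=21)
    fit = cal.fit_ph_calibration(table)
    assert fit.pka == pytest.approx(PH.pka, abs=0.05)


def test_ph_fit_needs_four_levels():
    table = sd.generate_calibration_series("ph", levels=[6.0, 7.0, 8.0],
                                           cal=PH, noise_sd=0.0, seed=0)
    with pytest.raises(ValueError):
        cal.fit_ph_calibration(table)


def test_ca_fit_recovers_noise_free_parameters():
    gen = cal.CaCalibration(keff=0.85, hill_slope=1.0)
    table = sd.generate_calibration_series("ca", cal=gen, noise_sd=0.0, seed=0)
    fit = cal.fit_ca_calibration(table, ci=False)
    assert fit.keff == pytest.approx(gen.keff, rel=1e-6)
    assert fit.r0 == pytest.approx(gen.r0, abs=1e-6)
    assert fit.rm == pytest.approx(gen.rm, rel=1e-6)
    assert fit.hill_slope == pytest.approx(1.0, rel=1e-4)


def test_ca_fit_preconditions():
    with pytest.raises(ValueError, match="5 distinct"):
        cal.fit_ca_calibration((np.array([0, 1, 2, 3.0]),
                                np.array([0.2, 1.0, 1.4, 1.6])))
    with pytest.raises(ValueError, match="0 mM"):
        cal.fit_ca_calibration((np.array([0.5, 1, 2, 4, 8.0]),
                                np.array([0.8, 1.1, 1.4, 1.6, 1.8])))


def test_ca_response_shape_matches_probe():
    """Default calibration: near-linear below 0.5 mM, near-saturated above
    1 mM — the sensitivity at 1.5 mM is a small fraction of that at 0.1."""
    d = 1e-4
    slope = lambda c: (cal.ratio_from_ca(c + d, CA) - cal.ratio_from_ca(c, CA)) / d  # noqa: E731
    assert slope(1.5) <= 0.25 * slope(0.1)


def test_ca_fit_ph_robustness():
    """Series generated at nominal pH 7.0 and 7.4 with identical underlying
    response fit to the same keff (within 2%)."""
    t1 = sd.generate_calibration_series("ca", cal=CA, noise_sd=0.01, seed=31)
    t2 = sd.generate_calibration_series("ca", cal=CA, noise_sd=0.01, seed=32)
    f1 = cal.fit_ca_calibration(t1, ci=False)
    f2 = cal.fit_ca_calibration(t2, ci=False)
    assert f1.keff == pytest.approx(f2.keff, rel=0.02)


def test_ca_joint_fit_consistent_with_per_ph_fits():
    t1 = sd.generate_calibration_series("ca", cal=CA, noise_sd=0.0, seed=0)
    t2 = sd.generate_calibration_series("ca", cal=CA, noise_sd=0.0, seed=1)
    import pandas as pd
    both = pd.concat([t1, t2], ignore_index=True)
    labels = [7.0] * len(t1) + [7.4] * len(t2)
    joint = cal.fit_ca_calibration(both, ph_labels=labels, joint=True, ci=False)
    per = cal.fit_ca_calibration(both, ph_labels=labels, joint=False, ci=False)
    for f in per.values():
        assert f.keff == pytest.approx(joint.keff, rel=1e-6)


def test_ca_fit_ci_bounds_contain_estimate():
    table = sd.generate_calibration_series("ca", cal=CA, noise_sd=0.02,
                                           seed=33)
    fit = cal.fit_ca_calibration(table, n_boot=50, seed=1)
    lo, hi = fit.ci90["keff"]
    assert lo <= fit.keff <= hi


# ---------------------------------------------------------------------------
# day-to-day reference adjustment
# ---------------------------------------------------------------------------

def test_day_adjust_identity_and_scaling():
    ref = cal.DayReference(ratio_ref=1.4, ca_ref=0.5, kd=0.85)
    assert cal.day_adjust_ratio(1.1, ref, ref) == pytest.approx(1.1, abs=1e-15)
    ref2 = cal.DayReference(ratio_ref=0.7, ca_ref=0.5, kd=0.85)
    assert cal.day_adjust_ratio(1.1, ref, ref2) == pytest.approx(2.2, rel=1e-12)


def test_day_adjust_against_exact_rational_arithmetic():
    """Term-by-term evaluation with exact fractions as the oracle."""
    kd, ca1, ca2 = Fraction(85, 100), Fraction(1, 2), Fraction(1, 4)
    r1, r2, rm = Fraction(14, 10), Fraction(13, 10), Fraction(11, 10)
    expected = rm * (r1 / r2) * ((1 / kd + 1 / ca1) / (1 / kd + 1 / ca2))
    got = cal.day_adjust_ratio(
        float(rm),
        cal.DayReference(float(r1), float(ca1), float(kd)),
        cal.DayReference(float(r2), float(ca2), float(kd)))
    assert got == pytest.approx(float(expected), rel=1e-12)


def test_day_adjust_rejects_nonpositive_reference():
    with pytest.raises(ValueError):
        cal.DayReference(ratio_ref=0.0, ca_ref=0.5)


# ---------------------------------------------------------------------------
# uncertainty propagation
# ---------------------------------------------------------------------------

def test_uncertainty_asymmetry():
    # near R0 the response is linear: interval nearly symmetric
    lin = cal.propagate_ratio_uncertainty(0.35, 0.02, CA)
    up = lin["high"] - lin["point"]
    down = lin["point"] - lin["low"]
    assert abs(up - down) / max(up, down) <= 0.05
    # near RM the spread is asymmetric toward high calcium
    sat = cal.propagate_ratio_uncertainty(1.85, 0.05, CA)
    assert sat["high"] - sat["point"] > sat["point"] - sat["low"]
    # degenerate interval
    z = cal.propagate_ratio_uncertainty(1.0, 0.0, CA)
    assert z["low"] == z["point"] == z["high"]
    # one-sided when the upper bound reaches saturation
    one = cal.propagate_ratio_uncertainty(1.98, 0.05, CA)
    assert one["one_sided"] and np.isinf(one["high"])
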