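"""Photocycle model: closed forms, conservation, steady states, calibration."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from lexykit.photocycle import (CalibrationError, DomainError, LightProtocol,
                                LightSegment, ParameterError, PhotocycleParams,
                                StateTrace, calibrate_rate, dark_initial_state,
                                lit_initial_state, observable_half_time, simulate,
                                steady_state)
from lexykit.presets import (INDUCTION_HALF_TIME_MIN, LIVE_PRESETS, live_preset,
                             recovery_half_time)

rates = st.floats(min_value=0.01, max_value=5.0, allow_nan=False)


def test_no_driving_term_stays_dark():
    """With no light and no thermal unfolding, u stays 0 and the N/C ratio
    holds at the dark balance k_imp/k_exp0."""
    p = PhotocycleParams(k_act=10.0, k_unf=0.0, k_rec=1.0, k_exp0=0.25,
                        k_exp_lit=1.0, k_imp=0.5)
    ratio0 = p.k_imp / p.k_exp0
    n0 = ratio0 / (1 + ratio0)
    tr = simulate(p, LightProtocol.constant(0.0, 10.0), np.linspace(0, 10, 51),
                  initial=(0.0, n0, 1 - n0))
    assert np.all(tr.u == 0.0) or np.allclose(tr.u, 0.0, atol=1e-12)
    assert np.allclose(tr.ratio, ratio0, rtol=1e-9)


def test_closed_form_lit_state_decay():
    """With activation off, u(t) = exp(-k_rec t); u at ln2/k_rec is 1/2."""
    p = PhotocycleParams(k_act=0.0, k_unf=0.0, k_rec=0.8, k_exp0=0.2,
                        k_exp_lit=1.0, k_imp=0.5)
    t_half = math.log(2) / p.k_rec
    t = np.linspace(0, 5 * t_half, 101)
    tr = simulate(p, LightProtocol.constant(0.0, t[-1]), t, initial=(1.0, 0.5, 0.5))
    assert np.allclose(tr.u, np.exp(-p.k_rec * t), atol=1e-9)
    tr_mid = simulate(p, LightProtocol.constant(0.0, t_half), [t_half],
                      initial=(1.0, 0.5, 0.5))
    assert tr_mid.u[0] == pytest.approx(0.5, abs=1e-9)


@given(k_act=rates, k_rec=rates, k_exp0=rates, k_exp_lit=rates, k_imp=rates)
def test_mass_conservation(k_act, k_rec, k_exp0, k_exp_lit, k_imp):
    """N + C is conserved over any step protocol for arbitrary rate draws."""
    p = PhotocycleParams(k_act=k_act, k_unf=0.001, k_rec=k_rec, k_exp0=k_exp0,
                        k_exp_lit=k_exp_lit, k_imp=k_imp)
    proto = LightProtocol.step(t_on=1.0, duration=6.0, intensity=1.0)
    tr = simulate(p, proto, np.linspace(0, 6.0, 61))
    total0 = tr.N[0] + tr.C[0]
    assert np.max(np.abs(tr.N + tr.C - total0)) / total0 < 1e-8


def test_monotone_depletion_under_step_on():
    """Step-on light from the dark steady state only moves reporter out of
    the nucleus: N non-increasing, C non-decreasing."""
    p = live_preset("live-iLEXYs")
    tr = simulate(p, LightProtocol.constant(1.0, 10.0), np.linspace(0, 10, 401))
    assert np.all(np.diff(tr.N) <= 1e-12)
    assert np.all(np.diff(tr.C) >= -1e-12)


def test_steady_state_symmetry_and_dark_limit():
    p = PhotocycleParams(k_act=5.0, k_unf=0.0, k_rec=1.0, k_exp0=0.5,
                        k_exp_lit=0.0, k_imp=0.5)
    u, ratio = steady_state(p, 0.7)
    assert ratio == pytest.approx(1.0)
    u0, _ = steady_state(p, 0.0)
    assert u0 == 0.0


def test_long_run_reaches_steady_state():
    """Simulating 100x the slowest timescale lands on the closed-form
    steady state within 1e-4 relative."""
    p = PhotocycleParams(k_act=10.0, k_unf=0.001, k_rec=0.5, k_exp0=0.2,
                        k_exp_lit=0.8, k_imp=0.5)
    slowest = 1.0 / min(p.k_rec, p.k_imp, p.k_exp0)
    t_end = 100.0 * slowest
    tr = simulate(p, LightProtocol.constant(1.0, t_end), [t_end])
    u_star, r_star = steady_state(p, 1.0)
    assert tr.u[-1] == pytest.approx(u_star, rel=1e-4)
    assert tr.ratio[-1] == pytest.approx(r_star, rel=1e-4)


def test_duty_cycle_averaging_matches_resolved_pulses():
    """LED-style pulsing (2 s on / 1 s off) averaged to I*duty agrees with the
    exact pulse-resolved integration: pulse period << photocycle timescales."""
    p = live_preset("live-iLEXYi")
    proto = LightProtocol.led_box(duration=5.0)
    t = np.linspace(0, 5.0, 51)
    tr_avg = simulate(p, proto, t)
    tr_exact = simulate(p, proto, t, resolve_pulses=True)
    assert np.allclose(tr_avg.ratio, tr_exact.ratio, rtol=0.02)


def test_calibrate_rate_single_compartment_closed_form():
    """Pure export limit (import ~ 0, u pinned at 1): nuclear amount decays as
    exp(-k t), so the calibrated rate is exactly ln2/target."""
    p = PhotocycleParams(k_act=1e6, k_unf=0.0, k_rec=0.0, k_exp0=0.0,
                        k_exp_lit=1.0, k_imp=1e-12)
    target = 2.0
    k = calibrate_rate(p, "k_exp_lit", target, phase="induction",
                       observable="nuclear", initial=(1.0, 0.9, 0.1))
    assert k == pytest.approx(math.log(2) / target, rel=1e-4)


def test_calibrated_recovery_rate_monotone_in_target():
    """A 5-min recovery target needs strictly faster dark reversion than a
    50-min target."""
    p = live_preset("live-iLEXYs")
    k_fast = calibrate_rate(p, "k_rec", 5.0, phase="recovery")
    k_slow = calibrate_rate(p, "k_rec", 50.0, phase="recovery")
    assert k_fast > k_slow


@pytest.mark.parametrize("name", sorted(LIVE_PRESETS))
def test_preset_recovery_self_consistency(name):
    """Re-simulating each calibrated preset reproduces its recovery ratio
    half-time to 0.1%."""
    t = observable_half_time(live_preset(name), "recovery")
    assert t == pytest.approx(recovery_half_time(name), rel=1e-3)


@pytest.mark.parametrize("name", ["live-iLEXYi", "live-iLEXYs"])
def test_preset_induction_self_consistency(name):
    """Slow-cycling presets reproduce the 25-s induction ratio half-time to
    0.1% (the fast-cycling original trades induction for its recovery target)."""
    t = observable_half_time(live_preset(name), "induction")
    assert t == pytest.approx(INDUCTION_HALF_TIME_MIN, rel=1e-3)


def test_parameter_and_domain_errors():
    with pytest.raises(ParameterError):
        PhotocycleParams(k_rec=-1.0)
    with pytest.raises(ParameterError):
        PhotocycleParams(k_imp=0.0)
    with pytest.raises(ParameterError):
        PhotocycleParams(k_exp0=0.0, k_exp_lit=0.0)
    with pytest.raises(DomainError):
        LightSegment(0.0, 1.0, intensity=1.5)
    with pytest.raises(DomainError):
        LightProtocol((LightSegment(0.0, 1.0, 0.5), LightSegment(2.0, 3.0, 0.5)))
    p = PhotocycleParams()
    with pytest.raises(DomainError):
        simulate(p, LightProtocol.constant(1.0, 2.0), [0.0, 3.0])


def test_protocol_and_params_roundtrip():
    proto = LightProtocol.led_box(10.0)
    assert LightProtocol.from_dict(proto.to_dict()) == proto
    p = live_preset("live-iLEXYi")
    assert PhotocycleParams.from_dict(p.to_dict()) == p


def test_trace_frame_columns(constant_trace):
    df = constant_trace.to_frame()
    assert list(df.columns) == ["time_min", "u", "N", "C", "ratio"]
    assert np.allclose(df["ratio"], 3.0)
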