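"""Deterministic kinetic model of a LOV2-gated nuclear-export reporter.

A LEXY-type construct couples a blue-light-sensitive *As*LOV2 domain to a
nuclear export sequence (NES) buried in the domain's C-terminal Jα helix.
Blue light unwinds the helix, exposes the NES, and the CRM1 machinery exports
the fused cargo from the nucleus; in the dark the helix refolds and import
restores the nuclear pool.  Slow-cycling LOV2 point mutants (the iLEXY
variants) lengthen the dark-reversion time and thereby both the recovery
half-time and the depletion efficiency.

The model has two coupled pieces:

* the lit-state fraction ``u`` of the photoswitch population::

      du/dt = (k_act * I_eff(t) + k_unf) * (1 - u) - k_rec * u

  where ``I_eff`` is the duty-cycle-averaged blue-light intensity of the
  active protocol segment, ``k_act`` the activation rate at full intensity,
  ``k_unf`` the thermal (dark) unfolding rate responsible for dark-state
  activity, and ``k_rec`` the dark reversion rate of the lit state;

* nucleocytoplasmic transport of the cargo amounts ``N`` and ``C``::

      dN/dt = k_imp * C - (k_exp0 + k_exp_lit * u) * N,   dC/dt = -dN/dt

  with basal export ``k_exp0``, light-gated export ``k_exp_lit * u`` and
  import ``k_imp``.  No synthesis or degradation is modelled, so ``N + C``
  is conserved; the integrator exploits this by evolving only ``(u, N)``
  and reconstructing ``C`` from the conserved total.

All rates are per minute and all times are minutes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

__all__ = [
    "ParameterError",
    "DomainError",
    "CalibrationError",
    "PhotocycleParams",
    "LightSegment",
    "LightProtocol",
    "StateTrace",
    "simulate",
    "steady_state",
    "dark_initial_state",
    "lit_initial_state",
    "observable_half_time",
    "calibrate_rate",
]

RATE_FIELDS = ("k_act", "k_unf", "k_rec", "k_exp0", "k_exp_lit", "k_imp")


class ParameterError(ValueError):
    """Invalid photocycle rate constants."""


class DomainError(ValueError):
    """Evaluation requested outside the valid domain (time grid, fraction...)."""


class CalibrationError(RuntimeError):
    """Rate calibration could not bracket or reach the requested half-time."""


@dataclass(frozen=True)
class PhotocycleParams:
    """Rate constants of the light-switchable export system (1/min).

    Attributes
    ----------
    k_act : activation rate at full light intensity.
    k_unf : thermal (dark) unfolding rate; sets the dark-state activity.
    k_rec : dark reversion rate of the lit state; slow-cycling variants
        have a small ``k_rec``.
    k_exp0 : basal nuclear export rate.
    k_exp_lit : additional export rate at fully lit state (u = 1).
    k_imp : nuclear import rate.
    """

    k_act: float = 30.0
    k_unf: float = 0.001
    k_rec: float = 2.0
    k_exp0: float = 0.5 / 3.0
    k_exp_lit: float = 1.0
    k_imp: float = 0.5

    def __post_init__(self) -> None:
        for name in RATE_FIELDS:
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise ParameterError(f"{name} must be a finite non-negative rate, got {value!r}")
        if self.k_imp <= 0:
            raise ParameterError("k_imp must be positive")
        if self.k_exp0 + self.k_exp_lit <= 0:
            raise ParameterError("k_exp0 + k_exp_lit must be positive")

    def replace(self, **kwargs: float) -> "PhotocycleParams":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {name: float(getattr(self, name)) for name in RATE_FIELDS}

    @classmethod
    def from_dict(cls, data: dict) -> "PhotocycleParams":
        unknown = set(data) - set(RATE_FIELDS)
        if unknown:
            raise ParameterError(f"unknown rate fields: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in data.items()})


@dataclass(frozen=True)
class LightSegment:
    """One piece of a piecewise illumination protocol.

    ``intensity`` is the relative blue-light intensity in [0, 1]; pulsed
    segments carry a pulse period (seconds) and an on-duty fraction.  By
    default pulses are averaged to an effective intensity ``intensity*duty``
    (pulse periods of a few seconds are far below photocycle timescales);
    the integrator can optionally resolve them exactly.
    """

    t_start: float
    t_end: float
    intensity: float
    pulse_period_s: float | None = None
    duty: float = 1.0

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise DomainError("segment must have positive duration")
        if not 0.0 <= self.intensity <= 1.0:
            raise DomainError(f"intensity must be in [0, 1], got {self.intensity}")
        if not 0.0 <= self.duty <= 1.0:
            raise DomainError(f"duty must be in [0, 1], got {self.duty}")
        if self.pulse_period_s is not None and self.pulse_period_s <= 0:
            raise DomainError("pulse period must be positive")

    @property
    def effective_intensity(self) -> float:
        return self.intensity * self.duty


@dataclass(frozen=True)
class LightProtocol:
    """Ordered, contiguous illumination segments covering [0, duration]."""

    segments: tuple[LightSegment, ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise DomainError("protocol needs at least one segment")
        if abs(self.segments[0].t_start) > 1e-12:
            raise DomainError("protocol must start at t = 0")
        for a, b in zip(self.segments, self.segments[1:]):
            if abs(a.t_end - b.t_start) > 1e-9:
                raise DomainError("segments must be contiguous and ordered")

    @property
    def duration(self) -> float:
        return self.segments[-1].t_end

    @classmethod
    def constant(cls, intensity: float, duration: float,
                 pulse_period_s: float | None = None, duty: float = 1.0) -> "LightProtocol":
        return cls((LightSegment(0.0, duration, intensity, pulse_period_s, duty),))

    @classmethod
    def step(cls, t_on: float, duration: float, intensity: float = 1.0,
             **kwargs) -> "LightProtocol":
        """Dark until ``t_on``, then constant light until ``duration``."""
        if t_on <= 0:
            return cls.constant(intensity, duration, **kwargs)
        return cls((LightSegment(0.0, t_on, 0.0),
                    LightSegment(t_on, duration, intensity, **kwargs)))

    @classmethod
    def led_box(cls, duration: float, intensity: float = 0.7,
                pulse_on_s: float = 2.0, pulse_off_s: float = 1.0) -> "LightProtocol":
        """Bulk LED illumination: pulsed blue light (default 2 s on / 1 s off, 70%)."""
        period = pulse_on_s + pulse_off_s
        return cls.constant(intensity, duration, pulse_period_s=period,
                            duty=pulse_on_s / period)

    def intensity_at(self, t: float, resolve_pulses: bool = False) -> float:
        seg = self._segment_at(t)
        if not resolve_pulses or seg.pulse_period_s is None or seg.duty >= 1.0:
            return seg.effective_intensity
        period = seg.pulse_period_s / 60.0
        phase = ((t - seg.t_start) % period) / period
        return seg.intensity if phase < seg.duty else 0.0

    def _segment_at(self, t: float) -> LightSegment:
        if t < -1e-9 or t > self.duration + 1e-9:
            raise DomainError(f"time {t} outside protocol [0, {self.duration}]")
        for seg in self.segments:
            if t <= seg.t_end + 1e-12:
                return seg
        return self.segments[-1]

    def to_dict(self) -> dict:
        return {"segments": [
            {"t_start": s.t_start, "t_end": s.t_end, "intensity": s.intensity,
             "pulse_period_s": s.pulse_period_s, "duty": s.duty}
            for s in self.segments]}

    @classmethod
    def from_dict(cls, data: dict) -> "LightProtocol":
        return cls(tuple(LightSegment(**seg) for seg in data["segments"]))


@dataclass(frozen=True)
class StateTrace:
    """Dense model trajectory: lit fraction and compartment amounts over time."""

    times: np.ndarray
    u: np.ndarray
    N: np.ndarray
    C: np.ndarray

    @property
    def ratio(self) -> np.ndarray:
        """Nuclear/cytoplasmic amount ratio N(t)/C(t)."""
        return self.N / self.C

    @property
    def total(self) -> float:
        return float(self.N[0] + self.C[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_min": self.times, "u": self.u,
                             "N": self.N, "C": self.C, "ratio": self.ratio})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def steady_state(params: PhotocycleParams, intensity: float) -> tuple[float, float]:
    """Closed-form steady state (u*, N/C ratio*) under constant light.

    u* = (k_act I + k_unf) / (k_act I + k_unf + k_rec) and
    ratio* = k_imp / (k_exp0 + k_exp_lit u*).
    """
    drive = params.k_act * intensity + params.k_unf
    denom_u = drive + params.k_rec
    if denom_u <= 0:
        raise ParameterError("lit-state fraction undefined: k_act*I + k_unf + k_rec = 0")
    u_star = drive / denom_u
    denom_r = params.k_exp0 + params.k_exp_lit * u_star
    if denom_r <= 0:
        raise ParameterError("export rate is zero at steady state; N/C ratio diverges")
    return u_star, params.k_imp / denom_r


def dark_initial_state(params: PhotocycleParams, total: float = 1.0) -> tuple[float, float, float]:
    """(u0, N0, C0) at the dark steady state with total amount ``total``."""
    u0, r0 = steady_state(params, 0.0)
    n0 = total * r0 / (1.0 + r0)
    return u0, n0, total - n0


def lit_initial_state(params: PhotocycleParams, intensity: float = 1.0,
                      total: float = 1.0) -> tuple[float, float, float]:
    """(u0, N0, C0) at the lit steady state under constant ``intensity``."""
    u0, r0 = steady_state(params, intensity)
    n0 = total * r0 / (1.0 + r0)
    return u0, n0, total - n0


def _rhs(params: PhotocycleParams, intensity: float, total: float):
    k_on = params.k_act * intensity + params.k_unf

    def rhs(t, y):
        u, n = y
        du = k_on * (1.0 - u) - params.k_rec * u
        dn = params.k_imp * (total - n) - (params.k_exp0 + params.k_exp_lit * u) * n
        return (du, dn)

    return rhs


def _pieces(protocol: LightProtocol, resolve_pulses: bool) -> list[tuple[float, float, float]]:
    """Flatten the protocol to (t0, t1, I_eff) pieces of constant intensity."""
    pieces: list[tuple[float, float, float]] = []
    for seg in protocol.segments:
        if resolve_pulses and seg.pulse_period_s is not None and 0.0 < seg.duty < 1.0:
            period = seg.pulse_period_s / 60.0
            t = seg.t_start
            while t < seg.t_end - 1e-12:
                t_on_end = min(t + seg.duty * period, seg.t_end)
                pieces.append((t, t_on_end, seg.intensity))
                if t_on_end < seg.t_end - 1e-12:
                    t_off_end = min(t + period, seg.t_end)
                    pieces.append((t_on_end, t_off_end, 0.0))
                t += period
        else:
            pieces.append((seg.t_start, seg.t_end, seg.effective_intensity))
    return pieces


def simulate(params: PhotocycleParams, protocol: LightProtocol,
             times: Sequence[float], initial: tuple[float, float, float] | None = None,
             resolve_pulses: bool = False, rtol: float = 1e-10,
             atol: float = 1e-12) -> StateTrace:
    """Integrate the photocycle + transport model over a light protocol.

    Parameters
    ----------
    times : increasing time grid (min) within ``[0, protocol.duration]``.
    initial : optional ``(u0, N0, C0)``; defaults to the dark steady state
        with unit total amount.
    resolve_pulses : integrate pulsed segments at pulse resolution instead of
        duty-cycle averaging (validation mode).

    Notes
    -----
    Only ``(u, N)`` are integrated; ``C = total - N`` by construction, so the
    conserved total is exact to floating point.
    """
    t_eval = np.atleast_1d(np.asarray(times, dtype=float))
    if t_eval.ndim != 1 or np.any(np.diff(t_eval) < 0):
        raise DomainError("time grid must be one-dimensional and non-decreasing")
    if t_eval[0] < -1e-9 or t_eval[-1] > protocol.duration + 1e-9:
        raise DomainError(
            f"time grid [{t_eval[0]}, {t_eval[-1]}] outside protocol "
            f"[0, {protocol.duration}]")

    if initial is None:
        u0, n0, c0 = dark_initial_state(params)
    else:
        u0, n0, c0 = (float(v) for v in initial)
        if not 0.0 <= u0 <= 1.0:
            raise DomainError("initial lit fraction must be in [0, 1]")
        if n0 < 0 or c0 < 0:
            raise DomainError("initial amounts must be non-negative")
    total = n0 + c0

    u_out = np.empty_like(t_eval)
    n_out = np.empty_like(t_eval)
    y = np.array([u0, n0])
    # exact-grid hits: times exactly at 0 are filled from the initial state
    for t0, t1, inten in _pieces(protocol, resolve_pulses):
        mask = (t_eval >= t0 - 1e-12) & (t_eval <= t1 + 1e-12)
        pts = np.clip(t_eval[mask], t0, t1)
        sol = solve_ivp(_rhs(params, inten, total), (t0, t1), y,
                        method="LSODA", t_eval=pts if pts.size else None,
                        dense_output=not pts.size, rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(f"integration failed on [{t0}, {t1}]: {sol.message}")
        if pts.size:
            u_out[mask] = sol.y[0]
            n_out[mask] = sol.y[1]
        y = sol.y[:, -1] if sol.y.shape[1] else y
        if sol.t[-1] < t1 - 1e-12:  # t_eval did not include the piece end
            sol_end = solve_ivp(_rhs(params, inten, total), (sol.t[-1], t1), y,
                                method="LSODA", rtol=rtol, atol=atol)
            y = sol_end.y[:, -1]

    u_out = np.clip(u_out, 0.0, 1.0)
    n_out = np.clip(n_out, 0.0, total)
    return StateTrace(times=t_eval, u=u_out, N=n_out, C=total - n_out)


def _dense_constant(params: PhotocycleParams, intensity: float,
                    initial: tuple[float, float, float], t_max: float):
    """Dense solution of the constant-light model for root finding."""
    u0, n0, c0 = initial
    total = n0 + c0
    sol = solve_ivp(_rhs(params, intensity, total), (0.0, t_max),
                    [u0, n0], method="LSODA", dense_output=True,
                    rtol=1e-11, atol=1e-13)
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    return sol, total


def observable_half_time(params: PhotocycleParams, phase: str,
                         intensity: float = 1.0,
                         observable: str = "ratio",
                         initial: tuple[float, float, float] | None = None) -> float:
    """Midpoint-crossing time of the noise-free observable under a step protocol.

    ``phase="induction"`` steps light on (from the dark steady state) and
    ``phase="recovery"`` steps light off (from the lit steady state).  The
    half-time is when the observable crosses the midpoint between its initial
    value and the closed-form asymptote; for a single exponential this equals
    ln2/k.  ``observable`` is the N/C amount ratio (default) or the nuclear
    amount ``N``.
    """
    if phase == "induction":
        i_final = intensity
        if initial is None:
            initial = dark_initial_state(params)
    elif phase == "recovery":
        i_final = 0.0
        if initial is None:
            initial = lit_initial_state(params, intensity)
    else:
        raise ValueError(f"phase must be 'induction' or 'recovery', got {phase!r}")

    total = initial[1] + initial[2]
    _, r_inf = steady_state(params, i_final)
    if observable == "ratio":
        y0 = initial[1] / initial[2]
        y_inf = r_inf

        def value(sol, t):
            n = sol.sol(t)[1]
            return n / (total - n)
    elif observable == "nuclear":
        y0 = initial[1]
        y_inf = total * r_inf / (1.0 + r_inf)

        def value(sol, t):
            return sol.sol(t)[1]
    else:
        raise ValueError(f"unknown observable {observable!r}")

    if abs(y0 - y_inf) <= 1e-12 * max(abs(y0), abs(y_inf), 1.0):
        raise CalibrationError("observable has no dynamic range between the endpoints")
    mid = 0.5 * (y0 + y_inf)

    t_max = 1.0
    for _ in range(60):
        sol, _tot = _dense_constant(params, i_final, initial, t_max)
        g = lambda t: value(sol, t) - mid
        if g(0.0) * g(t_max) < 0:
            return float(brentq(g, 0.0, t_max, xtol=1e-12, rtol=8.9e-16))
        t_max *= 4.0
    raise CalibrationError("observable never crossed the midpoint (non-monotone or flat)")


def calibrate_rate(params: PhotocycleParams, free_rate: str,
                   target_half_time: float, phase: str,
                   intensity: float = 1.0, observable: str = "ratio",
                   initial: tuple[float, float, float] | None = None,
                   rtol: float = 1e-6) -> float:
    """Solve for the rate constant giving a target observable half-time.

    The experiments report observable half-times (the time for the noise-free
    N/C ratio to traverse half of its excursion under a step-on or step-off
    protocol) rather than rate constants; this routine inverts the model by
    bracketing plus Brent root finding on the chosen free rate, assuming the
    half-time is monotone in that rate over the bracket.
    """
    if target_half_time <= 0:
        raise DomainError("target half-time must be positive")
    if free_rate not in RATE_FIELDS:
        raise ValueError(f"free_rate must be one of {RATE_FIELDS}")

    def f(k: float) -> float:
        p = params.replace(**{free_rate: k})
        return observable_half_time(p, phase, intensity, observable,
                                    initial=initial) - target_half_time

    k0 = math.log(2.0) / target_half_time
    f0 = f(k0)
    if f0 == 0.0:
        return k0
    lo, hi = k0, k0
    f_lo = f_hi = f0
    for _ in range(60):
        if f_lo * f_hi < 0:
            break
        if f0 > 0:  # half-time too long: need a faster rate
            hi *= 3.0
            f_hi = f(hi)
        else:
            lo /= 3.0
            f_lo = f(lo)
    else:
        raise CalibrationError(
            f"could not bracket target half-time {target_half_time} min for "
            f"{free_rate}: f({lo})={f_lo:.4g}, f({hi})={f_hi:.4g}")
    return float(brentq(f, lo, hi, rtol=rtol, xtol=1e-12))
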