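"""The three control laws: threshold (bang-bang), timed-activation, and PID.

Threshold control (TC) is plain bang-bang switching on a single threshold at
``setpoint - hysteresis``: below it the solenoid opens, at or above it the
solenoid closes.  With a laggy sensor this overshoots badly.

Timed-activation control (TAC) — the strategy the device actually ships —
replaces continuous switching with fixed-duration valve pulses: a short
pulse (``open_short_s``) when the reading is moderately below the setpoint,
a long pulse (``open_long_s``) when it is far below, and after every pulse a
mandatory lockout (default 60 s) so the slow sensor can register the change
before any further action.  The chamber cannot be vented, so readings at or
above the setpoint produce no action.

Discrete PID computes ``u = kp*e + ki*sum(e*dt) + kd*de/dt`` on the error
``e = setpoint - measurement``, with integral clamping for anti-windup, and
maps ``u`` through a proportional-valve current characteristic: flow starts
at 160 mA and grows linearly to full flow at 330 mA.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Tuple

from pydantic import BaseModel, ConfigDict, model_validator

SETPOINT_MIN_PPM = 10_000.0
SETPOINT_MAX_PPM = 60_000.0


def _hysteresis_ppm(setpoint_ppm: float, hysteresis_pct: float) -> float:
    return setpoint_ppm * hysteresis_pct / 100.0


class TcConfig(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    setpoint_ppm: float = 50_000.0
    hysteresis_pct: float = 0.5

    @model_validator(mode="after")
    def _check(self) -> "TcConfig":
        if not (SETPOINT_MIN_PPM <= self.setpoint_ppm <= SETPOINT_MAX_PPM):
            raise ValueError("setpoint_ppm must be within 10,000-60,000 ppm (1-6%)")
        if self.hysteresis_pct <= 0:
            raise ValueError("hysteresis_pct must be positive")
        return self

    @property
    def hysteresis_ppm(self) -> float:
        return _hysteresis_ppm(self.setpoint_ppm, self.hysteresis_pct)


class TacConfig(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    setpoint_ppm: float = 50_000.0
    hysteresis_pct: float = 0.5
    open_short_s: float = 2.0
    open_long_s: float = 6.0
    post_response_wait_s: float = 60.0
    long_boundary_ppm: Optional[float] = None  # default: 4 x hysteresis_ppm

    @model_validator(mode="after")
    def _check(self) -> "TacConfig":
        if not (SETPOINT_MIN_PPM <= self.setpoint_ppm <= SETPOINT_MAX_PPM):
            raise ValueError("setpoint_ppm must be within 10,000-60,000 ppm (1-6%)")
        if self.hysteresis_pct <= 0:
            raise ValueError("hysteresis_pct must be positive")
        if not (0 < self.open_short_s <= self.open_long_s):
            raise ValueError("require 0 < open_short_s <= open_long_s")
        if self.post_response_wait_s < 60.0:
            raise ValueError("post_response_wait_s must be >= 60 s")
        if self.long_boundary_ppm is not None and (
            self.long_boundary_ppm <= self.hysteresis_ppm
        ):
            raise ValueError("long_boundary_ppm must exceed the hysteresis band")
        return self

    @property
    def hysteresis_ppm(self) -> float:
        return _hysteresis_ppm(self.setpoint_ppm, self.hysteresis_pct)

    @property
    def effective_long_boundary_ppm(self) -> float:
        if self.long_boundary_ppm is not None:
            return self.long_boundary_ppm
        return 4.0 * self.hysteresis_ppm


@dataclass(frozen=True)
class TacSchedulerState:
    """Tracks when the last valve pulse ended and when the valve closes."""

    last_response_end_s: float = -1e18
    valve_open_until_s: float = -1e18


class PidConfig(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    kp: float = 20.0
    ki: float = 0.6
    kd: float = 5.0
    dt_s: float = 1.0
    integral_limit: Optional[float] = None  # default from valve full-scale
    output_to_mA: float = 0.01

    @model_validator(mode="after")
    def _check(self) -> "PidConfig":
        if self.dt_s <= 0:
            raise ValueError("dt_s must be positive")
        if self.integral_limit is not None and self.integral_limit <= 0:
            raise ValueError("integral_limit must be positive")
        return self

    def effective_integral_limit(self, valve: "ProportionalValveParams") -> float:
        """Clamp such that the ki-weighted integral alone can reach full-scale
        valve current, and no further (anti-windup)."""
        if self.integral_limit is not None:
            return self.integral_limit
        if self.ki == 0.0 or self.output_to_mA == 0.0:
            return float("inf")
        return valve.full_open_mA / self.output_to_mA / abs(self.ki)


@dataclass(frozen=True)
class PidState:
    integral_accum: float = 0.0
    prev_error: Optional[float] = None  # None until first step (no derivative kick)


class ProportionalValveParams(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    open_onset_mA: float = 160.0
    full_open_mA: float = 330.0

    @model_validator(mode="after")
    def _check(self) -> "ProportionalValveParams":
        if not self.open_onset_mA < self.full_open_mA:
            raise ValueError("open_onset_mA must be < full_open_mA")
        return self


def tc_decide(reading_ppm: float, config: TcConfig) -> bool:
    """Bang-bang decision: True = open. Opens strictly below the threshold
    ``setpoint - hysteresis``; a reading at the threshold closes (ties close)."""
    return reading_ppm < config.setpoint_ppm - config.hysteresis_ppm


def tac_decide(
    reading_ppm: float,
    config: TacConfig,
    sched: TacSchedulerState,
    now_s: float,
) -> Tuple[Optional[float], TacSchedulerState]:
    """Timed-activation decision at an accepted reading.

    Returns ``(duration_s or None, new_scheduler_state)``.  No action within
    the post-response lockout, inside the hysteresis band, or at/above the
    setpoint (no exhaust exists, so overshoot cannot be corrected).  The
    pulse duration is ``open_short_s`` for moderate deficits and
    ``open_long_s`` beyond ``long_boundary_ppm``.
    """
    if now_s < sched.last_response_end_s + config.post_response_wait_s:
        return None, sched
    deviation = config.setpoint_ppm - reading_ppm
    if deviation <= config.hysteresis_ppm:
        return None, sched
    duration = (
        config.open_long_s
        if deviation > config.effective_long_boundary_ppm
        else config.open_short_s
    )
    new_sched = TacSchedulerState(
        last_response_end_s=now_s + duration,
        valve_open_until_s=now_s + duration,
    )
    return duration, new_sched


def pid_step(
    setpoint_ppm: float,
    reading_ppm: float,
    state: PidState,
    config: PidConfig,
    valve: Optional[ProportionalValveParams] = None,
) -> Tuple[float, PidState]:
    """One discrete PID update; returns ``(u, new_state)``.

    e = setpoint - reading; the integral accumulates e*dt and is clamped to
    the anti-windup limit; the derivative is the backward difference of e
    (zero on the very first step).
    """
    valve = valve if valve is not None else ProportionalValveParams()
    e = setpoint_ppm - reading_ppm
    limit = config.effective_integral_limit(valve)
    integral = state.integral_accum + e * config.dt_s
    integral = min(max(integral, -limit), limit)
    prev = state.prev_error if state.prev_error is not None else e
    derivative = (e - prev) / config.dt_s
    u = config.kp * e + config.ki * integral + config.kd * derivative
    return u, PidState(integral_accum=integral, prev_error=e)


def control_to_valve_fraction(
    u: float,
    valve: ProportionalValveParams,
    config: PidConfig,
) -> float:
    """Map the PID control signal to a proportional-valve open fraction.

    The commanded coil current is ``u * output_to_mA`` clamped to
    [0, full_open_mA]; flow is zero up to the opening-onset current and
    grows linearly to 1.0 at the full-open current.
    """
    current_mA = min(max(u * config.output_to_mA, 0.0), valve.full_open_mA)
    span = valve.full_open_mA - valve.open_onset_mA
    fraction = (current_mA - valve.open_onset_mA) / span
    return min(max(fraction, 0.0), 1.0)
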