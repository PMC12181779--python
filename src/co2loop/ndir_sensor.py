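"""NDIR CO2 sensor model: first-order lag, range clipping, bias, noise.

Models the two sensors of the device: the chamber sensor (MH-Z16 class,
0-100,000 ppm, T90 < 30 s, 6% accuracy, minimum 1020 ms between reads) and
the optional environment sensor (MH-Z19E class, 400-5000 ppm).  The sensed
value relaxes toward the true concentration as a first-order system with
time constant ``tau = t90 / ln(10)``; reads on top of that apply a constant
multiplicative calibration bias, optional Gaussian noise, range clipping and
integer rounding (the serial protocol reports whole ppm).

A ``stuck`` fault freezes the *reported* value while the internal lag state
keeps tracking the chamber — mimicking a sensor whose output register has
frozen, which the firmware's safety logic must detect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

LN10 = math.log(10.0)


class NdirSensorParams(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    range_min_ppm: float = 0.0
    range_max_ppm: float = 100_000.0
    t90_s: float = 30.0
    bias_fraction: float = 0.0
    noise_sd_ppm: float = 0.0
    min_read_interval_ms: float = 1020.0

    @model_validator(mode="after")
    def _check(self) -> "NdirSensorParams":
        if not self.range_min_ppm < self.range_max_ppm:
            raise ValueError("range_min_ppm must be < range_max_ppm")
        if self.t90_s < 0:
            raise ValueError("t90_s must be >= 0")
        if self.min_read_interval_ms < 0:
            raise ValueError("min_read_interval_ms must be >= 0")
        if self.noise_sd_ppm < 0:
            raise ValueError("noise_sd_ppm must be >= 0")
        return self

    @property
    def tau_s(self) -> float:
        """First-order time constant; T90 = tau * ln(10)."""
        return self.t90_s / LN10


def environment_sensor_params(**overrides) -> NdirSensorParams:
    """Defaults for the room-monitoring sensor (400-5000 ppm, slower lag)."""
    base = dict(
        range_min_ppm=400.0,
        range_max_ppm=5000.0,
        t90_s=60.0,
        bias_fraction=0.0,
        noise_sd_ppm=0.0,
        min_read_interval_ms=1020.0,
    )
    base.update(overrides)
    return NdirSensorParams(**base)


@dataclass(frozen=True)
class SensorState:
    """Internal lagged concentration plus read-timing and fault state."""

    lagged_ppm: float
    last_read_ms: float = -math.inf
    stuck_value_ppm: Optional[float] = None  # None = no fault

    @property
    def fault(self) -> str:
        return "none" if self.stuck_value_ppm is None else "stuck"


def sensor_lag_step(
    state: SensorState,
    true_ppm: float,
    dt: float,
    params: NdirSensorParams,
) -> SensorState:
    """Relax the lagged concentration toward ``true_ppm`` over ``dt`` seconds.

    Exact exponential update for the first-order lag; ``t90_s = 0`` means
    the sensor tracks the true concentration instantly.
    """
    if not (math.isfinite(dt) and dt > 0):
        raise ValueError(f"dt must be positive and finite, got {dt}")
    if not math.isfinite(true_ppm):
        raise ValueError("true_ppm must be finite")
    if params.t90_s == 0.0:
        new_lag = true_ppm
    else:
        decay = math.exp(-dt / params.tau_s)
        new_lag = true_ppm + (state.lagged_ppm - true_ppm) * decay
    return replace(state, lagged_ppm=new_lag)


def sensor_read(
    state: SensorState,
    now_ms: float,
    params: NdirSensorParams,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[Optional[float], SensorState]:
    """Attempt a read at wall time ``now_ms``.

    Returns ``(reading_ppm, new_state)``; the reading is ``None`` when the
    minimum inter-read interval has not yet elapsed (a refusal, not an
    error — the firmware simply tries again next loop).  Accepted readings
    are bias-scaled, noise-perturbed, clipped to the reporting range and
    rounded to whole ppm.  A stuck sensor returns its frozen value but the
    read still counts against the interval clock.
    """
    if now_ms - state.last_read_ms < params.min_read_interval_ms:
        return None, state
    if state.stuck_value_ppm is not None:
        return state.stuck_value_ppm, replace(state, last_read_ms=now_ms)
    value = state.lagged_ppm * (1.0 + params.bias_fraction)
    if params.noise_sd_ppm > 0.0:
        if rng is None:
            raise ValueError("rng required when noise_sd_ppm > 0")
        value += rng.normal(0.0, params.noise_sd_ppm)
    value = min(max(value, params.range_min_ppm), params.range_max_ppm)
    value = math.floor(value + 0.5)  # half-up to whole ppm
    return float(value), replace(state, last_read_ms=now_ms)


def inject_fault(
    state: SensorState,
    fault: str,
    value_ppm: Optional[float] = None,
) -> SensorState:
    """Set the sensor fault mode: ``"none"`` or ``"stuck"``.

    ``stuck`` freezes the reported value at ``value_ppm`` if given, else at
    the current lagged concentration (rounded, as a report would be).
    """
    if fault == "none":
        return replace(state, stuck_value_ppm=None)
    if fault == "stuck":
        frozen = value_ppm if value_ppm is not None else float(
            math.floor(state.lagged_ppm + 0.5)
        )
        return replace(state, stuck_value_ppm=frozen)
    raise ValueError(f"unknown fault mode {fault!r}")
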