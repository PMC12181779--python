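"""Well-mixed chamber CO2 mass balance.

The incubator is treated as a single well-mixed volume ``V`` receiving pure
CO2 at volumetric flow ``q * u`` (``u`` the valve-open fraction) and
exchanging air with the room at a first-order rate ``k_leak``.  The true
concentration ``C`` (ppm) then obeys the linear ODE

    dC/dt = (q*u/V) * (source_ppm - C) - k_leak * (C - ambient_ppm)

which, for ``u`` held constant over a step, has the closed-form solution
used by :func:`plant_step`.  The exact exponential update is unconditionally
stable and exactly composable, so the control loop may take steps of any
length without numerical drift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from pydantic import BaseModel, ConfigDict, model_validator

PURE_GAS_PPM = 1_000_000.0


class GasPlantParams(BaseModel):
    """Physical parameters of the chamber gas balance.

    volume_L
        Chamber volume in litres.
    injection_flow_Lps
        Volumetric flow of injected gas with the valve fully open, L/s.
    source_ppm
        CO2 fraction of the injected gas in ppm (pure CO2 = 1,000,000).
    leak_rate_per_s
        First-order air-exchange rate with the room, 1/s.
    ambient_ppm
        Room CO2 concentration in ppm.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    volume_L: float = 55.0
    injection_flow_Lps: float = 0.012
    source_ppm: float = PURE_GAS_PPM
    leak_rate_per_s: float = 5e-5
    ambient_ppm: float = 450.0
    uptake_ppm_per_s: float = 0.0  # constant biological drawdown; 0 = off

    @model_validator(mode="after")
    def _check(self) -> "GasPlantParams":
        if not all(
            math.isfinite(v)
            for v in (
                self.volume_L,
                self.injection_flow_Lps,
                self.source_ppm,
                self.leak_rate_per_s,
                self.ambient_ppm,
                self.uptake_ppm_per_s,
            )
        ):
            raise ValueError("plant parameters must be finite")
        if self.volume_L <= 0:
            raise ValueError("volume_L must be positive")
        if self.injection_flow_Lps < 0:
            raise ValueError("injection_flow_Lps must be non-negative")
        if self.leak_rate_per_s < 0:
            raise ValueError("leak_rate_per_s must be non-negative")
        if not (0 <= self.ambient_ppm <= self.source_ppm <= PURE_GAS_PPM):
            raise ValueError("require 0 <= ambient_ppm <= source_ppm <= 1e6")
        return self


@dataclass(frozen=True)
class GasPlantState:
    """True chamber concentration (ppm) and the simulation clock (s)."""

    co2_ppm: float
    time_s: float = 0.0


def plant_step(
    state: GasPlantState,
    params: GasPlantParams,
    valve_fraction: float,
    dt: float,
) -> GasPlantState:
    """Advance the chamber concentration by ``dt`` seconds.

    Uses the exact solution of the linear balance for a constant valve
    fraction: with ``a = q*u/V`` and ``r = a + k_leak``,

        C(t+dt) = C_inf + (C(t) - C_inf) * exp(-r*dt),
        C_inf   = (a*source + k_leak*ambient - uptake) / r.

    ``r = 0`` (valve closed, sealed chamber) leaves the concentration
    unchanged apart from any constant uptake.
    """
    if not (0.0 <= valve_fraction <= 1.0):
        raise ValueError(f"valve_fraction must be in [0, 1], got {valve_fraction}")
    if not (math.isfinite(dt) and dt > 0):
        raise ValueError(f"dt must be positive and finite, got {dt}")
    if not math.isfinite(state.co2_ppm):
        raise ValueError("co2_ppm must be finite")

    a = params.injection_flow_Lps * valve_fraction / params.volume_L
    r = a + params.leak_rate_per_s
    if r == 0.0:
        new_c = state.co2_ppm - params.uptake_ppm_per_s * dt
    else:
        c_inf = (
            a * params.source_ppm
            + params.leak_rate_per_s * params.ambient_ppm
            - params.uptake_ppm_per_s
        ) / r
        new_c = c_inf + (state.co2_ppm - c_inf) * math.exp(-r * dt)
    new_c = min(max(new_c, 0.0), params.source_ppm)
    return replace(state, co2_ppm=new_c, time_s=state.time_s + dt)


def plant_equilibrium(params: GasPlantParams, valve_fraction: float) -> float:
    """Steady-state concentration for a constant valve fraction.

    ``C* = (a*source + k_leak*ambient) / (a + k_leak)`` with ``a = q*u/V``.
    With the valve closed this is the room concentration; a sealed chamber
    (``k_leak = 0``, valve closed) is degenerate and returns ambient by
    convention.
    """
    if not (0.0 <= valve_fraction <= 1.0):
        raise ValueError(f"valve_fraction must be in [0, 1], got {valve_fraction}")
    a = params.injection_flow_Lps * valve_fraction / params.volume_L
    r = a + params.leak_rate_per_s
    if r == 0.0 or (a == 0.0 and params.uptake_ppm_per_s == 0.0):
        return params.ambient_ppm
    c = (
        a * params.source_ppm
        + params.leak_rate_per_s * params.ambient_ppm
        - params.uptake_ppm_per_s
    ) / r
    return min(max(c, 0.0), params.source_ppm)
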