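"""Firmware safety state machine.

Three independent interlocks gate every valve action:

* **Pause button** — suspends control for a fixed countdown (default 60 s)
  so the incubator can be opened without triggering a corrective burst;
  a second press restarts the countdown.
* **Stuck-sensor freeze** — if the chamber sensor reports the identical
  integer reading for more than a window (default 60 s), control freezes
  until a differing reading arrives; it then clears automatically.
* **Environmental-leak latch** — the optional room sensor is checked every
  30 s; a room concentration above the leak threshold closes the valve and
  latches: the latch never clears without an explicit reset (the hardware
  analogue is a required reboot).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from pydantic import BaseModel, ConfigDict, model_validator


class SafetyConfig(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    pause_duration_s: float = 60.0
    stuck_window_s: float = 60.0
    env_check_period_s: float = 30.0
    env_threshold_ppm: float = 2000.0

    @model_validator(mode="after")
    def _check(self) -> "SafetyConfig":
        for name in (
            "pause_duration_s",
            "stuck_window_s",
            "env_check_period_s",
            "env_threshold_ppm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        return self


@dataclass(frozen=True)
class SafetyState:
    pause_until_s: float = -math.inf
    last_reading_ppm: float = math.nan
    last_change_s: float = -math.inf
    frozen: bool = False
    latched: bool = False


def pause_press(state: SafetyState, now_s: float, config: SafetyConfig) -> SafetyState:
    """Pause-button press: (re)start the countdown from now."""
    return replace(state, pause_until_s=now_s + config.pause_duration_s)


def stuck_check(
    state: SafetyState,
    reading_ppm: float,
    now_s: float,
    config: SafetyConfig,
) -> SafetyState:
    """Update stuck-sensor tracking with an accepted reading.

    Readings are integer ppm, compared for exact equality.  An unchanged
    value for longer than the window freezes control; any differing value
    clears the freeze and resets the memory.
    """
    if not math.isnan(state.last_reading_ppm) and reading_ppm == state.last_reading_ppm:
        if now_s - state.last_change_s > config.stuck_window_s:
            return replace(state, frozen=True)
        return state
    return replace(
        state,
        last_reading_ppm=reading_ppm,
        last_change_s=now_s,
        frozen=False,
    )


def env_check(
    state: SafetyState,
    env_reading_ppm: float,
    now_s: float,
    config: SafetyConfig,
) -> SafetyState:
    """Room-concentration check; above threshold sets the permanent latch."""
    if env_reading_ppm > config.env_threshold_ppm:
        return replace(state, latched=True)
    return state


def reset_latch(state: SafetyState) -> SafetyState:
    """Explicit reset (the 'reboot'); the only way to clear the leak latch."""
    return replace(state, latched=False)


def is_action_allowed(state: SafetyState, now_s: float) -> bool:
    """Gate consulted by the control loop before any valve command."""
    return (not state.latched) and (not state.frozen) and now_s >= state.pause_until_s
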