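"""Setpoint calibration, volume scaling, serial parsing and persistence.

The device is calibrated at three setpoint anchors for a 50-60 L incubator:

    setpoint %   hysteresis %   open_long s   open_short s
        1            2              4             1
        2            1              4             1
        5            0.5            6             2

``calibrate_setpoint`` returns these rows exactly at the anchors and
piecewise-linearly interpolates between them; setpoints above 5% clamp to
the 5% row.  ``scale_for_volume`` scales the opening times proportionally
to the chamber volume relative to the 55 L reference (doubling at 110 L).

Setpoint changes arrive as a bare decimal over a serial line ("2.5" sets
2.5% CO2); settings survive a power cycle via a small JSON state file that
plays the role of the microcontroller's non-volatile memory.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Tuple

from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

logger = logging.getLogger(__name__)

SETPOINT_MIN_PCT = 1.0
SETPOINT_MAX_PCT = 6.0
REFERENCE_VOLUME_L = 55.0

# (setpoint_pct, hysteresis_pct, open_long_s, open_short_s)
CALIBRATION_ANCHORS: Tuple[Tuple[float, float, float, float], ...] = (
    (1.0, 2.0, 4.0, 1.0),
    (2.0, 1.0, 4.0, 1.0),
    (5.0, 0.5, 6.0, 2.0),
)

FACTORY_DEFAULT_SETPOINT_PCT = 5.0
FACTORY_DEFAULT_PAUSE_S = 60.0


class CalibrationSettings(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    setpoint_pct: float
    hysteresis_pct: float
    open_long_s: float
    open_short_s: float

    @model_validator(mode="after")
    def _check(self) -> "CalibrationSettings":
        if not (SETPOINT_MIN_PCT <= self.setpoint_pct <= SETPOINT_MAX_PCT):
            raise ValueError("setpoint_pct must lie within 1-6%")
        if self.hysteresis_pct <= 0:
            raise ValueError("hysteresis_pct must be positive")
        if not (0 < self.open_short_s <= self.open_long_s):
            raise ValueError("require 0 < open_short_s <= open_long_s")
        return self

    @property
    def setpoint_ppm(self) -> float:
        return self.setpoint_pct * 10_000.0

    @property
    def hysteresis_ppm(self) -> float:
        return self.setpoint_ppm * self.hysteresis_pct / 100.0


class PersistedSettings(BaseModel):
    """What survives a power cycle: calibration plus the pause duration."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    setpoint_pct: float = FACTORY_DEFAULT_SETPOINT_PCT
    hysteresis_pct: float = 0.5
    open_long_s: float = 6.0
    open_short_s: float = 2.0
    pause_duration_s: float = FACTORY_DEFAULT_PAUSE_S

    def calibration(self) -> CalibrationSettings:
        return CalibrationSettings(
            setpoint_pct=self.setpoint_pct,
            hysteresis_pct=self.hysteresis_pct,
            open_long_s=self.open_long_s,
            open_short_s=self.open_short_s,
        )


def factory_defaults() -> PersistedSettings:
    return PersistedSettings()


def calibrate_setpoint(setpoint_pct: float) -> CalibrationSettings:
    """Hysteresis and opening times for a setpoint in [1, 6] percent.

    Exact at the anchors (1, 2, 5); piecewise-linear in between; above 5%
    the 5% row is used unchanged.
    """
    if not (SETPOINT_MIN_PCT <= setpoint_pct <= SETPOINT_MAX_PCT):
        raise ValueError(
            f"setpoint {setpoint_pct}% outside the supported 1-6% range"
        )
    anchors = CALIBRATION_ANCHORS
    if setpoint_pct >= anchors[-1][0]:
        _, hyst, long_s, short_s = anchors[-1]
    else:
        for (x0, h0, l0, s0), (x1, h1, l1, s1) in zip(anchors, anchors[1:]):
            if x0 <= setpoint_pct <= x1:
                f = (setpoint_pct - x0) / (x1 - x0)
                hyst = h0 + f * (h1 - h0)
                long_s = l0 + f * (l1 - l0)
                short_s = s0 + f * (s1 - s0)
                break
    return CalibrationSettings(
        setpoint_pct=setpoint_pct,
        hysteresis_pct=hyst,
        open_long_s=long_s,
        open_short_s=short_s,
    )


def scale_for_volume(
    settings: CalibrationSettings, volume_L: float
) -> CalibrationSettings:
    """Scale valve opening times linearly with chamber volume.

    The calibration reference is 55 L; a 110 L incubator doubles the
    opening times.  Hysteresis is volume-independent.
    """
    if volume_L <= 0:
        raise ValueError(f"volume_L must be positive, got {volume_L}")
    factor = volume_L / REFERENCE_VOLUME_L
    return CalibrationSettings(
        setpoint_pct=settings.setpoint_pct,
        hysteresis_pct=settings.hysteresis_pct,
        open_long_s=settings.open_long_s * factor,
        open_short_s=settings.open_short_s * factor,
    )


def parse_serial_setpoint(text: str) -> float:
    """Parse a serial setpoint command ("2.5" -> 2.5% = 25,000 ppm)."""
    try:
        value = float(text.strip())
    except (TypeError, ValueError) as exc:
        raise ValueError(f"could not parse setpoint from {text!r}") from exc
    if not (SETPOINT_MIN_PCT <= value <= SETPOINT_MAX_PCT):
        raise ValueError(
            f"setpoint {value}% rejected: must lie within the 1-6% range"
        )
    return value


def persist_settings(settings: PersistedSettings, state_path: str | Path) -> None:
    """Write settings to the JSON state file (the non-volatile memory)."""
    path = Path(state_path)
    path.write_text(json.dumps(settings.model_dump(), indent=2) + "\n")


def load_settings(state_path: str | Path) -> PersistedSettings:
    """Load persisted settings; missing or corrupt files fall back to
    factory defaults (corruption logs a warning)."""
    path = Path(state_path)
    if not path.exists():
        return factory_defaults()
    try:
        data = json.loads(path.read_text())
        return PersistedSettings(**data)
    except (json.JSONDecodeError, ValidationError, TypeError) as exc:
        logger.warning("corrupt state file %s (%s); using factory defaults", path, exc)
        return factory_defaults()
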