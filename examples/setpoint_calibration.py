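"""Setpoint calibration: the serial 'set' workflow in library form.

Parses a setpoint command as it would arrive over the serial line,
recomputes the hysteresis band and valve opening times from the calibration
table (exact at the 1%, 2% and 5% anchors, linearly interpolated between),
rescales opening times for a larger incubator, and persists the result to
the JSON state file that stands in for the microcontroller's non-volatile
memory.
"""

import tempfile
from pathlib import Path

from co2loop import (
    calibrate_setpoint,
    load_settings,
    parse_serial_setpoint,
    persist_settings,
    scale_for_volume,
)

pct = parse_serial_setpoint("2.5")
settings = calibrate_setpoint(pct)
print(
    f"serial command '2.5' -> setpoint {settings.setpoint_pct:g}% "
    f"({settings.setpoint_ppm:.0f} ppm), hysteresis {settings.hysteresis_pct:g}% "
    f"({settings.hysteresis_ppm:.0f} ppm), "
    f"open long/short {settings.open_long_s:g}/{settings.open_short_s:g} s"
)

big = scale_for_volume(settings, 110.0)
print(
    f"for a 110 L incubator the opening times double: "
    f"{big.open_long_s:g}/{big.open_short_s:g} s"
)

with tempfile.TemporaryDirectory() as d:
    state = Path(d) / "state.json"
    persisted = load_settings(state).model_copy(
        update={
            "setpoint_pct": settings.setpoint_pct,
            "hysteresis_pct": settings.hysteresis_pct,
            "open_long_s": settings.open_long_s,
            "open_short_s": settings.open_short_s,
        }
    )
    persist_settings(persisted, state)
    back = load_settings(state)
    print(f"persisted and reloaded setpoint: {back.setpoint_pct:g}% (round-trip exact)")
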