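"""Exercising the safety state machine with injected faults.

Three short runs of the reference loop, each with one fault:

* an environmental leak (room CO2 jumps to 3000 ppm) — caught by the 30-s
  room check, which latches the valve closed permanently;
* a stuck chamber sensor (output register freezes) — detected after 60 s of
  identical readings, freezing control until the reading changes;
* a pause-button press — suspends control for the 60-s countdown so the
  incubator can be opened without triggering a corrective burst.
"""

from co2loop import (
    FaultSchedule,
    environment_sensor_params,
    reference_scenario,
    run_closed_loop,
)


def first_event_time(df, column, needle):
    hits = df.time_s[df[column].str.contains(needle)]
    return float(hits.iloc[0]) if len(hits) else None


# --- environmental leak at t = 600 s ---
sc = reference_scenario(
    5.0,
    duration_s=1500.0,
    env_sensor=environment_sensor_params(t90_s=0.0),
    faults=FaultSchedule(leak_at_s=600.0, leak_env_ppm=3000.0),
)
df = run_closed_loop(sc).df
t_latch = first_event_time(df, "safety_event", "env_latched")
open_after = float(df[df.time_s > t_latch].valve_fraction.sum())
print(f"leak injected at 600 s -> latched at {t_latch:.0f} s; "
      f"valve-open time afterwards: {open_after:.1f} s (must be 0)")

# --- stuck sensor at t = 300 s ---
sc = reference_scenario(5.0, duration_s=1200.0, faults=FaultSchedule(stuck_at_s=300.0))
df = run_closed_loop(sc).df
t_frozen = first_event_time(df, "safety_event", "sensor_frozen")
print(f"sensor stuck at 300 s -> control frozen at {t_frozen:.0f} s "
      f"(after 60 s of identical readings)")

# --- pause button at t = 400 s ---
sc = reference_scenario(5.0, duration_s=900.0, faults=FaultSchedule(pause_press_at_s=(400.0,)))
df = run_closed_loop(sc).df
paused = df[(df.time_s > 400.0) & (df.time_s < 460.0)]
print(f"pause pressed at 400 s -> valve-open time in the 60-s countdown: "
      f"{float(paused.valve_fraction.sum()):.1f} s (must be 0)")
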