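"""Closed-loop scenario runner, stability metrics and trace/config I/O.

Wires the gas plant, the lagged NDIR sensor(s), one of the three control
laws and the safety state machine together on a 1-s control tick:

1. advance the true chamber concentration over the elapsed tick (sub-stepped
   at <= 0.1 s whenever the valve is open, so 1-6 s pulses are resolved),
   relaxing the sensor lag alongside;
2. attempt a chamber read, honouring the sensor's minimum 1020 ms spacing
   (at a 1-s tick this makes readings arrive every 2 s);
3. run the safety checks — stuck-sensor on every accepted reading, the
   environmental leak check every 30 s;
4. if the safety gate allows, invoke the controller: timed-activation (TAC)
   schedules a fixed-duration pulse, threshold control (TC) switches the
   solenoid, PID commands a proportional-valve fraction.

Runs are deterministic given the scenario seed.  Stability is summarised
the way incubator validation reports it: the maximal deviation of the
measured trace from its window mean, expressed both in ppm and as a percent
of the setpoint (half-up, two decimals).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Dict, List, Literal, Optional, Tuple

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .calibration import calibrate_setpoint
from .control_laws import (
    PidConfig,
    PidState,
    ProportionalValveParams,
    TacConfig,
    TacSchedulerState,
    TcConfig,
    control_to_valve_fraction,
    pid_step,
    tac_decide,
    tc_decide,
)
from .gas_plant import GasPlantParams, GasPlantState, plant_step
from .ndir_sensor import (
    NdirSensorParams,
    SensorState,
    environment_sensor_params,
    inject_fault,
    sensor_lag_step,
    sensor_read,
)
from .safety_logic import (
    SafetyConfig,
    SafetyState,
    env_check,
    is_action_allowed,
    pause_press,
    stuck_check,
)

__version__ = "0.1.0"

MAX_OPEN_SUBSTEP_S = 0.1

ControllerKind = Literal["none", "tc", "tac", "pid"]


class FaultSchedule(BaseModel):
    """When to inject faults into a run (seconds from start; None = never)."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    stuck_at_s: Optional[float] = None
    leak_at_s: Optional[float] = None
    leak_env_ppm: float = 3000.0
    pause_press_at_s: Tuple[float, ...] = ()


class Scenario(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    plant: GasPlantParams = Field(default_factory=GasPlantParams)
    sensor: NdirSensorParams = Field(default_factory=NdirSensorParams)
    env_sensor: Optional[NdirSensorParams] = None
    controller: ControllerKind = "tac"
    tc: TcConfig = Field(default_factory=TcConfig)
    tac: TacConfig = Field(default_factory=TacConfig)
    pid: PidConfig = Field(default_factory=PidConfig)
    valve: ProportionalValveParams = Field(default_factory=ProportionalValveParams)
    safety: SafetyConfig = Field(default_factory=SafetyConfig)
    duration_s: float = 7200.0
    tick_s: float = 1.0
    seed: int = 0
    initial_co2_ppm: float = 450.0
    faults: FaultSchedule = Field(default_factory=FaultSchedule)

    @model_validator(mode="after")
    def _check(self) -> "Scenario":
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.tick_s <= 0:
            raise ValueError("tick_s must be positive")
        if not (0 <= self.initial_co2_ppm <= self.plant.source_ppm):
            raise ValueError("initial_co2_ppm outside plant bounds")
        return self

    def setpoint_ppm(self) -> float:
        if self.controller == "tc":
            return self.tc.setpoint_ppm
        if self.controller == "pid":
            return self.tac.setpoint_ppm  # pid shares the tac setpoint field
        return self.tac.setpoint_ppm

    def hysteresis_ppm(self) -> float:
        if self.controller == "tc":
            return self.tc.hysteresis_ppm
        return self.tac.hysteresis_ppm

    def content_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ClosedLoopTrace:
    """Per-tick log of a closed-loop run plus run metadata."""

    df: pd.DataFrame
    metadata: Dict[str, object] = field(default_factory=dict)

    def trace_hash(self) -> str:
        return hashlib.sha256(
            self.df.to_csv(index=False).encode()
        ).hexdigest()


@dataclass(frozen=True)
class StabilityMetrics:
    window: Tuple[float, float]
    mean_ppm: float
    max_dev_from_mean_ppm: float
    pct_of_setpoint: float
    settling_time_s: Optional[float]
    valve_actuations: int
    total_open_s: float


def reference_scenario(
    setpoint_pct: float,
    controller: ControllerKind = "tac",
    duration_s: float = 7200.0,
    seed: int = 0,
    **overrides,
) -> Scenario:
    """The reference validation scenario: 55 L plant, calibrated controller
    settings for the given setpoint, 120-min run from a 450 ppm off-state."""
    cal = calibrate_setpoint(setpoint_pct)
    tac = TacConfig(
        setpoint_ppm=cal.setpoint_ppm,
        hysteresis_pct=cal.hysteresis_pct,
        open_short_s=cal.open_short_s,
        open_long_s=cal.open_long_s,
    )
    tc = TcConfig(setpoint_ppm=cal.setpoint_ppm, hysteresis_pct=cal.hysteresis_pct)
    return Scenario(
        controller=controller,
        tac=tac,
        tc=tc,
        duration_s=duration_s,
        seed=seed,
        **overrides,
    )


def _advance(
    plant: GasPlantState,
    chamber: SensorState,
    scenario: Scenario,
    segments: List[Tuple[float, float]],
) -> Tuple[GasPlantState, SensorState, float]:
    """Advance plant + chamber sensor over (dt, valve_fraction) segments.

    Open segments are sub-stepped at <= 0.1 s so the sensor lag sees the
    fill transient.  Returns the new states and the valve-open seconds
    accumulated (fraction-weighted).
    """
    open_time = 0.0
    for seg_dt, u in segments:
        if seg_dt <= 0:
            continue
        n_sub = max(1, math.ceil(seg_dt / MAX_OPEN_SUBSTEP_S)) if u > 0 else 1
        sub_dt = seg_dt / n_sub
        for _ in range(n_sub):
            plant = plant_step(plant, scenario.plant, u, sub_dt)
            chamber = sensor_lag_step(chamber, plant.co2_ppm, sub_dt, scenario.sensor)
        open_time += u * seg_dt
    return plant, chamber, open_time


def run_closed_loop(scenario: Scenario) -> ClosedLoopTrace:
    """Run the full closed loop and return the per-tick trace."""
    rng = np.random.default_rng(scenario.seed)
    tick = scenario.tick_s
    n_ticks = int(round(scenario.duration_s / tick))

    plant = GasPlantState(co2_ppm=scenario.initial_co2_ppm, time_s=0.0)
    chamber = SensorState(lagged_ppm=scenario.initial_co2_ppm)
    env_params = scenario.env_sensor
    env_state = (
        SensorState(lagged_ppm=scenario.plant.ambient_ppm)
        if env_params is not None
        else None
    )
    safety = SafetyState()
    sched = TacSchedulerState()
    pid_state = PidState()

    tc_open = False
    pid_fraction = 0.0
    stuck_injected = False
    pause_done = [False] * len(scenario.faults.pause_press_at_s)
    last_env_check_s = -math.inf
    last_reading: Optional[float] = None
    was_latched = was_frozen = False

    rows = []
    for k in range(n_ticks):
        t0, t1 = k * tick, (k + 1) * tick

        # ---- plant + chamber-sensor advance over (t0, t1] ----
        if scenario.controller == "tac":
            open_until = sched.valve_open_until_s
            open_dt = min(max(open_until - t0, 0.0), tick)
            segments = [(open_dt, 1.0), (tick - open_dt, 0.0)]
        elif scenario.controller == "tc":
            segments = [(tick, 1.0 if tc_open else 0.0)]
        elif scenario.controller == "pid":
            segments = [(tick, pid_fraction)]
        else:
            segments = [(tick, 0.0)]
        plant, chamber, open_s = _advance(plant, chamber, scenario, segments)

        # environment channel: room air, or the injected leak level
        leak_at = scenario.faults.leak_at_s
        env_true = (
            scenario.faults.leak_env_ppm
            if (leak_at is not None and t1 >= leak_at)
            else scenario.plant.ambient_ppm
        )
        if env_state is not None:
            env_state = sensor_lag_step(env_state, env_true, tick, env_params)

        controller_events: List[str] = []
        safety_events: List[str] = []

        # ---- fault / button injection at the tick boundary ----
        if (
            scenario.faults.stuck_at_s is not None
            and t1 >= scenario.faults.stuck_at_s
            and not stuck_injected
        ):
            chamber = inject_fault(chamber, "stuck")
            stuck_injected = True
            safety_events.append("stuck_injected")
        for i, press_t in enumerate(scenario.faults.pause_press_at_s):
            if not pause_done[i] and t1 >= press_t:
                safety = pause_press(safety, t1, scenario.safety)
                pause_done[i] = True
                safety_events.append("pause_pressed")

        # ---- chamber read (1020-ms rule) + stuck detection ----
        reading, chamber = sensor_read(chamber, t1 * 1000.0, scenario.sensor, rng)
        if reading is not None:
            safety = stuck_check(safety, reading, t1, scenario.safety)
            last_reading = reading

        # ---- environmental leak check every env_check_period_s ----
        if env_state is not None and t1 - last_env_check_s >= scenario.safety.env_check_period_s:
            env_reading, env_state = sensor_read(env_state, t1 * 1000.0, env_params, rng)
            if env_reading is not None:
                safety = env_check(safety, env_reading, t1, scenario.safety)
                last_env_check_s = t1
                safety_events.append("env_check")
        if safety.latched and not was_latched:
            safety_events.append("env_latched")
        if safety.frozen and not was_frozen:
            safety_events.append("sensor_frozen")
        if was_frozen and not safety.frozen:
            safety_events.append("sensor_unfrozen")
        was_latched, was_frozen = safety.latched, safety.frozen

        # ---- controller (gated by safety) ----
        allowed = is_action_allowed(safety, t1)
        if not allowed:
            # force the valve closed for the next tick; TAC pulses are cut short
            sched = TacSchedulerState(
                last_response_end_s=sched.last_response_end_s,
                valve_open_until_s=min(sched.valve_open_until_s, t1),
            )
            if tc_open or pid_fraction > 0:
                controller_events.append("valve_forced_closed")
            tc_open = False
            pid_fraction = 0.0
        elif scenario.controller == "tac" and reading is not None:
            duration, sched = tac_decide(reading, scenario.tac, sched, t1)
            if duration is not None:
                controller_events.append(f"open_for:{duration:g}")
        elif scenario.controller == "tc" and reading is not None:
            new_open = tc_decide(reading, scenario.tc)
            if new_open != tc_open:
                controller_events.append("valve_open" if new_open else "valve_close")
            tc_open = new_open
        elif scenario.controller == "pid" and last_reading is not None:
            u, pid_state = pid_step(
                scenario.tac.setpoint_ppm,
                last_reading,
                pid_state,
                scenario.pid,
                scenario.valve,
            )
            pid_fraction = control_to_valve_fraction(u, scenario.valve, scenario.pid)

        rows.append(
            (
                t1,
                plant.co2_ppm,
                reading if reading is not None else math.nan,
                open_s / tick,
                ";".join(controller_events),
                ";".join(safety_events),
            )
        )

    df = pd.DataFrame(
        rows,
        columns=[
            "time_s",
            "true_ppm",
            "measured_ppm",
            "valve_fraction",
            "controller_event",
            "safety_event",
        ],
    )
    metadata = {
        "scenario_hash": scenario.content_hash(),
        "seed": scenario.seed,
        "version": __version__,
        "controller": scenario.controller,
        "setpoint_ppm": scenario.setpoint_ppm(),
        "hysteresis_ppm": scenario.hysteresis_ppm(),
    }
    return ClosedLoopTrace(df=df, metadata=metadata)


def percent_of_setpoint(dev_ppm: float, setpoint_ppm: float) -> float:
    """Deviation as a percent of the setpoint, half-up to 2 decimals
    (145 ppm at 20,000 ppm is 0.725% and reports as 0.73)."""
    if setpoint_ppm <= 0:
        raise ValueError("setpoint_ppm must be positive")
    pct = Decimal(100 * dev_ppm) / Decimal(setpoint_ppm)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def fluctuation_metrics(
    trace: ClosedLoopTrace,
    window: Tuple[float, float],
    setpoint_ppm: float,
    hysteresis_ppm: Optional[float] = None,
) -> StabilityMetrics:
    """Stability summary over a time window.

    The fluctuation is the maximal deviation of the measured signal from its
    *window mean* — the reference point a threshold-triggered loop actually
    oscillates around sits slightly below the setpoint, so measuring about
    the mean characterises the oscillation amplitude itself.  Settling time
    (if a hysteresis band is given) is the first time after which every
    subsequent measurement stays within +/- 2 hysteresis of the setpoint.
    """
    t_start, t_end = window
    if t_end <= t_start:
        raise ValueError("empty metrics window")
    df = trace.df
    in_win = df[(df.time_s >= t_start) & (df.time_s <= t_end)]
    measured = in_win.measured_ppm.dropna()
    if measured.empty:
        raise ValueError("no accepted measurements inside the window")
    mean = float(measured.mean())
    max_dev = float((measured - mean).abs().max())

    settling: Optional[float] = None
    if hysteresis_ppm is not None:
        m = df.measured_ppm.dropna()
        ok = (m - setpoint_ppm).abs() <= 2.0 * hysteresis_ppm
        # first index from which ok holds to the end of the run
        bad_times = df.time_s[m.index[~ok]]
        if len(bad_times) == 0:
            settling = float(df.time_s.iloc[0])
        else:
            last_bad = float(bad_times.max())
            after = df.time_s[m.index][df.time_s[m.index] > last_bad]
            settling = float(after.min()) if len(after) else None

    vf = in_win.valve_fraction.to_numpy()
    opens = int(np.sum((vf[1:] > 0) & (vf[:-1] == 0)))
    if len(vf) and vf[0] > 0:
        opens += 1
    dt = float(np.median(np.diff(df.time_s))) if len(df) > 1 else 1.0
    total_open = float(np.sum(vf) * dt)

    return StabilityMetrics(
        window=(t_start, t_end),
        mean_ppm=mean,
        max_dev_from_mean_ppm=max_dev,
        pct_of_setpoint=percent_of_setpoint(max_dev, setpoint_ppm),
        settling_time_s=settling,
        valve_actuations=opens,
        total_open_s=total_open,
    )


COMPARISON_CADENCE_S = 60.0


def compare_strategies(
    scenario: Scenario,
    window: Optional[Tuple[float, float]] = None,
    measurement_cadence_s: Optional[float] = COMPARISON_CADENCE_S,
) -> Dict[str, object]:
    """Run TC, TAC and PID on the identical plant/sensor/seed and report
    per-strategy stability metrics plus the TC:TAC fluctuation ratio.

    By default the comparison reproduces the head-to-head validation
    protocol, in which measurements are spaced 60 s apart: at that cadence
    continuous bang-bang switching keeps the valve open through stale
    readings and overshoots, while timed-activation pulses (already limited
    to one per 60 s by their lockout) are barely affected — the effect the
    comparison exists to show.  Pass ``measurement_cadence_s=None`` to use
    the scenario's own sensor read interval instead.
    """
    if window is None:
        window = (scenario.duration_s * 0.75, scenario.duration_s)
    sensor = scenario.sensor
    if measurement_cadence_s is not None:
        sensor = sensor.model_copy(
            update={"min_read_interval_ms": measurement_cadence_s * 1000.0}
        )
    report: Dict[str, object] = {}
    for kind in ("tc", "tac", "pid"):
        sub = scenario.model_copy(update={"controller": kind, "sensor": sensor})
        trace = run_closed_loop(sub)
        report[kind] = fluctuation_metrics(
            trace, window, sub.setpoint_ppm(), sub.hysteresis_ppm()
        )
    tc_dev = report["tc"].max_dev_from_mean_ppm
    tac_dev = report["tac"].max_dev_from_mean_ppm
    report["tc_tac_ratio"] = tc_dev / tac_dev if tac_dev > 0 else math.inf
    return report


# ---------------------------------------------------------------- I/O ----

TRACE_COLUMNS = ["time_s", "true_ppm", "measured_ppm", "valve_fraction", "event"]


def write_trace(trace: ClosedLoopTrace, path: str | Path) -> None:
    """Write the trace as CSV (header: time_s,true_ppm,measured_ppm,
    valve_fraction,event); controller and safety events are merged."""
    df = trace.df.copy()
    ev = df.controller_event.fillna("") + np.where(
        (df.controller_event != "") & (df.safety_event != ""), ";", ""
    ) + df.safety_event.fillna("")
    out = df[["time_s", "true_ppm", "measured_ppm", "valve_fraction"]].copy()
    out["event"] = ev
    out.to_csv(path, index=False)


def read_trace(path: str | Path) -> ClosedLoopTrace:
    df = pd.read_csv(path, keep_default_na=True)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace file missing columns: {missing}")
    df = df.rename(columns={"event": "controller_event"})
    df["controller_event"] = df.controller_event.fillna("")
    df["safety_event"] = ""
    return ClosedLoopTrace(df=df, metadata={"source": str(path)})


def read_scenario(path: str | Path) -> Scenario:
    """Load a scenario from JSON or YAML with schema validation; unknown
    keys and invalid values are rejected with itemized messages."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if not isinstance(data, dict):
        raise ValueError(f"scenario file {path} must contain a mapping")
    try:
        return Scenario(**data)
    except ValidationError as exc:
        items = "; ".join(
            f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in exc.errors()
        )
        raise ValueError(f"invalid scenario {path}: {items}") from exc


def write_scenario(scenario: Scenario, path: str | Path) -> None:
    path = Path(path)
    data = scenario.model_dump(mode="json")
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=2) + "\n")
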