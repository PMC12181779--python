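"""Closed-loop runner: loop timing, safety composition, metrics, I/O."""

import math

import numpy as np
import pandas as pd
import pytest

from co2loop import (
    ClosedLoopTrace,
    FaultSchedule,
    NdirSensorParams,
    Scenario,
    environment_sensor_params,
    fluctuation_metrics,
    percent_of_setpoint,
    read_scenario,
    read_trace,
    reference_scenario,
    run_closed_loop,
    write_scenario,
    write_trace,
)


def _open_event_times(trace):
    df = trace.df
    return df.time_s[df.controller_event.str.startswith("open_for")].to_numpy()


def test_disabled_controller_stays_at_ambient():
    sc = Scenario(controller="none", duration_s=600.0)
    trace = run_closed_loop(sc)
    assert np.allclose(trace.df.true_ppm, 450.0, atol=1e-9)
    assert (trace.df.valve_fraction == 0.0).all()


def test_tac_responses_spaced_by_lockout():
    sc = reference_scenario(5.0, duration_s=3600.0)
    trace = run_closed_loop(sc)
    opens = _open_event_times(trace)
    assert len(opens) >= 3
    assert np.diff(opens).min() >= 60.0


def test_accepted_reads_spaced_at_least_1020_ms():
    sc = reference_scenario(5.0, duration_s=600.0)
    trace = run_closed_loop(sc)
    read_times = trace.df.time_s[trace.df.measured_ppm.notna()].to_numpy()
    assert np.diff(read_times).min() >= 1.02


def test_determinism_identical_seed_identical_trace():
    noisy = NdirSensorParams(noise_sd_ppm=5.0)
    a = run_closed_loop(reference_scenario(5.0, duration_s=900.0, seed=3, sensor=noisy))
    b = run_closed_loop(reference_scenario(5.0, duration_s=900.0, seed=3, sensor=noisy))
    c = run_closed_loop(reference_scenario(5.0, duration_s=900.0, seed=4, sensor=noisy))
    assert a.trace_hash() == b.trace_hash()
    assert a.trace_hash() != c.trace_hash()


def test_leak_latch_stops_all_subsequent_valve_action():
    sc = reference_scenario(
        5.0,
        duration_s=2400.0,
        env_sensor=environment_sensor_params(t90_s=0.0),
        faults=FaultSchedule(leak_at_s=1200.0, leak_env_ppm=3000.0),
    )
    trace = run_closed_loop(sc)
    df = trace.df
    latch_t = float(df.time_s[df.safety_event.str.contains("env_latched")].iloc[0])
    assert latch_t <= 1200.0 + 31.0  # caught by the next 30-s check
    after = df[df.time_s > latch_t]
    assert (after.valve_fraction == 0.0).all()
    assert not after.controller_event.str.startswith("open_for").any()


def test_env_checks_spaced_at_period():
    sc = reference_scenario(
        5.0, duration_s=600.0, env_sensor=environment_sensor_params()
    )
    df = run_closed_loop(sc).df
    checks = df.time_s[df.safety_event.str.contains("env_check")].to_numpy()
    assert len(checks) >= 15
    assert np.all(np.abs(np.diff(checks) - 30.0) <= sc.tick_s)


def test_stuck_sensor_freezes_control():
    sc = reference_scenario(
        5.0, duration_s=2400.0, faults=FaultSchedule(stuck_at_s=600.0)
    )
    df = run_closed_loop(sc).df
    frozen_t = float(df.time_s[df.safety_event.str.contains("sensor_frozen")].iloc[0])
    assert 600.0 < frozen_t <= 600.0 + 70.0  # window is 60 s of identical readings
    after = df[df.time_s > frozen_t]
    assert (after.valve_fraction == 0.0).all()


def test_pause_press_suspends_valve_action():
    sc = reference_scenario(
        5.0, duration_s=1500.0, faults=FaultSchedule(pause_press_at_s=(300.0,))
    )
    df = run_closed_loop(sc).df
    paused = df[(df.time_s > 300.0) & (df.time_s < 360.0)]
    assert (paused.valve_fraction == 0.0).all()
    assert not paused.controller_event.str.startswith("open_for").any()


class TestMetrics:
    def test_constant_trace_zero_deviation(self):
        df = pd.DataFrame(
            {
                "time_s": np.arange(1.0, 101.0),
                "true_ppm": 50_000.0,
                "measured_ppm": 50_000.0,
                "valve_fraction": 0.0,
                "controller_event": "",
                "safety_event": "",
            }
        )
        m = fluctuation_metrics(ClosedLoopTrace(df), (1.0, 100.0), 50_000.0)
        assert m.max_dev_from_mean_ppm == 0.0
        assert m.pct_of_setpoint == 0.0

    def test_sawtooth_amplitude_recovered(self):
        # symmetric sawtooth of amplitude a about 50,000: max dev from mean = a
        a, n = 300.0, 400
        t = np.arange(1.0, n + 1.0)
        phase = (t % 40) / 40.0
        saw = 50_000.0 + a * (2.0 * np.abs(2.0 * phase - 1.0) - 1.0)
        df = pd.DataFrame(
            {
                "time_s": t,
                "true_ppm": saw,
                "measured_ppm": saw,
                "valve_fraction": 0.0,
                "controller_event": "",
                "safety_event": "",
            }
        )
        m = fluctuation_metrics(ClosedLoopTrace(df), (1.0, float(n)), 50_000.0)
        assert m.max_dev_from_mean_ppm == pytest.approx(a, rel=0.01)

    def test_empty_window_rejected(self):
        df = pd.DataFrame(
            {
                "time_s": [1.0],
                "true_ppm": [450.0],
                "measured_ppm": [450.0],
                "valve_fraction": [0.0],
                "controller_event": [""],
                "safety_event": [""],
            }
        )
        with pytest.raises(ValueError):
            fluctuation_metrics(ClosedLoopTrace(df), (5.0, 5.0), 50_000.0)

    @pytest.mark.parametrize(
        "dev,setpoint,expected",
        [(120.0, 10_000.0, 1.2), (145.0, 20_000.0, 0.73), (260.0, 50_000.0, 0.52), (0.0, 50_000.0, 0.0)],
    )
    def test_percent_of_setpoint_half_up(self, dev, setpoint, expected):
        # 145/20000 = 0.725 exactly: must round half-up to 0.73
        assert percent_of_setpoint(dev, setpoint) == expected

    def test_valve_actuation_count(self):
        vf = np.array([0, 0, 1, 1, 0, 0, 0.4, 0, 1, 0], dtype=float)
        df = pd.DataFrame(
            {
                "time_s": np.arange(1.0, 11.0),
                "true_ppm": 50_000.0,
                "measured_ppm": 50_000.0,
                "valve_fraction": vf,
                "controller_event": "",
                "safety_event": "",
            }
        )
        m = fluctuation_metrics(ClosedLoopTrace(df), (1.0, 10.0), 50_000.0)
        assert m.valve_actuations == 3
        assert m.total_open_s == pytest.approx(vf.sum())


class TestScenarioIO:
    def test_trace_round_trip_row_count(self, tmp_path):
        sc = reference_scenario(5.0, duration_s=300.0)
        trace = run_closed_loop(sc)
        path = tmp_path / "trace.csv"
        write_trace(trace, path)
        back = read_trace(path)
        assert len(back.df) == len(trace.df) == 300
        header = path.read_text().splitlines()[0]
        assert header == "time_s,true_ppm,measured_ppm,valve_fraction,event"

    def test_scenario_round_trip_reproduces_trace_hash(self, tmp_path):
        sc = reference_scenario(2.0, duration_s=600.0, seed=11)
        for suffix in ("json", "yaml"):
            path = tmp_path / f"scenario.{suffix}"
            write_scenario(sc, path)
            again = read_scenario(path)
            assert run_closed_loop(again).trace_hash() == run_closed_loop(sc).trace_hash()

    def test_missing_field_value_rejected_with_field_name(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"plant": {"volume_L": -3}}')
        with pytest.raises(ValueError, match="volume_L"):
            read_scenario(path)

    def test_unknown_keys_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"volume": 55}')
        with pytest.raises(ValueError, match="volume"):
            read_scenario(path)


def test_scenario_validation():
    with pytest.raises(ValueError):
        Scenario(duration_s=-1.0)
    with pytest.raises(ValueError):
        Scenario(initial_co2_ppm=2e6)
    with pytest.raises(ValueError):
        Scenario(tick_s=0.0)
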