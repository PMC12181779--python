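# Methods

## The plant model

The incubator is a single well-mixed volume `V` (litres). Pure CO₂ enters
at volumetric flow `q·u` (`u ∈ [0,1]` the valve-open fraction) and the
chamber exchanges air with the room at a first-order rate `k_leak` (1/s),
giving

    dC/dt = (q·u/V)·(C_src − C) − k_leak·(C − C_amb)

with `C` in ppm, `C_src = 10⁶` ppm for pure gas and `C_amb` the room
concentration. For constant `u` this is linear with rate `r = q·u/V +
k_leak` and fixed point `C* = (q·u/V·C_src + k_leak·C_amb)/r`, so each step
applies the exact solution `C ← C* + (C − C*)·e^(−r·dt)`. The exact update
is unconditionally stable, composes exactly (two steps of `dt₁`, `dt₂`
equal one of `dt₁+dt₂`), and makes agreement with an independent ODE
integration a 10⁻⁹-relative test rather than a discretisation question.
An optional constant uptake term (ppm/s) represents culture CO₂
consumption and defaults to 0.

**Reference parameterisation** (used by all validation scenarios):
`V = 55 L` (mid-range of the 50–60 L incubators the calibration targets),
`q = 0.012 L/s`, `k_leak = 5×10⁻⁵ /s`, `C_amb = 450 ppm`. The hardware
documentation prescribes neither an injection flow nor a leak rate; these
values are the package's calibration choice, set so that one short (2 s)
pulse moves the chamber by a few hundred ppm and unaided decay at a 5%
setpoint is a few ppm/s — consistent with a loop that corrects at most once
per 60 s. Spatial gradients, temperature/pressure effects and
humidity-CO₂ interaction are out of scope.

## The sensor model

NDIR sensors respond to a concentration step as a first-order system; the
datasheet T₉₀ (time to 90% of a step) fixes the time constant
`τ = T₉₀/ln 10`. The chamber sensor defaults to the stated worst case
`T₉₀ = 30 s` (`τ ≈ 13.03 s`); the optional room sensor to `T₉₀ = 60 s`
with a 400–5000 ppm reporting range. Reads are refused if less than
1020 ms has elapsed since the last accepted read (at the 1-s control tick
this makes measurements arrive every 2 s); accepted reads apply a constant
multiplicative calibration bias, optional seeded Gaussian noise, clipping
to the reporting range (0–100,000 ppm for the chamber sensor) and half-up
rounding to whole ppm, mimicking the serial protocol.

The chamber sensor's quoted 6% error is modelled as *accuracy* — a
constant of-reading bias, default 0 in reference scenarios — not as
per-read noise: observed stability traces are smooth, and the bias cancels
out of mean-centred fluctuation metrics anyway. Reference runs are
therefore deterministic. A `stuck` fault freezes the reported value while
the internal lag state keeps tracking, which is the failure the safety
logic must detect. Optical physics, warm-up and zero-calibration routines
are not modelled.

## Control laws

*Threshold (bang-bang, TC).* Open iff `reading < setpoint − hysteresis`,
with `hysteresis = setpoint · hysteresis_pct/100`; a reading at the
threshold closes. There is only the one threshold: the same value that
opens the valve (strictly below) closes it (at or above).

*Timed-activation (TAC).* At each accepted reading, if the loop is outside
its post-response lockout and the deficit `setpoint − reading` exceeds the
hysteresis band, the valve opens for a fixed duration: `open_short_s` for
moderate deficits, `open_long_s` when the deficit exceeds a far/near
boundary. The boundary defaults to 4× the hysteresis band: it must exceed
the band, and 4× keeps settled-state cycles on the short pulse while the
initial fill uses the long one. The lockout (≥ 60 s, measured from the
*end* of the pulse) gives the slow sensor time to register the correction.
Readings at or above the setpoint produce no action — there is no exhaust
valve, so overshoot can only decay through the leak.

*PID.* Discrete `u = K_p e + K_i Σe·dt + K_d Δe/dt` on
`e = setpoint − reading`, with the shipped gains 20/0.6/5. Anti-windup
clamps the integral accumulator so that its `K_i`-weighted contribution
alone cannot exceed full-scale valve current. The derivative acts on the
error, with the previous error initialised to the first error so startup
produces no derivative kick. The control signal maps to coil current as
`u · output_to_mA` (default 0.01 mA per unit, a scale the firmware leaves
implicit), clamped to [0, 330] mA; flow is zero below the 160 mA opening
onset and rises linearly to full flow at 330 mA.

## Safety state machine

Three interlocks gate every valve command; a run trace never contains
valve-open time while any is active.

- **Pause button**: suspends control for `pause_duration_s` (60 s); a
  second press restarts the countdown (restart rather than ignore — the
  firmware description leaves this open, and restart is the conservative
  reading for "open the incubator without corrective bursts").
- **Stuck-sensor freeze**: identical integer readings for more than 60 s
  freeze control; any differing reading clears the freeze automatically.
- **Environmental latch**: the room sensor is checked every 30 s; a
  reading above `env_threshold_ppm` closes the valve and latches until an
  explicit reset (the hardware analogue is a required reboot). The
  threshold defaults to 2000 ppm — clearly above occupied-room levels yet
  well under the 5000 ppm occupational exposure limit; no numeric
  threshold is published, so this is a design choice.

## Calibration

Anchors for a 50–60 L incubator:

| setpoint % | hysteresis % | open_long s | open_short s |
|-----------:|-------------:|------------:|-------------:|
| 1 | 2   | 4 | 1 |
| 2 | 1   | 4 | 1 |
| 5 | 0.5 | 6 | 2 |

The anchors are authoritative; between them the package interpolates
piecewise-linearly (the firmware's exact adjustment formula is not
published), and setpoints above 5% clamp to the 5% row. Opening times
scale linearly with chamber volume relative to the 55 L reference —
doubling for a 100–120 L incubator — while hysteresis is
volume-independent. Settings survive "power cycles" through a small JSON
state file; a missing file yields factory defaults (5% setpoint, 0.5%
hysteresis, 6 s/2 s opening times, 60 s pause), and a corrupt file falls
back to the same defaults with a logged warning.

## The closed loop

The runner advances on a 1-s control tick: plant and chamber-sensor lag
first (sub-stepped at ≤ 0.1 s whenever the valve is open, so 1–6 s pulses
and the lag transient are resolved), then fault injection, then a read
attempt under the 1020-ms rule, then the safety checks (stuck on every
accepted reading, environment every 30 s), then — if allowed — the
controller. TAC pulses are scheduled as a valve-open deadline consumed by
subsequent sub-steps; TC and PID set the valve state/fraction held over
the next tick, PID recomputing each tick from the most recent accepted
reading. Runs are deterministic given the scenario seed; traces log
per-tick time, true and measured ppm, valve fraction and
controller/safety events, and hash reproducibly.

**Stability metric.** Fluctuation is the maximal deviation of the measured
signal from its *window mean*, reported in ppm and as a percent of the
setpoint with half-up rounding to two decimals (so 145 ppm at 20,000 ppm
is 0.73%). Mean-centring is deliberate: a below-threshold trigger
oscillates about a level slightly below the setpoint, and the mean-centred
amplitude characterises the oscillation itself rather than the (separate,
bias-like) offset. Settling time is the first instant after which every
measurement stays within ±2 hysteresis bands of the setpoint.

**Reference validation scenario** (also what `scripts/acceptance.py`
runs): reference plant and sensor, calibrated TAC settings for the chosen
setpoint, long boundary 4× hysteresis, 60-s lockout, 120 simulated minutes
from a 450 ppm off-state, metrics over the final 30 minutes. Each run is
7200 ticks and completes in well under a second.

**Comparison protocol.** `compare_strategies` runs TC, TAC and PID on the
identical plant, sensor and seed. By default it spaces measurements 60 s
apart, reproducing the head-to-head validation protocol. The cadence
matters: with ~2-s reads, sampled bang-bang closes the valve almost as
soon as the lagged reading crosses the threshold and its fluctuation is
comparable to TAC's; at a 60-s cadence the valve stays open through stale
readings, overshooting by thousands of ppm — the failure mode that
motivates timed activation (TAC, already limited to one pulse per minute
by its lockout, is barely affected). Pass `measurement_cadence_s=None` to
compare at the scenario's own read interval instead.

## What the simulation does and does not show

The plant is an idealised first-order mass balance with a calibrated flow
and leak; real incubators have door events, fan mixing transients,
pressure-regulator drift and discrete sensor update intervals that this
model smooths over. Passing stability envelopes here demonstrates that
the *control logic* — thresholds, pulse durations, lockouts, safety
gating — behaves as specified on a plant of realistic scale, not that a
particular physical incubator will achieve the same numbers. Quantities
that depend on uncharacterised hardware (the exact bang-bang fluctuation
magnitude, PID settling shape) are treated qualitatively, as ordering and
bound properties, never as point targets.

## Numerical choices

- Exact exponential updates for plant and sensor lag; no Euler error.
- Ties: a reading exactly at the TC threshold closes the valve; a TAC
  deficit exactly at the hysteresis band takes no action; exactly at the
  far/near boundary uses the short pulse.
- Percent metrics round half-up (`decimal`), not banker's.
- Integer-ppm readings are compared exactly for stuck detection.
- Degenerate configurations (zero flow and zero leak) are accepted and
  reported as the ambient fixed point rather than rejected.
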