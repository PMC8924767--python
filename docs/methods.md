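# Methods

## The model

`hevsim` co-simulates three coupled subsystems at a fixed physics timestep
(default 1 ms), with the controller executing at its own period (default
10 ms, mirroring an embedded control rate):

**Gas path.** The buffer is a rigid volume whose state is (absolute
pressure, temperature, O2 mole fraction); it is accounted in moles
throughout. Valves obey a linear conductance law Q = c·x·(p_up − p_down)
with the flow referenced to outlet conditions, behind a first-order
actuator lag (5 ms for the proportional inhale valve, 2 ms for the on/off
solenoids, with a seating snap below 0.1% opening so a closing valve
reaches exactly zero). A linear law rather than an orifice √Δp law is
adequate at the small pressure heads on the patient side and keeps the
closed loop analytically checkable; the law is isolated behind `ValveSpec`
so an orifice law can be swapped in. While the buffer delivers (inlets
closed) its energy balance d(nT) = γ(T_in·ṅ_in − T·ṅ_out)dt reduces to the
reversible adiabat, which is what the volume estimator inverts; refills are
treated isothermally (slow, wall-coupled), and the buffer re-equilibrates
to ambient temperature when delivery ends. Gas is ideal with γ = 1.4 for
both species (both diatomic; composition dependence neglected).

**Airway.** The circuit node is volumeless: with every element linear, the
airway pressure is the closed-form solution of the node flow balance each
step. The exhale path is an ideal threshold (PEEP relief) element in series
with the on/off exhale valve — the prototypes of this device class used a
manual PEEP valve. The leak sits at the airway (mask/circuit side,
downstream of the proximal sensor), conductance presets
none/weak/medium/strong = 0/0.5/1/2 (l/min)/cmH2O, chosen so the strong
setting leaks ≈10 l/min at PEEP 5.

**Patient.** A linear single-compartment lung: flow = (P_aw − P_alv)/R,
P_alv = V/C + P_mus. Compliance is constant by design (the physical test
lung's nonlinear P–V physiology is out of scope; all quantitative bench
conditions are quoted at fixed C). Spontaneous effort is a muscle-pressure
ramp at −(P0.1/0.1) cmH2O/s for the scripted inhale duration, then a 300 ms
linear release — short enough not to overlap the pressurization metric
windows. Effort onsets are exported as ground truth for the synchrony
metrics.

## Control

The breathing loop is a finite state machine (buffer purge/fill states,
pre-inhale, inhale, pause, exhale ± refill). A breath starts on the
mandatory-rate timer or a patient trigger; triggering is refractory during
inhalation and pause, and a breath only starts once the buffer holds 90% of
its gauge refill target and the buffer valves are seated.

**Pressurization.** A discrete PID (derivative on measurement, conditional
anti-windup, output clamped to [0,1]) drives the proportional inhale valve.
The rise-time presets combine a gain triple with a linear inspiratory
setpoint ramp (0/150/300 ms). The ramp is the standard mechanism by which
pressure controllers realize a clinician-selectable rise time; pure gain
triples could not reach a ~300 ms 95% rise on this quasi-static plant (the
achievable range capped near 210 ms across the stable gain region, measured
with `scripts/tune_pid.py`). The frozen presets give 95% rise times of
roughly 31/155/290 ms on the nominal lung. The integral resets at each
inhale start: pressurization restarts from a closed valve every breath.

**PEEP support and triggering.** During idle exhalation the PID valve
regulates the airway at PEEP − 0.1 cmH2O. This is what makes a flow
trigger physically possible on a threshold-PEEP circuit: an inspiratory
effort dips the airway below PEEP and the PID supplies the flow the
proximal sensor detects. The 0.1 cmH2O deadband keeps sensor noise from
being amplified into real valve flow (noise-driven openings were the one
observed autotrigger mechanism); it was chosen as the smallest margin that
left five minutes of noisy passive ventilation trigger-free while keeping
the leak-on/leak-off metric shift well inside 10%.

The trigger itself follows the device's published rule: the window opens at
the first sample whose magnitude has decayed to 10% of the peak exhale flow
(or, when no exhalation has been seen yet — start of ventilation, PSV — it
arms 0.5 s into the idle phase); the expected flow is a least-squares line
over the trailing 500 ms excluding a 20 ms guard gap; the measured flow is
the mean over that guard gap, and the baseline is evaluated at the guard
gap's centroid so a purely linear flow trend can never look like an effort.
The decision `corrected flow > threshold` is evaluated at the sensor rate
(1 kHz) and invokes the control step immediately, like an interrupt, so
trigger latency reflects detection physics rather than 10 ms control-grid
aliasing. Averaging over the guard gap is the minimal smoothing consistent
with that window layout: a raw-sample comparison autotriggers at the
default noise level (σ_flow = 0.3 l/min against a 0.5 l/min threshold).

**Oxygen mixing.** During each refill the scheduler computes the O2/air
partial-pressure split that lands the post-fill mole fraction on the FIO2
target; when even a full single-species refill cannot reach it, the buffer
is purged to atmosphere first (O2-first for upward steps, air-first for
downward ones, the latter mirroring the device's "reverse procedure").
The buffer valves are interlocked so only one moves gas at a time; every
fill/purge is therefore a pure-species segment whose pressure endpoints
carry the complete mole balance, and the event-replay FIO2 calculation
agrees with the gas model to machine precision (the 1e-9 contract).
Fill cutoffs anticipate the actuator tail (ṅ·R·T/V·τ) so overshoot stays
below ~1 mbar; residual error is absorbed by the next breath's plan.

**PRVC** multiplies ΔP toward the volume target with per-breath steps
capped at 3 cmH2O (monotone on a linear lung). **PSV** cycles to exhalation
when inspiratory flow falls below 25% of its peak, with a 3 s backup.
**CPAP** keeps the air inlet open (bang-bang around the buffer target) and
the PID holding a constant pressure; CPAP is air-only in this
implementation. The safety loop raises debounced (≥100 ms) limit alarms
for pressure, plus per-breath volume/FIO2/rate checks, obstruction
(near-zero volume at full pressurization) and leakage (exhaled < 50% of
inhaled), mapped to high/medium/low priorities.

## Derived measurements

Delivered volume is reported two ways per breath: the trapezoidal integral
of positive proximal flow over the inhale phase, and the buffer-drop
calculation `Δn·R·T_amb/P_amb` with the adiabatic endpoint temperatures.
All reported flows and volumes are referenced to ambient conditions
(1013 mbar, 293 K), not BTPS. Occlusion readouts (plateau, intrinsic PEEP)
average the final half of the occluded window and flag settling when the
peak-to-peak variation of that half exceeds 0.5 cmH2O; static compliance is
VT/(plateau − total PEEP). The O2 sensor is a first-order lag (τ = 1.5 s,
consistent with a response time under 4 s) with 0.5% O2 Gaussian error.

## Buffer sizing and defaults

Defaults: 25 l buffer filled to 200 mbar gauge; supplies at 2 bar gauge;
inlet conductance 0.25 (l/min)/mbar (refill after a 500 ml breath ≈ 0.15 s,
always < 1 s), inhale valve 2 (l/min)/mbar (peak deliverable flow ≈ 300
l/min at a 35 cmH2O airway), purge 12 (l/min)/mbar. The buffer must feed
the worst supported breath — high ΔP plus a strong 1 s effort on a
compliant linear lung demands ~3.4 l ambient-equivalent — while staying
above the 45 cmH2O airway ceiling; 25 l × 200 mbar holds ≈5 l. A 500 ml
breath still drops the buffer ~20 mbar, well resolved by the estimator.
Ambient conditions default to 1013 mbar / 293 K.

## What the synthetic bench does and does not show

The scenario generator reproduces the published bench conditions: the
nominal patient (C = 50 ml/cmH2O, R = 5 cmH2O/(l/s)) and the 10–100 × 5–50
grid; the trigger matrix (ΔP ∈ {10,15,20,25} × P0.1 ∈ {2,4}, threshold
0.5 l/min, efforts at 12/min); leak series; the FIO2 program (95% then 50%
at 15 breaths/min); and the pressurization sweep (15–45 cmH2O on a
20 ml/cmH2O lung, 1.5 s inhale + 0.5 s pause). Sensor noise defaults to
Gaussian σ = 0.1 cmH2O (pressure) and 0.3 l/min (flow), seeded; runs are
bit-deterministic given the scenario and seed.

A linear, volumeless-airway, ideal-valve simulator has no valve dead
time, sensor electronics, tubing compliance or humidity, so its absolute
trigger latencies (~20 ms) and pause accuracies (≈0) are better than any
physical device; the meaningful claims are the bounds and invariants
(accuracy < 3%, TDT/TPM ≤ 150 ms, PTP ≤ 0.3 cmH2O·s, leak shift ≤ 10%,
FIO2 within 5%, refill < 1 s, peak flow ≥ 120 l/min, mole conservation,
estimator agreement), all of which the test suite checks end to end.
Passing them shows the control logic and gas accounting are sound, not that
a physical build would achieve these latencies. The linear lung also means
strong scripted efforts draw unrealistically large tidal volumes (no
volume saturation), which drove the buffer sizing above.

## Numerical choices

Explicit Euler at 1 ms for lung and buffer (stability margins ≥100× for
all default conductances); the buffer step refuses dt > 10 ms. The
adiabatic Euler energy balance agrees with the closed-form adiabat to
~1e-5 over a delivery stroke, so the estimator cross-check (≤1% against
the valve-flow integral) is discretization-limited, not model-limited.
Trigger regression uses O(1) rolling sums identical to the batch
least-squares formula. Crossing times in the metrics are linearly
interpolated between samples; metric integrals are trapezoidal. Degenerate
inputs fail loudly: zero airway resistance, buffer depletion during
delivery, occlusion windows outside the trace and plateau ≤ PEEP all raise
typed errors rather than returning numbers.
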