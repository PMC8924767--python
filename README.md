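# hevsim

A closed-loop digital twin of a buffer-based, pressure-controlled ICU
ventilator, coupled to a configurable single-compartment mechanical patient.

The device class it models decouples the gas path into two stages through an
intermediate pressure **buffer**: air and oxygen are admitted sequentially
into the buffer between breaths (passive mixing, filled to a target
pressure), and a proportional inhale valve under PID control delivers each
breath from the buffer to the patient. This architecture makes two derived
measurements possible that `hevsim` reproduces in full:

* **tidal volume from the buffer pressure drop** — with the inlets closed
  during delivery, the ideal gas law gives the moles delivered from
  `p1 → p2` along the adiabat `T2 = T1 (p2/p1)^((γ−1)/γ)`:

      Δn = (V_buf / R) · (p1/T1 − p2/T2),   VT = Δn·R·T_amb / P_amb

  an estimator that is completely independent of the proximal flow sensor;

* **FIO2 by calculation** — every fill and purge of the isolated buffer is a
  pure-species event, so a running mole balance over the recorded events
  yields the delivered O2 fraction exactly, with the (slow, zirconia-cell)
  O2 sensor only confirming it.

On top of the gas path, the package implements the ventilator's control
stack and its qualification battery:

* **modes**: PC-A/C, PC-A/C-PRVC (per-breath ΔP adaptation toward a volume
  target), PC-PSV (flow-cycled pressure support) and CPAP;
* **flow trigger**: the trigger window opens when exhale flow decays to 10%
  of its peak; the measured flow is compared against a least-squares
  regression baseline, and a breath starts when the corrected flow exceeds
  the clinician threshold (0.2–20 l/min);
* **patient model**: linear single-compartment lung (`C` 10–100 ml/cmH2O,
  `R` 5–50 cmH2O/(l/s)), airway leak presets, and scripted spontaneous
  efforts parameterized by the occlusion pressure P0.1 (ramp at −P0.1/0.1
  cmH2O/s), providing ground-truth effort onsets;
* **synchrony metrics**: TPM, TDT, PD, PTP and PTP300%/PTP500%, plus
  pause-phase pressurization accuracy and 95% rise time;
* **safety loop**: debounced pressure/volume/FIO2/rate limit alarms,
  obstruction and leakage detection, three-level priorities.

## A worked example

```
python examples/trigger_qualification.py
```

runs one cell of the trigger-qualification matrix — spontaneous high-effort
breaths (P0.1 = 4 cmH2O) against PC-A/C at ΔP = 20 cmH2O, threshold
0.5 l/min — and prints, per effort:

```
12 of 12 efforts triggered a breath

 TPM[ms]  TDT[ms]  PD[cmH2O]  PTP[cmH2O s]  PTP300[%]  PTP500[%]
    18.0     18.5       0.56        0.0058       95.7       97.1
    ...
mean TDT 18.4 ms -- commercial ICU ventilators span roughly 90-250 ms, and
anything under 150 ms is considered imperceptible to the patient.
```

TPM is the time from effort onset to the airway-pressure minimum, TDT the
total trigger latency until pressure is restored to baseline, PD the dip
depth the patient generated, PTP the pressure-time product of that effort,
and PTP300/500 the pressurization actually delivered in the 300/500 ms
after triggering as a percentage of an ideal square pressurization. The
simulated controller, free of valve dead time and sensor electronics,
triggers in ~18 ms — comfortably inside every commercial envelope.

Other examples: `run_nominal_patient.py` (dual tidal-volume estimators on
the nominal patient), `oxygen_mixing.py` (FIO2 step program with
purge-and-refill convergence), `pressurization_and_rise_time.py` (target
sweep and rise-time presets).

A thin CLI wraps the same library for shell use:

```
hevsim presets
hevsim run --preset mhra_nominal --out out/
hevsim metrics --timeseries out/timeseries.csv --onset 3.0 --delta-p 20 --out m.csv
```

## Scenarios

Everything a run needs lives in one validated YAML document (ventilator
settings, lung mechanics, effort schedule, buffer hardware, sensor noise,
timing, scheduled occlusion maneuvers and setting changes); unknown keys are
rejected. The preset registry (`hevsim.preset`) reproduces the standard
bench matrices: `mhra_nominal`, `patient_grid`, `table1_matrix`,
`leak_series`, `fio2_program`, `pressurization_sweep`.

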