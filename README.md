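# frostprobe

A toolkit for impedance-probe monitoring of volumetric ice content in
woody-plant branches during overwintering. It implements:

- **`frostprobe.core_model`** — forward physics of the probe: three-phase
  (gas/liquid/solid) dielectric mixture impedance and the reflection-voltage
  transfer function of the coaxial measurement line, plus its inverse.
- **`frostprobe.calibration`** — ordinary-least-squares fit, persistence and
  application of the linear voltage → volumetric-water-content calibration
  (per species/instrument).
- **`frostprobe.freeze_thaw`** — the deployed pipeline: frozen-state
  detection from ambient temperature, pre-freeze baseline water content,
  volumetric ice content `delta = (theta0 - theta_x) * rho_ice/rho_water`,
  the absolute ice freeze–thaw rate (%/min) and its summary statistics.
- **`frostprobe.characterization`** — sensor figures of merit: sensitivity
  factor (%/V), resolution, ± accuracy, environmental error bounds, radial
  energy index, conductivity response and ring-electrode coverage area.
- **`frostprobe.synthetic_data`** — a simulator standing in for the hardware:
  chamber ramp / diurnal temperature protocols, first-order liquid↔ice phase
  relaxation with known ground truth, and noisy voltage synthesis (via the
  calibration line or the full physics chain).
- **`frostprobe.io` / `frostprobe.cli`** — CSV/JSON readers and writers and
  the command-line entry points.

## CLI

```sh
# print the sensor characterization report (also available as --json)
frostprobe characterize

# generate a synthetic chamber run (readings.csv + ground_truth.csv)
frostprobe simulate --out-dir sim/ --seed 7

# fit a calibration from (voltage_v, theta_pct) pairs
frostprobe calibrate --pairs pairs.csv --species juniperus --out cal.json

# run the freeze–thaw pipeline (records.csv + summary.json)
frostprobe process --readings sim/readings.csv --calibration cal.json --out-dir out/
```

Readings CSV columns: `timestamp` (ISO-8601 UTC), `voltage_v`, `temp_c`.
Output records CSV columns: `timestamp, theta_pct, delta_pct,
sigma_pct_per_min, frozen`; the summary JSON carries `mean, sd, min, max`
of the freeze–thaw rate in %/min.

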