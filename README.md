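# cpbsim

Simulator and control library for automatic regulation of arterial flow and
venous-reservoir level in a cardiopulmonary-bypass (CPB) circuit.

The plant couples a static exponential tube-crush map (occluder opening → flow)
with first-order-plus-dead-time actuator dynamics and a reservoir mass balance.
The controller is a nested cascade: a two-degree-of-freedom model-matching flow
loop (static-map-inverting feedforward + feedback PID tracking a first-order
reference model) sits inside an I-PD level regulator whose output corrects the
venous-flow-derived reference. Sensor emulation adds seeded Gaussian noise, a
low-pass filter on flow signals, and quantization on the level readout.

## Layout

| module | contents |
|---|---|
| `cpbsim.plant` | occluder statics + inverse, FOPDT actuator, reservoir, sensors, parameter presets |
| `cpbsim.identification` | sweep/step fixture generators, nonlinear least-squares fits of the static and dynamic constants |
| `cpbsim.control` | reference shaping, 2-DOF flow controller, I-PD level controller, nested cascade |
| `cpbsim.scenarios` | trial runner, perfusion (400 s) and disturbance (200 s) protocol presets, seeded batches |
| `cpbsim.metrics_io` | J_Q%/J_L% metrics, trajectory CSV I/O, YAML config loading |
| `cpbsim.cli` | `cpbsim run | identify | metrics` |

## CLI

```sh
# 10 seeded perfusion trials with default presets, per-trial CSVs + summary
cpbsim run --scenario perfusion --preset default --seed 1 --trials 10 --out out/

# ablation: remove the level-control unit
cpbsim run --scenario disturbance --seed 1 --no-level-control --out out_ablated/

# fit plant constants from sweep/step CSVs (opening_pct,flow_lpm / time_s,response)
cpbsim identify --sweep sweep.csv --step step.csv --out params.yaml

# evaluate a logged trial
cpbsim metrics --in out/trial_seed1.csv --target-level 0.45
```

Plant, sensor, and controller settings can be overridden with
`--config cfg.yaml` (sections `plant`, `sensor`, `control`; unknown keys are
rejected). Trajectory CSVs use the fixed header
`time_s,q_venous,q_ref,q_arterial,occ_cmd,occ_eff,level_L,level_meas_L,disturbance`.

## Notes

- The plant parameter presets (`glycerin-like`, `blood-like`) are synthetic
  stand-ins with plausible magnitudes; fit your own from data via
  `cpbsim identify`.
- Every trial is fully reproducible from `(config, seed)`; batches use
  consecutive seeds.
- An emptied reservoir is flagged in the result (hazard condition), not raised,
  so ablation runs complete and remain measurable.
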