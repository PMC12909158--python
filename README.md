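# evlpsim

A lumped-parameter ventilation–perfusion simulator for *ex vivo* lung
perfusion (EVLP). The model couples:

- a pressure-controlled **ventilator** (linear inspiratory ramp from PEEP to
  the plateau pressure implied by the set tidal volume and static compliance,
  instantaneous expiratory release),
- single-compartment **lung mechanics** (airway resistance in series with an
  elastic alveolar volume),
- alveolar–capillary **gas exchange** for O2 and CO2 with anatomical
  dead-space rebreathing, lung metabolism and bicarbonate buffering of CO2,
- a **perfusion circuit** in which the perfusate splits between a gas-exchanging
  capillary compartment and an intrapulmonary shunt, mixing in the left atrium.

The primary outputs are the left-atrial partial pressures P_LA_O2 and
P_LA_CO2. On top of the simulator the package provides:

- **calibration**: RMSE against monitor records, mono-exponential
  step-response fitting (time constant τ of the oxygenation challenge), and
  automated tuning of the four intrinsic parameters (airway resistance,
  anatomical dead space, alveolar dead-space fraction, shunt fraction),
- **sensitivity**: Morris elementary-effects screening (seeded randomized
  trajectories on a 10-level grid) of the steady outputs and τ,
- **uncertainty**: Monte-Carlo propagation of sensor-accuracy input noise
  through static and dynamic simulations,
- **clinical_io**: CSV monitor-record reading/writing and synthetic
  oxygenation-challenge record generation (3-s grid, per-channel sensor
  noise).

## Python API

```python
import evlpsim as ev

cfg = ev.default_config()                      # Table defaults, canonical units
state, means = ev.run_to_steady_state(cfg)     # cyclic steady state
result = ev.simulate(cfg, 30.0, initial=state) # 100 Hz time series
result.to_dataframe().to_csv("run.csv", index=False)

# oxygenation challenge: FiO2 step to 1.0 at t = 180 s
sched = ev.InputSchedule.step("fio2", 180.0, 1.0)
challenge = ev.simulate(cfg, 900.0, schedule=sched, initial=state)

# studies
uq = ev.run_monte_carlo_static(cfg, n=10_000, seed=42)
scores = ev.run_sensitivity_study(cfg, trajectories=75, seed=42)

# synthetic record -> intrinsic-parameter estimation
rec, truth = ev.generate_record(ev.ChallengeScenario(seed=7))
fit = ev.tune_intrinsic(rec, seed=0)
```

## CLI

```bash
evlpsim simulate --duration 30 --out result.csv
evlpsim simulate --config cfg.yaml --fio2-step 180 1.0 --duration 900 --out challenge.csv
evlpsim synth --seed 7 --out record.csv
evlpsim calibrate --record record.csv --out calib.json
evlpsim morris --trajectories 75 --levels 10 --seed 42 --out scores.csv
evlpsim montecarlo --mode static --n 10000 --seed 42 --out uq.csv
```

Config files (JSON or YAML) mirror the monitor conventions (compliance in
mL·cmH2O⁻¹, flow in L·min⁻¹, pH); unknown keys are rejected. Record CSVs
use a uniform 3-s time grid with columns
`time_s, vt_l, t_insp_s, t_exp_s, peep_cmh2o, fio2, cstat_ml_per_cmh2o,
q_l_per_min, ph, ppa_o2_mmhg, ppa_co2_mmhg, pla_o2_mmhg[, pla_co2_mmhg]`.

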