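# actimet

Activity-type-aware estimation of physical-activity energy expenditure (EE)
from dual-site (thigh + hip) tri-axial accelerometry, with a built-in
protocol simulator, leave-one-subject-out calibration and a full
method-agreement statistics suite.

## The problem

Counts-per-minute (CPM) regressions map accelerometer output to metabolic
cost, but a single CPM→MET line cannot hold across activity types: cycling
produces almost no hip counts at 7 MET, and stair walking produces
walking-like counts at much higher cost. The approach implemented here
first recognises the activity type of every second from thigh and hip
signals (posture from segment inclination, movement from signal SD), then
applies an **activity-specific** linear calibration

    MET = a_activity · CPM + b_activity            (walking, running, stairs)
    MET = a · CPM + c · sex + b                     (cycling; sex: 1 = female, 2 = male)

with fixed MET values for lying, sitting and standing, and the walking line
as fallback for unrecognised movement ("move"). Calibration is
**leave-one-subject-out (LOSO)**: the model applied to a subject is fit on
every other subject's standardized-protocol data, so estimates are honest
out-of-sample predictions. Agreement against reference EE is summarised by
the mean-square error decomposition

    MSE = (N−1)/N · s² + z̄²

(s = SD, z̄ = mean of the between-method differences), paired t tests,
Pearson R², ICC(2,1) and Bland–Altman limits of agreement (z̄ ± 1.96 s).

MET is used operationally as kcal per kg of (participant + 1.6 kg worn
calorimeter) per hour. Protocol intensities come from the ACSM metabolic
equations, e.g. running VO₂ = 0.2·speed + 0.9·speed·grade + 3.5 mL/kg/min.

Because no public recordings exist for this protocol, the package ships a
synthetic-data generator (`actimet.synthetic_data`) that simulates the
standardized calibration protocol (lying/sitting/standing + three
intensities each of treadmill walking and running, ergometer cycling and
stair walking) and the self-paced 30-min semi-standardized protocol, with
ground-truth EE generated from published activity-specific regressions —
so every stage of the pipeline is exercisable and testable end to end.

## Worked example

Run the full pipeline on a simulated four-subject study:

```python
from pathlib import Path
from actimet.cli_io import (RunConfig, simulate_run, classify_run,
                            calibrate_run, estimate_run, validate_run)

run = Path("demo")
cfg = RunConfig(seed=1, n_female=2, n_male=2)
simulate_run(run, cfg)     # raw signals, HR, reference EE per subject
classify_run(run, cfg)     # counts, cadence, per-second activity labels
calibrate_run(run, cfg)    # LOSO CPM→MET regressions per site
estimate_run(run, cfg)     # per-epoch EE per method
df = validate_run(run, cfg)
print(df[["method", "period", "mean_measured", "mean_estimated",
          "mse", "percent_bias"]].round(3).to_string(index=False))
```

prints

```
       method     period  mean_measured  mean_estimated    mse  percent_bias
  AGhip+Acti4   physical          6.462           6.052  0.304        -6.342
  AGhip+Acti4 stationary          1.252           1.341  0.014         7.163
  AGhip+Acti4      total          4.725           4.482  0.113        -5.150
AGthigh+Acti4   physical          6.462           6.177  0.237        -4.410
AGthigh+Acti4 stationary          1.252           1.318  0.012         5.314
AGthigh+Acti4      total          4.725           4.558  0.086        -3.552
     ActivPAL   physical          6.462           3.091 11.459       -52.172
     ActivPAL stationary          1.252           1.115  0.024       -10.927
     ActivPAL      total          4.725           2.432  5.291       -48.530
```

Each row compares one estimator against the simulated reference EE over the
semi-standardized session's stationary period (first 10 min), physical
period (last 20 min) and the full 30 min. The activity-type-aware thigh
method tracks the reference closely (physical-period MSE 0.24 MET², bias
−4%), while the fixed-MET + cadence posture-monitor estimator, which knows
nothing about running, cycling or stairs intensity, underestimates the
physical period by half — the qualitative pattern such validation studies
report.

The same pipeline is available from the shell:

```sh
actimet simulate demo --seed 1
actimet classify demo && actimet calibrate demo
actimet estimate demo && actimet validate demo
actimet report demo          # table + Bland–Altman plots
```

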