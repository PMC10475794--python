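# wearssm

Personalized dynamical modeling of multimodal wearable biosensor data.

`wearssm` fits continuous-time linear Gaussian state-space models to
per-participant streams from a continuous glucose monitor (CGM, ~15-min
sampling over ~14 days), a combined activity/heart-rate sensor (activity
counts, HR, HRV as RMSSD) and a timestamped meal log. Three nested models
are fitted with exact Kalman-filter likelihoods and Hamiltonian Monte
Carlo:

1. **Glucose model** — a 2-D stochastic differential equation with
   negative feedback; meals inject impulse responses (one height
   parameter per unique meal annotation) and a 24-h sinusoid models the
   circadian baseline. Derived metrics: response half-life, damping
   coefficient (under/over/critically damped), mean meal height,
   circadian amplitude and peak time, explained-variance decomposition,
   and a BIC comparison against a no-circadian variant (cutoff 2 ln 10).
2. **Cardio model** — coupled activity → HR / HRV dynamics with
   correlated HR–HRV fluctuations, per-channel circadian baselines, and
   conditional-prediction explained-variance tables.
3. **Combined model** — a 5-D model feeding activity, HR and HRV into the
   glucose dynamics through three unconstrained coefficients, staged on
   locked cardio posterior means; reports coupling posteriors, the
   added explained glucose variance, the weighted aux sum and its
   cross-correlation with glucose.

A first-class synthetic-data module generates device-realistic
participants (irregular meal schedules, exercise bouts, measurement
noise, block missingness) with known ground truth, and drives the
parameter-recovery studies used for acceptance testing.

## CLI

```bash
# simulate a participant from a preset scenario
wearssm simulate --preset high-circadian --seed 1 --out runs/p1/data

# dataset summary (coverage, meal-log adherence)
wearssm report --data runs/p1/data

# fit Model 1 (GP detrend, MAP init, two-stage HMC), then inspect metrics
wearssm fit --data runs/p1/data --model 1 --out runs/p1/fit1 --seed 1
wearssm metrics --report runs/p1/fit1/model1_report.json

# circadian vs no-circadian BIC comparison
wearssm fit --data runs/p1/data --model 1 --no-circadian --out runs/p1/fit1nc --seed 1
wearssm compare --full runs/p1/fit1/model1_report.json --reduced runs/p1/fit1nc/model1_report.json

# Model 2, then Model 3 staged on the locked Model-2 posterior means
wearssm fit --data runs/p1/data --model 2 --out runs/p1/fit2 --seed 1
wearssm fit --data runs/p1/data --model 3 --model2-report runs/p1/fit2/model2_report.json \
        --out runs/p1/fit3 --seed 1
```

Presets: `high-circadian`, `underdamped`, `exercise-spiker`,
`null-coupling`. Default HMC settings are reduced for desk-scale runs;
`--full-protocol` switches to the reference 4 chains × 10,000 retained
draws (burn-in 10,000, 5 leapfrog steps, target acceptance 0.75).

Gradients for HMC are finite differences (no autodiff dependency), so
per-iteration cost grows with the parameter count: Model 1 fits run in
well under a minute at reduced settings, while full-length Model 2/3
fits (17–21 parameters over 14 days of data) take substantially longer —
budget accordingly or shorten the record/draw counts.

## Package layout

| module | contents |
| --- | --- |
| `wearssm.datamodel_io` | sensor/meal domain types, CSV dialect reader/writer, adherence and label metrics |
| `wearssm.preprocess` | squared-exponential GP detrending (l = 48 h), SD normalization, RMSSD inversion |
| `wearssm.ssm_core` | exact SDE discretization, masked Kalman filter/smoother, likelihoods, simulation |
| `wearssm.glucose_model` | Model 1, meal impulse responses, half-life/damping/circadian metrics |
| `wearssm.cardio_model` | Model 2, conditional predictions, explained-variance tables |
| `wearssm.combined_model` | Model 3, coupling variants, weighted aux sum, cross-correlation |
| `wearssm.inference` | priors/transforms, BFGS MAP, two-stage HMC, BIC, explained variance, R-hat |
| `wearssm.synthetic` | scenario specs, participant generator, recovery studies |
| `wearssm.cli` | `simulate` / `fit` / `metrics` / `compare` / `report` commands |
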