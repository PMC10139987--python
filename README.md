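# ventpkpd

Physiology-based PK/PD modelling of opioid-induced respiratory depression
(OIRD), built around the hypercapnic ventilatory response (HCVR).

Opioids depress breathing, but "breathing" is not one number: resting
ventilation, resting end-tidal PCO2, the CO2 recruitment threshold, the
HCVR slope and the extrapolated ventilation at a fixed PCO2 all respond to
the drug with different potency and speed, because resting (poikilocapnic)
measurements let arterial CO2 rise and partially offset the depression
through the chemoreflex loop. This package implements the full modelling
chain needed to compare these biomarkers quantitatively in experimental
opioid studies, and ships a synthetic-trial generator so every stage can
be exercised and validated without human data.

## The model

**Pharmacokinetics.** A two-compartment model with zero-order oral
absorption over `Tabs` hours: apparent volumes `V1`, `V2`, elimination
clearance `CL`, intercompartmental clearance `CL2`, all scaled linearly
to a 70-kg reference. Concentrations are in mg/L. Population estimation
is two-stage: a joint proportional-error fit with shared structural
parameters and subject-specific CL, then robust summaries (median,
between-subject variance of log CL, bootstrap SEs).

**CO2 loop.** Alveolar and tissue mass balances with a brain-tissue lag
and a hinge ventilation law,

```
VALV * dPa/dt = (VE - VD)(PI - Pa) + lam1*Q*(Pv - Pa)
VTS  * dPv/dt = Q*(Pa - Pv) + lam2*VCO2
tau  * dPb/dt = Pa - Pb
VE = baseline_VE + S * H(Pb - VRT),    H(x) = delta*log(1 + exp(x/delta))
```

with end-tidal PCO2 identified with arterial/alveolar PCO2. A
proportional-integral controller on inspired CO2 emulates dynamic
end-tidal forcing (steps of +4.5/9/13.5 mmHg above resting). At steady
state the loop obeys the metabolic hyperbola
`(VE - VD)(Pa - PI) = lam1*lam2*VCO2`.

**Biomarkers.** Each forced run is fitted with the kinetic forward model
to give resting VE, resting PETCO2, VRT and slope S, from which
`VE55 = baseline_VE + S*H(55 - VRT)` and the classical apneic threshold
`B = 55 - VE55/S` are derived.

**Pharmacodynamics.** Biomarker time courses follow a sigmoid EMAX law in
the effect-site concentration `Ce` (first-order lag of plasma with
half-life `h1/2`, `ke0 = ln2/h1/2`): depressed biomarkers as
`e0*C50/(C50 + Ce)`, elevated ones (resting PETCO2, VRT) as the
reciprocal form. Per-subject baselines are profiled in closed form;
shared-vs-separate dynamics across biomarkers are compared with a
Gaussian likelihood-ratio test.

## Worked example

Simulate one noise-free HCVR run at the population medians and fit it
back:

```python
from ventpkpd import (HCVRParameters, PhysiologyConstants,
                      simulate_run, fit_run)

truth = HCVRParameters(baseline_ve=8.3, resting_petco2=41.0,
                       vrt=44.0, slope_s=2.5)
rec = simulate_run(truth, PhysiologyConstants())
fit = fit_run(rec)
print(fit.params, fit.ve55, fit.apneic_threshold)
```

prints (formatted):

```
baseline VE    = 8.30 L/min
resting PETCO2 = 41.0 mmHg
VRT = 44.0 mmHg, S = 2.50 L/min/mmHg
VE55 = 35.8 L/min, apneic threshold B = 40.68 mmHg
```

i.e. the estimator recovers the generating parameters exactly, and the
derived VE55 is the ventilation the fitted curve extrapolates to at an
effect-site PCO2 of 55 mmHg.

The full study-scale run — 24 simulated subjects (12 per 100/200-mg
arm), hourly HCVRs for 8 h and hourly plasma samples, fitted end to end:

```sh
ventpkpd paper-run --seed 1 --no-dynamics
```

```
pop_cl                   206.9
baseline_resting_ve      8.142
baseline_resting_petco2  41.12
baseline_vrt             43.22
baseline_slope           2.608
baseline_ve55            35.6
c50_resting_class        0.795
c50_slope                0.202
c50_ve55                 0.1087
h_half_resting_class     1.271
h_half_slope             0.8024
h_half_ve55              1.015
```

The recovered potencies reproduce the central finding: VE55 is the most
sensitive biomarker (smallest C50), followed by the slope, with the
resting-class biomarkers roughly an order of magnitude less sensitive and
slower (larger `h1/2`).

The CLI also provides `simulate` (write a trial bundle of CSVs),
`fit` (fit a bundle and write `table1.csv`, `fig4f.csv`,
`recovery_report.csv`) and `report` (render the tables as text).

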