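# Methods

This note documents the models, the synthetic-study generator, the
estimation procedures and the numerical and design choices behind
`ventpkpd`. Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`.

## Pharmacokinetic model

Oral dosing is modelled as a zero-order input of the whole dose into the
central compartment over the absorption duration `Tabs` (no absorption
compartment), followed by linear two-compartment disposition. Parameters
are apparent oral quantities — bioavailability is unidentifiable in an
oral-only design and is fixed to 1, so reported `V` and `CL` are `V/F`
and `CL/F`. Volumes and clearances scale linearly with `weight/70`; an
allometric law would add parameters the data cannot inform.

The solution is the closed-form bi-exponential convolution of the
zero-order input (degenerate one-compartment case handled separately),
verified in the tests against an adaptive ODE integration at rtol 1e-6
and against a dose-conservation quadrature (integral of `CL*Cp(t)`
returns the dose to 0.5%).

**Units.** Plasma concentration is carried as mg/L (= ug/mL).
The defaults place a 200-mg dose peak near 0.26 mg/L, which is the scale
on which the pharmacodynamic potencies (C50 0.81 / 0.23 / 0.08) produce
the moderate (25–70%) biomarker effects the model is meant to describe;
the same numerals on a ng/mL scale would saturate every response.

**Estimation** is deliberately two-stage rather than full nonlinear
mixed-effects: stage 1 is a joint least-squares fit in which `V1`, `V2`,
`CL2`, `Tabs` are shared across subjects and `CL` is subject-specific;
stage 2 takes the median of the individual `CL`s, the variance of their
logs as the between-subject variance, and nonparametric bootstrap SEs
over subjects. Acceptance of the package is defined by parameter
recovery, not by algorithm identity with any particular mixed-effects
implementation.

Two numerical points matter in stage 1:

- *Residuals are log-transformed.* Minimizing `(obs-pred)/pred` directly
  lets the optimizer shrink its own weights by inflating predictions,
  which biased recovered `CL` downward by up to ~10% in pilot runs;
  log-both-sides residuals remove that mechanism (for 12% proportional
  noise the two error models are nearly equivalent).
- *The absorption duration is profiled on a coarse grid* (0.6–2.4 h)
  before the free refinement, because `min(t, Tabs)` makes the objective
  kinked at the sample times and gradient descent from a single start
  reliably lands in local basins.

With hourly sampling 0–7 h the structural parameters sit in a very flat
likelihood valley: even noise-free data are interpolated to ~1e-10 by
parameter sets whose `CL` differs by ~2%. Population `CL` at study scale
is still recovered well within 10%; individual structural parameters
should not be over-interpreted. Wide plausibility bounds (V1 20–300 L,
V2/CL2 50–2000, Tabs 0.3–3 h) keep the valley from reaching degenerate
corners.

## CO2 chemoreflex loop

State variables are arterial, venous and brain-tissue PCO2. Constants
(defaults): lambda0 = 0.115 mmHg per mL CO2/100 mL blood, lambda1 = 10,
lambda2 = 100*lambda0 = 11.5 (enforced at construction), alveolar volume
3 L, dead-space ventilation 1.8 L/min, tissue distribution volume 10 L,
cardiac output 4 L/min, brain time constant tau = 2.5 min, hinge
smoothness delta = 0.1 mmHg. End-tidal PCO2 is reported equal to
arterial/alveolar PCO2; no alveolar–arterial gradient is modelled.

The tissue mass balance is implemented as `Q*(Pa - Pv) + lam2*VCO2`
(arterial minus venous). The alternative sign ordering would make venous
PCO2 sit *below* arterial at steady state, contradicting both physiology
and the lung equation; with this form the fixed point satisfies
`Pv - Pa = lam2*VCO2/Q` and the metabolic hyperbola
`(VE - VD)(Pa - PI) = lam1*lam2*VCO2`, which the tests verify to 1e-8
relative.

CO2 production `VCO2` is kept in the internal units defined by the
lambda bookkeeping and is never set directly: it is calibrated per
subject/run so that the closed loop rests exactly at the observed
(resting VE, resting PETCO2) pair. The calibration uses the full
ventilation law at the resting point — if the recruitment threshold sits
at or below resting PETCO2 the hinge term contributes to resting
ventilation — which keeps generator and estimator in the same model
family for every parameter combination the generator can produce.

**Dynamic end-tidal forcing** is idealized as a sampled-data
proportional-integral controller on inspired PCO2 (gains 10 mmHg/mmHg
and 5 mmHg/(mmHg*min), anti-windup, actuator clipped to [0, 90] mmHg),
updated once per integration substep. Achieved plateaus land within
0.15 mmHg of target at the defaults (tested against a 0.5-mmHg bound).
The protocol is 6 min of CO2-free resting breathing followed by steps of
+4.5, +9, +13.5 mmHg above resting, 7 min each; the printed step range is
6–8 min and 7 min is used as the midpoint. The +18-mmHg step is dropped
whenever the preceding steps exceed the 20-min cap — always, at the
7-min default — matching the protocol's three-to-four-step description.

**Integration** is a fixed-step classical RK4 at 0.25-s substeps in
numba-compiled kernels, with inspired PCO2 held constant within a
substep. The fastest loop time constant (alveolar washout) is a few
seconds, so 0.25 s is deeply resolved; the tests check agreement with an
adaptive LSODA reference at rtol 1e-8 and stability of 1-min block
averages under output-grid refinement. The fixed-step sampled-data
design was chosen over an adaptive solver because the per-run estimator
needs thousands of forward solves, and because it makes a simulated run
*exactly* reproducible by re-driving the model with the recorded
substep-resolution inspired trace — the noise-free estimator round trip
is then exact to machine precision rather than to solver tolerance.

## Per-run HCVR estimation

Observations are 1-min ventilation averages. The fit drives the loop
with the recorded inspired PCO2 (substep trace when available, minute
averages interpolated at midpoints after a CSV round trip), starts from
the resting steady state, and minimizes uniform-weighted least squares
over (baseline VE, VRT, S). Resting PETCO2 is taken directly as the mean
of the CO2-free resting minutes: the ventilation series alone cannot
identify the absolute PCO2 level, and the resting minutes measure it.
Together with calibrating `VCO2` from the *difference* between resting
end-tidal and inspired PCO2, this makes the estimator exactly
equivariant under a common shift of all PCO2 channels (tested).

Initialization is deterministic and data-driven: resting pair from the
pre-CO2 minutes, slope from an ordinary regression of the elevated
minutes, threshold from that line's intersection with resting VE. Runs
lacking 3 resting minutes or 2 distinct CO2 plateaus raise an
insufficient-excitation error; fits with the slope pinned at zero or a
non-converged optimizer are returned flagged, not silently.

Derived biomarkers: `VE55 = baseline + S*H(55 - VRT)` and the apneic
threshold `B = 55 - VE55/S` (undefined at S = 0). When VRT sits clearly
below 55 mmHg the hinge is effectively linear and VE55 equals the linear
extrapolation.

## Pharmacodynamics

Each biomarker follows `e0 * C50/(C50 + Ce)` (depressed: resting VE, S,
VE55) or `e0 * (C50 + Ce)/C50` (elevated: resting PETCO2, VRT), with the
shape factor fixed to 1 and `Ce` the effect-site concentration from a
first-order lag of plasma concentration, `ke0 = ln2/h_half`. The
elevated form is the reciprocal of the inhibitory one so that the
generator and the estimator are self-consistent for biomarkers that rise
under opioid; it doubles the biomarker at `Ce = C50`.

Fitting profiles the per-subject baselines in closed form (the model is
linear in `e0`) and optimizes log C50 and log h1/2 by bounded least
squares; residuals are weighted by per-biomarker SDs so biomarkers on
different scales can share one objective. The resting-class biomarkers
(resting VE, resting PETCO2, VRT) are fitted with one shared (C50,
h1/2) pair by default, mirroring their identical published dynamics; an
unconstrained mode exists for the model comparison. Shared versus
separate dynamics are compared with the scale-free Gaussian LR statistic
`n*ln(RSS0/RSS1)` against chi-square with 2*(groups-1) degrees of
freedom; under an equal-dynamics null the empirical type-I error at
alpha = 0.01 is conservative (0/100 in the test suite's reduced
simulation).

The effect-site lag is solved with an exact exponential integrator for
piecewise-linear input on a 0.01-h grid (0.005 h in the standalone
helper), implemented as an IIR filter.

## Synthetic study generator

The generator emulates the study design: 24 healthy adults, 12 per oral
dose arm (100/200 mg), weight ~ normal(74, 10) truncated to [57, 103] kg,
one pre-drug HCVR plus hourly HCVRs to 8 h, hourly plasma samples 0–7 h
with 12% proportional noise. Subject-level parameters are log-normal
around the population truth with the published between-subject
variances; the drug scales each subject's instantaneous baseline VE,
resting PETCO2, VRT and S through the per-pathway effect compartments
and EMAX laws, held constant within a ~27-min run (intra-run drug drift
is second-order at these half-lives). Run-level jitter uses the
published within-subject SDs; 1-min ventilation noise has SD 0.44 L/min
at the reference resting ventilation, scaling linearly with VE.

Two correlation choices are the package's own (the study publishes only
marginal variances):

- Subject-level log deviations of VRT and resting PETCO2 are drawn with
  correlation 0.9, and the run-level VRT jitter shares the resting-PETCO2
  jitter component (independent remainder sized to preserve the printed
  SD). Physiologically the recruitment threshold rides a few mmHg above
  each subject's resting operating point; independent draws would put
  VRT below resting PETCO2 in ~25% of subjects, versus ~3% with the
  correlated draws — rare dog-leg-free subjects remain representable and
  are handled by the hinge-aware calibration.
- All other deviations (CL, baseline VE, S, the three C50s) are drawn
  independently.

Infeasible run-level draws (baseline VE within 0.5 L/min of dead space,
non-positive slope) are redrawn up to 10 times before erroring.

VE55 is *emergent* in the generator: it is computed from the drugged
(baseline, S, VRT), not generated from its own EMAX pathway. Its
recovered potency is therefore a genuine composite prediction — at the
published truth values the pipeline recovers C50(VE55) ≈ 0.09–0.11 mg/L
against the published 0.08 — and the headline sensitivity ordering
C50(VE55) < C50(S) < C50(resting class) is reproduced in every tested
replicate. One model-implied discrepancy is documented rather than
hidden: in the dose-effect comparison (change in peak fractional effect
between arms) the generator puts VE55 slightly above S, whereas the
study's empirical ordering had S first; VRT and resting PETCO2 tie
exactly because they share one pathway by construction.

What passing tests do **not** show about real data: the generator
contains no breath-by-breath mechanics, no measurement artifacts or sigh
/apnea episodes, no assay LLOQ censoring, no dropout, no oxygen effects
(end-tidal O2 is assumed perfectly clamped), and its noise is Gaussian
with known SDs. Recovery results certify the estimation pipeline under
the stated statistical structure, not robustness to violations of it.

## Reproducibility and problem sizes

All randomness descends from one root seed through `SeedSequence`
spawning (one stream per subject); regenerating a trial with the same
seed is byte-identical. The acceptance script runs five full-trial
replicates (24 subjects, 216 runs each) and reports medians across
seeds; this size reproduces the study design exactly while keeping the
whole script at a few minutes on one CPU. The dynamics type-I simulation
uses a reduced design (2 biomarkers, 8 subjects, 100 replicates) for the
same reason.

## Known limitations

- The two-stage population PK intentionally forgoes shrinkage; with
  sparse hourly sampling the shared structural parameters are only
  practically identified (flat valley), though population CL is robust.
- The PD likelihood treats per-run biomarker estimates as data with
  known weights, ignoring their estimation covariance.
- The LR test's chi-square reference is asymptotic; its conservatism at
  study size is demonstrated by simulation, not theory.
- Elevated-biomarker dynamics use the reciprocal EMAX form as a modelling
  choice; other increase laws (e.g. additive) would change the implied
  VRT/PETCO2 trajectories at high exposure.
- A Laplace-approximation joint-likelihood backend is a natural
  extension; only the two-stage backend is implemented and the config
  rejects anything else explicitly.
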