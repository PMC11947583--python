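# Methods

This note documents the model, the simulation and estimation machinery, the
virtual-trial generator, and the numerical and design choices behind them.

## Population pharmacokinetic model

**Disposition.** Unbound cefazolin follows a two-compartment model with
linear elimination, written in unbound-referenced amounts A1 (central) and
A2 (peripheral):

    dA1/dt = input(t) − (CL+Q)/V1 · A1 + Q/V2 · A2
    dA2/dt =            Q/V1 · A1   − Q/V2 · A2

with zero-order infusion input (all doses are 30-min i.v. infusions),
unbound central concentration Cu = A1/V1 and peripheral concentration
C2 = A2/V2. Within every interval of constant infusion rate the solution is
a biexponential evaluated in closed form from the eigendecomposition of the
2×2 rate matrix; running time-integrals (for dialysate interval averages
and mass-balance checks) use the same closed form. The implementation
accepts batched parameter arrays and complex dtypes, so population
simulation and complex-step differentiation share one code path.

**Saturable plasma binding.** Total central concentration is an
observation-level map from the unbound concentration, a single-site
Langmuir relation

    C_total = Cu + Bmax·Cu / (Kd + Cu),

with capacity Bmax = 247 mg/L and dissociation constant Kd = 65.3 mg/L: at
Cu = Kd half the binding sites are occupied (bound = 123.5 mg/L). The
kinetic mass balance itself stays linear in unbound-referenced amounts; we
also implemented the alternative — binding inside the mass balance, fluxes
driven by unbound concentration — and found it grossly incompatible with
the reported target-attainment results, so the observation-level reading
was kept. The inverse map (`unbind`) solves the binding quadratic with a
cancellation-free quadratic formula and round-trips to 1e−10.

**Tissue and dialysate observation layer.** Interstitial-space-fluid (ISF)
concentration is C_ISF = TF·C2 with tissue factor TF = 0.655 shared
between obesity groups. A microdialysate concentration over a collection
interval is RR times the time-average of C_ISF over that interval
(integrated dialysate-based approach); a retrodialysate sample perfused at
concentration P is P + RR·(mean C_ISF − P). Relative recovery RR is
group-specific (obese 0.233, nonobese 0.411) and catheter-specific (see
below). Interval averages use exact closed-form integrals in the fitting
path and trapezoidal integration of the simulated profile (≥20 grid points
per interval) in the profile-based path; the two agree to ~1e−4 and are
cross-checked in the tests.

**Covariate model.** CL carries no covariate. With lean body weight LBW
(Janmahasatian) and fat mass FM = TBW − LBW:

    V1 = 22.9 L · (LBW/64.3)
    Q  = 56.8 L/h · (LBW/64.3)^0.75
    V2 = 34.3 L · (0.764·LBW/64.3 + 0.236·FM/41.5)

Reference covariates 64.3 kg LBW / 41.5 kg FM are the trial's all-subject
medians. The Q exponent is the fixed allometric 0.75 from the parameter
table (the results prose describes Q as scaling "linearly", which we read
as "monotonically with LBW"; the table is taken as the estimate record).
Ideal body weight uses Devine, floored at the sex base value below 60 in;
adjusted body weight is IBW + 0.4·(TBW − IBW). eGFR is carried but has no
effect in the final model.

**Variability.** Independent log-normal interindividual effects multiply
CL, V1, Q, V2 and Bmax (CVs 21.9/40.1/54.8/12.4/9.2%); Kd carries none. A
CV is converted to a log-scale SD by ω = sqrt(ln(1 + CV²)), which makes the
stated CV exact. Residual error is proportional per stream (plasma 35.7%,
microdialysate 52.1%, retrodialysate 28.9%), implemented as log-normal
(Gaussian on log concentration with matched CV) — equivalent at small CV
and numerically robust at 50%+ CV, and the natural companion of the
log-normal random effects.

**Recovery hierarchy.** RR carries a subject-level effect (CV 43.3%) and a
catheter-level effect (intercatheter CV 58.6%); the resulting calibrated
catheter recovery is a fraction, so it is capped below 0.95 by a smooth
soft-minimum `rr/(1+(rr/0.95)^8)^(1/8)` (indistinguishable from identity
below rr ≈ 0.7, analytic so complex-step differentiation works). The
per-interval (intracatheter, CV 90.3%) fluctuation is treated as a
microdialysis sampling phenomenon: it multiplies the recovery of each
microdialysate collection interval. Because a microdialysate prediction is
proportional to recovery, this per-sample effect is log-additive and folds
*exactly* into the microdialysate residual variance; with one observation
per interval the two components are not separately identifiable anyway.
Retrodialysis calibration samples carry their own 28.9% residual error
only. This attachment is a design choice on a point the source analysis
leaves unspecified; the alternative (per-sample recovery effects on
retrodialysate records too) makes the likelihood of those records — affine,
not proportional, in recovery — heavily skewed, is numerically fragile, and
in our experiments biased TF and RR recovery by 25–50%.

## Dosing simulation and target attainment

Monte Carlo simulation draws n = 1000 virtual subjects per scenario
(covariate scaling at the reference patient, then independent log-normal
effects) and evaluates the closed-form solution on a 0.01-h grid over
0–8 h. Residual (assay) error is excluded: attainment reflects true
concentration profiles, not measurements.

Reference patients: nonobese (TBW 70 kg, FM 24.8%), obese (95.1 kg, 29.5%)
and morbidly obese (127 kg, 39.5%); FM = TBW·FM%, LBW = TBW − FM (reference
patients are defined by weight and fat-mass percentage, not by a formula).

Regimens are "dose plus redosing every 3 or 4 h" across the 8-h window:
1 g q3h doses at 0, 3 and 6 h; q4h at 0 and 4 h; likewise for 2 g. We
initially read the regimens as two doses only (initial plus one redose);
under the two-dose reading the ISF trough 5 h after the last q3h dose
dominates attainment and the reported ISF percentages cannot be reproduced
in any window convention we scanned, while the repeated-dosing reading
reproduces all reported percentages and every adequacy statement
simultaneously. This is the main interpretive sensitivity of the
reproduction.

The target is unbound concentration above the MIC 100% of the time. The
evaluation window runs from the end of the first infusion (0.5 h) to 8 h —
concentration is zero at the start of the infusion, so a window anchored at
t = 0 could never be attained. Ties at exactly the MIC count as
non-attainment; window endpoints are included by linear interpolation.
Halving the grid step changes PTA by well under half a percentage point.
PTA is the fraction of subjects attaining; a regimen is adequate at
PTA ≥ 90%. CFR weights PTA over a pathogen MIC distribution (user-supplied
two-column files; the analysis scripts generate synthetic wild-type-like
doubling-dilution distributions, since the clinical databases are not
redistributed here).

## Virtual-trial generator

The generator emulates the source trial: 15 obese (BMI ≥ 35) and 15
age/sex-matched nonobese (BMI 18.5–30) subjects, 2 g over 30 min, plasma
samples at 0.5–8 h, ultrafiltration (unbound) at 0.5/1/4/8 h, ten
microdialysate intervals over 0–8 h on each of two catheters, and 3×15-min
retrodialysis samples per catheter after 8 h (perfusate 50 mg/L — a design
input the source does not print). Covariates are sampled to approximate the
published summaries: each obese/nonobese pair shares an age (uniform
21–65 y) and sex draw with a fixed 1:2 male:female ratio; BMI is truncated
log-normal within the group range (medians 26.0 / 52.6 kg/m²); height is
sex-specific normal (168/180 ± 6 cm); TBW = BMI·height²; LBW by
Janmahasatian. This reproduces group TBW medians within ~10% of the
published 78 / 155 kg. Only marginal summaries are emulated — joint
covariate correlations, measured eGFR–clearance relations, dropout or
sampling deviations of real trials are not, so passing recovery tests shows
identifiability under the stated design and noise, not robustness to
real-data pathologies. No below-quantification handling is generated (none
is described for the source data).

## Estimation

Maximum marginal likelihood with eight subject-level random effects
(CL, V1, Q, V2, Bmax, subject RR, two catheter RR effects). The marginal
likelihood is approximated by Laplace at the per-subject empirical-Bayes
mode. The inner mode search is a damped Newton iteration run for all
subjects of a shared observation design simultaneously, with exact
gradients by complex-step differentiation through the closed-form solver
and a Gauss-Newton Hessian; the outer optimizer is L-BFGS-B on log- (logit-
for fractions) transformed parameters with finite-difference gradients and
warm-started inner modes. A naive-pooled prefit (random effects off) moves
the fixed effects and residual SDs from generic round-number starting
values (CL 10, volumes/flows 30, Bmax 150, Kd 30, fractions 0.3–0.5, all
CVs ~30%) into the right region first. Verification fallbacks: plain Monte
Carlo integration over the random-effect prior, and adaptive Gauss-Hermite
for one-dimensional cases, which is compared against dense-grid integration
in the tests (the Laplace error on a two-subject case is a few 1e−3 of a
log-likelihood unit).

Default fit estimates all ten fixed effects (including the V2 partition
fraction R), six variability magnitudes, the intercatheter magnitude, and
three residual SDs (20 parameters). Parameters may be fixed via
`FitSpecification`. The objective is reported as −2·log marginal
likelihood (without the log-data Jacobian constant).

Operating characteristics under the trial design (medians over replicate
fits from generic starts): CL, V1, V2, TF and the recoveries land within a
few percent to ~10% of truth. Bmax and Kd lie on a long flat likelihood
ridge (only four paired total/unbound samples per subject at 35.7% noise
constrain the curvature of the binding relation), so single-trial estimates
wander by ±50–80% along the ridge in either direction; their *median* over
20 replicates is within ~10–15% of truth. Profile scans and Monte Carlo
integration confirm the ridge is a property of the likelihood, not of the
Laplace approximation or the optimizer.

## Numerical choices

- Closed-form solver: real distinct eigenvalues are guaranteed for positive
  parameters; tiny negative round-off concentrations (≈1e−17 at t = 0) are
  clipped to zero in profile containers.
- Smooth positivity floor `0.5(x + sqrt(x² + 0.01))` on dialysate
  predictions: a retrodialysate prediction can cross zero for trial
  recoveries near 1 during optimization; the floor keeps log-likelihoods
  finite with bounded, complex-step-safe gradients and is within 0.1% of
  the identity above 1 mg/L. A matching guard with scale 1e−6 protects
  against exponential underflow at extreme line-search parameters.
- Inner Newton: trust-region step cap of 2 log units, Armijo halving with a
  1e−10 round-off slack, gradient tolerance 1e−4 (contributing ≲1e−8
  objective noise, well under the 1e−5 finite-difference step of the outer
  gradient).
- All randomness flows from one user seed, split per stage/scenario with
  `numpy` SeedSequence spawning; seeded runs are bit-reproducible.
- Problem sizes: 1000 subjects per attainment scenario and 20 replicate
  fits in the recovery study; these match the source analysis scale while
  keeping the full pipeline re-runnable in minutes on one core.

## Known limitations

- Bmax/Kd are weakly identified by this design (see above): single-study
  estimates are honest but imprecise; only replicate medians are stable.
- The estimator assumes all subjects share the observation schedule when
  batching; heterogeneous datasets fall back to per-design groups and are
  slower.
- The Laplace approximation is not exact; its error is documented on small
  cases rather than corrected (no importance-sampling refinement).
- Reference patients are simulated without parameter uncertainty — fixed
  effects are treated as known, so attainment percentages carry Monte Carlo
  noise only (binomial SE ≈ 1.5 points at n = 1000).
- The regimen reading ("redosing every 3/4 h over the window") and the
  attainment window start (end of first infusion) are interpretive choices;
  both are documented above because the reported percentages are sensitive
  to them.
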