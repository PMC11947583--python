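# cefazolin-pk

Population pharmacokinetics of unbound cefazolin for surgical antibiotic
prophylaxis in obese and nonobese patients: a reusable implementation of the
full analysis pipeline — structural model, Monte Carlo dosing simulation,
target-attainment evaluation, virtual-trial generation and population
fitting.

## The problem

Cefazolin is the standard prophylactic antibiotic against surgical-site
infections, whose incidence is higher in obese patients. Whether obese
patients need dosing adaptations is decided by whether unbound drug
concentration — in plasma and at the infection site, the interstitial space
fluid (ISF) of subcutaneous adipose tissue, sampled by microdialysis —
stays above the pathogen's MIC throughout surgery (*f*T>MIC = 100%). This
package implements a published population model of that problem and the
simulations built on it, together with a synthetic-trial generator so every
stage is testable without the original (non-deposited) trial data.

## The model

Two-compartment disposition of unbound cefazolin with linear elimination
and zero-order infusion input:

    dA1/dt = input(t) − (CL+Q)/V1·A1 + Q/V2·A2,   Cu = A1/V1
    dA2/dt =            Q/V1·A1     − Q/V2·A2,    C2 = A2/V2

Saturable (single-site) plasma binding as an observation-level map,
C_total = Cu + B_max·Cu/(K_d + Cu); ISF concentration C_ISF = TF·C2; a
microdialysate concentration is the catheter's relative recovery RR times
the time-average of C_ISF over the collection interval, and retrodialysis
calibration samples perfused at concentration P predict
P + RR·(mean C_ISF − P). Body size enters through lean body weight and fat
mass: V1 ∝ LBW, Q ∝ LBW^0.75, V2 ∝ 0.764·LBW/64.3 + 0.236·FM/41.5; CL
(17.9 L/h) carries no covariate. Interindividual variability is log-normal
on CL, V1, Q, V2 and B_max; RR is obesity-group-specific (23.3% obese,
41.1% nonobese) with subject- and catheter-level variability; residual
error is proportional per observation stream. Parameter values, units and
all modelling choices are documented in [docs/methods.md](docs/methods.md).

Dosing regimens are 1 g or 2 g infused over 30 min with redosing every 3 or
4 h across an 8-h window; the target is unbound concentration above the MIC
at every instant from the end of the first infusion to 8 h. PTA is the
fraction of 1000 simulated subjects attaining the target; CFR weights PTA
over a pathogen MIC distribution; both are adequate at ≥90%.

## Worked example

Attainment of the 4 mg/L clinical breakpoint by the 1 g regimens
(`python analysis/02_target_attainment.py --seed 1` computes the full
grid; the fragment below reproduces the headline scenarios):

```python
from cefazolin_pk import (PopulationParameters, REFERENCE_PATIENTS,
                          SimulationConfig, simulate_population, pta)
from cefazolin_pk.reporting import standard_regimen

pop = PopulationParameters()
for regimen, matrix in [("1g_q4h", "plasma_unbound"), ("1g_q3h", "isf")]:
    for patient in REFERENCE_PATIENTS:
        ens = simulate_population(pop, REFERENCE_PATIENTS[patient],
                                  standard_regimen(regimen),
                                  SimulationConfig(n_subjects=1000, seed=1))
        print(regimen, patient, matrix, f"{100*pta(ens, 4.0, matrix=matrix).pta:.1f}%")
```

```
1g_q4h nonobese plasma_unbound 64.1%
1g_q4h obese plasma_unbound 76.8%
1g_q4h morbidly_obese plasma_unbound 79.1%
1g_q3h nonobese isf 84.2%
1g_q3h obese isf 75.2%
1g_q3h morbidly_obese isf 61.1%
```

The 1 g q4h regimen misses the 90% adequacy threshold in plasma for all
three reference patients, and 1 g q3h misses it in tissue — most severely
in the morbidly obese patient, whose larger peripheral volume dilutes early
tissue concentrations. Both 2 g regimens are adequate everywhere at the
breakpoint, and every regimen is adequate at MIC ≤ 2 mg/L, so standard 2 g
dosing with a 4-h redose needs no adaptation for obesity.

Fitting a virtual trial (`python analysis/04_fit_synthetic_study.py
--seed 7`) generates a 30-subject study at the published parameters and
re-estimates them from generic starting values in about 10–30 s:

```
fit finished in 11 s, converged=True, -2LL=2191.2
parameter  estimate  generating_value  rel_error_pct
       cl    17.464            17.900         -2.437
     bmax   243.708           247.000         -1.333
       kd    67.096            65.300          2.750
       tf     0.664             0.655          1.304
 rr_obese     0.235             0.233          0.962
 ...
```

Clearance, the binding pair and the tissue factor come back within a few
percent on this replicate; across replicates B_max and K_d wander along a
flat likelihood ridge (see the methods note) while their medians stay near
the truth.

The numbered scripts under `analysis/` run the whole pipeline:
`01_simulate_profiles.py` (percentile bands of the simulated profiles),
`02_target_attainment.py` (PTA/CFR tables and adequacy report),
`03_generate_study.py` (virtual trial), `04_fit_synthetic_study.py` (one
fit), `05_parameter_recovery.py` (replicate fits). Each writes delimited
tables plus a reproducibility manifest under `results/`.

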