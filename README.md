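# ceftriaxpk

Population pharmacokinetics of **free ceftriaxone** in elderly patients with
*Enterococcus faecalis* infective endocarditis, and Monte Carlo optimisation
of dosing regimens for outpatient parenteral antibiotic therapy (OPAT).

Ceftriaxone is given together with ampicillin because free ceftriaxone
concentrations of 5–10 mg/L potentiate ampicillin killing of *E. faecalis*.
The clinical question is which regimen — intermittent 1-h infusions or a
continuous 24-h infusion — keeps the free concentration above that synergy
threshold (Cs) for 50–100% of the dosing interval in at least 90% of
patients.

The package provides, as a reusable and tested pipeline:

* a closed-form **two-compartment model with zero-order (infusion) input**
  (`structural`), verified against an independent ODE integrator;
* the **covariate / random-effects layer** (`population`): log-normal
  between-subject variability and power-law covariate effects
  `θᵢ = θ_pop · (Cov/Cov_median)^β · e^η`, with the published final model
  (CrCl on CL, BMI on V1) built in;
* a **synthetic cohort generator** (`cohort`) emulating the study design —
  24 episodes, three samples at steady state (trough, 2 ± 0.5 h, 4 ± 0.5 h),
  regimen mix 75% 2 g/12 h, 12.5% 4 g/24 h, 12.5% 6 g/24 h, covariates from
  log-normal marginals matched to the cohort medians/IQRs, free-drug LLOQ
  0.5 mg/L — plus a Cockcroft–Gault helper and a saturable
  protein-binding emulator for total-drug readouts;
* a **SAEM estimation engine** (`estimation`): stochastic-approximation EM
  with MCMC E-step, importance-sampled −2 log-likelihood, BIC, eta
  shrinkage, empirical Bayes estimates, stepwise forward/backward covariate
  selection (ΔminusLL ≥ 3.84, BIC decrease, BSV reduction) and a
  nonparametric episode-level bootstrap;
* **simulation diagnostics** (`diagnostics`): NPDE and prediction-corrected
  VPC;
* **Monte Carlo PTA analysis** (`pta`): simulate thousands of virtual
  subjects per regimen, compute the fraction of the dosing interval with
  free concentration ≥ Cs (`fT ≥ Cs`), and tabulate the probability of
  target attainment with the ≥90% optimality rule;
* NONMEM-style CSV I/O, a YAML-configured pipeline with a reproducibility
  manifest, and a `ceftriaxpk` command-line interface (`dataio`,
  `pipeline`, `cli`).

## Worked example

Simulate the six studied regimens from the published final model
(CL 11.57 L/h with (CrCl/59.5)^0.62, V1 43.6 L with (BMI/29.3)^2.52,
Q 19.8 L/h, V2 40.94 L; ω = 0.48/0.77/0.75/0.09, σ = 1.41 mg/L) and
tabulate the PTA:

```python
import ceftriaxpk as cpk

table, profiles = cpk.run_pta(
    cpk.final_model(), cpk.SimulationSpec(n_subjects=10_000), rng=1
)
print(table.table.round(1))
```

```
cs_mg_L      5.0               10.0
ft_required  0.50  0.75  1.00  0.50  0.75  1.00
2g_q12h_1h   84.4  70.0  56.4  58.1  41.8  29.5
4g_q24h_1h   72.2  49.6  32.9  46.9  26.7  14.2
6g_q24h_1h   81.7  60.8  43.7  63.2  40.3  24.9
2g_q24h_ci   74.2  74.0  73.8  26.4  25.9  25.1
4g_q24h_ci   97.4  97.4  97.4  74.2  74.0  73.8
6g_q24h_ci   99.7  99.7  99.7  92.0  92.0  91.9
```

Each cell is the percent of 10,000 virtual elderly subjects whose free
ceftriaxone stays at or above the column's synergy threshold (5 or
10 mg/L) for at least the required fraction of a post-48 h dosing
interval. Reading the table: no intermittent 1-h regimen keeps 90% of the
population above even the lower threshold, while 4 g/24 h as a continuous
infusion holds ≥ 5 mg/L for the whole interval in 97% of subjects and
6 g/24 h holds ≥ 10 mg/L for the whole interval in 92% — the quantitative
basis for preferring high-dose continuous infusions in OPAT.

Fit a synthetic cohort and inspect the estimates:

```python
import numpy as np

data = cpk.generate_dataset(cpk.StudyDesign(), cpk.final_model(),
                            np.random.default_rng(1))
fit = cpk.saem_fit(data, cpk.final_model(), cpk.SaemSettings(seed=1))
print({k: round(v, 2) for k, v in fit.theta_hat.items()})
```

```
{'CL': 12.54, 'V1': 23.48, 'Q': 19.0, 'V2': 45.68}
```

With only 72 observations (24 episodes × 3 samples) clearance is recovered
well; the peripheral parameters carry more uncertainty, as their reported
relative standard errors and shrinkage in the study also indicate.

The same stages are scriptable:

```bash
ceftriaxpk simulate-cohort --out run1 --seed 1
ceftriaxpk fit --dataset run1/dataset.csv --out run1 --seed 2
ceftriaxpk pta --out run1 --seed 3
```

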