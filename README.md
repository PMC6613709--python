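# gadoflux

Mechanistic modeling of liver function from gadoxetate-enhanced MRI.

Gadoxetate is a liver-specific MRI contrast agent: hepatocytes take it up
through OATP1-family transporters and excrete it into bile through MRP2,
so the time course of the contrast-induced change in relaxation rate
(ΔR1, s⁻¹) in liver and spleen carries quantitative information about
transporter function. `gadoflux` is for researchers who want to turn such
ΔR1 time series into per-patient transport rates and population-level
liver-function biomarkers — including in chronic liver disease, where
hepatocyte uptake falls with advancing fibrosis.

## The model

A whole-body compartment model tracks gadoxetate concentration in plasma
(C_p), extracellular extravascular space (C_ees) and hepatocytes (C_hep):

    dC_hep/dt = k_ph·C_p·Alb − (k_hp + k_hb)·C_hep
    dC_p/dt   = [(k_hp·C_hep − k_ph·C_p·Alb)·V_l·v_h − CLr·C_p·Alb
                 + k_diff·(C_ees − C_p·Alb)·V_ees + u(t)] / V_p
    dC_ees/dt = k_diff·(C_p·Alb − C_ees)

where u(t) is the weight-based bolus (0.1 mL/kg at 1 mL/s) and the
subject-level parameters are the transport rates k_diff, k_ph (OATP1
uptake), k_hp (MRP3 back-flux), k_hb (MRP2 biliary excretion) and a signal
scale ξ. The signal model predicts the measured ΔR1 from the compartment
concentrations via tissue volume fractions and relaxivities. The system is
linear with piecewise-constant input, so trajectories are computed exactly
with matrix exponentials (an independent stiff integrator is kept as a
cross-check).

Two estimation routes are provided:

* **STS** — each subject fitted independently by minimizing the χ²
  cost V(p) = Σ (ŷ−y)²/σ², with σ = max(ROI SEM, 0.18) and only data from
  3 min post-injection onward; goodness of fit is a χ² test with degrees
  of freedom equal to the number of observations.
* **NLME** — a population model (lognormal rates, normal ξ) estimated by
  an alternating MAP/EM scheme; each subject's parameters are MAP
  estimates shrunk toward the population, which keeps short (≤10 min)
  protocols usable.

A synthetic-cohort generator reproduces the study conditions (91 subjects,
fibrosis-stage mix F0–F4 of 29/16/25/14/7, the clinical sampling schedule,
0.18 ΔR1 noise) so the whole pipeline can be exercised and validated
without clinical data. See `docs/methods.md` for assumptions, numerical
choices and known limitations.

## Worked example

```python
import numpy as np
from gadoflux import (
    CohortSpec, DoseProtocol, PhysiologicalConstants,
    fit_population, fit_sts, generate_cohort,
)

# a seeded virtual cohort: 8 subjects, no fibrosis
spec = CohortSpec(n_patients=8, stage_counts=(8, 0, 0, 0, 0), seed=21)
cohort, truth = generate_cohort(spec)

# standard two-stage fit of the first subject
patient = cohort.patients[0]
fit = fit_sts(patient)
print(f"k_ph = {fit.params.k_ph:.4g} 1/s  (truth "
      f"{truth.loc[patient.patient_id, 'k_ph']:.4g})")
print(f"chi2 = {fit.gof.chi2:.2f} on df={fit.gof.df} "
      f"-> {'pass' if fit.gof.passed else 'reject'}")

# population fit across the cohort
pop = fit_population(cohort, max_iter=25)
kph = pop.population["k_ph"]
print(f"population k_ph: theta = {kph.theta:.4g} 1/s, omega = {kph.omega:.2f}")
```

Output:

```
k_ph = 0.002544 1/s  (truth 0.003473)
chi2 = 1.42 on df=8 -> pass
population k_ph: theta = 0.007877 1/s, omega = 0.27
```

The single-subject fit passes the χ² test (critical value 15.5 at df 8)
and its uptake rate lands within the per-patient uncertainty of the
generating value — which is large: at the 0.18 noise floor one subject's
data constrain log k_ph only to about ±0.7, so individual uptake
estimates must be read with that spread in mind. The population typical
value from just eight subjects overshoots the generating 4.7×10⁻³ s⁻¹ for
the same reason (the likelihood is nearly flat along a ridge trading k_ph
against the other rates); `scripts/acceptance.py` quantifies the recovery
behaviour on a 50-subject cohort. See `docs/methods.md`, "Known
limitations".

The same stages are scriptable from the shell:

```bash
gadoflux simulate --n-patients 20 --seed 42 --out cohort.csv --truth truth.csv
gadoflux fit-sts  --cohort cohort.csv --out fits_sts.csv
gadoflux fit-nlme --cohort cohort.csv --out fits_nlme.csv --max-iter 25
gadoflux experiment --cohort cohort.csv --method both --out report.json
gadoflux classify --estimates fits_nlme.csv --cutoff 0.00198
```

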