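# imatinib-pbpk

A minimal, fully open physiologically based pharmacokinetic (PBPK)
model of oral imatinib in adults — for pharmacologists who want to ask,
with inspectable code and parameters, why steady-state imatinib
exposure varies so much between patients with chronic myeloid leukemia
and what that implies for dosing, therapeutic drug monitoring and
co-medication.

The package simulates plasma concentration–time profiles of imatinib
given once daily for 14 days in virtual adults (healthy, cirrhotic,
renally impaired; European/Chinese/Japanese ancestry), maps real
patient covariate records to *virtual twins*, runs one-at-a-time
sensitivity analyses over physiological parameters, and predicts
drug–drug interactions (DDIs) with five CYP3A4/CYP2C8 modulators.

## The model in brief

Five compartments (depot, gut wall, liver, central, peripheral) with
per-route elimination bookkeeping. The core mechanisms:

* **Saturable AAG binding** — imatinib binds α1-acid glycoprotein;
  the unbound fraction solves a one-site binding quadratic at every
  step, calibrated so fu_p = 0.05 at the reference AAG of 0.91 g/L
  (kd_app = AAG·fu/(1−fu)).
* **Well-stirred liver** — CL_h = Q_h·fu_b·CL_int/(Q_h + fu_b·CL_int),
  with unbound intrinsic clearance scaled from per-pmol enzyme
  clearances: CL_int = Σ_e clint_e·abundance_e·activity_e·MPPGL·liver
  weight, plus P-gp/BCRP biliary terms and a fixed 3 % minor-CYP share.
* **Enzyme turnover** — de/dt = k_deg·s(t) − e·(k_deg + k_inact(t));
  imatinib mechanism-based-inactivates its own CYP3A4 pathway, so
  hepatic CYP3A4 activity is roughly halved at steady state. This is
  why CYP3A4 inhibitors (diltiazem, verapamil) barely move steady-state
  exposure while CYP2C8 inhibitors (trimethoprim, clopidogrel) do.
* **Virtual population** — truncated log-normal enzyme abundances
  (CYP3A4 93 pmol/mg, 0–600; CYP2C8 22.4 pmol/mg, 0–85) with a Gaussian
  copula (Spearman 0.68), ancestry/sex-specific body size and AAG,
  eGFR from the 2009 CKD-EPI creatinine equation.
* **Paired DDI design** — each subject is simulated with and without
  the perpetrator (an analytic multi-dose forcing function); geometric
  mean ratios carry 90 % CIs and the conventional 0.80–1.25 no-effect
  interval.

See `docs/methods.md` for assumptions, calibration and limitations.

## Worked example

Steady-state exposure of a reference 50-year-old European man (81 kg,
176 cm, mean enzyme abundances, AAG 0.91 g/L) on imatinib 400 mg daily:

```python
import imatinib_pbpk as ip

cfg = ip.load_default_config()
ind = ip.sample_individual(
    cfg.system, {"age": 50, "sex": "M"}, seed=1, drug=cfg.drug,
    overrides={"weight": 81.0, "height": 176.0, "serum_creatinine": 80.0,
               "CYP3A4_hepatic": 93.0, "CYP2C8_hepatic": 22.4,
               "CYP3A4_gut": 66.0, "P-gp": 0.201, "BCRP": 0.044,
               "AAG": 0.91})
ind.mppgl = 40.0
regimen = ip.DoseRegimen(dose=400.0, interval=24.0, n_doses=14)
res = ip.simulate(ind, cfg.drug, regimen, kdeg=cfg.system.kdeg,
                  options=ip.SolverOptions.population())
for k, v in res.metrics.items():
    print(f"{k:>12s}  {v:.3f}")
print(f"{'CYP3A4 act.':>12s}  {res.enzyme_activity['CYP3A4_hepatic'][-1]:.3f}")
```

prints

```
 auc_0_24_ss  39.108
     css_max  2.438
     css_min  1.066
   cl_over_f  10.228
 CYP3A4 act.  0.437
```

i.e. a day-14 AUC over the dosing interval of 39.1 µg·h/mL, a peak of
2.44 µg/mL, a trough of 1.07 µg/mL — just above the 1.0 µg/mL
efficacy target used in therapeutic drug monitoring — an apparent oral
clearance of 10.2 L/h, and hepatic CYP3A4 autoinhibited to 44 % of its
baseline activity.

A command-line layer wraps the common studies:

```bash
imatinib-pbpk simulate-cohort --n 68 --seed 1 --out-dir results/cohort
imatinib-pbpk sensitivity --parameter AAG --levels 0.3,3.2 --seed 1 --out-dir results/aag
imatinib-pbpk ddi --perpetrator clopidogrel --seed 1 --out-dir results/ddi
imatinib-pbpk compare-outcomes --cohort results/cohort/cohort.csv \
    --exposures results/cohort/exposures.csv --out-dir results/cohort
```

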