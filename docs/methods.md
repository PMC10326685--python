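# Model and methods

`imatinib-pbpk` is a minimal, fully open physiologically based
pharmacokinetic (PBPK) model of oral imatinib in adults, built to study
how patient physiology and co-medication shape steady-state plasma
exposure. It reproduces, with transparent and editable parameters, the
class of analyses usually run in commercial whole-body simulators:
virtual-population exposure prediction, "virtual twin" simulation of
real patient covariate records, one-at-a-time sensitivity analysis, and
drug–drug interaction (DDI) studies summarised as geometric mean ratios
(GMRs).

## Structural model

The whole-body tissue network is collapsed to five drug compartments:

* **depot** — gut lumen; first-order absorption (`ka`, fraction
  absorbed `fa`);
* **gut wall** — a small enterocyte pool in which gut CYP3A4 competes
  with transfer to the portal circulation (`gut_transit`), so gut
  availability F_g emerges from the ODEs (~0.95 at baseline; imatinib
  undergoes little enterocyte metabolism);
* **liver** — well-stirred: elimination is driven by the unbound
  concentration in emergent venous blood, with liver:blood partition
  `liver_kp_blood` setting the (pharmacodynamically inert) liver
  amount;
* **central** and **peripheral** — lumped distribution volumes
  (`vc_per_kg`, `vp_per_kg`, inter-compartmental clearance `q_inter`)
  calibrated to imatinib's ~18–20 h terminal half-life and its
  peak/trough fluctuation at 400 mg daily. Only plasma metrics are
  reported, so tissue-level resolution is deliberately not modelled.

Cumulative elimination is tracked per route (CYP3A4, CYP2C8, minor
CYPs, biliary, renal, gut), which makes a 0.1 % mass-balance assertion
possible on every simulation.

### Plasma protein binding

Imatinib binds saturably to α1-acid glycoprotein (AAG). One binding
site class per AAG molecule is assumed (stoichiometry is not
identifiable from an unbound fraction alone). The apparent dissociation
constant is not a free parameter: it is calibrated so that the
dilute-drug unbound fraction equals fu_p = 0.05 at the healthy
reference AAG of 0.91 g/L, giving kd_app = AAG·fu/(1−fu) ≈ 0.0479 g/L.
At therapeutic concentrations the bound drug occupies only a few
percent of sites, so fu is near-constant in a healthy adult; at low AAG
(0.3 g/L) saturation becomes material and is handled by solving the
binding quadratic at every right-hand-side evaluation.

### Clearance

Unbound hepatic intrinsic clearance is scaled up from per-pmol enzyme
clearances: `CLint = Σ clint_e · abundance_e · activity_e · MPPGL ·
liver weight`, plus P-gp/BCRP biliary terms proportional to transporter
abundance and relative liver size, and a fixed minor-CYP term pinned at
3 % of hepatic metabolism at reference abundances (non-inhibitable,
non-inducible). Hepatic clearance follows the well-stirred model;
renal clearance scales an empirical patient value by absolute
glomerular filtration (eGFR × BSA/1.73). Because the empirical renal
clearance in patients reflects filtration plus secretion, it is applied
per unit GFR and *not* additionally scaled by fu; a `renal_fu_scaling`
switch restores strict filtration scaling for users who prefer it.
With the shipped configuration, steady-state clearance in a reference
adult partitions roughly as CYP2C8 38 %, biliary 43 %, CYP3A4 13 %
(after autoinhibition), minor CYPs 2 %, renal 4 %, and CL/F ≈ 9–10 L/h.

### Enzyme turnover, autoinhibition and interactions

Each enzyme pool (hepatic CYP3A4, hepatic CYP2C8, gut CYP3A4) follows a
turnover model `de/dt = kdeg·s(t) − e·(kdeg + k_inact(t))` with
degradation half-lives of ~44 h (hepatic) and ~23 h (gut). Imatinib
inactivates its own CYP3A4 pathway (mechanism-based, driven by unbound
liver concentration), which halves hepatic CYP3A4 activity by day 14 of
400 mg daily dosing. This is the mechanism behind two headline
behaviours: day-14 CL/F sits below day-1 CL/F, and steady-state
CYP3A4-inhibitor DDIs are weak (the pathway is already mostly shut
down) while CYP2C8 inhibitors matter.

Perpetrators are analytic one-compartment forcing functions (closed
form multi-dose superposition; one optional first-order metabolite
chain), not co-integrated states. Interactions act through unbound
systemic concentration: competitive inhibition scales pathway activity
by 1/(1+Cu/Ki) instantaneously, mechanism-based inhibitors add to the
turnover inactivation rate, and induction multiplies enzyme synthesis.
The shipped perpetrator files are deliberately *effective in vivo*
parameterisations on this concentration scale: diltiazem and verapamil
fold their active metabolites into the parent inactivation constants;
clopidogrel acts through an explicit acyl-glucuronide metabolite
(mechanism-based CYP2C8); trimethoprim is a competitive CYP2C8
inhibitor; hyperforin induces gut CYP3A4 only. When a perpetrator is
started before the victim drug, its effect on the enzyme pools is
pre-equilibrated by integrating the drug-free turnover equations over
the lead-in period.

## Virtual population

Individuals are sampled from explicit, config-visible covariate models
(the commercial population libraries are proprietary, so these are this
package's own):

* body size from ancestry/sex-specific truncated normals; BSA by
  Du Bois; liver weight ∝ BSA^1.5 and hepatic blood flow ∝ BSA^0.75,
  both declining linearly after age 40 (−0.4 %/y and −0.6 %/y). The
  liver-size exponent is an *effective* value chosen so that total
  clearance scales with body weight the way the calibrated
  weight-sensitivity target requires; it is steeper than
  anatomical liver-volume regressions because it also absorbs body-size
  dependence that a full tissue model would distribute over other organs.
* MPPGL log-normal (mean 40 mg/g, CV 30 %); hepatic CYP3A4
  (93 pmol/mg, CV 50 %, truncated 0–600) and CYP2C8 (22.4 pmol/mg, CV
  60 %, truncated 0–85) drawn through a Gaussian copula with Spearman
  correlation 0.68, with marginals preserved exactly via inverse-CDF
  transforms; gut CYP3A4 and P-gp/BCRP abundances independent
  truncated log-normals at their meta-analysis means/CVs.
* AAG by ancestry and sex (European mean ≈ 0.91 g/L, males slightly
  higher, Asian ancestries ~10 % lower), truncated to the healthy
  0.36–1.46 g/L range; serum creatinine by sex with a mild age trend;
  eGFR from the 2009 CKD-EPI creatinine equation (original published
  constants, no race coefficient).
* Enzyme abundance means are common across ancestries — a documented
  simplification; ancestry acts through body size and AAG.

Reproducibility: one root seed; each (trial, subject) or cohort row
draws from its own `SeedSequence` substream, so trial composition is
stable under any execution order.

Special populations are multiplier tables applied to healthy
individuals. Cirrhosis (Child-Pugh A/B/C) reduces liver weight, hepatic
flow, CYP abundances and AAG with graded severity; the values are
calibrated so B raises steady-state AUC by ~35 % and C by ~65 % while A
stays within population noise. Renal impairment bands raise AAG
(acute-phase response, ×1.3 / ×1.5) and reduce CYP abundances (×0.85 /
×0.65) and pin eGFR at 45 / 25 mL/min/1.73 m² with a back-computed
consistent creatinine; a "modified" mode restores healthy CYP
abundances. In this lumped model the default renal bands yield ~1.9-fold
(GFR < 30) AUC elevation — directionally right but smaller than the
~2.6-fold a full-PBPK renal population produces, a known limitation.

Virtual twins fix every observed covariate of a patient record (age,
sex, ancestry, weight, height, creatinine, cirrhosis class, dose,
comedications) and sample only unobserved physiology conditional on
demographics; missing weight/height are imputed with the ancestry/sex
distribution means (the imputation rule is this package's choice).

## Study designs

* **Virtual trials**: 10 trials × 10 subjects by default, a fixed 4-of-10
  female mix, ages uniform 20–91 — the demographic envelope used for
  the DDI and sensitivity designs. Failed subjects (solver errors) are
  excluded with a warning; >10 % failures aborts.
* **Sensitivity sweeps** re-simulate the *same* subjects at each level
  with only the target parameter overridden, so fold-changes between
  extreme levels are nearly Monte-Carlo-free; significance uses
  Kruskal–Wallis across levels plus a Wilcoxon–Mann–Whitney contrast of
  the extremes.
* **DDI studies** are paired: every subject is simulated with and
  without the perpetrator with identical physiology. GMRs carry 90 %
  t-based confidence intervals on the log ratio with subjects pooled
  over trials (trial-level pooling is this package's choice; the
  conventional 0.80–1.25 interval flags clinical relevance). Pairing
  makes a no-interaction perpetrator give GMR = 1 to machine precision.
* **Outcome contrasts** use Kruskal–Wallis on the raw metric and a
  Welch t-test on the log metric, two-sided at α = 0.05, with geometric
  means and 95 % CIs per group.

## Synthetic cohort and outcome link

The study-sized cohort (n = 68; 45 evaluable for early molecular
response with 35 achievers; 47 with grade ≥3 adverse reactions) cannot
be reconstructed from public data, so `generate_cohort` draws a
covariate table from documented stand-in marginals: age ~ N(57, 15)
clipped to 20–91, 40 % female, ancestry 70/15/15
European/Chinese/Japanese, rare cirrhosis (8 %), dose mix 75 % at
400 mg (remainder 300/600/800), and at most one CYP-modulating
comedication per patient (6 % each). Outcomes are assigned by a
logistic link on log steady-state AUC with positive slopes (higher
exposure → more response *and* more toxicity, the directions this kind
of exposure-outcome analysis observes). The default slopes (4.5 for
EMR, 4.0 for ADR) and intercepts were chosen once so that (a) expected
prevalences match the study frame at the reference exposure
distribution (log AUC ≈ N(3.85, 0.43), measured from the pipeline
itself) and (b) a Kruskal–Wallis contrast at n = 68 detects the link in
well over 90 % of replications. Passing those checks therefore
demonstrates that the *pipeline* recovers a true exposure–outcome
signal at study size — not that real imatinib outcomes follow this
particular link.

## Numerical choices

* LSODA with rtol 1e-8 / atol 1e-10 mg by default; population batches
  use 1e-6 / 1e-8 (tightening tolerances 10× moves steady-state AUC by
  <0.1 %). Doses are integration restarts with depot increments.
* Steady-state metrics come from the 14th dosing interval (312–336 h)
  on a 241-point grid: AUC by trapezoid, C_ss,min as the
  end-of-interval (pre-dose) concentration, CL/F = dose/AUC.
* Binding quadratic solved in closed form with the numerically stable
  root; KI-type constants are interpreted as unbound concentrations in
  µM and converted with molecular weight.
* Degenerate inputs: zero dose yields identically zero trajectories;
  AAG = 0 means fu = 1; zero abundances zero out their pathway;
  stacked special-population conditions are rejected.

## Calibration

The in-vitro kinetic constants behind the per-enzyme intrinsic
clearances are not publicly tabulated, so the shipped defaults are
calibrated, not transcribed: they were fixed once so that the reference
adult meets fu_p = 0.05, CL/F ≈ 9–10 L/h, fm(minor CYP) = 3 %, and the
model reproduces the documented steady-state sensitivity magnitudes
(CYP2C8 0→85 pmol/mg ≈ −70 % AUC; CYP3A4 0→600 ≈ −50 %; AAG 0.3→3.2 g/L
≈ 8.4-fold; weight 45→125 kg ≈ −44 %) and DDI ratios (diltiazem 1.04,
verapamil 1.06, hyperforin 0.95, trimethoprim +23 %, clopidogrel +32 %).
These magnitudes are therefore *calibration checks*, not independent
predictions; the genuinely emergent content is everything that follows
from the mechanisms jointly (autoinhibition dynamics, paired-design
statistics, population variability, special-population shifts).

## Known limitations

* No mechanistic absorption model, no enterohepatic recirculation, no
  transporter-mediated DDIs, no metabolite plasma kinetics, no
  intracellular (target-cell) concentrations, perfect adherence.
* P-gp/BCRP biliary clearance carries a substantial share of
  elimination here, so transporter-abundance sweeps move exposure more
  than a full-PBPK model reports; gut CYP3A4 sweeps are correctly
  negligible.
* Age effects are mild (~1.4-fold AUC from 40→90 y), weaker than
  full-PBPK population libraries produce.
* Perpetrator "effective" constants are tied to the unbound systemic
  concentration scale of this engine and should not be quoted as
  in-vitro values.
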