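# Methods

This note records the model structure, parameter provenance, numerical
choices and the places where the design was genuinely open. Units are fixed
throughout: time h, volume L, flow L/h, amount mg, concentration ng/mL
(mg/L × 1000), dose mg, eGFR mL/min.

## Model structure

The body is a mamillary whole-body PBPK system: twelve perfusion-limited
tissue compartments (heart, brain, muscle, adipose, skin, bone, liver,
kidney, gut, spleen, pancreas, rest), a lung in series between the venous
and arterial blood pools, and a liver that receives the hepatic artery plus
the venous outflow of gut, spleen and pancreas. Perfusion-limited transport
was chosen over a permeability-limited (two-phase) tissue model because
vildagliptin is a small, highly permeable molecule; for such compounds the
two descriptions converge and the perfusion-limited form is simpler and
faster. The blood:plasma ratio defaults to 1 (erythrocyte:plasma partition
coefficient of 1 at hematocrit 0.47), so blood and plasma concentrations
coincide and venous plasma is what the engine reports.

### Reference anatomy

The paper-trail for a virtual individual starts from an embedded 70-kg adult
table (`data/reference_anatomy.csv`) with organ volumes and blood-flow
fractions of a 336 L/h cardiac output, compiled from the standard
ICRP/Brown reference-physiology compilations. All volumes, flows and
cardiac output scale linearly with body weight. Organ flow fractions sum to
exactly 1, and flow conservation (Σ organ inflows = cardiac output) is an
enforced invariant — also after inter-individual variability, where flows
are renormalized to the (perturbed) cardiac output.

### Partition coefficients

Tissue:plasma partition coefficients use the Poulin–Theil
tissue-composition equation on an embedded fractional water / neutral-lipid
/ phospholipid table (`data/tissue_composition.csv`, standard human values
from the tissue-composition literature). Non-adipose tissues use the
octanol:water partition coefficient of the neutral species (logP 1.55, the
optimized input value; the literature 1.12 is retained as metadata) with
tissue binding approximated by fu_t = 1/(1 + 0.5·(1 − fu_p)/fu_p); adipose
uses the ionization-corrected vegetable-oil:water coefficient
(log P_vo:w = 1.115·logP − 1.35, times the neutral fraction at pH 7.4).
Because vildagliptin is a base with pKa 9.7, only ~0.5% is neutral at
plasma pH and adipose partitioning is strongly suppressed
(K_adipose ≈ 0.18 versus K_muscle ≈ 1.5); the resulting steady-state volume
of distribution is ≈ 70–100 L, consistent with the compound's known ~71 L.

### Elimination

Two processes, both linear at therapeutic concentrations (Cmax is two
orders of magnitude below Km):

* **Hydrolysis** (Michaelis–Menten, Km 190 µM, Vmax 23.31 nmol/L/s) acts on
  the unbound tissue-water concentration. Vildagliptin's cyanopyrrolidine
  is cleaved by DPP-4 itself and by broadly distributed hydrolases; DPP-4
  sits largely on the vascular endothelium and is most abundant in the
  kidney. The intrinsic capacity is therefore distributed across tissues in
  proportion to perfusion (vascular surface), not tissue bulk, and carries
  a renal-function dependence g = (1 − w) + w·(eGFR/110) with
  w = `metabolic_renal_dependence` = 0.85. The value 0.85 mirrors the ~85%
  of a dose recovered in urine (parent plus metabolites), i.e. the share of
  total disposition tied to the kidney; it also captures the well-documented
  uremic suppression of non-renal drug metabolism in CKD. Localizing all
  metabolism in the liver (or even kidney alone) cannot reproduce the
  observed near-proportional decline of vildagliptin total clearance with
  eGFR: a single-organ process is capped by that organ's blood flow, which
  truncates the CKD effect. This distributed formulation is the package's
  principal structural choice and is deliberate.
* **Renal excretion** is a plasma clearance of 0.18 L/h/kg (13 L/h at
  72.2 kg), scaled linearly by eGFR/110 and by the unbound-fraction ratio.
  It is referenced to venous plasma — the fluid actually sampled and the
  basis on which literature clearances are reported — so a renal-only model
  recovers the nominal CL_R exactly in NCA (this identity is an engine
  test).

The healthy reference eGFR is fixed at 110 mL/min (a documented constant;
the source data only bound it below by 60 mL/min). The per-1.73 m² label is
treated as mL/min without body-surface rescaling.

### Calibration (the model's single fit)

The printed Vmax/Km pair fixes only the saturation shape, not the enzyme
abundance (the volume basis of the printed Vmax is unspecified). The
scaling factor on hydrolytic capacity is therefore calibrated **once**, by
`VildagliptinPBPK.fit()`: a bracketed root search (scipy `brentq` on the
log of the scaling) matches the NCA clearance of a simulated 25 mg IV
infusion (30 min, 68.1 kg reference subject) to 52.1 L/h. Clearance is
monotone in the scaling, so the root is unique; the fitted value is ≈ 1.8
and is reported by `summary()`. No other parameter is ever fitted.

### Oral absorption

Solid drug dissolves in place along the GI tract with a Weibull cumulative
release (t50 = 50 min; shape not reported, default 1.0 = exponential,
exposed in the drug parameters). Lumen transit is: stomach (first-order
emptying, t½ = gastric emptying time) → three serial small-intestinal
compartments (total mean transit = the intestinal transit time parameter)
→ one colon compartment (mean residence 20 h, a fixed constant). Dissolved
drug is absorbed from each post-gastric segment into the portal inflow at
k_a = P_int × (S/V), with the effective surface-to-volume constant
S/V = 1.8 cm⁻¹ for the small intestine — a one-time setting chosen so the
healthy oral bioavailability ≈ 1, matching the dose-normalized oral/IV AUC
ratio of the reference data — and 25% of that in the colon. The colon
matters: with a 50-min dissolution half-time, roughly 40% of a dose is
still undissolved when it leaves a 2.1-h small intestine; without colonic
absorption the model's bioavailability would drop to ≈ 0.55, contradicting
the near-complete absorption seen clinically. Solubility (60 mg/mL) is high
enough that dissolution is never solubility-limited at ≤ 200 mg, so no
precipitation model is included.

IV dosing is a zero-order infusion into the venous pool; the infusion
duration of the reference study is not reported and defaults to 30 min
(configurable).

### Mass ledger

Every simulation returns a time-resolved ledger with cumulative absorbed,
metabolized, renally excreted, amount in body, and unreleased/unabsorbed in
gut. The conservation check is
metabolized + renally excreted + in body + unreleased = dose (within 0.1%,
in practice ~10⁻⁸ relative); "absorbed" is redundant with the others
(absorbed drug is subsequently in-body or eliminated) and is checked
separately as dose − unreleased.

## CKD configuration

Stage parameter sets (moderate: eGFR 48 mL/min, gastric emptying 20.63 min,
transit 2.94 h, hematocrit 0.42, protein scaling 0.93; severe: 29 mL/min,
39 min, 4.12 h, 0.37, 0.83) overwrite the healthy values; the effective
unbound fraction is recomputed as fu′ = 1/(1 + s·(1/fu − 1)) (binding-site
dilution: scaling the binding-protein pool by s scales the bound:free
ratio by s). Applying a stage is idempotent and the healthy stage is the
identity.

## Virtual populations

A population spec fixes n, female fraction, age range, weight mean ± SD and
stage. Weights are truncated-normal (bounds 30–150 kg), ages uniform, sex
Bernoulli. Organ volumes and flows get independent log-normal
inter-individual variability with a 15% CV (median-preserving, flows
renormalized to conserve cardiac output); the source model only states that
1000-subject cohorts were used, so the 15% CV is this package's documented
choice of a typical anatomical variability. Sex has no effect beyond the
sampled weight. Default demographics per stage mirror the packaged study
table (healthy 68.1 ± 7.1 kg, 45% female; CKD groups ≈ 63 kg with only the
mean printed, so SD is taken as a 15% CV). Sampling is deterministic given
the seed.

## NCA

Single-dose, linear-up/linear-down trapezoid for AUC_last; λz from the
best adjusted-R² log-linear window over the last 3–6 points, the window
allowed to start at (not before) Tmax; trailing non-positive concentrations
are treated as below quantification and excluded from the terminal fit;
AUC0–∞ = AUC_last + C_last/λz; CL/F = dose/AUC0–∞ with exact mg→ng and
mL→L conversions. Profiles with > 20% extrapolated AUC are flagged.
Population summaries report arithmetic mean, SD, 5th/95th percentiles, min
and max.

## Qualification statistics

R = predicted/observed; fold error is the identical quotient. AFE defaults
to the magnitude convention 10^|mean log₁₀ FE| (so a uniformly
under-predicting parameter still reads as an ≥ 1 average fold deviation),
with the signed convention — equal to the geometric mean — available; the
magnitude convention is what reproduces the published renal-impairment
clearance AFE of 1.30 from fold errors that are all < 1. Mean R ratios
carry t-based 95% CIs on the untransformed ratios. The acceptance window is
0.5 ≤ R ≤ 2.0, closed at both ends. VPC bands are per-time 5th/95th
percentiles, mean, min and max over the simulated cohort, with the fraction
of observed points inside the band reported.

## Dose adjustment

`find_equivalent_dose` bisects on dose until the CKD population mean
AUC0–∞ (total or fu-weighted unbound) matches a healthy reference exposure
within 5% (the matching tolerance is this package's choice; kinetics are
linear, so bisection is guaranteed to converge and the one-step estimate
dose × AUC_healthy/AUC_CKD is used as an independent cross-check in tests).
The healthy reference population is demographically matched to the CKD
study (~63 kg) rather than to the heavier healthy reference study; with
that convention the computed equivalent doses are ≈ 56% (moderate) and
≈ 34% (severe) of 50 mg. The literature this model tracks reports the same
analysis with the two group labels interchanged between its results and
discussion sections ("57%" vs "30%"); the package simply reports the
computed percentage per stage and leaves the bracket 30–60% as the robust
statement. Total-AUC and unbound-AUC matching agree within ~2% because the
unbound fractions of the two populations differ by < 2%.

## Synthetic observed studies

The evaluation data behind the packaged tables were digitized
concentration–time profiles; they are emulated, not redistributed. A
synthetic study simulates its printed demographics with the engine, samples
at a sparse clinical grid (default 0.25–24 h, eleven points; the cited
studies do not print their grids), and multiplies by log-normal residual
noise exp(ε), ε ~ N(0, σ²) with σ² = ln(1 + CV²), default CV 15%
(digitization plus assay error — a documented assumption). A deliberate
clearance mis-specification can be injected as an exact exposure scaling
(valid under linear kinetics) to demonstrate that the two-fold flag detects
a 2× clearance error: with a noiseless 2× error the study-level ratio sits
exactly on the window boundary, so detection is asserted statistically —
the per-subject flag rate rises from ~0 to ≳ 25–50% and the study-mean
ratio shifts to ≈ 2 (AUC) / ≈ 0.5 (CL).

Because generator and evaluator share the engine, the self-consistency
loop (generate → NCA → R ratios centred on 1) validates the pipeline's
internal coherence, not the model's fidelity to real patients; the
packaged observed/predicted tables provide the external anchor.

## Numerical choices

LSODA (scipy `solve_ivp`) with rtol 10⁻⁷ / atol 10⁻⁹ mg; integration is
split at the infusion stop time so the discontinuity never crosses a solver
step. Output every 0.1 h over 24 h by default (keeps AUC extrapolation
≈ 0–2%); halving tolerances moves Cmax and AUC by < 0.1% (tested). A
negative state beyond 10³·atol aborts with a diagnostic. Weibull shapes ≠ 1
use the time-dependent hazard b·ln2·t^(b−1)/t50^b with t clipped at 10⁻⁶ h
to avoid the t = 0 singularity for b < 1. Zero-dose regimens short-circuit
to an all-zero profile.

## Problem sizes

The packaged defaults used by the tests and the reproduction script are
100-subject populations for exposure predictions, 16–50 subjects per
bisection step for dose adjustment, and 20-subject synthetic studies for
the recovery checks — sizes at which population means are stable to a few
percent, which is well inside the two-fold qualification window the
results are judged against.

## Known limitations

* No target-mediated (covalent DPP-4) binding, no metabolite (LAY151)
  kinetics, no enterohepatic recirculation, no modified-release
  formulations, no pH-dependent solubility.
* Single-dose only; repeated-dose profiles in the reference tables are
  treated as single-dose (vildagliptin shows no relevant accumulation).
* The perfusion-proportional, eGFR-scaled distribution of hydrolysis is a
  structural simplification calibrated at the whole-body level; it is not
  organ-resolved enzymology.
* Healthy-reference eGFR (110 mL/min), IV infusion duration (30 min),
  colonic residence (20 h), anatomical variability CV (15%) and residual
  noise CV (15%) are documented constants, not reported values.
* Mild renal impairment has no printed stage parameters and is treated as
  healthy physiology.
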