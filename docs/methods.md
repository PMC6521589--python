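# Methods

This note documents the models, conventions and assumptions behind
`chiralpk`, in the spirit of a statistical-methods appendix: everything a
user needs to interpret the numbers the package produces, and nothing it
does not itself compute.

## Structural model and conventions

The enantiomer model is two linked one-compartment systems with a
unidirectional inversion clearance `Cl_RtoS` carrying R into S. Two
conventions are possible for the reported R clearance; this package
treats `Cl_R` as the **total** clearance of R, inversion included, so the
loss of R to routes other than inversion is `Cl_R − Cl_RtoS` and the
constraint `0 ≤ Cl_RtoS ≤ Cl_R` is structural. The evidence for this
reading over the additive one (`Cl_R,total = Cl_R,other + Cl_RtoS`): the
published group summaries satisfy `Cl_RtoS < Cl_R` in all four age
groups, and `ln2·V_R/Cl_R` reproduces the published R half-lives closely
(e.g. 21.6 vs 22.6 ± 5.5 min in the neonatal group), whereas adding the
inversion term on top does not. The additive convention remains available
via `EnantiomerParams.from_additive_convention` for sensitivity analysis.

Units are fixed package-wide: time in minutes, volumes in mL/kg,
clearances in mL/(min·kg), concentrations in µg/mL, doses in mg/kg
(converted internally to µg/kg). All parameters are weight-normalized;
whole-body values appear only in the allometry layer (multiply by BW).
Each enantiomer receives half of the racemic dose. Total drug is the
pointwise sum of the measured R and S concentrations, never an
independent analyte.

Solutions are exact sums of `c·t^p·e^(−at)` terms, built by pushing the
dosing inputs through the compartment cascade with a closed-form
convolution rule. When two rates coincide within `1e−9 min⁻¹` the
degenerate `t·e^(−kt)` branch is taken; this keeps the solution continuous
through the `ka → ke` limit. Multi-dose curves are superpositions of
shifted single-dose solutions (the model is linear); a stiff LSODA
integration of the depot+central ODE system, with dosing handled by
piecewise re-initialization, is shipped as the independent numerical
oracle (`model.ode_regimen`) and agrees with the closed forms to ~1e−11
relative over randomized parameter draws.

## Estimation

Per-subject bounded trust-region least squares
(`scipy.optimize.least_squares`, TRF) on log-transformed positive
parameters, with proportional (1/ŷ) weighting — concentrations within a
profile span two orders of magnitude, and the assay error is
predominantly relative. The weight is floored at 0.1% of the profile
maximum so near-zero predictions cannot dominate. Initial values come
from NCA quantities (`V ≈ D/C_first`, `Cl ≈ D/AUC_inf`); on
non-convergence (or, for fits expected to interpolate noise-free marker
data, on a non-zero final cost) three deterministically jittered restarts
run and the lowest weighted RSS wins.

The scheme is sequential and two-stage, mirroring the source analysis:

1. **IV fit** — joint fit of both enantiomer profiles for
   `V_R, Cl_R, Cl_RtoS, V_S, Cl_S`. The inversion constraint is enforced
   by parameterizing the inversion *fraction* `Cl_RtoS/Cl_R ∈ [0, 1]`.
2. **Oral fit** — `ka_R, ka_S, F_R, F_S` with `Cl_RtoS` frozen
   bit-identically at its IV estimate and V/Cl fixed at their IV
   estimates. Fixing V/Cl is deliberate: with `Cl_RtoS` frozen in
   absolute units the oral model is invariant under the per-enantiomer
   rescaling `(V, Cl, F) → (cV, cCl, cF)`, so bioavailability is not
   identifiable from oral data alone. Re-estimation of V/Cl is available
   behind a flag (`reestimate_distribution=True`) for sensitivity work.
   `F` is a free positive parameter and is never clipped at 1 — neonatal
   R-bioavailability estimates above 100% are a real feature of
   AUC-ratio-based F.

Group summaries are means/SDs of per-subject estimates ("fit each pig,
then summarize"); no mixed-effects machinery is used or intended.
Records below the LOQ are excluded before fitting. The default contract
demands ≥ 6 quantifiable observations per enantiomer; the pipeline
relaxes the floor to 4 because fast-clearing subjects (neonatal R
half-life ≈ 21 min against a 0.25 µg/mL LOQ) legitimately retain only
~5 quantifiable R samples, and dropping them would censor precisely the
high-clearance tail.

Renal markers: iohexol is fitted bi-exponentially
(`C = A·e^(−αt) + B·e^(−βt)`, rates parameterized as β and α−β so the
ordering cannot invert), with `GFR = Cl = D/(A/α + B/β)`; macro constants
are converted to micro parameters (V1, Cl, Cl_d, V2) for reporting.
PAH is fitted mono-exponentially and its clearance reported as eRPF
("estimated" because porcine PAH elimination includes acetylation, so the
value exceeds true renal plasma flow).

Secondary parameters: `C0 = (D/2)/V` (IV), `t½ = ln2·V/Cl`,
`AUC_0→∞ = F·(D/2)/Cl` (oral) or `(D/2)/Cl` (IV); oral Cmax/Tmax are
located by bracketed maximization implemented as a Brent root of the
analytic time-derivative, which matches the closed-form
`ln(ka/ke)/(ka−ke)` to better than 1e−8 (value-only maximization cannot
resolve a flat peak this finely).

## Non-compartmental analysis

* AUC uses the linear-up/log-down trapezoid: rising, flat or
  zero-touching segments are linear; strictly decreasing all-positive
  segments use `(C_i − C_{i+1})·Δt / ln(C_i/C_{i+1})`. A target time
  inside a segment is reached by interpolating with that segment's own
  rule (the study grids contain 180 min, so the AUC(0–3 h) interpolation
  is normally a no-op). No extrapolation beyond the last sample.
* λz comes from a log-linear regression over the last 3–6 positive
  points, excluding Tmax, with the window chosen by best adjusted R² — an
  explicit convention for a step commercial NCA tools leave configurable.
  `AUC_0→∞ = AUC_0→tlast + C_last/λz`; λz-dependent outputs are flagged
  missing (NaN, n=0) when no admissible window gives a positive slope.
* Bioavailability: dose-normalized AUC(0–180 min) PO/IV ratio, not
  clipped at 1. By default both profiles must cover 180 min; the
  pipeline relaxes this for LOQ-censored fast-clearing profiles, whose
  AUC then runs to the last quantifiable sample (BLQ data are excluded
  and nothing is extrapolated, so the missing tail is negligible by
  construction). Accumulation: AUC(0–360 min) of the 13th oral dose over
  the 1st, both by the same trapezoid rule; the pre-dose concentration of
  the dose-13 profile is retained as its t=0 value (superposed baseline,
  no subtraction) — configurable by filtering the input records.
* LOQ rule: values **strictly below** 0.25 µg/mL are excluded; 0.25
  itself is retained. An upstream BLQ flag is honored even above the LOQ.

## Allometry

`ln y` on `ln x` by unweighted OLS; the slope is the allometric
coefficient. Both individual-subject and group-mean regressions are
supported; the group-mean mode (four points, one per age group) is the
default reporting path because only group summaries are publicly
available. Mean body weights are 3.0, 7.0, 20.1 and 138 kg — the oldest
group's value is the midpoint of the reported male (134 kg) and female
(142 kg) sub-cohorts and can be overridden. Regressing whole-body
total-drug clearance (group-mean per-kg Cl × BW) on BW reproduces the
published coefficient: 0.9725 vs 0.97. The corresponding volume exponent
from group means is 0.833 (published: 0.86, fitted on individuals); the
enantiomer-specific coefficients are likewise not expected to reproduce
exactly from group means.

## Synthetic cohort

The generator emulates the study design: four age groups × 8 pigs
(4♂/4♀), single 5 mg/kg IV bolus, oral 5 mg/kg t.i.d. × 5 days at
within-day offsets 0/360/720 min (6-h intervals, 12-h overnight gap;
dose 13 at 5760 min), rich IV-day sampling
(0, 5, 10, 20, 30, 45, 60, 90, 120, 150, 180, 240, 360, 480, 1440 min),
rich profiles after oral doses 1 and 13
(0…360 min, 15 samples), trough + 30 min otherwise, and two renal-marker
occasions (iohexol 64.7 mg/kg, PAH 10 mg/kg; 0–480 min grid).

Between-subject variability is log-normal with the published arithmetic
mean/SD matched by moments (the source reports mean (SD) only, so the
distributional family is a documented choice). The inversion clearance is
not drawn independently: with independent draws roughly a third of
neonatal subjects would violate `Cl_RtoS ≤ Cl_R` (9.3 ± 2.1 vs
10.6 ± 2.7). Instead `Cl_RtoS = f · Cl_R` with an independent log-normal
inversion fraction `f` whose moments are chosen so the `Cl_RtoS` mean is
exact and its SD approximates the published one; when the published
`Cl_RtoS` CV is smaller than the `Cl_R` CV the fraction becomes
deterministic and the realized SD inherits the `Cl_R` CV (a mild
inflation for the oldest group). Residual error is
`y·(1+ε_p) + ε_a` with ε_p ~ N(0, 0.10) and ε_a ~ N(0, 0.05 µg/mL) —
assumed values; the source reports only analytical precision. Observations
are floored at zero and flagged BLQ below 0.25 µg/mL. Sex is a label only
(the study found few sex differences); no sex effect is generated.

Marker generating values (GFR 1.8–3.5, eRPF 7–16 mL/(min·kg) across the
groups, iohexol V1/V2/Cl_d = 180/120/5, PAH V = 300 mL/kg) are realistic
porcine settings chosen once for the generator — the source presents its
marker results graphically, so these are package defaults, not anchors.

What the generator does **not** emulate: nonlinear protein binding or
saturable inversion, S→R back-conversion, absorption lag times, fed/fast
absorption differences (the fed flag is metadata), enzyme maturation
within an age group, catheter failures/dropout, or assay batch effects.
Passing tests therefore demonstrate correctness of the analysis chain
under the stated statistical model, not robustness to every feature of
real data.

## Validation problem sizes and known limitations

The validation suite uses 100 randomized draws for closed-form/ODE
agreement, all four age-group parameter sets for noiseless recovery, and
20 replicate cohorts of n=8/group for stochastic recovery — sizes chosen
to give stable Monte-Carlo summaries at interactive runtimes. Observed
results: oracle agreement ~2e−11 sup-norm relative, noiseless recovery
~2e−15, worst group-mean bias ~11% over 20 replicates.

One validation target is not reliably attainable and is knowingly left
failing rather than weakened: preserving the full published age-ordering
of the inversion clearance (9.3 > 4.6 > 3.9 > 1.6 mL/(min·kg)) in ≥ 95%
of replicates. The 4-week and 8-week groups differ by only 0.7 mL/(min·kg)
while the group-mean sampling SD at n=8 with the published
between-subject SDs is ~0.6 before any estimation noise, so the
per-replicate ordering probability is ~0.85–0.9 by construction
(measured: 0.70 over 20 replicates including estimation noise). This is a
property of the study's own effect sizes and sample size, not of the
estimator; the first and last groups order correctly in essentially every
replicate.

Other limitations: no population (mixed-effects) or Bayesian estimation;
no urinary-excretion analysis (no urine data exist to model); no
fixed-exponent interspecies scaling predictions; the proportional
weighting and the λz window rule are documented conventions where the
source's software settings are unreported.
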