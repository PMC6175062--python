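# Methods

`copropk` implements a semimechanistic population-pharmacokinetic analysis
of coproporphyrin I (CPI) as an endogenous biomarker of hepatic OATP1B
transport, together with the forward simulations that such a model is built
for: predicting drug–drug-interaction (DDI) magnitudes for hypothetical
OATP1B inhibitors and sizing crossover biomarker studies. This note
documents the models, the synthetic-data generator, the estimation
machinery, and the numerical and design choices, so that every reported
number can be traced to an explicit assumption.

## Structural models

**Perpetrator (rifampicin, RIF).** One-compartment disposition with
first-order elimination (CL/V) and a continuous transit-compartment
absorption delay: the drug input rate into the depot is

    in(t) = F·D·ktr·(ktr·t)^n·e^(−ktr·t) / Γ(n+1),  ktr = (n+1)/MTT,

with the transit number n continuous (estimated ≈ 8.6) and mean transit
time MTT in hours. The input is evaluated analytically in log space rather
than as a chain of discrete compartments, because n is a continuous
estimate. F is fixed to 1; CL and V are apparent oral parameters. Doses are
converted to molar amounts with MW 822.94 g/mol (plasma concentrations in
µM).

**Biomarker (CPI).** A turnover model: zero-order synthesis ksyn (nM/h)
into a single volume V (L), first-order loss through a biliary route CLb
(L/h) and a renal route CLR (L/h), the latter feeding an observed urine
compartment:

    dC/dt = [ ksyn/(1 + ρ·x) − CLb·C/(1 + r·x) − CLR·C ] / V,
    dU/dt = CLR·C,            x = C_RIF(t)/Ki.

The perpetrator inhibits the biliary route competitively through its total
plasma concentration and a total Ki (µM); the unbound Ki is Ki·fu with
fu = 0.11. r is the I/Ki multiplier of a DDI scenario (r = 1 is rifampicin
itself; other values emulate weaker or stronger perpetrators). ρ scales a
hypothetical inhibition of the synthesis rate relative to the effect on
CLb; ρ = 0 (the default and the fitted model) is transporter inhibition
only. The form ksyn/(1+ρ·x) was chosen so that ρ = 0 reproduces the
transporter-only equations exactly and ρ has the same driving term x as the
clearance effect; the sensitivity scenarios use ρ ∈ {0, 0.1, 10}.

Because CPI is endogenous, every occasion starts at the individual steady
state Css = ksyn/(CLb+CLR) at the beginning of the pre-dose urine interval
(−7 h); the urine compartment resets at each collection-interval start.

**Covariate.** The distribution volume carries a binary
perpetrator-condition covariate (V = 6.59 L at baseline, 3.4 L when the
perpetrator is co-administered), applied after the random effects with a
shared random effect. The same construction shifts the rosuvastatin
distribution parameters (V1, V2, Q). Hypothetical-inhibitor simulations
retain the shift: the shifted volume is treated as a property of the
inhibited condition, not of rifampicin specifically. Note that the
baseline volume never enters the likelihood in this parameterization — a
steady-state baseline has no observable kinetics — which is why it is
excluded from estimation by default (see *Identifiability*).

**Probe drug (rosuvastatin, RSV).** Two-compartment disposition with
first-order absorption, elimination split into biliary (inhibitable, same
competitive form) and renal clearances, and an observed urine compartment.
Concentrations in µM (MW 481.54 g/mol), urine amounts in nmol.

## Population layer

Parameters are log-normal: θ_ik = θ·exp(η_i + κ_ik), with η (IIV) constant
per subject and κ (IOV) drawn independently per occasion. The parameter
table stores variability as %CV on the natural scale and converts with
ω² = ln(1+(CV/100)²). Ω is diagonal (no correlations are reported in the
reference table). Residual error is combined proportional + additive per
observation stream, y = f(1+ε_p)+ε_a; simulated observations may be
negative (an optional LLOQ-censoring switch exists, off by default).
The RSV residual proportional terms in the reference table are stored as
fractions (0.257, 0.578), the reading consistent with the other compounds'
percent entries.

## Synthetic-trial generator

The generator reproduces the reference clinical design: 12 subjects, three
occasions with 7-day washouts (OCC1 600 mg oral RIF, OCC2 5 mg oral RSV,
OCC3 both), rich plasma sampling over 24 h, CPI urine over (−7,0), (0,7),
(7,24) h and RSV urine over (0,7), (7,24) h. The published exact clock
times are not available, so schedules were chosen once to reproduce the
published record counts — RIF 276 (144+132), CPI 420 (144+144+132), RSV 264
(132+132) — including a pre-dose CPI sample per occasion so baseline
statistics can be formed: CPI {0, 0.25, 0.5, 1, 1.5, 2, 3, 4, 6, 8, 12, 24} h
(OCC3 drops 0.25), RIF {0.25 … 16, 24} (OCC3 drops 16), RSV the 11-point
variant. Urine is generated complete (the published urine counts imply a
few missing samples whose pattern is unknown; a missingness mask exists but
defaults to off). η is shared across occasions; κ and residuals are fresh
per occasion/row; every subject's own simulated RIF exposure drives that
subject's CPI and RSV inhibition. Everything is reproducible from a single
integer seed.

What the generator does *not* emulate: body-size or genotype covariates
(the reference cohort was wildtype *SLCO1B1*), dropout/missingness
patterns, circadian variation of the baseline, enterohepatic
recirculation, and assay LLOQ handling. Passing tests therefore show that
the estimation and power machinery behaves correctly *under the stated
model*, not that the model is correct for any particular real cohort.

## Simulation numerics

Two simulation paths exist and are cross-checked in the tests:

- A reference path per subject using an adaptive stiff-capable integrator
  (LSODA, rtol 1e-8, atol 1e-10) with dose times and urine-interval
  boundaries as explicit segment ends.
- A fixed-grid vectorized path used for population work: the linear
  one-state models (RIF depot/central, CPI) use an exponential integrator
  that is exact for source terms linear within a step and unconditionally
  stable; RSV uses RK4 with automatic sub-stepping keeping max(rate)·h
  below 0.5. Grid steps: 0.05 h for DDI/power simulation, 0.02 h for trial
  generation, 0.1 h inside estimation. Halving any of these changes mean
  AUC ratios by < 0.1%, which is far inside the Monte-Carlo noise; the two
  paths agree within 0.5% wherever concentrations are non-negligible (the
  pre-absorption tail below ~10⁻³ of Cmax is compared absolutely).

AUCs are linear trapezoids with no extrapolation; all DDI metrics use the
0–24 h window on the clinical sampling schedule.

## Estimation

The marginal likelihood is approximated subject-by-subject with the
Laplace method, with the residual variance evaluated at the conditional
prediction (FOCE-with-interaction flavour). The inner problem — maximizing
the joint density over each subject's random-effect vector (η stacked with
per-occasion κ, 8–11 dimensions) — is a damped Newton iteration with
Gauss–Newton curvature from a finite-difference prediction Jacobian and
Levenberg–Marquardt fallback, vectorized across subjects: one batched call
into the grid simulators evaluates all subjects × all perturbed
random-effect vectors. An exact finite-difference Hessian replaces the
Gauss–Newton one for the log-determinant when the random-effect dimension
is ≤ 2 (cheap there); on one-random-effect problems the whole construction
agrees with adaptive quadrature to well under 0.1 of an objective-function
unit (tested to 0.5).

Fixed effects are optimized on the log scale with Powell's method, bounded
to a factor-10 window around the start. The inner modes are *anchored*:
they are recomputed from scratch once at the start of a fit and then used
as the fixed warm start for every objective evaluation, making the
objective a deterministic function of the parameters (re-anchoring during
the search makes the objective history-dependent and can strand the
optimizer; this was observed, not hypothesized). Random-effect variances
and residual sigmas are held at their input values by default and can be
estimated jointly (log scale) with `estimate_variances=True`.

The sequential workflow fits the perpetrator model to its plasma data
first, then fixes each subject's empirical-Bayes concentration *curve*
(continuous, from the fitted ODE parameters — not interpolated
observations) as the inhibitor input of the CPI fit (plasma + urine, both
conditions simultaneously) and optionally the RSV fit.

Replication of any specific software's objective-function values is
explicitly not a goal; the acceptance standard is recovery of the
generating parameters from simulated trials. In 20 replicate 12-subject
trials at the reference parameters, the median bias of ksyn, CLb, CLR and
Ki is below 10% (test suite). The perpetrator absorption parameters
(ka, MTT, n) show large trial-to-trial scatter — the transit chain and the
first-order absorption step are nearly exchangeable on this design, and
the reference analysis itself reported a failed covariance step and a 46%
SE for ka — but the resulting concentration curves, which are all the
downstream fits consume, are stable.

## Identifiability

With plasma data alone the CPI system is observationally equivalent under
(ksyn, CLb, CLR, V) → (c·ksyn, c·CLb, c·CLR, c·V): only ratios to V are
identified. Urine amounts pin CLR absolutely and thereby the volume. The
package expresses this as profile likelihoods: the profile of the
DDI-condition volume V_rif is flat (rise < 3.84, the χ²₁ 95% cut) under
baseline-plasma-only data and sharply curved (rise ≫ 3.84 within ±50%)
once urine and the DDI occasion are included. The baseline volume V is the
degenerate limit of this: baseline occasions sit at steady state, so V has
no observable effect at all and is excluded from the default fit.

## DDI simulation and power

Each virtual subject is a two-period one-way crossover (baseline, washout,
single 600-mg perpetrator dose) with shared η, per-period κ, and the
subject's own perpetrator PK driving the inhibition scaled by r. Per
subject, AUC(0–24) is computed by trapezoid on the clinical CPI sampling
schedule from the noise-free model concentrations; the mean of per-subject
AUC ratios is the reported DDI magnitude, the median profile is used for
plots. A switch (`include_residual`) adds residual error to the sampled
concentrations first; it is off by default — with it on, the simulated
power at the weak-inhibitor boundary no longer reproduces the published
minimal sample size, consistent with the source analysis having applied
the trapezoid to simulated model concentrations. The perpetrator-condition
volume shift is retained for hypothetical inhibitors (and removable by a
switch): of the switch combinations examined, only this one reproduces the
published DDI magnitudes and the published minimal sample sizes
simultaneously — dropping the shift underestimates the strong-inhibitor
plateau, while computing the AUCs on a dense grid instead of the clinical
schedule shifts the weak-inhibitor power just below its published
threshold. The residual ~5–7% overestimate of the mid-range mean AUCRs is
the arithmetic mean over a right-skewed population combined with the
sparse-schedule trapezoid, and sits well inside the Monte-Carlo +
model-ambiguity tolerance used for those quantities.

Power: for each sample size n, replicate trials are formed from a common
pool of simulated crossover subjects (replicate × subject layout; reusing
the pool across n is a variance-reduction device and leaves each power
estimate marginally valid), and a two-sided one-sample t-test of mean
log AUCR ≠ 0 at α is applied; power is the rejection fraction over (by
default) 5000 replicates. The default planning grid is {10, 15, 20, 25,
30}: the published minimal sizes are both multiples of five, and under any
subject-level variability consistent with the published weak-inhibitor
result the power for the moderate inhibitor is ≈ 1 for all n ≥ 7, so the
published "10 subjects" can only be the smallest predefined sample size
cleared — a step-1 grid would report a crossing near n = 5. The grid is an
explicit argument everywhere; tests also exercise finer grids, the type-I
error calibration at r = 0 (which relies on IOV making the null log AUCR
non-degenerate), and the monotonicity of power in n and r.

## Problem sizes used by the shipped checks

Mean AUCR targets: 3000–10000 virtual subjects per scenario (Monte-Carlo
SE of the mean ≤ 0.02). Power targets: 1500–5000 replicates per sample
size.
Parameter recovery: 20 replicate 12-subject trials, sequential RIF→CPI
fits with variances fixed at the generating values (the RSV stage is
exercised separately; all recovery-target parameters belong to the CPI
model). Profile likelihoods: 5-point grids at ±50% around the reference
volume. These sizes were chosen so the whole validation runs on a single
CPU in well under half an hour while keeping Monte-Carlo error a small
fraction of each acceptance tolerance.

## Known limitations

- The Laplace/Powell stack is built for this model family (a handful of
  fixed effects, ≤ ~12 random-effect dimensions), not as a general NLME
  engine; there is no covariance step (SEs would need a bootstrap).
- The anchored-objective device trades a small risk of a locally stale
  inner mode for determinism of the outer search; pathological multimodal
  subjects are handled by LM damping but a global inner search is not
  attempted.
- The perpetrator absorption triplet (ka, MTT, n) is weakly identified on
  a 12-subject design; only its implied concentration curves should be
  interpreted.
- Urine collection is modelled as complete and exactly timed; the
  published data had a few missing urine records whose pattern is unknown.
- The hypothetical-inhibitor machinery inherits rifampicin's PK time
  course for every scenario (only the potency/exposure ratio changes), as
  in the source analysis; a perpetrator with different kinetics would need
  its own model.
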