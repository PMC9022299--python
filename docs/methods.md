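# Methods

## Structural model and solution

Drug amounts follow the linear mammillary two-compartment system

    dA1/dt = rate(t) − (k10 + k12)·A1 + k21·A2
    dA2/dt = k12·A1 − k21·A2,          C(t) = A1 / V1

with k10 = CL/V1, k12 = Q/V1, k21 = Q/V2. The hybrid rates λ1 > λ2 > 0 are
the roots of λ² − (k10+k12+k21)λ + k10·k21; λ2 is computed as
(k10·k21)/λ1 to avoid subtractive cancellation. If the roots ever came
within a relative 1e-9 of each other, λ2 is nudged apart by 1e-9·λ1; this is
analytically unreachable for positive distinct micro-constants and exists
only to guard degenerate inputs.

A constant-rate infusion started at t=0 gives
C(t) = R·Σᵢ aᵢ(1 − e^(−λᵢt)) with per-mode amplitudes

    a1 = (λ1 − k21) / (V1·λ1·(λ1 − λ2)),   a2 = (k21 − λ2) / (V1·λ2·(λ1 − λ2)),

so the plateau is R·(a1+a2) = R/CL. Finite dosing histories superpose
shifted copies of the single-infusion solution; repeated dosing at interval τ
uses the per-mode accumulation factor 1/(1 − e^(−λτ)), which makes the
steady-state solution exact (no truncated sums). For the continuous-infusion
encoding (tinf = τ = 24 h) the general formula collapses algebraically to
rate/CL at every time point.

The trough is defined as the concentration at t = τ⁻ of a steady-state
interval whose origin is the start of infusion; for continuous infusion the
trough is the plateau. An independent verification path integrates the ODE
system segment-by-segment (Radau, rtol 1e-11, atol 1e-12, analytic constant
Jacobian) and is used only in tests; closed form and integrator agree to
relative 1e-6 or better on randomized parameter/regimen sets (typically
~1e-10).

## Covariate model

Population clearance is CL = θ_nr + (CrCl/120)^θ_r with θ_nr = 3.5 L/h and
θ_r = 2.5. The published equation is typeset ambiguously (a literal reading
cancels the non-renal term, leaving (CrCl/120)^θ_r alone). The additive
reading was adopted because it is the unique simple reading that reproduces
the published attainment grid; the discrimination analysis
(`analysis/02_clearance_reading_check.py`) shows the literal reading misses
12 of 20 grid cells by more than 15 percentage points (max ≈ 49), while the
additive reading stays within Monte Carlo tolerance. CrCl enters in mL/min,
normalised by 120 exactly as printed; no body-surface correction is applied —
scenarios are defined directly by the covariate value.

## Virtual population

Each scenario fixes CrCl (160, 200 or 240 mL/min for the ARC grid) and draws
1000 subjects (the study size; any n is supported) with independent lognormal
random effects: CL_i = TVCL·e^η1, V1_i = V1_pop·e^η2, η1 ~ N(0, 0.327²),
η2 ~ N(0, 0.561²). Reported IIV percentages are interpreted as 100·ω (the SD
of the log-scale effect), the usual reporting convention for this model form;
the alternative CV-to-ω transform (ω = √ln(1+CV²) = 0.319/0.523) was
evaluated and changes grid cells by well under one percentage point on
average, so the simpler fixed convention is kept. No η correlation is
modelled (none is reported). Q and V2 carry no IIV.

Proportional residual error (σ = 0.223, truncated below zero) is available
but **excluded from PTA by default**: attainment is judged on
individual-predicted troughs, which is what back-calculates to the published
grid; a flag (`--include-residual-error`) enables it for sensitivity
analysis.

Randomness: one master seed spawns per-scenario substreams via numpy
`SeedSequence.spawn`; each child is collapsed to a 31-bit integer so seeds
survive round-trips through CSV/JSON. Scenarios are independent by default;
a common-random-numbers option reuses one seed across the grid for
monotonicity comparisons (whether the original study reused cohorts across
regimens is not stated; fresh draws are the default here).

## Target attainment

PTA uses strict comparisons: P(Cmin > 12) and P(Cmin > 46) in percent, plus
the joint in-window probability P(12 < Cmin ≤ 46) as a clearly-marked
extension. Trough percentiles are reported at {5, 25, 50, 75, 95}% with
linear interpolation between order statistics (numpy's default quantile
rule; the original analysis does not state its rule). Values are compared
unrounded and rounded only at presentation time.

The packaged reference grid stores the published integer percentages;
"<0.5" cells (and one printed "0" sibling, plus a second such cell found in
the table text) are stored as ≤0.5 upper bounds with a marker column, and a
simulated value at or below the bound counts as exact agreement. The
comparison tolerance is ±4 points at n=1000 (≈2.5 binomial SD at p=0.5) and
±2 points at n=50,000, where residual disagreement reflects the reference
values' own 1000-subject origin.

### Fidelity of the reproduction

With the printed parameters the simulated grid tracks the published one with
a mean absolute deviation ≈1.6 points at the study size. A small systematic
offset remains at n=50,000 (mean ≈1.7 points, max 4.7, concentrated in the
intermittent-infusion cells; continuous-infusion cells agree with the exact
lognormal tail probability). Because the closed form is verified against the
ODE oracle and the Monte Carlo engine against the analytic CDF, this residual
offset is attributed to the source of the reference values themselves:
parameter estimates printed to 2–3 significant figures (relative standard
errors 9–29%) and attainment percentages printed as integers from a single
1000-subject draw. Consequently one or two grid cells can sit just outside
the ±4-point band at n=1000, and several exceed ±2 at n=50,000; the
1000 mg q8h/4 h cell at CrCl 160 simulates at ≈79% against a printed 81%,
i.e. at the boundary of the "≥80%" headline claim. The corresponding
assertions in `tests/test_acceptance.py` are stated at their nominal
tolerances and document this rather than papering over it.

## Time to target and loading doses

`time_to_target` locates the earliest time the finite-superposition profile
reaches a threshold: within each infusion/decay segment the profile is
sampled on a dense grid to bracket the first crossing, then refined by Brent
root-finding on the closed form (xtol 1e-10 h). The horizon covers the
approach to steady state (≈14/λ2, capped at 2000 doses, extended once if the
steady-state envelope exceeds the target but no crossing was bracketed);
math.inf is returned as the "never" sentinel when the steady-state maximum —
attained at the end of infusion — stays below the target. Loading-dose
convention: the loading infusion starts at t=0 and the first maintenance
dose at t=τ; overlap handling is not specified by the source analysis, and
this convention keeps the no-loading and loading schedules directly
comparable.

## Problem sizes

The packaged analyses use 1000 subjects per scenario (the study size) and a
50,000-subject replicate to isolate systematic error; the full 20-cell grid
at 50,000 subjects runs in roughly a second because troughs are evaluated in
closed form over parameter vectors. Property tests use 10⁵ draws for moment
checks and 10⁶ for the residual-error unbiasedness check.

## Known limitations

- The model is taken as given: no re-estimation, no parameter uncertainty
  propagation (simulation uses point estimates; RSEs are ignored).
- Fixed CrCl per scenario: no covariate distribution, no within-patient
  renal-function dynamics, although ARC is a transient state in practice.
- Linear kinetics only; no protein binding, renal-replacement clearance or
  oral absorption.
- The virtual population emulates only the statistical structure the
  analysis assumes (lognormal IIV on CL and V1 at fixed CrCl). Passing tests
  therefore demonstrate fidelity to that model, not predictive accuracy for
  real ICU patients.
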