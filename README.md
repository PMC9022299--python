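# levsim

Population-pharmacokinetic dosing simulations for **levetiracetam in
critically ill patients with augmented renal clearance (ARC)**.

Levetiracetam is cleared mainly by the kidneys. In ICU patients with ARC
(creatinine clearance, CrCl, well above 130 mL/min) standard regimens
(500–1500 mg twice daily, short infusion) often fail to keep steady-state
trough concentrations inside the 12–46 mg/L reference range recommended for
therapeutic monitoring. `levsim` implements the published two-compartment
population model for this population and uses Monte Carlo simulation to
estimate, for any regimen and CrCl level, the **probability of target
attainment (PTA)** — the fraction of virtual patients whose steady-state
trough Cmin exceeds 12 mg/L (and the fraction above 46 mg/L) — for
intermittent, extended-infusion (4 or 6 h) and continuous-infusion regimens.

## Model

Two-compartment intravenous-infusion kinetics with parameters

| parameter | value | meaning |
|---|---|---|
| CL | θ\_nr + (CrCl/120)^θ\_r | total clearance (L/h); θ\_nr = 3.5, θ\_r = 2.5 |
| V1 | 20.7 L | central volume |
| Q | 31.9 L/h | intercompartmental clearance |
| V2 | 33.5 L | peripheral volume |
| ω\_CL | 0.327 | SD of the lognormal random effect on CL (IIV 32.7%) |
| ω\_V1 | 0.561 | SD of the lognormal random effect on V1 (IIV 56.1%) |
| σ\_prop | 0.223 | proportional residual error (off by default for PTA) |

Each virtual subject draws CL\_i = TVCL(CrCl)·e^η1 and V1\_i = V1·e^η2 with
independent η ~ N(0, ω²); Q and V2 are fixed. Concentrations are evaluated in
closed form as a two-exponential solution with per-mode steady-state
accumulation factors 1/(1 − e^(−λτ)); a high-accuracy ODE integrator serves as
an independent oracle in the tests. For continuous infusion the steady-state
trough is simply rate/CL.

## Worked example

PTA for 3000 mg/day as a continuous infusion at CrCl 200 mL/min,
1000 virtual subjects:

```text
$ levsim simulate --crcl 200 --dose 3000 --tau 24 --tinf 24 --n 1000 --seed 12345
 crcl  total_daily_dose   dose  tau  tinf  p_gt_12  p_gt_46  p_in_window    p5   p25   p50   p75   p95    n  seed
200.0            3000.0 3000.0 24.0  24.0     88.6      0.1         88.5 10.23 14.48 18.05 22.49 30.35 1000 12345
```

88.6% of subjects hold a steady-state trough above 12 mg/L and essentially
none exceed 46 mg/L (the published value for this cell is 89). The trough
percentiles show the median subject at ≈18 mg/L, comfortably inside the
window. `p_in_window` (the joint probability 12 < Cmin ≤ 46) is an extension
beyond the two published columns.

Time to reach the 12 mg/L target for the typical CrCl-200 subject, without
and with a 1500 mg/0.5 h loading infusion:

```text
$ levsim profile --crcl 200 --dose 3000 --tau 24 --tinf 24 \
    --loading-dose 1500 --loading-tinf 0.5 --hours 48 --out profile.csv
time to 12 mg/L (no loading): 8.75 h
time to 12 mg/L (with loading): 0.09 h
```

Other commands: `levsim grid` runs the full packaged 20-row grid
(CrCl 160/200/240 × regimen) and reports per-cell deviations from the
published attainment values; `levsim compare` re-checks a saved results CSV.

Configuration files are TOML — flat keys override model parameters, and an
optional list of tables defines a custom grid:

```toml
omega_cl = 0.327
theta_nr = 3.5

[[scenarios]]
crcl = 200
dose = 3000
tau = 24
tinf = 24
```

## Analysis scripts

Numbered drivers under `analysis/` write their tables to `results/`:

1. `01_pta_grid.py` — the full attainment grid at n=1000 and n=50,000 per
   scenario, with comparison against the packaged published values.
2. `02_clearance_reading_check.py` — discrimination between the two readings
   of the ambiguously typeset clearance covariate equation.
3. `03_loading_dose.py` — time-to-target with and without a loading dose at
   each ARC level, plus a 48-h concentration profile.

## Scope

The package simulates the given population model; it does not re-estimate it,
model nonlinear kinetics or renal-replacement therapy, or perform Bayesian
dose individualisation from measured levels. See `docs/methods.md` for
modelling conventions, numerical choices and known limitations.
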