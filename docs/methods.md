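# Methods

This note documents the models implemented in `combotrans`, the parameter
choices that matter, the design decisions taken where the methodology was
genuinely open, and what the synthetic-data generators do and do not
emulate.

## Dose–response fitting and synergy scoring

Single-agent curves are decreasing log-logistic functions
`v(d) = lower + (upper − lower) / (1 + (d/EC50)^h)`. The three-parameter
form fixes `upper = 1` (control-normalized data); the four-parameter form
is selected automatically when the zero-dose margin deviates from 1 by more
than 0.1. Fitting is bounded least squares with five deterministic starts
(log-EC50 at the 0.1–0.9 quantiles of the tested log-dose range, Hill slope
alternating 1 and 2); the best SSE wins, and a flat-curve fallback flagged
`converged=False` covers total failure. Derived metrics: **absolute IC50**
is the dose where the fitted curve crosses viability 0.5 (undefined when it
never does), distinct from the EC50 inflection; **Emax** is fitted viability
at the highest tested dose; **AUC** is the mean fractional inhibition of the
fitted curve over the tested log10-dose grid — a convention chosen to match
common growth-response pipeline usage, since the quantity is only defined
relative to a dose range.

Combination matrices are smoothed by fitting a four-parameter curve along
every row and every column and averaging the two fitted surfaces; a slice
whose fit degenerates falls back to its observed values with a logged
warning. Responses are fractional inhibitions `r = 1 − v` computed on the
smoothed surface clipped to [0, 1], so positive excess means synergy. The
Bliss expectation for cell (i, j) is `r_A + r_B − r_A·r_B` and the HSA
expectation is `max(r_A, r_B)`, both built from the smoothed single-agent
margins (using the same surface for margins and interior keeps the excess
of the margins at zero by construction). The **combination score** is the
mean of the `ceil(0.10 · N)` largest excess values over all N matrix cells,
margins included (their excess is ~0, which is conservative). Ties at the
cutoff are resolved by rank, i.e. exactly k values enter the mean — this
keeps the canonical check "one cell at 0.5 in a 10×10 zero matrix scores
exactly 0.05" true, which an include-all-ties rule would not.

## Growth-rate translation and xenograft prediction

Endpoint relative viability v after T = 120 h of treatment converts to the
GR metric using the untreated doubling time Td = 60 h:
`GR = 2^(1 + log2(v)·Td/T) − 1`, and to the control-normalized growth rate
`r_norm = log2(GR + 1) = 1 + log2(v)·Td/T`. GR is computed on the smoothed
viability matrix by default (a switch exposes the raw matrix), floored at
1e−4 before the logarithm.

Nominal in vitro concentrations become free concentrations through the
media fraction unbound (10% FBS defaults: belvarafenib 0.034, cobimetinib
0.196; 5% FBS alternatives 0.068 / 0.3 selectable in config). In vitro free
concentration is treated as directly comparable to in vivo free plasma
concentration — the conversion factor is exposed as a config scalar but
defaults to unity, the empirically supported choice for this drug pair.

Surface lookup is bilinear interpolation in (log10 dose_A, log10 dose_B)
over the nonzero-dose grid, implemented as a tensor-product of 1-D rules.
Queries between zero and the lowest tested dose bridge linearly in *linear*
dose between the zero-dose margin value and the lowest-dose value (log
space is undefined at zero and a log-bridge would overweight the margin);
queries above the grid maximum clamp to the boundary with a logged warning
rather than extrapolating.

Xenograft prediction multiplies the vehicle-arm growth rate
`k = ln(2) / 18 d = 0.0385 /day` by the projected `r_norm` and grows the
shared initial volume (240 mm³) exponentially:
`V(t) = V0·exp(k·r_norm·t)`. Mouse exposures are used as constant effective
free concentrations (point measurements, no mouse PK time course). Bench
formulas — caliper volume `L·W²/2`, percent body-weight change with the
20%-loss flag, and 2^(−ΔΔCt) fold change — live alongside.

## Population PK simulation

Concentrations follow a one-compartment model with first-order absorption,
evaluated by closed-form superposition of doses
`C(t) = Σ D·ka/(V(ka−ke))·(e^(−ke·Δt) − e^(−ka·Δt))`, with the analytic
`t·ka·e^(−ka·t)` limit when ka → ke. The simulation grid is dt = 0.25 h for
30 days; days 22–26 form the steady-state analysis window. QOD dosing
starts at t = 0 and repeats every 48 h. Interindividual variability is
lognormal per parameter and individual (`θ·exp(η)`, `η ~ N(0, ω²)`), with
no covariates, no residual-error model (downstream projection consumes true
concentrations), and no interoccasion variability.

The clinical popPK models behind the study regimens are nonlinear
mixed-effects fits that are not publicly reproducible, so the simulator is
generic and config-driven. Default typical values — belvarafenib CL/F 9 L/h,
V/F 400 L, ka 0.5 /h; cobimetinib CL/F 13.8 L/h, V/F 680 L, ka 0.4 /h; all
ω = 0.3 — were chosen once so that mean steady-state free exposures of the
mid regimens (belvarafenib 100–200 mg BID ≈ 5–10 nM free; cobimetinib
20–40 mg QD ≈ 6–12 nM free) fall inside the in vitro free-dose grids, i.e.
they are calibration targets for a self-consistent synthetic study, not
claims about the real compounds. Unit convention: ng/mL divided by
molecular weight (g/mol) is taken as µM total, times plasma fu (0.00258 /
0.052) for free µM.

## Exposure projection

Regimen-level projection evaluates the GR and Bliss-excess surfaces at the
population-mean free exposure. Patient-level projection samples paired
profiles (patient i receives profile i of each drug; no between-drug PK
correlation model), reads free concentrations once per hour for 48 h
starting at the beginning of day 23 (≥ 2 cycles for QD/BID, one full QOD
cycle), and pools all hourly GR / Bliss-excess values across 75 patients
into quantile summaries (5/25/50/75/95%). Per-patient means are emitted
alongside the pooled samples, since either pooling convention can be wanted
downstream. GR and Bliss surfaces are interpolated independently.

## MAPK feedback model

The signaling module is an explicitly coarse-grained ODE model — five
fractional-occupancy states — built to reproduce the feedback architecture
that differentiates the mutational contexts, not to re-derive any
rule-based model's quantitative output. States: RAS-GTP fraction R, RAF
dimers D, feedback-phosphorylated RAF F_p (free protomers
F_u = 1 − F_p − 2D by conservation), pMEK m, pERK e:

```
dR/dt  = k_ras_act(1−R) − k_ras_hyd·hyd_factor·R
dD/dt  = k_dim·stab_factor·R·F_u² − k_undim·D
dFp/dt = k_fb·e·F_u − k_fb_rev·F_p
dm/dt  = k_mek_cat·active·(1−m)·(1−(1−α)·b_M) − k_mek_ptase·m
de/dt  = k_erk_cat·m·(1−b_M)·(1−e) − k_erk_ptase·e
```

Drug binding is rapid-equilibrium (separation of timescales):
`b_R = B/(B+Kd_RAFi)`, `b_M = C/(C+Kd_MEKi)`; `active = 2D(1−b_R)` for the
RAS-driven variants. MEK-inhibitor-bound MEK is phosphorylated by RAF at
relative rate α (default 0.45) and is catalytically dead toward ERK. The
NRAS Q61 variant reduces GTP hydrolysis 10-fold (`hyd_factor = 0.1`) and
dimer stability 5-fold (`stab_factor = 0.2`); the no-feedback variant sets
`k_fb = 0`; the BRAF V600E variant drops the RAS/dimer states entirely and
drives the cascade with a constant RAS-independent monomer
(`active = 1 − b_R`), with lower cascade gains
(`k_mek_cat = k_erk_cat = 0.4`) so its baseline sits off saturation.

Steady states are found by integrating in 4-h windows until every state
changes by less than 0.1% per window, then polishing with a Newton solve of
the stationarity conditions; dose matrices use 10×10 grids (0 plus 9
log-spaced doses, belvarafenib 10^−2.25–10^0.5 µM, cobimetinib
10^−2.75–10^0 µM) normalized to the drug-free steady state, and Bliss
excess on pERK inhibition is computed with the same machinery as the
viability analysis (without smoothing — model output is noiseless).

Default kinetic constants were calibrated once, by a documented scan, to
satisfy the directional property suite: (i) the feedback-competent NRAS
variant shows paradoxical pMEK activation under MEK inhibition (×2.1 at
0.5 µM), suppressed by adding 133 nM panRAF inhibitor; (ii) the
no-feedback and BRAF variants show monotone pMEK decreases; (iii) maximum
pERK Bliss excess orders NRAS (0.049) > no-feedback (0.027) > BRAF (0.015).
A structural note on magnitudes: because dimer formation scales as F_u²,
the ERK→RAF feedback loop gain is bounded, which caps the attainable Bliss
excess of this reduced model near 0.05 — the *ordering* and the pMEK
signatures are the model's claims, not the absolute excess values, and the
tests assert exactly that.

## Clinical TGI model

Tumor size follows the biexponential regression/regrowth form
`TS(t) = TS0·(e^(−KS·t) + e^(KG·t) − 1)` with KG, KS in 1/week. In place of
population mixed-effects machinery, each subject is fit independently by
bounded nonlinear least squares on log size with a deterministic (KG, KS)
multi-start grid; all-growth series pin KS at 0 and are flagged as boundary
fits. Cohort summaries are means of per-subject estimates, and group
trajectories are simulated for 52 weeks from a common TS0 = 50 (units
follow the input series; treated as arbitrary size units).

## Synthetic data: what it emulates, and what it does not

Generators are seeded, deterministic, and return their generating
parameters (ground truth), which all recovery tests consume directly.

- **Checkerboards**: `v(i,j) = vA(d_i)·vB(d_j) − bump + noise`, where the
  margins are log-logistic, the synergy bump is an isotropic Gaussian in
  log10-dose space (amplitude, center, width in decades) — reproducing the
  narrow-dose-window synergy geometry seen in NRAS-mutant lines — the
  surface is truncated at 0, and noise is multiplicative lognormal
  (CellTiter-Glo-like heteroscedasticity). Amplitude 0 gives exact Bliss
  independence before noise, which is what the synergy-score calibration
  tests exploit.
- **Screen panel**: 43 lines (32 BRAF V600, 6 NRAS Q61, 5 RAS/RAF wild
  type) on 9×9 half-log grids (tops 10 µM panRAFi / 5 µM MEKi, zero
  margins). Per-line absolute IC50s are drawn lognormally around group
  means — MEKi log10 IC50 −1.66/−1.08/−0.68 with SDs 0.6/0.39/0.82 for
  BRAF/NRAS/WT — and converted internally to EC50s given the group Emax
  floors. Bump amplitudes (0.24/0.68/0.50 mean) were calibrated once so the
  *recomputed* group-mean Bliss scores land at ≈0.10/0.27/0.25. Viability
  noise sd is 0.05.
- **Xenograft volumes**: exponential growth sampled at the twice-weekly
  caliper schedule (days 0–21) with lognormal noise.
- **TGI cohorts**: per-subject (KG, KS) lognormal around group means,
  biexponential series with lognormal noise.

Not emulated: plate/edge and batch effects, replicate correlation, mouse PK
time courses, drug–drug PK interaction, tumor heterogeneity or acquired
resistance. Passing tests therefore demonstrate that the *analysis chain*
is correct and self-consistent under the stated noise models — not that
real screens are free of the artifacts the generators omit.

## Numerical choices

- Fit tolerances: curve fits run to xtol/ftol 1e−12 with bounded trust
  region; TGI fits to 1e−14. Matrix validation tolerates 0.25 deviation of
  the untreated cell from 1.
- The untreated-cell invariant, strictly increasing doses, and finite
  non-negative viabilities are enforced at matrix construction/read time.
- ODE integration uses LSODA at rtol 1e−8 / atol 1e−10; steady-state
  uniqueness in tests is checked by multi-start integration.
- Problem sizes: the test suite and acceptance script use 100-seed synergy
  calibrations, 200-replicate bias studies, 500-patient PK populations, 75
  projected patients, and 3–5 replicate screen panels — sizes chosen to
  keep Monte-Carlo error comfortably below the tolerances being asserted.
- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; identical seeds give bit-identical outputs, which the manifest
  hashes in the pipeline verify.

## Known limitations

- The GR conversion uses the endpoint-only viability reading; with
  time-resolved data the full growth-rate formulation would be preferable.
- The PK simulator's typical values are self-consistent defaults, not
  estimates for the real drugs; absolute exposure predictions should not be
  read off them.
- The MAPK surrogate reproduces directional signatures and orderings; its
  absolute pMEK/pERK levels and synergy magnitudes are not calibrated to
  molecular data.
- Per-subject TGI least squares ignores shrinkage toward the population
  mean that mixed-effects estimation would provide; with sparse or noisy
  series the per-subject estimates are accordingly more variable.
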