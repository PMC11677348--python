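# Methods

## Transport model

`sdmcell` models a dead-end stirred filtration cell with the
solution–diffusion picture: solvent and solute cross the membrane
independently, the solvent driven by the net pressure `ΔP − Δπ` through
the permeability `Lv`, the solute driven by its concentration difference
across the membrane through `Ls`. Concentration polarization is handled
with stagnant-film theory: convection drags solute to the membrane
surface, back-diffusion through a boundary layer of effective
mass-transfer coefficient `k` opposes it, and at quasi-steady state

    (Cm − Cp)/(Cb − Cp) = exp(Jv / k).

`k` comes from the stirred-cell Sherwood correlation
`Sh = 0.104 Re^(2/3) Sc^(1/3)` on the stirring radius `r`, with the
stirring speed `w` interpreted as an angular velocity in rad/s (rpm is
converted by 2π/60 at the interfaces). That reading makes `w r² ρ/μ` a
rotational Reynolds number and keeps the correlation dimensionless; it is
an interpretive choice, since correlations of this family are sometimes
quoted per revolution.

Key assumptions, in decreasing order of consequence:

* **Osmotic pressure is van 't Hoff**: π = i·(c/M)·R·T, with i = 2 for
  NaCl. This is accurate to a few percent below ~10 g/L NaCl, which covers
  a 500 mg/L feed concentrated tenfold. Pharmaceuticals at 50 ng/L are
  flagged osmotically inactive and contribute exactly zero π; flux decline
  in a run is therefore entirely the salt's doing.
* **Δπ is evaluated at the membrane surface**, π(Cm) − π(Cp), because
  polarization is invoked precisely to correct surface conditions. A
  bulk-based Δπ remains available (`surface_osmotic=False`) for
  sensitivity checks.
* **Trace solutes do not feed back on the flux.** Once the salt fixes
  `Jv`, each trace solute obeys the closed form
  `Cp = Ls·E·Cb/(Jv + Ls·E)`, `E = e^(Jv/k)`, hence
  `R_obs = Jv/(Jv + Ls·E)`. The solver exploits this structure: a damped
  fixed-point iteration on `Jv` (adaptive damping, tolerance 1e-10
  relative, 500 iterations, warm-started along a trajectory) with a
  bracketed Brent fallback on the monotone residual
  `g(Jv) = Jv − Lv(ΔP − Δπ(Jv))`, which brackets in `(0, Lv·ΔP]`.
* No pore flow, no electrostatic or hydrophobic interaction mechanism
  (log Kow and pKa ride along as metadata only), no fouling resistance:
  rejection differences between compounds live entirely in their fitted
  `Ls`.

A useful consequence worth stating explicitly: differentiating `R_obs`
with respect to `Jv` gives `dR/dJv ∝ Ls·E·(1 − Jv/k)`. Rejection therefore
rises with pressure only in the stirring-controlled regime `Jv < k`; past
it, polarization grows faster than the drive and rejection falls with
further pressure. Rejection is monotone increasing in `k` (hence in rpm)
everywhere. The qualitative-trend tests assert the pressure trend only on
grids within the `Jv < k` regime (≤9 bar at ≥250 rpm for this cell), and
this is the regime where the model should be trusted for extrapolation.

## Batch simulation

The dead-end run is integrated over cumulative permeate volume `Vp`
(quasi-steady: each instant is a converged transport solve), with the feed
solute masses advanced by classical RK4 on `dM/dVp = −Cp(M, V)`,
`dV/dVp = −1`, default step 1 mL. RK4 keeps the step-refinement error
below 1e-6 relative even at VCF 10, where the feed volume has shrunk to
30 mL and first-order stepping would leave ~1e-4 errors. Cumulative
permeate mass is accumulated from the exact per-step feed decrements, so
the mass balance `feed + permeate = initial` closes to floating-point
round-off by construction — the conservation test then guards the
bookkeeping, not the integrator. Samples are recorded every 30 mL (the
study cadence) plus the initial state; both instantaneous and cumulative
permeate concentrations are reported, with instantaneous the default
convention for rejection. Elapsed time is recovered as `ΔVp/(Jv·A)`. Runs
stop at VCF 10 (270 mL of 300 mL) or earlier with an explicit
`zero_flux` termination if the concentrating feed's osmotic pressure
overtakes `ΔP`.

## Parameter estimation

* **Lv** from a flux series with measured salt passage: each observed
  `(Jv, Cb, Cp)` is lifted to `Cm` by film theory, giving the effective
  driving pressure `d = ΔP − (π(Cm) − π(Cp))`; `Lv` is the least-squares
  slope of `Jv` on `d` over the points (pooled across records when fitting
  a membrane).
* **Ls, trace solutes**: fitted in rejection space. The model rejection
  for a record is the run average of the closed form over the record's own
  flux samples, matching the generator's averaging convention; `Ls`
  minimizes squared rejection residuals across records
  (`scipy.optimize.least_squares` on log10 Ls, bounds [~0, 1e-3] m/s —
  the log parameterization spans the ~3 decades between NF and RO values).
  A single-sample record reduces exactly to the analytic inversion
  `Ls = Jv(1 − R)/(R·e^(Jv/k))`; a single multi-sample record is solved by
  bracketed root-finding on the monotone mean-rejection residual.
* **Ls, salt**: the salt shapes the flux itself, so its forward model is a
  full batch re-simulation; otherwise the same objective.
* Records whose rejections sit entirely at 0 or 1 are non-identifiable;
  the fit returns a flagged bound instead of a number.
* Rejections are fitted and reported run-averaged because bench reports
  print one number per compound per condition; per-sample rejections
  remain available on every trajectory.

Validation re-simulates each held-out record's conditions with the fitted
membrane and pools all (record, solute) pairs into one RMSE in
rejection-fraction units.

## Synthetic data

The generator wraps the forward simulator with multiplicative lognormal
noise (unit mean, specified CV) on sampled water flux and permeate
concentrations — both positive quantities whose measurement errors scale
with magnitude; default CV 1%. Feed-side concentrations are left exact,
as in practice they follow from the mass balance. The packaged emulation
suite reproduces the reference study design: 300 mL of 500 mg/L NaCl plus
13 pharmaceuticals at 50 ng/L, 14.6 cm² membrane, 25 °C, 10 bar, runs at
300 and 450 rpm sampled every 30 mL, with the transcribed per-compound
`Ls` table as generating truth.

Constants the study never published, fixed here as package choices:

| quantity | value | basis |
| --- | --- | --- |
| `Lv` (NF / RO) | 1.45e-11 / 4.2e-12 m s⁻¹ Pa⁻¹ | puts initial flux at ~50 / ~14 LMH at 10 bar, typical for these membrane classes |
| stirring radius `r` | 0.02 m | HP4750-class cell stir bar |
| `D` (NaCl) | 1.61e-9 m²/s | standard aqueous value, 25 °C |
| `D` (PhACs) | 1.2e-8·MW^(−0.53) m²/s | molecular-weight power law; reproduces literature magnitudes (8.4e-10 at MW 151, 3.5e-10 at MW 791) |
| ρ, μ (25 °C) | 997 kg/m³, 8.9e-4 Pa·s | water; overridable in config |
| units of tabulated `Ls` | m/s | printed as ×10⁻⁶ without units in the source; taken as m/s and never rescaled |

What the synthetic data does *not* emulate: analytical (LC–MS/MS)
artifacts beyond a CV, pH-dependent speciation, membrane fouling or
compaction, temperature drift, or inter-membrane-coupon variability (both
rpm runs share one membrane). Passing recovery tests therefore show the
estimator is correct *for the stated measurement model*, not that real
stirred-cell data are this well behaved; with real data the fitted `Ls`
absorbs every unmodelled mechanism.

## Numerical choices and degenerate inputs

* Transport solve tolerance 1e-10 relative; closure residuals of all
  equations are attached to the returned state and checked against 1e-8.
* `w = 0` makes film theory diverge; `k` is reported as 0 and the solver
  raises rather than extrapolating.
* `ΔP ≤ π(Cb)` raises a no-positive-flux error at solve time and truncates
  a batch run with an explicit reason mid-trajectory.
* Rejections outside [0, 1] raise — values are never silently clipped.
* Reported percentages round half-up at 2 decimals at presentation only;
  internal values are never rounded.
* Experiment-record CSVs are written with 17 significant digits and read
  back with round-trip float parsing, so persisted records are bit-exact.

## Problem sizes

Default test and acceptance runs use: batch integration at 1 mL steps to
VCF 10 (~270 transport solves per run, each a handful of fixed-point
iterations), 1000 randomized draws for the closed-form agreement check,
and 20 seeded replicates per membrane class for noisy recovery. These
sizes put all Monte-Carlo medians well inside their tolerance bands while
keeping a full run of the suite around a minute on one core.

## Known limitations

* The reference study's own predicted rejections for its four validation
  conditions cannot be recomputed, because its `Lv`, diffusion
  coefficients and stirring radius were not published; the packaged
  validation table is a qualitative reference only, and the package
  validates against its own synthetic ground truth instead.
* Van 't Hoff π and the single-film polarization model degrade at high
  salinity (brackish/seawater feeds) and at very low stirring.
* Run-averaged rejection depends on the sampling grid; comparisons across
  different sample cadences should use per-sample rejections.
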