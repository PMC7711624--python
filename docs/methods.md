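# Methods

`buccalfilm` implements the computational chain used to characterize a
mucoadhesive buccal film: dissolution-kinetics model fitting with a
mechanistic (Fickian vs relaxational) decomposition, Franz-cell permeation
flux estimation, mucoadhesion/quality-control arithmetic, and the
steady-state pharmacokinetic bridge that compares the film's mucosal input
rate with oral prolonged-release dosing.  This note records the models, the
defaults and the numerical choices, and what the synthetic-data tests do and
do not demonstrate.

## Release kinetics

Cumulative release D(t) (percent of dose, t in minutes) is fitted to six
closed-form models:

| model | equation | free parameters |
|---|---|---|
| zero order | D = k t | k |
| first order | D = 100 (1 − e^{−kt}) | k |
| Higuchi | D = k t^{1/2} | k |
| Hopfenberg | D = 100 [1 − (1 − k t)^n] | k (n fixed; n = 1 for a film) |
| power law | D = k t^n | k, n |
| two-term (Peppas–Sahlin) | D = k₁ t^m + k₂ t^{2m} | k₁, k₂, m (m fixable) |

Fitting is bounded-free nonlinear least squares (`scipy.optimize.curve_fit`)
with multi-start initialization: log–log linearization for the power-law
family, ratio heuristics for the one-parameter models, and variable
projection for the two-term model (for each m on a grid over [0.05, 1.5],
k₁ and k₂ solve a linear system; the best few grid points seed the full
fit).  Goodness of fit is R² = 1 − SSR/SST and the reduced chi-square
SSR/(N − p), the convention of the dissolution-fitting software this
mirrors.  Parameter standard errors come from the fit covariance.  A fit
that converges from no start returns an explicit failure object, never
NaNs.

Two named fit ranges mirror common practice: `to_plateau` keeps points up to
the first one within 1% of the final value; `first_60pct` keeps points with
D ≤ 60%, the validity range conventionally quoted for the power-law family.

`rank_models` orders results by descending R², ties broken by ascending
reduced chi-square (the sort is stable, so exactly equivalent models — e.g.
zero order and Hopfenberg with n = 1, which are the same line with
k_zero = 100 k — keep their input order).

The transport mechanism is classified from the power-law exponent n; for a
film: n ≤ 0.5 Fickian diffusion, 0.5 < n < 1 anomalous transport, n = 1
(within a configurable ±0.02 band) Case II, n > 1 Super Case II
(relaxation/erosion dominated).  Cylinder (0.45/0.89) and sphere
(0.43/0.85) breakpoints are available.  The boundary n = 0.5 is assigned to
Fickian by convention.

The two-term model's mechanistic split is F = 1/(1 + (k₂/k₁) t^m),
R = 1 − F, R/F = (k₂/k₁) t^m.  F + R = 1 is an algebraic identity and holds
at machine precision.  With a negative fitted k₁ — which is what the
characterized film produces — F leaves [0, 1] and R/F is negative; the
package computes the printed formulas as-is and flags out-of-range points
rather than clipping, because in that regime the "fractions" are no longer
fractions and silently normalizing them would misrepresent the fit.

The pure-Fickian exponent m of a disk is obtained from its aspect ratio
(diameter/thickness) by piecewise-linear interpolation, in log aspect
ratio, of a packaged table.  The table is an approximate digitization of
the classical aspect-ratio chart, anchored at (13.9, 0.415) — the
characterized dissolution disk (11 mm / 793 µm) — with m tending to the
slab limit 0.5 at both extremes; users with a better digitization can
supply their own table.  Ratios outside the table clamp with a warning.

## Permeation flux

Acceptor-compartment concentrations are converted to cumulative permeated
amount per area with the sampling-replacement correction
Qₙ = (Cₙ V_acceptor + V_sample Σ_{i<n} Cᵢ)/A (default cell: 15 mL acceptor,
0.5 mL samples, 0.636 cm² diffusion area, consistent with the 9-mm
orifice).  The correction is on by default and can be disabled for
pre-corrected input; with V_sample = 0 it reduces to Cₙ V/A exactly.

The steady-state flux Js is the slope of an ordinary least-squares line on
the steady-state window; the lag time is max(0, x-intercept), with the raw
intercept kept as a diagnostic.  The automatic policy selects the longest
prefix window (anchored at the earliest samples) whose R² meets a threshold
(default 0.99).  When no prefix of the samples qualifies — the typical case
when the steady state spans only the first two hourly samples — the policy
prepends the physical origin (Q(0) = 0, exact by definition of a cumulative
amount) and repeats the search.  Trying the samples alone first keeps
genuine lag times intact: on Q = 0.2(t − 0.5) the samples already form a
perfect line and the origin is never used, so Js = 0.2 and lag = 0.5 are
recovered exactly.  A dataset with no qualifying window raises an error
carrying every candidate window's R².

## Synthetic data

The generators sample the closed-form curves the fits assume and add
i.i.d. Gaussian noise; they emulate the study conditions, not the physics
(no flow-cell hydrodynamics, no mucosal diffusion model, no inter-film
variability, no correlated assay drift).

- **Release**: model curve on t = dt, 2dt, …, t_end (default 2-min sampling
  to 64 min); noise sd default 1.5% of dose, chosen so a six-replicate
  standard error is under 1%, the order of the error bars such experiments
  report.  Clipping to [0, 100] is on by default for realism and off for
  parameter-recovery work, where the unclipped tail carries information.
- **Permeation**: zero to the lag time, slope `flux` to the breakdown time
  (defaults 0.237 mg cm⁻² h⁻¹, lag 0, breakdown 2.5 h, hourly sampling over
  6 h), then an exponential approach to an asymptote, slope-continuous at
  the breakdown, with time constant τ (default 0.1 h).  The sharp default
  encodes a rapid stall of permeation once acceptor-side sink conditions
  are lost; it is also the regime in which the prefix-window policy at the
  hourly sampling cleanly separates steady state from slowdown.  A slow
  decay (τ ≈ 0.5–1 h) leaves the first post-breakdown sample near-linear,
  the R²-threshold window absorbs it, and any prefix-window estimator
  under-reports the flux by 5–10%; with the default conditions the
  estimator's mean bias over 100 seeds is a fraction of a percent, within
  the module's stated 2% calibration contract.  The noise sd default of
  0.003 mg cm⁻² (≈1.3% of the first sample) matches six-replicate UV assay
  precision and keeps the window selection reliable.
- **Adhesion**: F(t) = F_max (1 − e^{−rt}) at the requested contact times
  (defaults F_max 0.88 N, r 0.065 min⁻¹, noise sd 0.01 N — plateau inside
  the 50-min protocol, replicate scatter of the order of the published
  standard errors).

Because generation and fitting share the same closed forms, noiseless
round-trip recovery demonstrates correctness of the optimization, not
validity of the models for real films; the stochastic flux test
demonstrates estimator calibration under the assumed noise model only.

## Adhesion and QC

Balance readings convert as force (N) = mass (g) × 9.81/1000 and detachment
force (N/m²) = force / area.  The default disk area is 0.2827 cm², computed
from the 0.6-cm disk diameter; the characterization tables round it to
0.282 cm², so per-area checks carry a ±0.5% tolerance (the published
detachment-force rows themselves imply effective areas spanning
0.280–0.283 cm² and cannot all be reproduced simultaneously to better than
~1%).

`characterize_adhesion` fits the saturating exponential and reports a
model-free plateau onset: the earliest observed contact time whose force
reaches 95% (configurable) of the final force.  The fitted curve's own 95%
crossing is reported as a diagnostic.  The two can disagree: a saturating
exponential can rise at most 5-fold between 10 and 50 min, so on strongly
sigmoidal series (such as the published forces, which rise 12.5-fold) the
least-squares exponential is quasi-linear and its crossing falls far beyond
the data; the summary then carries "plateau not reached" and poor-fit
flags while the empirical onset still identifies the observed plateau
(40 min on the published series).

Drug loading is 100 × drug mass / sample mass (% w/w); dose scales
proportionally with cut area from the characterized disk (2.29 mg per
0.2827 cm²).  The UV calibration line A = 30.81143 c − 0.01213 (c in
mg/mL, validated over 0.005–0.100 mg/mL) inverts exactly; out-of-range
concentrations are returned as computed but flagged.  Uniformity summaries
report mean ± SE (sd/√n).

## Pharmacokinetic bridge

One-compartment steady-state algebra with literature constants for
ropinirole: [Cp]ss = 1 ng/mL per mg of oral PR dose, t½ = 6 h, V_D =
7.5 L/kg × 70 kg = 525 L.  Ke = 0.693/t½ by default — the conventional
rounding, kept so the published chain reproduces digit-for-digit
(0.1155 h⁻¹; Ke·t½ matches ln 2 to 10⁻³ relative) — with an exact-ln2 flag.
Then Cp_ss = 1 × dose, D_E = Cp_ss·Ke (0.462 ng mL⁻¹ h⁻¹ at 4 mg) and
D_A = D_E·V_D/1000 (0.24255 mg/h unrounded; 0.243 displayed — values are
kept unrounded internally and rounded to 3 decimals only in the rendered
report; 0.485 mg/h at 8 mg).

The equivalence report presents both comparisons: the per-cm² basis that
sets Js (mg cm⁻² h⁻¹) directly against D_A (mg/h) — the presentation used
when the film and oral dose are judged "comparable" — and the dimensionally
homogeneous film input rate Js × area against D_A.  The area that would
match a target absorption rate is target/Js (≈1.03 cm² for the 4-mg
reference at Js ≈ 0.237), the dose-modulation argument for the film
format.  An optional area multiplier (default 1) covers the unresolved
question of whether both film faces absorb in vivo.

## Pipeline

`run_study` executes all stages from one validated config (YAML via
pydantic; `configs/paper_replication.yaml` spells out the defaults).  Runs
are deterministic given the config seeds; stage failures are recorded and
do not stop independent stages (an empty model list skips release fitting
but the PK chain still runs).  Outputs are a model-comparison CSV, a
decomposition CSV, flux/QC/equivalence JSON (unrounded), a rendered text
report and a manifest with seeds and package version.

## Problem sizes

Default problem sizes are those of the emulated protocols: 32 release
points, 6 hourly permeation samples, 6 adhesion contact times, and 100
seeded replicates for the flux-calibration check; the whole analysis runs
in seconds.

## Known limitations

- Only the six printed closed-form release models; no mechanistic
  diffusion–erosion simulation.
- The first-order model is implemented exactly as printed; a negative
  fitted k (which the printed characterization reports) predicts negative
  release and is flagged, not reinterpreted.
- Flux analysis assumes the prefix of samples contains the steady state; a
  late-developing steady state requires a manual window.
- No permeability-coefficient analysis (donor concentration
  uncharacterized) and no full concentration–time PK simulation or
  bioequivalence statistics — only steady-state algebra.
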