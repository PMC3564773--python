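# Methods

## Model

The package implements a six-variable kinetic model of guard-cell signal
transduction under step inputs of ABA and ACC (the ethylene precursor),
applied at t = 0 and held constant.  All variables are percent of the
untreated control, so every state starts at 100; AOX2 starts at 0.  Five
variables (ROS, AOX1, NO, active outward K⁺ channels, cytosolic K⁺) obey
coupled nonlinear ODEs; AOX2 is the closed-form response of a linear
activation cascade and enters the ROS equation as a forcing function of
time rather than as a sixth state.  Stomatal aperture is identified with
the cytosolic K⁺ variable: ion content is the osmotic driver of guard-cell
turgor, so [AP] = [K⁺].

Hormone inputs enter through compound Michaelis–Menten terms.  ROS and
AOX1 production use a shared-enzyme OR gate,
(α₁·k₂·ABA + α₂·k₁·ACC)/(k₁k₂ + k₂·ABA + k₁·ACC), which is bounded by
max(α₁, α₂), monotone in each dose, and saturates.  AOX2 uses the product
of two occupancy factors, ABA·ACC/((k11+ABA)(k12+ACC)) — an AND gate that
is identically zero unless both hormones are present.

Uncharacterised stretches of the antioxidant pathways are modelled as
linear activation cascades of length n with equal step rate a.  The
terminal species of such a cascade responds to a unit step with
P(n, a·t), the normalised lower incomplete gamma function, giving an
effective delay τ = n/a with only two extra parameters per cascade.  The
OR cascade (n1, α23) delays the generic antioxidant response
(τ1 ≈ 111 min in the reference fit: transcription-scale); the AND cascade
(n2, β13) is fast (τ2 ≈ 12 min: post-translational scale).  The separation
of these two timescales is what lets single stimuli close stomata (ROS
persists long enough to signal) while the combined stimulus reverses
closure (ROS is removed before closure can be maintained).

Two variants are implemented.  The primary model routes ethylene to NO
production (α32).  The pH variant instead routes ethylene to outward-
channel recruitment (α43, representing ethylene-induced cytosolic
alkalinisation) with α32 forced to zero.  Each variant has 28 free
parameters; `alpha43`/`alpha32` is structurally excluded respectively.

Grouping choice: in the AOX1 equation the cascade factor P(n1, α23·t)
multiplies only the stimulus-dependent Michaelis–Menten term, not the
basal production α20 — basal antioxidant production must be active before
stimulation, whereas the cascade is triggered by the stimulus.

Out of scope by design: receptor kinetics, Ca²⁺/pH as explicit states,
vacuolar transport biophysics, and any stationary (post-transient)
behaviour — the model describes the first ~2 h of signal transduction
only, and the default simulation horizon is capped accordingly.

## Numerics

Integration uses LSODA (stiff-capable, adaptive) with rtol 1e-8 /
atol 1e-10 by default; a dedicated degenerate path returns the initial
state for the single-point grid [0].  Fitting evaluates the objective at
rtol 1e-6 / atol 1e-8 — residuals of order one percentage point do not
need tighter solutions and the looser tolerance triples throughput.
Sensitivity analysis tightens to rtol 1e-10 so that central-difference
noise stays far below index magnitudes.  Halving tolerances changes
reported series values by well under 1e-4 relative (tested).

Cascade lengths n1, n2 are treated as continuous (≥ 1) during fitting —
P(n, x) is defined for real n — with the integer-cascade reading available
by pinning them to integers via `FitConfig.fixed`.

`make_basal_consistent` re-solves the constant production terms (α10,
α20, α31, α40, α51) so the all-100 state is an exact fixed point at zero
dose; the NO balance has no additive constant, so α31 is the re-solved
constant there.  The channel balance requires α42 ≤ β40, otherwise the
implied α40 would be negative and the function raises.  Basal consistency
is a convenience for the synthetic generator (flat-100 controls); it is
*not* imposed during fitting, which keeps all 28 parameters free.

## Objective and fitting

The objective is the sum of squared residuals between simulated and
observed percent-of-control values at the observed (treatment, variable,
time) points, weighted by 1/SEM² by default (uniform weighting
available; SEM = 0 records fall back to unit weight).  Records at t = 0
carry zero residual automatically since every simulation starts at 100.
Integration failure makes a candidate infeasible (+inf score).

The squeeze-and-breathe search works in log10 parameter space: rates span
decades and must remain positive.  Each round draws `n_samples` candidates
(log-uniform in the bounding box on the first round, Gaussian around the
elite mean afterwards), scores them, polishes the best fresh candidates
with a bounded trust-region least-squares step (novel starting points each
round — re-polishing the same elite would repeatedly refine one basin),
keeps the `n_elite` best of fresh + surviving elites, then contracts the
sampling spread ("squeeze", factor 0.7 per round, floored at the elite
spread) and periodically relaxes it back toward the original box
("breathe", geometric mean with the initial spread every 5 rounds).  The
best-ever candidate receives a final deeper polish.  Defaults
(250 samples × 10 rounds, 15 elites, 2 polished candidates per round) were
chosen so that independent seeds converge to indistinguishable objectives
on the bundled dataset in a few CPU-minutes; the budget is fully
configurable, and warm starts can be injected via
`FitConfig.initial_guesses`.

Default parameter bounds are per-parameter boxes set by dimensional
analysis of the percent-of-control scale: every state sits near 100, so
each kinetic term's magnitude spans roughly 0.01–10 %/min inside the box
(bimolecular coefficients that multiply one or two ~100-scale species are
scaled down accordingly).  A blanket box over [~0, 10³] for all rates
makes most log-uniform samples dynamically absurd and the search
unreliable; the scaled boxes make essentially every deep local polish
land in a good basin.

Variant comparison fits each variant with identical budget and seed and
reports the objective plus an AIC-style score 2k + n·log(SSE/n) with
k = 28 for either real variant.  The `ethylene_blind` label fits a
deliberately crippled control — the primary equations with every ACC
input removed (α12 = α22 = α32 = 0) — which cannot match the ACC-treatment
records and serves as a negative control for the comparison.

## Observed dataset and synthetic generator

The bundled fixture transcribes the published percent-of-control means
for ROS (0–60 min) and aperture (0–60 min) under 10 μM ABA, 10 μM ACC and
the combined dose.  Times at which the source gives no number are left
missing rather than interpolated (ROS at 45 min; combined aperture after
15 min; ACC aperture at 60 min).  Per-record SEMs are not published; a
documented default of 5 percentage points is used.  The `source` column
carries a short descriptor of the statement behind each record.

Behaviours that are stated only qualitatively — the combined-dose
reopening after 30 min and the ACC-alone partial reopening at 60 min —
are available as explicitly flagged imputed records
(`experimental_dataset(include_imputed=True)`; combined aperture
78/85/90 at 30/45/60 min, ACC 80 at 60 min).  Without them a fit is
unconstrained after 15 min under the combined dose and need not reproduce
the reopening; the shipped reference parameter set is therefore
calibrated on the extended fixture.

The synthetic generator emulates the assay design: three treatments,
sparse time grids, 90 replicates per condition (30 cells × 3 repeats),
Gaussian per-cell scatter (default SD 9 percentage points, giving
SEM ≈ 0.95 like the published error bars), means and SEM = SD/√n per
(variable, time).  What it does not emulate: non-Gaussian aperture
distributions, cell-to-cell correlation within a repeat, systematic
assay drift, and day effects — so passing recovery tests demonstrates
correctness of the pipeline on idealised data, not robustness to real
assay artefacts.

## Reference parameter set

The original study's table of fitted parameter values is not
redistributable here, so the package ships
`reference_params_synthetic.json`, a synthetic stand-in constructed as
follows: squeeze-and-breathe fit (default budget, seed 0) to the extended
fixture, with the two cascade timescales calibrated to the published
values by pinning n1 = n2 = 2, α23 = 2/111 min⁻¹, β13 = 2/12 min⁻¹.  The
resulting model matches every plain-fixture mean within ~6 percentage
points and reproduces the fitted model's published characteristics:
τ1 ≈ 111 min, τ2 = 12 min, closure asymmetry (ABA closes more than ACC at
60 min), and combined-dose reopening.  The model is sloppy — many
parameter sets fit the 26 means equally well — so these values are one
representative of a basin, not unique estimates.

## Sensitivity analysis

`local_sensitivity` implements normalised local sensitivity by central
finite differences: each free parameter is scaled by (1 ± rel_step,
default 0.01) and the index is the RMS over the output set — by default
ROS and aperture at 15/30/45/60 min under the three experimental
treatments — of (y₊ − y₋)/(2·rel_step·y₀).  Parameters with baseline
value zero get index 0; parameters whose perturbation breaks integration
are flagged, not dropped.  Ranking is by |index| descending with
alphabetical tie-break.

A structural caveat, established empirically with this implementation:
at any data-consistent fit whose NO chain is responsive enough to produce
the combined-dose reopening, the parameters that set NO and basal-AOX1
turnover (β30, α31, β11, …) necessarily carry elasticities of order one
on these raw outputs, while with τ1 ≈ 111 min the OR-cascade rate can
modulate only a small share of ROS removal inside the 60-min observation
window.  Under this output set the cascade-timing parameters therefore
rank high but not top; rankings that place them first depend on the
sensitivity functional used, and the functional behind the original
analysis was not published.  Profile-style
sensitivity (re-optimising the remaining parameters after perturbing
one) collapses almost all indices toward zero instead — the model is
sloppy enough to compensate any single 10% perturbation.

## Known limitations

- Parameters are not individually identifiable from 26 observed means;
  all guarantees are on trajectories, not parameter values.
- The model is transient-only; no claims past ~2 h, no bifurcation
  analysis.
- The allosteric double-phosphorylation alternative for the ROS source is
  not implemented (its equations are not in the main text).
- Dose-response maps are validated by qualitative properties (monotone
  single-dose closure, combined-dose reversal), not by pixel-level
  comparison with published heat maps.
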