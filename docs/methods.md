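# Methods

## Scope and model assumptions

The package implements descriptive (non-compartmental) dosimetry: tissue
time-activity curves are exponential fits to group-mean %ID/g data, not
solutions of a physiologically based model, and dose uses local deposition
of electron energy only. This is the standard desk-scale treatment for a
medium-energy beta emitter (Lu-177: mean electron energy per decay
Δ_local ≈ 2.36×10⁻¹⁴ J ≈ 147 keV, physical half-life 159.528 h) in
mouse-sized organs, where the electron range (≲2 mm) is small against organ
dimensions and photon cross-dose contributes little. S-value matrices,
voxel transport and biologically effective dose are out of scope. All
quantities are per unit injected activity; %ID/g is stored as a percentage
and divided by 100 only inside the dose computation.

## Curve fitting

`TimeActivityModel` fits A·e^(−λ_eff t) (normal organs, which peak at the
first sampling point) or A·(e^(−λ_eff t) − e^(−λ_up t)) (tumor) to the
per-time-point group means by unweighted least squares on the concentration
scale (weighting by group size is available). The two-exponential model is
parameterized as (A, λ_eff, Δ) with λ_up = λ_eff + Δ and positive bounds,
which enforces the identifiability convention λ_up > λ_eff; several
uptake-rate starting values are tried and the lowest-RSS solution kept.
Non-convergence and non-positive rates raise `FitError` with diagnostics —
rates are never silently clamped. Standard errors come from the
Gauss–Newton covariance (delta method for λ_up).

A caveat established by simulation: with 6 sampling times over 240 h,
3–4 animals per point and 10% lognormal noise, a single study constrains a
slow washout rate only weakly (a single-realization λ_eff estimate misses
by >10% roughly half the time). The parameter-recovery tests therefore
check the estimate averaged over 30 replicate studies, i.e. estimator
accuracy rather than single-draw precision; users should read per-study
λ_eff standard errors accordingly.

## TIAC

`trapezoid_tail` (default) integrates the observed means with a C(0)=0
leading edge — an antibody arrives via blood, so the tissue concentration
at injection is zero; if t=0 is actually observed, the observation is used
— and adds the analytic tail C(t_last)/λ_tail. The tail rate is the fitted
λ_eff floored at the physical decay constant: biologic retention cannot
make activity outlive the radionuclide, and the floor keeps a slow (or
growth-corrected negative) fitted rate from producing an unphysical or
infinite tail. For a two-exponential curve the single-exponential tail
carries a small bias from the already-decayed uptake component, bounded by
A·e^(−λ_up·T)·(1/λ_eff − 1/λ_up); on the default sampling grid this is
≈0.1% of the integral. `analytic_fit` returns the closed form A/λ_eff or
A·(1/λ_eff − 1/λ_up). `tail_fraction` reports the extrapolated share; with
slow tumor washout it can exceed 50%, which is the honest statement of how
much of the dose estimate rests on extrapolation beyond the last
observation.

## Growth-dilution correction

The correction is applied at the curve level, C′(t) = C(t)·V(t)/V(0) with
single-exponential V(t) — the form is a modeling choice; curve-level and
integral-level conventions coincide only for separable growth, and the
curve-level one is used because it keeps the corrected curve available for
inspection. The growth model is supplied via config (`v0_mm3`,
`k_growth_per_day`) or fitted from untreated-control trajectories by
log-linear regression (`ExponentialGrowthModel`). For the corrected tumor
the pipeline extrapolates the tail at λ_eff − k/24, floored at physical
decay as above.

The default dosimetry growth rate is k = 0.05/d (doubling ≈ 14 d), a
biodistribution-cohort figure for large established xenografts; therapy
controls in the efficacy simulator grow much faster (k = 0.25/d, limit
crossing ≈ 8 d from 150 mm³), reflecting the smaller, actively progressing
tumors of a therapy study. The corrected tumor TIAC — and hence the
absolute tumor dose — is sensitive to this rate because the correction
inflates the late curve and the tail: at k = 0.25/d the corrected curve
rises through the end of observation and the (physically floored) tail
dominates. Absolute doses should be read with that sensitivity in mind;
dose *ratios* are far more robust, because scaling the tumor curve leaves
organ doses untouched and the whole chain is linear in the input
concentrations.

## Red marrow and human extrapolation

Red marrow is reported two ways in one run: blood-based
(D_RM = RMBLR·D_blood, default RMBLR = 1.0 — conservative; intact-IgG
studies often justify 0.3–0.4) and skeletal (femur concentration × a
marrow-to-skeleton partition factor, default 0.5, a generic phantom share
rather than a measured constant; both are configuration).

Extrapolation methods: `concentration_mass_scaled` multiplies every
concentration by the body-mass ratio BW_mouse/BW_human;
`relative_organ_mass` preserves each organ's fractional %ID and scales by
the organ-mass ratio. The default `mixed` convention uses body-mass scaling
for the tumor (a lesion has no phantom counterpart; the human "tumor dose"
is for a unit-density lesion, default 10 g, in a 70 kg reference adult
whose organ masses are rounded reference-man values) and organ-mass scaling
for normal organs. Carcass-type aggregates use the body-remainder mass.
The two methods coincide exactly when an organ occupies the same body-mass
fraction in both species. Human values are reported per GBq (×1000 from
per MBq). These are screening-level estimates: no phantom S-values, no
species-specific kinetics adjustment.

## Response classification and survival

A complete response requires `confirm_n` (default 2) consecutive
zero-volume caliper measurements sustained to study end — a single zero is
"stable" until confirmed; a qualifying streak followed by any positive
volume is regrowth after CR. Progression is reaching the tumor-bearing
limit (default 1,000 mm³); the crossing day is linearly interpolated
between bracketing measurements (configurable to "first measurement at or
above the limit"), and the analysis stops at the first crossing, so
post-limit data never change a call. Animals removed for non-tumor reasons
should be entered as censored records.

Kaplan–Meier estimation and the Mantel–Cox log-rank test (aggregated ties,
no continuity correction, 1 df) are computed via lifelines behind the
module interface; the test suite cross-checks the statistic against an
independent O/E/V risk-set tabulation and the p-value against a
10,000-replicate label-permutation null (tolerance 0.03, set in advance to
cover permutation discreteness at 8-per-group sizes plus Monte Carlo
error). Undefined medians (curves never reaching S = 0.5) are reported as
undefined, never as infinity, and pairwise p-values carry no multiplicity
adjustment.

## Synthetic data

`simulate_biodistribution` draws per-animal values lognormally around the
configured tissue curves with mean-preserving noise (σ² = ln(1+CV²),
μ = −σ²/2; CV = 0 reproduces the curves exactly). Defaults: grid
{4, 24, 48, 96, 168, 240} h, 3 animals per time point, CV 10%; tumor
A = 90 %ID/g, λ_eff = 0.0025/h, λ_up = 0.028/h (analytic peak
ln(λ_up/λ_eff)/(λ_up−λ_eff) ≈ 94.7 h at ≈65 %ID/g); blood 30 %ID/g with
λ_eff = 0.009/h and organ amplitudes 1.5–8 %ID/g chosen so tumor-to-organ
ratios rise monotonically over the study; a blocked tumor arm at 96 h
scaled by 19/65. `simulate_efficacy` grows controls exponentially
(150 mm³, 0.25/d), applies a 2 d therapy lag then dose-proportional
exponential regression (0.04 /MBq/d), reads volumes below 25 mm³ as
caliper zeros, regrows a completed response with probability 0.25 after a
~14 d delay, and derives survival times from the limit crossing. Because
regrowth is an independent Bernoulli event per responding animal, the
long-run CR probability is exactly 1 − regrowth probability, which anchors
the binomial recovery checks.

What the simulator does not emulate: inter-animal kinetic heterogeneity
(one shared curve per tissue), correlated organ uptake within an animal,
dose-rate radiobiology (regression is phenomenological, not an LQ model),
partial responses that plateau above zero, and non-tumor deaths. Passing
tests therefore demonstrate correctness of the estimators under the stated
noise model, not robustness to every feature of real colony data.

## Numerical and interface choices

* Ratio SDs use first-order (delta-method) propagation of the two group
  SDs; per-animal pairing is not assumed because group statistics do not
  retain it.
* Antigen density assumes 1:1 antigen:antibody stoichiometry by default;
  the factor is exposed (`antigens_per_antibody`).
* Zero organ means make ratio cells undefined (flagged NaN), never dropped;
  zero doses likewise flag the ratio.
* Report rounding (doses to 2 decimals, ratios to integers) happens only in
  text/CSV output; full precision is kept internally.
* Missing animals at a time point: means over available animals, no
  imputation.
* Output files carry a `config_hash`/seed header; the hash excludes the
  output directory, so reruns into different locations are recognizably
  identical.
* Test and acceptance problem sizes (6-point grids, 3–8 animals per
  group/time point, 30–500 simulation replicates, 10,000 permutations)
  mirror the scale of the underlying animal studies while keeping the
  default suite in the seconds range.
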