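# Methods

## Signal model

An FDR sensor embedded in sapwood reports raw counts R. A manufacturer
polynomial maps counts to relative dielectric permittivity; for the
Teros 11/12 the manual polynomial yields √ε directly, so

ε(R) = (a₀ + a₁R + a₂R² + a₃R³)²,  a = (−43.39, 5.276·10⁻², −2.080·10⁻⁵, 2.887·10⁻⁹).

These coefficients are *configuration*, stored in the registry YAML, not
a fitted result of this package. A transform is accepted only if it is
strictly increasing with positive ε over its declared raw range (checked
numerically on a 2001-point grid at load time; with no declared range the
widest admissible region is found by grid search). The shipped default
range is 1800–3600 counts, inside the verified monotone region (the
polynomial's real root sits near 1650 counts; ε(1800) ≈ 1, air, and
ε(3400) ≈ 81, water). Out-of-range input raises; nothing is clipped,
because silent saturation would hide sensor faults in calibration work.

Because ε is strongly nonlinear in water content while √ε is close to
linear, all calibrations are linear in x = √ε:

θ = m·x + b  (absolute calibrations),  Δθ = m·Δx  (relative).

Intercepts are stored *signed* (the TTC stores b = −0.396) and always
applied as `slope*x + intercept`; this single convention avoids the sign
bugs invited by the "m√ε − b" notation. Negative predicted θ is returned
unclipped with a `NegativeVWCWarning` — dry-end extrapolation is a
diagnostic, and no clipping at physical bounds is applied anywhere.

Gravimetric reference quantities: θ_grav = ((m_f − m_d)/ρ_w)/V_f with
fresh mass m_f, oven-dry mass m_d (g), fresh volume V_f (cm³) and water
density ρ_w = 1.0 g cm⁻³ by default (configurable); wood density is
m_d/V_f (g cm⁻³).

## Registry

The packaged registry carries three calibrations — TTC (slope 0.2227,
intercept −0.396, slope CI (0.2111, 0.2344)), OSC (slope 0.2254, CI
(0.2130, 0.2379), relative-only) and the temperate meta-analysis slope
0.2233 (relative-only, for comparison) — and two temperature models: the
water-bucket coefficient −0.000974 m³ m⁻³ °C⁻¹ (default; CI
(−0.000988, −0.000960), with the √ε-scale slope −0.0145 °C⁻¹) and the
wood-block coefficient −0.000950 (diagnostic only: that experiment is
noisier because of condensation). Standard errors for the two
temperature slopes are reconstructed from their published t statistics
(slope/|t|). Relative-only entries carry no intercept and refuse
absolute application.

## Calibration fitting

**Pooled OLS** of θ on √ε gives the TTC-form line with 95% CIs and
in-sample R², RMSE, MAE and RAE. RAE is Σ|error| / Σ|θ − mean(θ)|, so
predicting the mean gives RAE = 1.

**Species models.** The ANCOVA θ ~ √ε * species is summarized with
sequential (type-I) sums of squares in the scientifically meaningful
order — common slope, then species intercepts, then the species × slope
interaction — against the full-model residual mean square. The explicit
sequence is computed from nested model SSRs rather than from the design
matrix ordering, because formula machinery reorders categorical terms
ahead of numeric ones and would otherwise test species *unconditionally*
on √ε (where intercept shifts are invisible, being absorbed into the √ε
distribution). The interaction-vs-main-effects comparison is also
reported as a standard F table.

**Mixed model.** θ ~ √ε (optionally + species-mean wood density) with
random intercepts for species and for individuals nested in species,
estimated with statsmodels MixedLM (REML by default for variance
components; ML for likelihood-ratio comparisons; L-BFGS with CG/Powell
fallbacks, max 2000 iterations). Marginal and conditional R² follow the
variance-partition definition: R²m = var(Xβ)/(var(Xβ) + σ²_sp + σ²_ind +
σ²_res) and R²c adds the random-intercept variances to the numerator.
A single-species, single-individual input is a degenerate hierarchy and
reduces exactly to OLS (zero variance components, OLS ML log-likelihood).
`mixed_loglik_zero_variance` evaluates the hierarchical likelihood with
both variances pinned at 10⁻¹² (the boundary limit; exactly zero makes
the random-effect covariance singular) and equals the pooled OLS
log-likelihood to well below 10⁻⁶ — the boundary-consistency check of the
hierarchy.

**Likelihood-ratio tests** of the random structure require ML fits with
identical fixed effects and strictly nested random structures; the
statistic 2Δℓ is clamped at zero. The default reference is χ²(Δk); the
50:50 mixture ½χ²(Δk) + ½χ²(Δk−1) appropriate for a variance component on
its boundary is available and flagged in the result. At the design scale
used throughout (8 species × 3 individuals × 11 segments, intercept
spreads 0.03/0.02, residual 0.05 m³ m⁻³) the mixture-null test of the
species variance holds its size (empirical type-I ≈ 0.03 at α = 0.05)
but has power ≈ 0.78 against a species spread of 0.03 — a genuine
property of the design, reproduced exactly by lme4 on the same simulated
data, not an estimation artefact.

**One-slope calibration.** Records are differenced within a configurable
unit — default (species, individual, treatment), each individual's
trajectory through one wet-up or dry-down sequence, ordered by
`order_index`; the unit is configurable (e.g. (species, sample)) because
the "species-sample combination" admits more than one reading when each
segment is measured once. Differences never cross unit boundaries;
duplicated order indices are an error. The OSC is the through-origin OLS
of Δθ on Δ√ε — differencing exists to remove intercepts, so none is
estimated by default; an intercept-included fit is available as a
diagnostic (its CI should cover zero). The through-origin slope always
equals the closed form Σ(ΔθΔx)/Σ(Δx²).

## Temperature artefact

The artefact model is linear: the sensor-reported water content of a
constant-WC medium falls by |slope_wc| per °C of warming. Correction
subtracts slope_wc·(T − T_ref) from the WC signal; T_ref defaults to
25 °C (a tropical below-canopy mean), configurable. The bias table is
bias(ΔT) = |slope_wc|·ΔT·ρ_w with ρ_w = 1000 kg m⁻³, hence 0.974 kg m⁻³
per °C and 4.87 kg m⁻³ for a 5 °C day–night difference with the default
coefficient.

Two correction routes exist and are deliberately kept apart. The default
corrects on the sensor-WC scale with the water-bucket coefficient (the
scale that coefficient was estimated on). Alternatively the artefact can
be removed on the √ε scale (slope −0.0145 °C⁻¹) *before* applying a
calibration — relevant when recalibrating with the TTC/OSC, since a
WC-scale coefficient estimated under the factory calibration does not
transfer exactly through a different line. The two routes disagree by
construction (their implied per-°C corrections differ by a factor of
~3.3 through the TTC); `correction_consistency_ratio` reports the ratio
as a diagnostic and the package asserts nothing about which the user
should prefer. Slope equality between two fitted temperature models is
tested with a two-sample z statistic on the difference of slopes.

## Field pipeline

Processing order is fixed and logged in the output metadata: raw → ε →
√ε → calibration → temperature correction → ΔStWC against a baseline.
ΔStWC is (θ − θ_baseline)·1000 kg m⁻³. The baseline is either the first
valid sample (default; ΔStWC(0) = 0) or the mean over a named time
window. With a relative-only calibration the slope-only signal m·√ε is
carried and the mandatory baseline removes its arbitrary offset. The
unadjusted and adjusted VWC columns differ row-wise by exactly
slope_wc·(T − T_ref); their Δ columns each use their own baseline.
Timestamps are timezone-naive local time and must be strictly
increasing; cadence gaps are recorded in metadata and never filled
(optional gap handling is left to the user). Diurnal cycles are
time-of-day bin means at the logger cadence; the reported amplitude is
peak-to-trough of the bin means. Seasonal aggregation requires every
row to be labelled and warns about declared-but-empty periods.

## Synthetic generators

All generators require a seed and are byte-deterministic.

*Calibration experiment* (defaults: 8 species × 3 individuals × 11
segments ≈ the real n = 262 design): species and individual intercept
offsets are centred normals (defaults 0.03 and 0.02 m³ m⁻³); each
individual's segments split ⅓ wet-up / ⅔ dry-down with exponential
approach trajectories (0.40 → 0.60 saturating, 0.40 → 0.05 drying, the
phenomenological shapes only set leverage, not the truth); √ε is
obtained by inverting each segment's effective line at its noiseless
trajectory VWC, and residual noise (default 0.05 m³ m⁻³) is added to the
*recorded* VWC — on the regression response, matching the fitted model's
error structure. Species mean wood densities are drawn uniformly over
0.22–0.84 g cm⁻³, the sampled range. Note a deliberate consequence:
because intercept offsets shift √ε, the naive pooled OLS slope is
attenuated while the mixed model and OSC are not — the generator
reproduces the reason the one-slope calibration exists.

*Temperature ramp* (defaults: 15 → 27 °C over 2 days at 5-min cadence):
both endpoints are logged, giving 2·288 + 1 = 577 records; sensor WC is
base + slope·(T − T_ref) + noise, with an optional parallel √ε channel.

*Field series* (defaults: 10 days at 15-min cadence, rows = days·96):
temperature is sinusoidal, peaking at 14:00; "amplitude"/"range" fields
are peak-to-trough throughout, so the default 5 °C swing reproduces the
4.87 kg m⁻³ artefact cycle. True WC is constant by default (optional
diurnal cycle anti-phased with temperature and linear seasonal drift);
the sensed signal adds the artefact and noise, and raw counts are
produced by pushing the sensed signal back through the calibration and
numerically inverting the transform (bisection to 10⁻¹²), so the full
pipeline round-trips to numerical precision.

What the generators do *not* emulate: sensor-to-sensor offsets,
installation effects (air gaps, drilling damage), wood anatomy beyond a
scalar density, condensation (the wood-block experiment's noise source),
autocorrelated sensor noise, and any biophysical drying model. Passing
recovery tests therefore demonstrates correctness of the estimators
under the assumed statistical structure, not field accuracy of the
shipped coefficients.

## Problem sizes and numerical choices

Simulation-based tests use 100–200 seeded replicates at the 264-record
design scale, chosen to give Monte-Carlo standard errors a few percent
wide while keeping the full suite fast on one CPU. Tolerances: exact
arithmetic identities at 10⁻¹²; likelihood boundary identities at 10⁻⁶;
generator round-trips at 10⁻¹⁰. Input validation bands: VWC sanity
(−0.05, 1.5) m³ m⁻³ (wider than physical, rejects percent-scale columns),
temperature sanity (−20, 60) °C; files with more than 10% invalid rows
are rejected outright, fewer are dropped with named line numbers.

## Known limitations

* The shipped calibrations were estimated on tropical diffuse-porous
  trees and palms with a shortened 3-cm probe; other anatomies, probe
  geometries or sensor families need their own registry entries.
* The temperature correction is a single linear coefficient estimated in
  water; wood-specific temperature responses may differ, and separating
  thermal artefact from genuine thermally driven storage dynamics is not
  attempted.
* Absolute VWC from the TTC in *unknown* species inherits the
  species-intercept spread; only relative dynamics via the OSC are
  species-independent.
* The OSC supports no absolute values by construction; field assessment
  of species intercepts is out of scope.
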