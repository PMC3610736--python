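# Methods

## Body-oxygen model

The organism is an infinite cylinder of radius *R* (end-caps ignored; for
meiofaunal aspect ratios the axial flux contribution is negligible) with a
spatially uniform volumetric oxygen consumption *Q* and a tissue
diffusivity *D*; the pore water at the wall is held at *AW*. The
steady-state radial balance (1/r)·d/dr(r·dC/dr) = Q/D with C(R) = AW and a
symmetric centre gives the parabola C(r) = AW − (Q/4D)(R²−r²). Everything
else is algebra on that parabola:

* critical thickness 2R_crit = 4·√(D·AW/Q), from C(0) = 0;
* its depth dependence, by composing with a pore-water O₂(z) profile;
* residence time τ = C̄/Q with C̄ = AW − Q·R²/(8D) (cross-sectional mean),
  bounded above by AW/Q (39.7 s at AW = 230 µmol l⁻¹, Q = 0.5 mol l⁻¹ d⁻¹)
  and equal to half that bound at the critical radius.

Parameters and defaults:

| parameter | default | units | rationale |
|---|---|---|---|
| Q | 0.5 | mol O₂ l⁻¹ d⁻¹ | literature value for active meiofaunal tissue |
| D | 1.0×10⁻⁹ | m² s⁻¹ | order of O₂ diffusivity in water/tissue at 20 °C |
| AW | user input | µmol l⁻¹ | 230 = air saturation at 20 °C, S=34 |

D for real tissue is uncertain; all body-model outputs should be read as
shapes and orders of magnitude in D, exactly reproducible only in the
closed forms above. Supercritical bodies (width beyond critical) raise an
error rather than solving the anoxic-core moving-boundary problem: the
model is only claimed up to the critical thickness. Oxygen storage
(pigment binding) is ignored — most nematodes lack oxygen-binding
pigments — which makes the residence time a pure turnover time.

Internally all diffusion math is SI (mol m⁻³, m, s); interface units are
the field's (µmol l⁻¹, µm, mm, mol l⁻¹ d⁻¹) with exact pure converters.

Sediment profiles are parametric: parabolic AW₀(1−z/OPD)² (the
steady-state shape for constant volumetric consumption with diffusive
supply, and the default), exponential (1% of AW₀ at the OPD), or linear;
all clipped to zero at and below the OPD.

## Chamber kinetics

Drawdown model: dC/dt = −R_max·(C−O₂,min)/(k_s + C−O₂,min), C(0) = O₂,init.
The offset form is chosen so consumption vanishes exactly at O₂,min (the
concentration at which the animal stops using oxygen; for most replicates
O₂,min = 0). The ODE is separable; the implicit solution
k_s·ln(u/u₀) + (u−u₀) = −R_max·t (u = C−O₂,min) inverts in closed form via
the Wright omega function, ω(y) = W(eʸ): u = k_s·ω((s − k_s·ln k_s)/k_s)
with s = k_s·ln u₀ + u₀ − R_max·t, numerically stable for any k_s.
`simulate_chamber` integrates the ODE with LSODA at rtol = atol = 10⁻⁹;
the fitters evaluate the closed form (hundreds of times faster, identical
to within integrator tolerance); the test suite checks the integrator
against an independent brentq root-finder on the implicit equation.

Fitting (`MonodFitter`): trust-region least squares on the closed-form
trace. Initial values follow the original protocol — R_max and O₂,min from
a linear fit of the data (slope magnitude; linear extrapolation to the end
of the record, floored at 0), k_s = 10 µmol l⁻¹, O₂,init = first
observation. Bounds: R_max > 0, 0 < k_s ≤ 350 µmol l⁻¹, O₂,min ≥ 0. The
k_s ceiling mirrors the original fits, where near-linear traces pin k_s at
exactly 350; `bound_hits` reports any pinned parameter. Non-convergence is
a flagged result, not an exception; a non-declining trace is a data error.

Two-phase (ostracod) fits: Monod before a breakpoint, ordinary least
squares after (the stress-response phase where respiration is simply
R_max with no rate limitation). With no breakpoint given, a coarse grid of
observation times plus local refinement minimises the combined SSR; during
*selection* the candidate line is anchored at the Monod prediction at the
candidate time — concentration is continuous in time, and the free-intercept
line localises the kink poorly (±2–4 samples) while the anchored one is
sharp (within one sample). The slope *reported* at the selected or supplied
breakpoint is plain OLS of the tail. If no split beats the single-phase
SSR, the fit falls back to plain Monod with a flag.

Blank correction subtracts the mean linear consumption rate of
seawater-only chambers from the faunal volumetric rate (a single scalar,
matching how such rates are reported); a blank above 50% of the faunal
signal flags contamination.

Conversions: Resp_day = rate × volume × 24 × 12 / biomass (1 mol O₂ per
mol C respired; 12 µg C per µmol). Respiration at p% of air saturation is
the plain Monod curve rescaled through the full-saturation value:
R(c) = R₁₀₀·(c/(c+k_s))·((C_sat+k_s)/C_sat), c = p/100·C_sat,
C_sat = 230 µmol l⁻¹ (fixed, not recomputed from a solubility formula).
O₂,min is deliberately excluded here: only the anchored plain-Monod form
round-trips the published saturation-rate columns for replicates fitted
with non-zero O₂,min. Table-style outputs round half-up (2 decimals for
coefficients, 3 for rates, 1 for overestimation factors). Two published
replicates (Foraminifer2, Gastropod2) fail the 3-decimal round-trip by one
unit in the last digit — their printed coefficients are themselves rounded
— and are documented exceptions, not force-matched.

## Carbon budget

Fully-oxic ("high O₂") community respiration: per individual
a·m^b·Q10^((T−20)/10) with a = 7.4×10⁻³, b = 0.75, Q10 = 2, m the carbon
mass from L·W²/1.6×10⁶ (µg wet), ×0.25 dry:wet, ×0.4 C:dry — all
config-exposed constants (the exact literature constants vary between
compilations; absolute budget values therefore are not a claim of this
package, the ratio structure is). Per layer: density × mean individual
rate; µg C (10 cm²)⁻¹ d⁻¹ ≡ mg C m⁻² d⁻¹ exactly.

Ambient-O₂ respiration replaces the allometric rate with the
biomass-specific Monod response of *Enoploides longispiculosus*
(R₁₀₀ = 0.045 µg C µg C⁻¹ d⁻¹, k_s = 105.25 µmol l⁻¹ by default; any
replicate can be substituted — the choice of replicate vs mean is left to
the user) evaluated at each layer's oxygen:

* stepwise (default): the full-saturation rate in the first fully
  oxygenated centimetre (layers wholly above min(OPD, 10 mm)), the 10%
  rate in layers intersecting the suboxic interval up to the OPD, the 1%
  rate below the OPD;
* continuous: the anchored Monod curve at O₂(z) of the layer midpoint.

Q10 correction (reference 20 °C, the measurement temperature) applies to
both budgets — cold deep-sea stations are unreachable without it. Depth
coordinates are millimetres, 0-based, half-open [top, bottom). When only
mean ± sd individual biomass is known, communities are Monte-Carlo sampled
from a moment-matched log-normal (b < 1 makes the mean-mass shortcut
biased; sd ≥ mean in field data rules out symmetric laws).

## Synthetic data

Generators are pure functions of (spec, seed) via `numpy.random.default_rng`:

* drawdown traces: forward simulation + i.i.d. Gaussian concentration
  noise (σ default 2 µmol l⁻¹ — an assumption; real optode noise is
  instrument-specific), clipped at 0, sampled every 5 min; default
  duration runs to predicted depletion + 2 h, clamped to the 5–30 h
  incubation span. No drift or autocorrelation is modelled, so recovery
  results bound what ideal-noise data allow, not what a drifting optode
  would;
* blanks: linear decline at a set fraction (default 0.15) of the faunal
  rate plus the same noise;
* two-phase traces: Monod decline levelling at a plateau, a plateau hold,
  then a linear fall, *ending at depletion* (a flat anoxic tail is not
  part of the drawdown and would corrupt the tail regression);
* communities: log-normal masses moment-matched to a target mean ± sd
  (default 0.62 ± 0.97 µg C), density decaying exponentially with depth
  (e-folding 15 mm — a modelling choice, field profiles vary).

## Problem sizes and numerical choices

Recovery studies use 100 traces per taxon (~180–360 points each) and
20-seed breakpoint experiments; the whole suite runs in well under a
minute on one core. Body-model oracle checks use 20 random parameter sets
(bisection to 80 halvings); ODE-vs-implicit equivalence uses 50 random
parameter sets at mixed tolerance 10⁻⁶ relative with a 10⁻⁹ µmol l⁻¹
absolute floor for the depleted tail. Ties in breakpoint SSR resolve to
the earliest candidate scanned. Default seed for stochastic defaults is
20130328.

## Known limitations

* D inside real tissue, and the AW/radius ranges behind published
  residence-time figures, are not constrained here; only closed-form
  values and qualitative spans are asserted.
* The budget's absolute values depend on allometric constants and on
  unpublished per-individual field data; the package reproduces the ratio
  structure and the methodology, not station-level absolute respiration.
* No anaerobic metabolism, sulphide chemistry, valve-closure mechanics or
  optode drift; blanks are linear by construction.
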