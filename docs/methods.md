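# Methods

This note documents the model equations, the synthetic forcing, every
parameter default with its rationale, the numerical scheme, and the
limitations of the desk-scale setup. All defaults live in one versioned
file, `src/coastbloom/data/default_params.yaml`, which is echoed into
every run's output directory.

## Model structure

Each station is a vertically averaged (0D) water column of fixed depth
`H`. State variables: DIC, DIN, DIP (mmol m⁻³); phytoplankton `Phy` and
zooplankton `Zoo` (mmol-C m⁻³, fixed Redfield stoichiometry
q_N = 16/106 mol-N/mol-C, q_P = 1/106 mol-P/mol-C); detritus and
dissolved organic matter with explicit C/N/P; intracellular virus
density `v` (dimensionless); and per-area benthic C/N/P pools
(mmol m⁻²). Chlorophyll is diagnostic, `CHL = θ_chl · Phy` with
θ_chl = 0.25 mg CHL per mmol-C (≈ 1:48 CHL:C by mass); there is no
photoacclimation.

Fixed stoichiometry is a deliberate simplification: the adaptive-trait
physiology (variable C:N:P quotas, photoacclimation, variable sinking)
of full shelf-sea ecosystem models is replaced by a minimal backbone so
that the coastal closure biology — turbidity, carnivory, virus — stands
out and every flux is analytically checkable.

### Phytoplankton

Growth μ = μ_max · f_T · f_I · f_N with

* μ_max = 1.5 d⁻¹;
* Q10 temperature response f_T = q10^((T−T_ref)/10), q10 = 2,
  T_ref = 10 °C (applied to growth, grazing, closure mortality and
  basal metabolism);
* depth-averaged light limitation f_I = Ī/(Ī + I_k) with
  Ī = I₀ (1 − e^(−kH))/(kH), I_k = 25 W m⁻²; total attenuation
  k = a_w + a_SPM + a_chl·CHL, a_w = 0.1 m⁻¹, a_chl = 0.02 m⁻¹ per
  mg CHL m⁻³;
* Liebig minimum of Monod terms f_N = min(DIN/(K_N+DIN), DIP/(K_P+DIP)),
  K_N = 1 mmol-N m⁻³ and K_P = K_N/16 = 0.0625 mmol-P m⁻³ (Redfield-
  consistent, so neither nutrient is artificially privileged at equal
  relative depletion).

Losses: herbivorous grazing, viral lysis (below), and quadratic
aggregation m_agg·Phy² with m_agg = 0.0015 m³ mmol-C⁻¹ d⁻¹ (a 10%/d
loss at Phy ≈ 67 mmol-C m⁻³; stands in for aggregation-enhanced
sinking, which is not mechanistically resolved here).

### Turbidity

SPM attenuation:

a_SPM = a'_SPM [ α + (1−α)/2 ( η_{20}(J) σ_{0.4}(H−H*) + ε_b/ε* ) ]

* η_L(J) = ½ + ½ cos(2π/365 (J−L)) peaks at Julian day L (winter
  maximum, L = 20); σ_s(x) = 1/(1+e^{sx}) is *decreasing* in x.
* a'_SPM = 2.0 m⁻¹ and α = 0.05: offshore background attenuation
  a'_SPM·α = 0.1 m⁻¹ on top of clear water, while a shallow station in
  winter with ε_b ≈ ε* reaches ≈ 2 m⁻¹ — a cross-shore contrast of
  more than a factor ten, matching the remotely sensed accumulation
  factor for the study region rather than the ~2× of older forcing
  climatologies.
* H* = 20 m: resuspension is confined to the shallow areas (H < 20 m).
* ε* = 10⁻⁵ W kg⁻¹: a representative storm-level bottom dissipation on
  a shallow shelf; the synthetic-forcing baseline sits below it at deep
  stations, so the event term engages mainly near shore and in storms.

### Coastal vicinity and the carnivory closure

σ̃(H,S) = max{σ_{0.4}(H−H*), σ_1(S−31)} + ½ σ_1(S−12) ∈ [0, 1.5]

marks shallow (H < H*), coastal (S < 31 PSU) and estuarine (S < 12 PSU)
water. It scales the herbivore grazing half-saturation,
K = K_graz·(½+σ̃) — offshore grazers exploit patchy prey more
efficiently, so their effective half-saturation halves — and the
zooplankton closure mortality

m_Z = m'_Z · f_T · σ̃ · ( γ Z + β η²_{250}(J) )

* m'_Z = 0.025 d⁻¹. With β = 1, unit vicinity and f_T at the summer
  maximum (~1.6) the seasonal (fish-predation) part of m_Z peaks at
  0.04 d⁻¹, the upper end of trawl-survey-based estimates for shelf
  mesozooplankton; the density-dependent part γZ adds benthic filter
  feeding and non-predation losses on top.
* γ = 1.5 m³ mmol-C⁻¹: at typical near-coast summer zooplankton of
  2–4 mmol-C m⁻³ this contributes 0.1–0.3 d⁻¹ — the magnitude reported
  above mussel beds — and acts as the stabilizing self-limitation of
  the closure.
* The squared harmonic η²_{250} concentrates carnivory in late summer
  (maximum at day 250) with the order-of-magnitude winter-summer
  contrast seen in reconstructions.

### Viral infection

Host mortality is a smooth step of the intracellular virus density,
normalized so v = 1 is the LD50:

m_P,vir = m_vir_max · σ_s(1−v), m_vir_max = 1 d⁻¹, s = 4

(50% loss per day at v = 1; saturating at 1 d⁻¹). Lysis routes 80% of
each elemental flux to detritus and 20% to dissolved organics. The
density evolves as dv/dt = r_ads·n_rep − r_defense − r_mort with the
package's rate forms:

* r_ads = k_ads·Phy/(K_ads+Phy), k_ads = 0.4 d⁻¹, K_ads = 10 mmol-C m⁻³
  (encounter saturating in host biomass, zero without hosts);
* n_rep = n_max·f_N, n_max = 3.5 (replication draws on the host's
  intracellular nutrient reserves);
* r_defense = k_def·v·f_N, k_def = 1 d⁻¹ (inducible defense, stronger
  in healthy hosts); r_mort = k_dec·v, k_dec = 0.3 d⁻¹.

Two consequences shape the seasonal cycle. Under ideal conditions
(host-rich, replete) the equilibrium v* = k_ads·n_max/(k_def+k_dec) ≈
1.08 slightly exceeds the critical density, so outbreaks can cross
v = 1 but mortality plateaus below the 1 d⁻¹ ceiling; in the seasonal
runs nutrient drawdown keeps v ≈ 0.6–0.8 and the induced mortality
near 0.2–0.3 d⁻¹. And because both replication and defense scale with
host physiology, the rate forms are kept temperature-neutral: a Q10
factor on replication alone would delay the simulated outbreak into
late summer, whereas the infection should bloom earlier and faster
than the herbivores, tracking the spring host bloom. The virus is a
host-associated intensive variable ("lysogenic-style"); there is no
explicit free-virion pool or burst-size bookkeeping, and v is clipped
at zero with every clipping logged.

### Zooplankton and recycling

Zooplankton assimilate ε = 0.3 of grazing (g_max = 1.5 d⁻¹), egest the
rest to detritus, pay a basal metabolic cost r_basal·f_T·Zoo with
r_basal = 0.05 d⁻¹ (respiration/excretion returned to DIC/DIN/DIP),
and die at rate m_Z (routed 80/20 to detritus/DOM, mirroring the lysis
split in the absence of a separately constrained value). The basal
term is a 0D necessity: the closure mortality vanishes offshore with
σ̃ → 0, and without a maintenance cost zooplankton would graze the
offshore phytoplankton to extinction — in three dimensions lateral
exchange prevents this degenerate state.

K_graz = 15 mmol-C m⁻³ is deliberately high for the backbone: with
prey densities mostly below K the functional response is close to
linear, which damps the boom-bust predator-prey oscillation a sharply
saturating response produces in a closed box. This keeps the
uniform-carnivory scenario in the grazer-dominated quasi-steady state
it is meant to probe instead of a delayed-bloom limit cycle.

Detritus remineralizes to DOM (r_det = 0.05 d⁻¹), DOM to inorganic
nutrients (r_dom = 0.05 d⁻¹), detritus sinks at w_det = 3 m d⁻¹ into
benthic pools that return at r_ben = 0.02 d⁻¹, with f_denit = 0.2 of
the benthic N return denitrified and f_burial = 0.05 of all benthic
returns buried. Denitrification, burial and river loads are
accumulated alongside the state vector, so elemental budgets close
exactly (see Numerics).

## Scenarios

* `reference` — the full model.
* `no_virus` — the replication multiplier n_rep is forced to zero;
  adsorption, defense and decay remain, so v decays rapidly and
  dv/dt ≤ 0 everywhere.
* `uniform_carnivory` — the vicinity index is frozen at its value for
  H = H*, S = 31 PSU (≈ 0.5, a transitional water body) at every
  station, wherever σ̃ enters (both m_Z and the grazing
  half-saturation). The seasonality of m_Z is preserved; only the
  lateral gradient is annihilated. A station already at that point is
  a fixed point of the override.

Season windows for diagnostics are fixed Julian-day ranges (spring
peak searched in days 30–180, summer peak in 180–300, summer means
over days 172–265) rather than event-detected, to keep the
diagnostics deterministic. "Shallowest/deepest" are resolved from
transect metadata, never from the chlorophyll field.

## Synthetic forcing

`make_station` generates one annual cycle per station, deterministic
per seed: temperature 10 + 7 sin-annual °C (minimum mid-February),
irradiance 20–170 W m⁻² (solstice-phased), salinity fluctuating weakly
(σ ≈ 0.3 PSU, ~2 d autocorrelation) around the station mean, and
bottom TKE dissipation as a depth-scaled baseline (0.5 ε* H*/H — below
ε* at deep stations), an M2-like tidal oscillation (±40%, period
0.5175 d) and Poisson storm spikes (12 yr⁻¹ on average) whose
intensity follows the same winter-peaked harmonic η_20 as the
turbidity parametrization, with ~1.5 d exponential decay.

`make_transect` (default 8 stations) spaces depth 5–50 m and salinity
25–34 PSU linearly, shallow stations fresher — the cross-shore ladder
of a river-influenced coast. Riverine nutrient input decreases
linearly from 0.3 mmol-N m⁻² d⁻¹ at the fresh end to zero offshore,
winter-peaked, with molar N:P = 40 — far above Redfield, as for
continental rivers; preprocessing helpers apply the 0.85 estuarine
retention factor and the 0.01 mol-P/mol-N atmospheric deposition
ratio (with a configurable climatological N enhancement factor,
default 3). Initial winter nutrient stocks scale with the freshwater
influence (DIN from 12 offshore to 58 mmol-N m⁻³ at the coast, N:P =
40), inside the observed ranges for near-coast and offshore stations.
The N:P supply above Redfield makes phosphorus deplete before
nitrogen in early summer, as observed near-shore.

Pseudo-observations subsample a trajectory at monitoring-like cadence
with uniform time jitter (±cadence/4) and multiplicative lognormal
noise exp(N(0, σ²)).

What the generator does *not* emulate: lateral transport and tidal
advection between stations, stratification, realistic meteorology,
sediment transport, and interannual variability (the spin-up repeats
the year-1 forcing). Passing scenario tests therefore demonstrate the
mechanisms' direction and rough magnitude in a closed seasonal cycle,
not hindcast skill against real monitoring data — reproducing the
observed station statistics requires three-dimensional hydrodynamics
and real forcing, which are out of scope.

## Skill statistics

For each observation event the best-matching model value within a 3 d
window (interpreted as ±1.5 d symmetric) is selected — by minimal
absolute log ratio, consistent with log-transformed error statistics;
nearest-in-time selection is available behind a flag. Events without
an in-window model value are dropped and counted. Taylor-diagram
statistics are computed on natural logs: correlation (angle),
STD(model)/STD(obs) (radius), and centered RMSD normalized by STD(obs)
(distance from the reference point), which satisfies the Taylor
identity rmsd² = σ_m² + σ_o² − 2σ_mσ_o·ρ exactly. The mean-normalized
bias is computed on raw values by default (so it reads as a
percentage); a pre/post-log choice is exposed since conventions vary.
Seasonal pooling groups pairs by meteorological season (DJF/MAM/JJA/
SON of the day-of-year) and computes statistics on the pooled pairs,
never by averaging per-scene statistics.

## Numerics

* Classical RK4, fixed step dt = 0.05 d; states stored every 1.5 d.
  Forcing is pre-sampled on the half-step grid (linear interpolation,
  periodic in the one-year record — the spin-up convention of
  repeating year-1 forcing; default 2 spin-up years + 1 evaluation
  year at desk scale, longer spin-up available).
* All losses are proportional to their donor pool (Monod/Holling
  forms), so trajectories stay positive for the default step;
  truncation-induced negative pools are clipped to zero and every
  clipping event is logged with its magnitude. A non-finite state or
  derivative aborts with the step index and the offending pool named.
* Because every internal transfer appears with equal and opposite
  signs, per-area totals of C, N and P are conserved to floating-point
  roundoff in a closed configuration (verified to 1e-8 relative over
  an annual run; in practice ~1e-14). External exchanges (river
  sources, denitrification, burial) are integrated as cumulative
  trackers inside the state vector, so `mass_balance` closes budgets
  without re-integrating fluxes.
* The integrator shows clean fourth-order convergence on smooth
  forcing; the bundled order test aligns the forcing grid with all
  RK4 substeps because the piecewise-linear interpolation of rough
  (storm/noise) forcing otherwise dominates the error at small steps.
* Sigmoid exponents are clamped at ±500 before exponentiation, so the
  step functions saturate instead of overflowing.
* Year length is fixed at 365 d; Julian day is continuous and wrapped
  mod 365; no leap years.

## Design choices in open territory

* The clear-water phase between spring and summer blooms emerges from
  mid-shelf outward in this setup, while the shallowest stations keep
  persistently elevated chlorophyll — the coastal-accumulation
  mechanism itself; the most near-shore waters of the study system
  likewise lack a clear-water phase.
* The 0D surrogate checks the *direction* and rough magnitude of the
  scenario responses (virus roughly doubling the coastal spring peak
  when removed; uniform carnivory flattening the cross-shore gradient
  and piling up near-coast grazers while leaving offshore stocks
  approximately unchanged). The full-domain magnitudes (order-of-
  magnitude CHL drop, 30–50% peak reductions) are three-dimensional
  results and are not targeted.
* Boundary-condition parametrizations of the full model (offshore
  nutrient/plankton boundaries) do not apply to a closed box and are
  not implemented.

## Known limitations

No oxygen, silicate or iron; no explicit SPM prognostics or wave
module; no vertical structure (depth enters only through light
averaging, benthic exchange scaling and the H-dependent
parametrizations); single phytoplankton and zooplankton compartments;
no multi-strain virus specificity. The closure calibration
(γ, K_graz, r_basal) is tied to the 0D setting and would need
re-calibration in any transport-resolving configuration.
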