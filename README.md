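# coastbloom

A reduced coastal plankton ecosystem model for shallow tidal shelf seas,
built to reproduce and probe — at desk scale, on synthetic forcing — the
mechanism behind *persistent near-shore chlorophyll accumulation*: the
interplay of turbidity, coastally intensified carnivorous grazing
pressure on zooplankton, and viral infection of phytoplankton.

It is aimed at marine ecosystem modellers and biogeochemists who want a
small, fully testable NPZD-type water-column model in which the coastal
closure biology is explicit and each mechanism can be switched off in a
controlled scenario experiment.

## The model

One zero-dimensional box per station (depth 5–50 m) carries dissolved
inorganic C/N/P, phytoplankton and zooplankton (fixed Redfield
stoichiometry), detrital and dissolved organic matter, benthic pools
coupled by detritus sinking and first-order benthic return (with
denitrified and buried fractions), and an intracellular virus density.
On this backbone sit the coastal parametrizations:

**Turbidity.** Light attenuation by suspended particulate matter (SPM)
follows

```
a_SPM = a'_SPM [ α + (1−α)/2 ( η_20(J) σ_0.4(H − H*) + ε_b/ε* ) ]
```

with the annual harmonic `η_L(J) = ½ + ½ cos(2π/365 (J − L))` peaking
in winter (day 20) and the decreasing smooth step
`σ_s(x) = 1/(1 + exp(s x))` confining resuspension to shallow water
(H < H* = 20 m); `ε_b/ε*` adds tidal- and storm-driven events.

**Coastal vicinity and carnivory.** The vicinity index

```
σ̃(H,S) = max{ σ_0.4(H − H*), σ_1(S − 31) } + ½ σ_1(S − 12)
```

ranges from ~0 offshore to 1.5 in estuarine water. It scales both the
herbivore grazing half-saturation, `K (½ + σ̃)`, and the zooplankton
closure mortality

```
m_Z = m'_Z f_T σ̃ ( γ Z + β η²_250(J) )
```

with `m'_Z = 0.025 d⁻¹` — predation by juvenile fish and benthic filter
feeders, concentrated near the coast with a pronounced late-summer peak.

**Viral infection.** Intracellular virus density `v` (normalized so
v = 1 is the LD50) imposes host mortality `m_P,vir = 1 d⁻¹ · σ₄(1 − v)`
— 50% loss per day at the critical density — and evolves as
`dv/dt = r_ads n_rep − r_defense − r_mort`. Lysis products are routed
80% to detritus, 20% to dissolved organics.

Scenario experiments: `reference`, `no_virus` (replication forced to
zero), and `uniform_carnivory` (vicinity frozen at its value for
H = H*, S = 31 PSU everywhere). Model–data skill uses best-match pairing
within a 3-day window and log-transform Taylor-diagram statistics.

## Worked example

```python
import coastbloom as cb
from coastbloom import experiments as xp

p = cb.CoastalParams.default()
transect = cb.make_transect(n_stations=8, seed=0)          # 5–50 m, 25–34 PSU
res = xp.run_experiment(transect, ["reference", "no_virus"], p)

coast = res.trajectories["reference"]["st00"]              # shallowest station
sl = res.eval_slice(coast)                                 # final year
bm = xp.bloom_metrics(coast.times[sl] % 365.0, coast.chl[sl])
```

which, with the shipped defaults, prints

```
vicinity(H=8 m,  S=27 PSU) = 0.992
vicinity(H=50 m, S=34 PSU) = 0.047
viral host mortality at v=1: 0.50 per day
coastal (st00) spring peak: 6.0 mg CHL/m3 on day 137
mid-shelf (st04) clear-water minimum: 0.93 mg CHL/m3 between blooms on days 112 and 275
no-virus coastal spring peak: 12.7 mg CHL/m3 (2.1 x reference)
summer cross-shore CHL ratio (reference): 11.7
```

Reading: the coastal station carries an order of magnitude more
summer chlorophyll than the offshore one (ratio 11.7); switching off
the virus roughly doubles the coastal spring bloom; the clear-water
phase between spring and summer blooms emerges from mid-shelf outward,
while near-shore chlorophyll stays persistently high.

The same runs are available from the shell:

```sh
coastbloom run-experiment --scenarios reference,no_virus,uniform_carnivory --out runs/demo
coastbloom skill --model model.csv --obs obs.csv --window 3 --log
```

Every output directory contains the trajectories as tidy CSV, a JSON
summary, and echoes of the parameter file and run configuration, so a
run can be reproduced bit-identically.

## Documentation

`docs/methods.md` describes the model equations, the synthetic forcing
generator, all parameter choices with units and rationale, numerical
details, and known limitations of the zero-dimensional setup.
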