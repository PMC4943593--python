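# Methods

This note documents the models implemented in `wetlandch4`, the choices made
where the underlying process descriptions leave the functional forms open,
and what the synthetic drivers do and do not emulate.

## Overview

The package projects daily CH₄ fluxes from temperate freshwater marshes
(the Sanjiang Plain setting: *Deyeuxia angustifolia* grass marsh and *Carex
lasiocarpa* sedge marsh) through a chain of four models:

1. a **scenario generator** producing daily weather, annual CO₂ paths and a
   wetland region grid for RCP-style pathways;
2. an **empirical water-table model** (daily bucket balance with
   Priestley–Taylor evapotranspiration);
3. an **ANPP response surface** supplying annual above-ground productivity;
4. a **substrate-based CH₄ core** (production, oxidation, and emission via
   plant transport, ebullition and diffusion);

followed by regional aggregation (area weighting, Tg totals, wetland-area
scenarios, CO₂-equivalent conversion) and validation statistics.

## Water-table model

State is the water table WT (cm, positive above the soil surface). Daily:

```
dWT = S_in − F_out − ET          April–October
dWT = P − ET                     November–March (frozen: no runoff,
                                  no inflow scaling)
S_in  = α₀ · P
F_out = a₁(WT−D₁) + a₂(WT−D₂)    WT > D₁
      = a₂(WT−D₂)                D₂ < WT ≤ D₁
      = 0                        WT ≤ D₂
```

with D₁ = 0 cm and D₂ = −15 cm shared across vegetation types, and the
field-calibrated constants α₀ = 1.1 / 1.25, a₁ = 0.012 / 0.011 and
a₂ = 0.02 / 0.005 d⁻¹ for grass / sedge marsh. The two-branch outflow as
printed in its source is single-valued and continuous only under the
reading above; ties go to the branch shown. Outflow and ET are evaluated at
the previous day's WT (explicit first-order scheme), which makes the
water-balance identity `WT_end − WT_0 = Σ(S_in − F_out − ET)` exact to
floating-point accumulation (< 1e-9 cm over a century).

Precipitation enters the frozen-season branch unscaled (P, not α₀P),
following the balance equation as printed rather than the inflow function.
Units inside the model are cm; the generator produces mm and the conversion
happens at the hydrology boundary.

**Evapotranspiration.** Priestley–Taylor with α = 1.26, λ = 2.45 MJ kg⁻¹,
daily ground heat flux 0; Δ from air temperature, γ from surface pressure.
Net radiation uses the FAO-56 chain: extraterrestrial radiation from
latitude and day of year, solar radiation from the diurnal temperature
range (Hargreaves coefficient 0.16, interior site), longwave from the
Stefan–Boltzmann term with vapour pressure taken from specific humidity,
cloudiness factor from Rs/Rso clipped to [0.3, 1]. Two surface choices are
deliberate: albedo 0.23 (vegetated marsh canopy, the FAO reference value —
a water-surface albedo near 0.08 pushes annual ET ~45 % above the region's
observed 540–580 mm range) and zero ET on days with sub-zero mean air
temperature (frozen surface). With these, baseline annual ET lands at
~590 mm, inside ±20 % of the observed range, and summer water tables
oscillate in the realistic −30…+15 cm band.

**Calibration.** `calibrate_ehm` minimises RMSE between simulated and
observed WT over (α₀, a₁, a₂) by default (D₁, D₂ held fixed since they are
shared across types, freeable via `bounds`), using a seeded Latin-hypercube
screen (160 points, midpoint always included) plus Nelder–Mead refinement.
At least 60 overlapping observation days are required. With 1 cm Gaussian
observation noise over two years, recovery is well within α₀ ± 0.15 and
±50 % on a₁/a₂. Note that a₁ is only weakly identified at sites that rarely
flood (it acts only when WT > D₁ = 0); its recovered value scatters more
than α₀ and a₂, which the recovery experiment in
`analysis/02_calibrate_water_table.py` quantifies.

## Scenario generator

The generator is a pure function of (spec, seed) — identical inputs give
bitwise-identical output.

* **Temperature**: annual mean 1.9 °C + sinusoidal seasonal cycle
  (amplitude 20 °C, peak around 27 July, giving the ≥ 40 °C July–January
  contrast of a continental monsoon climate) + AR(1) noise (ρ = 0.7,
  σ = 3 °C, stationary initialisation) + scenario trend. Linear scenarios
  warm at 0.26 (mid pathway) or 0.69 °C decade⁻¹ (high pathway) from 2011;
  the low pathway rises to +1.3 °C at 2050 and declines to a −0.75 °C
  anomaly by the mid-2090s. National-scale trend presets
  (0.06/0.24/0.63 °C decade⁻¹) are recorded alongside but the generator
  targets the region-specific rates.
* **Diurnal range**: uniform 6–14 °C, split symmetrically around the mean;
  it feeds only the solar estimate in the ET step.
* **Precipitation**: two-state occurrence chain (wet-after-wet 0.6,
  wet-after-dry 0.25) with gamma amounts (shape 0.8) and monthly scale
  weights concentrating ~74 % of rain in May–September; the absolute level
  is normalised so the expected annual total is exactly 600 mm. Scenario
  change is a multiplicative factor ramping to (600+Δ)/600 by 2100 with
  Δ = 81.1 / 76.6 / 133.0 mm for the low/mid/high pathways.
* **CO₂**: 370 ppm in 2001; quadratic rise to 1370 ppm at 2100 (high);
  rise and stabilisation at 650 ppm from 2080 (mid); single peak of
  490 ppm at 2050 declining to 440 ppm (low).
* **Region grid**: Dirichlet-partitioned cell areas summing to 10 714 km²,
  a 20/80 grass/sedge vegetation split honoured to within one cell, soil
  properties uniform in sand 10–40 %, SOM 50–200 g kg⁻¹, bulk density
  0.2–1.0 g cm⁻³, and subregion labels partitioning the cells into the
  seven prefecture groups.

What the generator does **not** emulate: real GCM internal variability and
spatial correlation between cells (cell noise streams are independent),
orographic gradients, multi-day storm structure beyond the first-order
chain, and observed interannual teleconnections. Tests passing on this
synthetic weather therefore establish the *pipeline's* correctness and the
stated statistical contracts, not skill against real station data.

## ANPP driver

A three-coefficient response surface replaces a full terrestrial ecosystem
model:

```
ANPP = anpp0 · (1 + β_c ln(CO₂/CO₂_ref)) · (1 + β_t ΔT + β_p ΔP/P₀),  ≥ 0
```

with `anpp0 = 480 g m⁻² yr⁻¹` (midpoint of the 260–700 range observed
across the plain's marshes) and an above-ground fraction of 0.5 applied
when converting from total NPP (the value used upstream is not published;
it is a config override). The coefficients are fit by least squares to the
published decadal ANPP increments of all three scenarios (27 rows), using
the generator's deterministic decadal anomalies as drivers. The fitted
surface reproduces the three 2091–2100 increments (38.2/116.6/250.4
g m⁻² yr⁻¹) within 4–13 % and preserves the low < mid < high ordering.
Any per-year ANPP table can replace the surface entirely; it is a declared
stand-in, not a mechanistic model.

## CH₄ core

Every rate constant lives in `params.py` and is overridable per run; the
process structure is:

* **Soil temperature**: 5-day trailing mean of air temperature, clamped at
  0 °C.
* **Redox**: Eh falls 20 mV d⁻¹ under standing water toward −250 mV and
  recovers at 2 mV d⁻¹ per cm of water-table deficit toward +300 mV.
  Production is unlimited below −150 mV, zero above −100 mV, linear
  between. Redox sees the true signed water table; the transport and
  ebullition pathways see the standing depth max(WT, 0). This dual view
  reconciles two requirements: drained soil must oxidise and stop
  producing, while emissions must be insensitive to *how deep* standing
  water is once a marsh has been flooded for a while.
* **Substrate**: root exudates = k_e · 0.45 · ANPP · g(t), with g(t) a
  logistic-derivative allocation curve over May 1–September 30 summing to
  exactly 1; litter and labile-SOM pools decompose first order
  (k = 0.01 / 0.001 d⁻¹ at the 30 °C reference) with Q10 = 3 scaling; the
  litter pool is replenished with litter_frac · 0.45 · ANPP at season end.
  The labile SOM pool is initialised as 2 % of the SOM carbon stock in the
  top 30 cm (0.58 g C per g SOM).
* **Production**: P = 0.5 · substrate · Q10^((T−30)/10) · f(Eh) · SI, with
  the texture index SI = 0.325 + 0.0225 · sand%, increasing with sand.
* **Pathways**: production (as CH₄ mass, 16/12 × CH₄-C) enters a dissolved
  store; plant transport removes min(1, 0.55 · aerenchyma · g_norm) of the
  store with 50 % oxidised in transit (aerenchyma factor 1.2 for sedges,
  0.9 for grasses); ebullition exports the excess above 1.5 g CH₄ m⁻²
  unoxidised when standing water is present; diffusion removes 8 % d⁻¹ of
  the remainder, 90 % oxidised when drained and 20 % when flooded. The
  identity production = emission + oxidation + Δstore holds exactly every
  day.

These constants are literature-style defaults chosen so that a permanently
flooded sedge marsh under baseline climate emits of order 10¹–10²
g CH₄ m⁻² yr⁻¹ (the configuration here yields ~15–20), drained soil emits
zero, and the Q10/redox/texture scalings are exactly as stated. They are
placeholders in the sense that the upstream publication defers its
parameter values to prior work; no claim is made that they equal the
original calibration.

## Regional calculus

Area-weighted mean = Σv·a/Σa; regional total = Σ flux·area · 10⁶ m² km⁻² ·
10⁻¹² Tg g⁻¹; the restoration scenario multiplies emissions by 1.25 (a
single end-state factor — the planned restored area is assumed uniformly
distributed over the existing wetland mask, so cells keep their fluxes);
CO₂-equivalent uses a 100-year GWP of 25. Decadal anomaly tables subtract
the 2001–2010 baseline decade mean per variable; subregion percent changes
are area-weighted within each label.

## Statistics

Observed-vs-simulated regression follows the "observed on simulated" axis
convention with a flag to swap; a constant predictor is reported as
degenerate rather than raising. Trends are OLS on year, reported per
decade, with a two-sided t-test p-value and no small-sample correction.
Both are cross-checked in the tests against a hand-rolled normal-equations
oracle at 1e-10.

## Problem sizes and determinism

Default analysis sizes are one site or a 14-cell grid at daily resolution
over 2001–2100 (a century of 14 cells runs in about half a minute); tests
use 2–10-year slices and the acceptance script century-scale single-site
runs. All stochastic stages consume a `numpy` `default_rng` seeded from the
run seed (per-cell streams derive from (seed, cell index)); every run
manifest records the seed and the full parameter set, and re-running a
manifest reproduces outputs bit for bit.

## Known limitations

* No freeze–thaw or snowmelt CH₄ burst processes; winter emissions are
  essentially zero by construction, so annual totals at sites with large
  thaw pulses would be biased low.
* No spatially distributed hydrology: each cell's water table is an
  independent bucket; no lateral routing between cells.
* Production, oxidation and the pathway partition are not separately
  validated — only their net effect is constrained by the property suite.
* The ANPP surface has no nutrient limitation or phenology; it is a
  calibrated interpolator of decadal increments and should not be
  extrapolated far outside the fitted CO₂/temperature range.
* The fixed-area regional increments produced by the synthetic grid are
  smaller than published regional values, as expected: the synthetic
  drivers and placeholder CH₄ constants reproduce statistical structure
  and conservation laws, not the original gridded forcing.
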