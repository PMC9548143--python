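# Methods

This note records the model structure, the parameter choices that
matter, what the synthetic forcing does and does not emulate, and the
numerical decisions a maintainer would otherwise have to reverse-engineer
from the code.

## Model structure

The simulator is a deliberately transparent surrogate for the
process-based terrestrial ecosystem models used in century-scale
attribution studies. Each cell of a regular lat/lon grid carries six
cover cohorts; each cohort has two carbon pools per unit area,
vegetation carbon Cv and soil organic carbon Cs. Monthly fluxes are
multiplicative-limitation products (see README for the equations), and
the defining identities NPP = GPP − RA and NEP = NPP − RH hold exactly
at every step by construction. There is no nitrogen cycle, no phenology
sub-model, no canopy radiative transfer, and a single soil carbon pool —
all deliberate: the aim is a model whose every number can be traced by
hand, not a calibrated reconstruction.

The temperature envelope f_T is the parabolic-ratio form
((T−Tmin)(Tmax−T)) / ((T−Tmin)(Tmax−T) − (T−Topt)²), zero outside
(Tmin, Tmax) and 1 at Topt. The CO₂ scalar is Michaelis–Menten with
half-saturation k_c = 400 ppm, normalised to 1 at 340 ppm so historical
values bracket unity; it is floored at 0 but *not* capped at 1 —
capping would extinguish the fertilisation response exactly when the
observed record passes the reference, which contradicts the phenomenon
being modelled. Light limitation is linear in cloud fraction
(f_L = 1 − 0.5·cloud). The moisture scalar rises linearly from 0 at
WFPS 0% to 1 at 60%, then falls to 0.6 at saturation (waterlogging);
the same ramp co-limits photosynthesis and decomposition, which keeps
one free function instead of two and encodes that water availability
constrains both plant growth and microbial activity.

## Soil physics

Soil temperature at 20 cm follows a first-order monthly relaxation
toward air temperature, T' = T + α(T_air − T) with α = 0.6 month⁻¹.
This is the simplest scheme that attenuates and lags the seasonal cycle
the way a shallow soil layer does; its frequency response has the
closed-form gain α/√(α² + 2(1−α)(1−cos ω)), which the tests verify to
2%. The water balance is a single bucket with texture-derived capacity
150·(1−clay) + 50 mm, Thornthwaite potential evapotranspiration
(temperature and day length only — exactly the inputs the monthly
forcing provides), an actual-ET ramp saturating at half capacity, and
instantaneous runoff of overflow. AET is additionally capped at the
water actually available so the budget closes exactly (to 1e-9 mm in
the tests). There is no snowpack and no freeze lock-up of the bucket, a
known fidelity loss for northeastern winters; WFPS = 100·store/capacity
is the moisture metric throughout.

## Biome parameters

Parameters live in a per-cover-type table (YAML-overridable); defaults
are calibration choices of this package, not field-measured constants.
Monthly maximum GPP c_max ranks the biomes — forest 150, cropland 110,
wetland 90, grassland 70, shrubland 60, bare 5 g C m⁻² month⁻¹ — and
litterfall separates woody from herbaceous turnover (forest
l_f = 0.012 month⁻¹ vs cropland 0.060). Base decomposition k_d is
0.004–0.005 month⁻¹ except wetland (0.0022, waterlogged soils
decompose slowly), and both Q10s default to 2.0. With these values the
default national run settles near 3.5 Pg C yr⁻¹ NPP against
3.4 Pg C yr⁻¹ RH — the right order for China — with soil pools around
100 Pg. The per-biome sink shares differ from published
inventory-calibrated estimates (the idealized all-land domain gives
forest a smaller area share than real China), which is acceptable: the
package's claims are structural and directional, not biome-calibrated.

## Synthetic forcing

The generator produces the drivers' *statistical structure*, not their
history. Temperature climatology is linear in latitude with a seasonal
sinusoid whose amplitude grows northward; precipitation decays
exponentially from a southeast maximum with summer concentration —
together these reproduce the southeast-wet/northwest-dry gradient that
makes the Hu Huanyong line a carbon-flux boundary. The century warming
is a two-segment ramp sized so the 1990s decadal mean exceeds the 1900s
by 1.0 °C with 0.30 °C/decade after 1970; precipitation has no
prescribed trend; cloudiness declines by 0.04 over the century.
Interannual anomalies are AR(1) (lag-1 ρ = 0.3) shared within grid
quadrants plus a local component — white noise would never produce the
spatially coherent wet/dry decades that real precipitation shows. The
1922–1932 drought is injected multiplicatively (precipitation × 0.6
over cells north of 33°N or east of 108°E). CO₂ rises 296 → 369 ppm
along an accelerating exponential-in-time curve anchored exactly at the
endpoints. Cropland follows a national trajectory (7% → 13.5% at 1980
→ 12.5% at 2000) placed preferentially in the southeast, with the
non-crop remainder allocated proportionally to the cell's reference
natural ratios.

What the generator does *not* emulate: observed spatial correlation
scales (quadrant blocks are a coarse stand-in), ENSO-like
teleconnections, monsoon interannual phasing, orographic precipitation,
coastlines (every cell is land), and any particular historical year
other than the 1922–1932 drought. Passing tests therefore demonstrate
that the *pipeline* behaves correctly under realistic forcing
statistics, not that any specific simulated year matches history.

## Protocol and numerics

Equilibrium iterates annual cycles under the 1900–2000 mean monthly
climatology and century-mean CO₂ until |annual NEP| < 0.1 g C m⁻² yr⁻¹
for five consecutive years (cap 3000 years; failures are flagged in run
metadata, never silently accepted). Because Cv's dynamics are linear in
the pool given forcing, the solver jumps the slow Cs pool to the fixed
point of its periodic annual map once Cv has settled, then verifies the
stated criterion by plain iteration — a pure-iteration run reaches the
same state, the accelerator only cuts wall time. Spin-up cycles the
1900–1949 block three times (150 years) with CO₂ and land cover held at
1900. The S3 "baseline climate" is the 20-year 1900–1919 mean monthly
cycle replayed every year; the equilibrium CO₂ reference is the
1900–2000 mean.

Land transitions apply each January before flux computation. Cropland
expansion clears the converted area's vegetation: 50% of that biomass
is released to the atmosphere (spread over the transition year's 12
months) and the rest enters cropland soil along with the converted
soil carbon; abandonment moves cropland area and carbon back to the
natural types with no release, and the abandoned land regrows through
ordinary NPP–litterfall dynamics — which is what makes mid-century
afforestation appear as a lagged sink. Attribution operates on the net
carbon exchange (NEP − conversion release): conversion emissions are
the dominant carbon consequence of expansion and belong to the
land-use factor; with plain NEP the land-use effect would be slightly
positive during expansion, which mis-books the cleared biomass.

Pool updates floor at zero with the deficit deducted from the
responsible flux (RA first, then litter; RH is capped at the available
soil carbon), so conservation holds exactly even under pathological
parameters. Decades are the clean ten-year blocks 1900–1909 …
1990–1999; year 2000 enters century means but no decadal bin. Area
weighting uses the spherical-zone formula with R = 6371 km. Spearman
correlations use average ranks with a t-approximation p-value; partial
correlations rank-transform all variables, regress the x and y ranks on
the control ranks, and correlate the residuals (reducing exactly to
Spearman with no controls). Spatial correlation tables use century
means across cells and temporal ones use annual series within cells —
both are provided because either reading is defensible.

## Problem sizes

The default grid is 2.0° (18 × 31 = 558 cells) rather than the 0.5°
used in full reanalysis-driven studies, chosen so that the complete
protocol — equilibrium, 150-year spin-up and four 101-year transients —
runs in seconds and the whole test suite in about a minute;
`GridSpec` accepts 0.5° when fidelity matters more than turnaround.
Everything is deterministic in (grid, scenario, seed): reruns are
byte-identical, which the tests assert at the level of written CSV
files.

## Known limitations

Single soil carbon pool and no vertical soil discretisation; no
nitrogen limitation or deposition, no fire, no ozone damage; no wood
products pool (conversion carbon is burned or transferred, never
stored); the all-land rectangular domain overstates China's area, so
absolute national totals run on a larger denominator than
inventory-based numbers; and the factorial decomposition leaves a
genuine interaction residual (reported, not hidden) because the flux
model is multiplicative in its drivers.
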