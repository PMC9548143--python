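# temcn

Process-based monthly carbon-balance simulation of China's terrestrial
ecosystems over 1900–2000, with a factorial attribution of the CO₂,
climate and land-use contributions to the national carbon sink.

`temcn` is aimed at carbon-cycle modellers and students of regional
biogeochemistry who want a transparent, fully testable stand-in for the
heavyweight terrestrial ecosystem models (TEM, LPJ, ORCHIDEE …) used in
century-scale attribution studies. Everything runs from a single integer
seed: a synthetic-forcing generator replaces the usual CRU/HYDE/FAO input
archives while reproducing their statistical structure (a ~1 °C century
warming concentrated after 1970, trendless high-variability precipitation
with a severe 1922–1932 drought in northern and eastern China, slightly
declining cloudiness, the 296 → 369 ppm CO₂ rise, cropland expansion to
~1980 followed by contraction).

## The model

Each grid cell carries up to six cover cohorts (forest, shrubland,
grassland, wetland, cropland, bare), each with a vegetation carbon pool
Cv and a soil organic carbon pool Cs (g C m⁻²). Monthly fluxes follow
the bookkeeping identities of process-based models:

    GPP = c_max · f_T(T_air) · f_CO2(C_a) · f_L(cloud) · f_W(WFPS)
    RA  = r_m·Cv·Q10_v^((T−10)/10) + r_g·max(GPP − R_maint, 0)
    NPP = GPP − RA
    RH  = k_d·Cs·Q10_s^((T_soil−10)/10) · f_W(WFPS)
    NEP = NPP − RH

with litterfall l_f·Cv linking Cv to Cs. The identities hold exactly at
every step and carbon is conserved: over any run without land-cover
change, cumulative NEP equals the total pool change to rounding error.
Soil state is a 20 cm soil temperature (first-order relaxation toward air
temperature) and a single-layer bucket (Thornthwaite PET, actual-ET ramp
saturating at half capacity), summarised as water-filled pore space
(WFPS).

Simulations follow the standard three-stage protocol — per-cohort
equilibrium under the century-mean climatology, a 150-year spin-up
cycling the 1900–1949 climate, then the 1900–2000 transient — and the
four-member factorial: S1 all drivers transient, S2 CO₂ fixed at 1900,
S3 climate replaced by the 1900–1919 mean cycle, S4 land use frozen at
1900. Decadal factor effects are differences of national means of the
net carbon exchange (NEP minus land-conversion release): CO₂ = S1−S2,
climate = S1−S3, land use = S1−S4.

## Worked example

```python
import numpy as np
import temcn
from temcn import aggregation_stats as agg, io as tio

res = tio.run_pipeline({"seed": 1}, write_outputs=False)
s = agg.aggregate_region(res["archives"]["S1"], areas=res["areas"])
print(f"century mean NEP : {s.national_nep.mean():6.1f} Tg C/yr")
print(f"NEP 1900s -> 1990s: {agg.decadal_means(s.national_nep)[0]:5.1f}"
      f" -> {agg.decadal_means(s.national_nep)[-1]:5.1f} Tg C/yr")
print(f"source years      : {agg.count_source_years(s.national_nep)}")
att = res["attribution"]
print(f"1990s effects     : CO2 {att.effect_co2[-1]:+6.1f}, "
      f"climate {att.effect_climate[-1]:+6.1f}, "
      f"LUC {att.effect_luc[-1]:+6.1f} Tg C/yr")
```

prints (seed 1, default 2° grid):

```
century mean NEP :   75.7 Tg C/yr
NEP 1900s -> 1990s:  33.2 -> 175.8 Tg C/yr
source years      : 20
1990s effects     : CO2 +192.4, climate  -16.8, LUC   +2.4 Tg C/yr
```

The national sink strengthens across the century, driven overwhelmingly
by CO₂ fertilisation; the climate effect has turned negative by the
1990s (warming-driven soil drying and respiration outpace the
photosynthetic gain), and the land-use effect, negative through the
expansion era, turns positive once cropland contracts after 1980.

A command-line interface wraps the same pipeline:

```sh
tem-cn gen-forcing --resolution 2.0 --seed 42 --out forcing.nc
tem-cn factorial --seed 42 --out-dir runs/
tem-cn summarize --run runs/s1.nc --out summary.csv
```

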