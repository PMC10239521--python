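# climshift

Climate velocity, species range shifts and community trait filtering from
province-level occupancy records.

## The problem

Faunistic catalogues in northern Europe record, per biogeographical province
and census year, which butterfly species had ever been observed there —
cumulative presence/absence at coarse spatial grain over more than a century.
`climshift` turns such records, together with gridded annual temperatures,
species trait tables and land-use histories, into a quantitative account of
how a fauna tracked (or failed to track) a warming climate:

- **Cumulative richness bookkeeping** — provincial species counts, richness
  increases per period (with exclusion masks for unreliably sampled
  province/census combinations), colonisation rates per decade and
  establishment success per species.
- **Range-shift inference** — northward velocity of each species' range
  front (the northernmost occupied province centroid), and per-colonisation
  shortest-route vectors from the nearest previously occupied province,
  averaged into one compass direction per province and period.
- **Climate velocity** — a nearest-thermal-analogue algorithm on an
  equal-area hexagon grid: for each start cell, the `k_temp = 100` cells
  closest in temperature at the next census, re-ranked to the `k_dist = 10`
  geographically nearest; their displacement vectors are averaged into one
  temperature shift vector per cell, then summarised per province as
  northward km/yr and a mean bearing.
- **Circular statistics** — compass-convention circular means and the
  two-sample Watson–Williams test
  `F = K (N−2)(R₁+R₂−R) / (N−(R₁+R₂))`, `K = 1 + 3/(8κ̂)`,
  comparing biological and climatic shift directions province by province.
- **Trait filtering** — z-scored Euclidean trait space (wingspan, European
  range size, STI mean, STI range), PERMANOVA for location differences and
  PERMDISP for dispersion differences between original communities and
  colonisers, per province with Benjamini–Hochberg FDR, plus
  dispersion-versus-latitude trends with a group interaction.
- **Count models** — NB2 (log link) regressions for colonisation and
  establishment counts, with offsets for unequal period lengths and a
  quadratic warming-rate term whose vertex estimates the colonisation
  optimum; and asymptotic (plateau) regression for richness gain versus
  warming.

A first-class synthetic-data module (`climshift.synth`) generates linked
province maps, climates, traits, occupancy histories and land-use tables
with the statistical structure these analyses assume, so the full pipeline
runs and is testable without any proprietary catalogue data.

## Worked example

```python
from climshift import SimulationConfig, simulate_dataset
from climshift.climate import analogue_shift_vectors_all_periods, province_temperature_velocity
from climshift.rangeshift import infer_colonisation_vectors, province_mean_shift_direction
from climshift.circular import paired_direction_test

data = simulate_dataset(SimulationConfig(seed=1))
cell_vecs = analogue_shift_vectors_all_periods(data["hex_timepoint_temps"], data["grid"])
temp_dirs = province_temperature_velocity(cell_vecs, data["grid"], data["map"])
spec_dirs = province_mean_shift_direction(infer_colonisation_vectors(data["cube"], data["map"]))
s = spec_dirs.groupby("province_id")["mean_direction_deg"].first().to_dict()
t = temp_dirs.groupby("province_id")["mean_direction_deg"].first().to_dict()
res, dropped = paired_direction_test(s, t)
print(f"Watson-Williams: F({res.df1},{res.df2}) = {res.F:.2f}, p = {res.p:.4g} "
      f"({dropped} provinces lacked one estimate)")
print(f"species mean direction {res.mean_dir_1:.1f} deg, "
      f"temperature mean direction {res.mean_dir_2:.1f} deg (0 = north, clockwise)")
```

On the default synthetic frame (51 provinces, 131 species, censuses
1901/1936/1987/2009/2019) this prints

```
Watson-Williams: F(1,98) = 4.83, p = 0.03039 (1 provinces lacked one estimate)
species mean direction 7.6 deg, temperature mean direction 354.0 deg (0 = north, clockwise)
```

— species colonisation routes and isotherm movements both point roughly
north but differ significantly in mean bearing; the F statistic's 98
denominator degrees of freedom reflect 50 provinces contributing one
direction estimate of each kind.  The scripts in `examples/` walk through
each capability the same way (simulation, richness metrics, climate
velocity, range shifts, trait filtering, count models) and print what the
numbers mean.

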