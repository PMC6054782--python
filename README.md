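# cranehab

Habitat use, habitat preference and utilization-distribution analysis for
wintering crane surveys, built for the line-transect study design: repeated
surveys of a fixed area, flocks recorded as single GPS points, a shared
communal roost, and a landscape classified into habitat polygons. It targets
spatial ecologists who need the full chain from raw flock tables to
publication-shaped selection and home-range tables — and a synthetic survey
generator with queryable ground truth, so every stage is testable without
field data.

## What it computes

**Flock discretization.** Observed bird groups are merged into discrete
flocks by single-linkage clustering: groups more than 500 m apart (the
default threshold) are separate sample units.

**Use vs. availability.** For each species, habitat use *a* is the
percentage of flocks in a habitat among flocks in available habitats
(farmland, marshland and grassland by default; flocks in other classes are
excluded and counted separately). Availability *b* is the habitat's share of
the total available area. Preference is Ivlev's electivity index

&nbsp;&nbsp;&nbsp;&nbsp;*s* = (*a* − *b*) / (*a* + *b*) ∈ [−1, +1],

−1 never used, 0 proportional use, +1 exclusive use. The package reports *s*
pooled over all flocks, as a per-survey mean ± SD, and pooled per calendar
month (for seasonal shifts in preference).

**Utilization distribution (r-LoCoH).** For every flock location, the local
hull is the convex hull of all locations within a fixed radius *r* (default
500 m). Hulls are sorted smallest-first — small hulls mean locally dense use
— and unioned cumulatively; the *p*% isopleth is the first running union
containing at least *p*% of the locations. The nested 50/70/90% isopleths
delimit the core, ordinary and overall distribution ranges, with areas in
hectares.

**Roost distance.** Euclidean distance (km) from each flock to the communal
roost, summarized per species (n, mean, SD, SE) and compared between species
with a survey-stratified permutation test (species labels shuffled within
each survey, preserving the repeated-survey structure) plus a companion
fixed-effects least-squares fit `distance ~ species + survey`.

All coordinates are planar meters (project lon/lat data, e.g. to the local
UTM zone, before use); flock tables are CSV, habitat maps and roosts are
GeoJSON with planar coordinates declared in a `crs_note` property.

## Worked example

```python
import numpy as np
from cranehab import (paper_mirror_scenario, generate_flocks, generate_landscape,
                      assign_flocks, AvailabilitySet, electivity_table,
                      ud_summary, roost_distances, species_comparison)

scenario = paper_mirror_scenario(seed=1)          # two species, shared roost
habitat_map = generate_landscape(scenario)
flocks = assign_flocks(generate_flocks(scenario), habitat_map)
avail = AvailabilitySet.from_map(habitat_map)

bnc = [f for f in flocks if f.species == "BNC"]   # the roost-bound species
table, _ = electivity_table(bnc, avail)
print(table.round({"use_pct": 1, "avail_pct": 1, "s_pooled": 2,
                   "s_mean": 2, "s_sd": 2}))
```

```
           n_flocks  use_pct  avail_pct  s_pooled  s_mean  s_sd
habitat
farmland        266     92.4       73.5      0.11    0.11  0.06
marshland        21      7.3        1.3      0.70   -0.11  0.94
grassland         1      0.3       25.2     -0.97   -0.98  0.08
```

Farmland is used far above its 73.5% availability (*s* = 0.11 > 0:
preference), grassland is almost never used (*s* = −0.97: strong avoidance),
and marshland's pooled preference hides a seasonal switch — its per-survey
mean is negative with a huge SD because the generator turns marshland on
only in February–March, mirroring a spring social-display shift.

```python
points = {sp: np.array([[f.x, f.y] for f in flocks if f.species == sp])
          for sp in ("BNC", "CC")}
areas, isosets = ud_summary(points, r=500.0)
print(areas)

dist = roost_distances(flocks, scenario.roost)
result = species_comparison(dist, n_perm=10_000, seed=1)
```

```
         isopleth_90_ha  isopleth_70_ha  isopleth_50_ha
species
BNC              623.67          460.03          286.23
CC               942.92          728.26          392.69
```

`result` reports mean roost distances 1.94 km (BNC) vs 4.11 km (CC),
Δ = 2.17 km, stratified permutation p = 0.0001 (10,000 permutations) and a
species F of 85.9 from the blocking-factor least-squares fit: the
roost-bound species holds a smaller range close to the roost, the other
ranges over twice the area, further out.

The same analyses run from the shell:

```bash
cranehab simulate --seed 1 --out-dir sim
cranehab report --flocks sim/flocks.csv --habitat sim/habitat.geojson \
                --roost sim/roost.geojson --out-dir report --seed 1
```

which writes the full bundle: per-species selection tables, monthly
electivity, isopleth-area table and GeoJSONs, roost-distance summary, and a
log of the configuration.

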