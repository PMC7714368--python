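# nrassess

National responsibility and conservation priority assessment from
species range polygons.

## The problem

Conservation resources are finite, and the responsibility for
protecting any one species is shared unevenly across the countries its
range touches. A country that holds a large share of a narrowly
distributed species' range should lead its conservation; a country
where a widespread generalist is merely proportionally present should
not. `nrassess` implements the standard polygon-overlay procedure for
turning species range maps, an environmental zonation, and political
boundaries into per-country **national responsibility** classes and
**conservation priority** scores, at any scale from provinces within a
country to countries within a continent or the globe.

## The method

For each species and each *focal area* (typically a country), two
proportions are computed against an enclosing *reference area*:

* expected distribution proportion
  `DP_exp = area(distribution ∩ reference) / area(reference)`
* observed distribution proportion
  `DP_obs = area(distribution ∩ focal) / area(focal)`

`DP_obs > DP_exp` means the focal area holds more of the range than
its size alone predicts. Independently, the species' within-reference
range is classified against biogeographical units (e.g. Global
Environmental Zones or Terrestrial Ecoregions) as **local**,
**regional**, or **wide**, by either

* the Polygon Count-Approach (PC-A): the number of occupied units
  (defaults: ≤ 1 local, 2–3 regional, ≥ 4 wide), or
* the Polygon Area-Approach (PA-A): the largest per-unit share of the
  range area (one unit → local; ≥ 2/3 in one unit → regional;
  otherwise wide).

A monotone decision table crosses pattern with the DP comparison into
a responsibility class (Basic / Medium / High / Very high; None for
absent species), and a fixed 6 × 4 matrix crosses responsibility with
the species' global IUCN Red List category into a priority class (1–4)
and an integer score (2–25). Data Deficient and Not Evaluated species
receive no priority score.

## Worked example

The built-in generator produces a deterministic toy world — a
100 × 100 km reference square tiled by 4 countries and 5 environmental
zones, with four archetype species (an island endemic, a compact
regional species, a disjunct species, and a widespread one):

```python
from nrassess import AssessmentConfig, assess, make_toy_world

world = make_toy_world(seed=7)
run = assess(world.to_layerset(), dict(world.iucn), AssessmentConfig())
rec = run.record("endemic", "C1")
```

Printing a few records gives:

```
   endemic in C1: pattern=local    DP_exp=0.0125 DP_obs=0.0500 NR=Very high CP=class 1, score 20
widespread in C1: pattern=wide     DP_exp=0.9000 DP_obs=0.9000 NR=Basic     CP=class 4, score 2
endemic in C2: None
```

The endemic (an Endangered species whose whole range lies inside
country C1) covers 1.25 % of the reference but 5 % of C1: C1 is
over-represented, the pattern is local, so C1 carries very high
responsibility and — crossed with the EN threat status — priority
class 1 with 20 points. The widespread Least Concern species covers
every country exactly in proportion to its size (`DP_obs = DP_exp`, a
tie, which is *not* over-representation), so every country carries
only basic responsibility and 2 points. C2, where the endemic does not
occur, has no responsibility for it at all.

## Command line

```sh
nrassess fixtures --seed 7 --out toyworld/        # emit example layers
nrassess assess --species-dir toyworld/ \
    --units toyworld/g-units.geojson \
    --reference toyworld/g-reference.geojson \
    --focal toyworld/f-countries.geojson \
    --metadata toyworld/species_metadata.csv \
    --approach count --out results/
nrassess compare results_count/results.csv results_area/results.csv
```

Input layers are GeoJSON and follow the naming convention `s-<name>`
(species range), `g-<name>` (units / reference area), `f-<name>`
(focal areas). `assess` writes per-species GeoJSON map layers joined
with the assessment attributes, a flat attribute table as CSV and
dBase III (.dbf), and an ASCII summary listing the configuration,
thresholds, and per-species per-country classes.

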