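# desertmap

Census-tract **pharmacy desert** classification: a reusable, tested
implementation of the standard two-criterion definition used in US
pharmacy-access research, together with the comparison tables and
map-ready outputs that national analyses of pharmacy deserts report.

A census tract is a *pharmacy desert* when it is simultaneously

* **low income** — at least 20% of its population lives below the
  Federal Poverty Level, *or* its median household income is below 80%
  of the median income of the nearest metropolitan area; and
* **low access** — more than one-third of its population lives at or
  beyond the access radius from every pharmacy, where the radius depends
  on urbanicity: 1 mile for urban tracts (density ≥ 5 000 persons/sq mi),
  5 miles for suburban, 10 miles for rural (density < 1 000), and
  0.5 miles for tracts where fewer than 100 residents own a car.

The access share is computed by **areal interpolation at the census-block
level**: every block centroid is tested against every pharmacy's radius
(great-circle distance on a sphere of radius 3958.8 miles), and the
tract's uncovered proportion is the population-weighted share of blocks
outside all radii. Tracts with zero population or with no income data
are reported as explicit *unclassified* categories rather than guessed.

The package is aimed at health-services and pharmaco-equity researchers
who want to apply, stress-test or re-parameterize the desert definition
— every numeric constant lives in a single `ThresholdPolicy` object —
without being tied to any particular proprietary pharmacy file.

## What's inside

| module | role |
| --- | --- |
| `desertmap.models` | domain types (`Block`, `Tract`, `Pharmacy`, `MetroArea`) and `ThresholdPolicy` |
| `desertmap.io` | CSV/GeoJSON readers and writers, with accept/reject accounting |
| `desertmap.access` | haversine distances, k-d-tree pharmacy index, per-tract coverage |
| `desertmap.classify` | urbanicity, radius policy, low-income criterion, five-way verdicts |
| `desertmap.synth` | synthetic regions with ground-truth verdicts forced by construction |
| `desertmap.stats` | desert vs non-desert tables: Welch t, chi-square, Benjamini–Hochberg |
| `desertmap.report` | state/national roll-ups, choropleth GeoJSON, pipeline driver + manifest |
| `desertmap.cli` | `desertmap simulate / classify / compare / report` |

Because real national inputs (a licensed pharmacy address file, decennial
census block counts, ACS tract attributes) cannot be redistributed, the
synthetic-geography module generates regions with the same statistical
structure — three density regimes, incomes straddling both low-income
thresholds, configurable pharmacy coverage — in which every tract's
correct verdict is known analytically, so the whole pipeline is testable
end to end.

## Worked example

```python
from desertmap import RegionSpec, generate_region, classify_all, national_rollup

spec = RegionSpec(n_urban=6, n_suburban=6, n_rural=6,
                  planted_desert_fraction=0.25, low_access_only_fraction=0.15,
                  seed=7)
region = generate_region(spec)
cls = classify_all(region.blocks, region.tracts, region.pharmacies,
                   region.metros, spec.policy)
national = national_rollup(cls, region.tracts)
print(f"{national.n_by_verdict['desert']} desert tracts, "
      f"{national.population_in_deserts} of {national.population_classified} "
      f"people ({national.percent_population_in_deserts:.1f}%)")
match = sum(c.verdict == region.truth[c.tract_id] for c in cls)
print(f"verdicts matching planted truth: {match}/{len(cls)}")
```

prints

```
4 desert tracts, 1513 of 6112 people (24.8%)
verdicts matching planted truth: 18/18
```

Of the 18 generated tracts, exactly `round(0.25 × 18) = 4` were
constructed to meet both desert criteria, and the classifier recovers
every planted verdict; 24.8% of the region's classified population lives
in those four tracts.

The same flow from a shell:

```sh
desertmap simulate --seed 7 --out region/
desertmap classify --blocks region/blocks.csv --tracts region/tracts.csv \
    --pharmacies region/pharmacies.csv --metros region/metros.csv \
    --out classified.geojson
```

`classified.geojson` is a choropleth-ready FeatureCollection with one
feature per tract carrying the verdict, urbanicity, uncovered-population
share and both criterion indicators. Passing `--no-income-gate` runs the
sensitivity variant that counts tracts by spatial access alone.

## Calibration notes

The urban (≥ 5 000 persons/sq mi) and rural (< 1 000) density cut-offs
are the package defaults; both are `ThresholdPolicy` fields and should
be calibrated to the boundary values of whatever urbanicity scheme your
study follows. The access-fraction cut (strictly more than one-third)
and the car-ownership override mode are likewise configurable. See
`docs/methods.md` for the full account of the model, its assumptions and
its limitations.
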