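# Methods

This note documents the classification model, every tunable parameter,
what the synthetic generator does and does not emulate, the numerical
choices that affect results, and the known limitations.

## 1. The desert definition

A census tract receives one of five verdicts:

| verdict | condition |
| --- | --- |
| `unclassified_zero_pop` | tract population is zero (checked first) |
| `unclassified_no_income` | both income fields are missing |
| `desert` | low income **and** low access |
| `low_access_only` | low access but not low income |
| `not_desert` | not low access |

Precedence is exactly the order above: zero population always wins, then
missing income, then the access × income cross. If exactly one income
field is missing, the known arm alone decides low-income status and the
result carries an `income_partial` flag.

**Low income.** `prop_below_fpl ≥ fpl_threshold` (inclusive) **or**
`median_income < metro_income_ratio × (median income of the nearest
metropolitan area)` (strict). "Nearest" is by great-circle distance from
the tract reference point (population-weighted mean of block centroids;
plain mean if the tract has no population), with ties broken
deterministically by metro identifier.

**Low access.** The uncovered population share must exceed
`access_fraction` (strictly, by default — a tract with exactly one-third
of its population uncovered is *not* low access). The share is the
block-level areal interpolation

```
prop_outside = Σ pop(b) · 1[ min_p d(b, p) ≥ r ]  /  Σ pop(b)
```

over blocks `b` with positive population; zero-population blocks are
excluded from numerator and denominator. Every pharmacy in the dataset
is a candidate for every block regardless of tract or state lines.
`d` is the great-circle distance and coverage is the strict inequality
`d < r`. A tract with population but only zero-population blocks has no
defined share and is reported with a sentinel (`prop_outside = None`),
which classifies as `unclassified_zero_pop`.

**Radius.** Chosen by urbanicity from population density
(population / land area, persons per square mile): urban when density ≥
`density_urban_min` (inclusive), rural when density < `density_rural_max`
(strict), suburban otherwise. If the tract's `car_owner_count` is known
and below `low_vehicle_count`, the low-vehicle radius applies. In the
default `car_override_mode="replace"` it *replaces* the class radius;
`"min"` instead takes the minimum of the two, for studies that do not
want the override to widen an urban tract's radius.

## 2. Parameters (`ThresholdPolicy`)

| field | default | units | rationale |
| --- | --- | --- | --- |
| `fpl_threshold` | 0.20 | proportion | conventional "poverty area" cut-off |
| `metro_income_ratio` | 0.80 | ratio | relative-income arm of the low-income test |
| `access_fraction` | 1/3 | proportion | share of population that must be uncovered |
| `access_strict` | True | — | cut is "> fraction"; set False for "≥" |
| `radius_urban` | 1 | miles | walkable urban access standard |
| `radius_suburban` | 5 | miles | short drive |
| `radius_rural` | 10 | miles | rural drive-time proxy |
| `radius_low_vehicle` | 0.5 | miles | walking distance without a car |
| `low_vehicle_count` | 100 | residents | car-owner count triggering the override |
| `car_override_mode` | "replace" | — | or "min"; see §1 |
| `density_urban_min` | 5 000 | persons/sq mi | urban floor (inclusive) |
| `density_rural_max` | 1 000 | persons/sq mi | rural ceiling (exclusive) |
| `alpha` | 0.01 | — | significance level after multiplicity adjustment |

All invariants (orderings, ranges) are validated at construction.

## 3. Distance and the spatial index

Distances are haversine great circles on a sphere of radius
3958.8 miles. The ellipsoidal error (< 0.5%) is far below the slack in
the radius policy, so a spherical model is used throughout and *one*
formula defines ground truth for both code paths.

The `PharmacyIndex` embeds pharmacies on the unit sphere in ℝ³ and
queries a `scipy.spatial.cKDTree` with the chord length corresponding to
the arc radius. Chord and arc are monotone bijections of one another, so
`chord(d) < chord(r) ⇔ d < r` holds exactly in exact arithmetic, and
both paths evaluate the same floating-point comparison after the same
trigonometric pipeline — indexed coverage is therefore *identical* to
brute force, not approximately equal, and the tests assert exact array
equality. Consequences: adding a pharmacy can only shrink a tract's
uncovered share, and growing the radius can only shrink it; both
monotonicity properties are tested under randomized perturbations.

## 4. Synthetic geography: scope and guarantees

`generate_region` builds regions where every tract's verdict is forced
*by construction with margins*, so planted truth is analytic, not the
output of a reference run:

* Tracts sit on a 30-mile grid — farther apart than twice the largest
  radius, so no pharmacy can affect a neighboring tract and per-tract
  truth composes.
* Density is drawn inside bands well away from the urbanicity cut-offs:
  urban 6 000–12 000, suburban 1 500–4 000, rural 100–800 persons/sq mi.
* Covered blocks are placed within 0.4 r of the tract's pharmacy;
  uncovered blocks in a ring 1.1 r–1.3 r. CSV round-tripping of
  coordinates cannot flip a block across the radius.
* Partially covered tracts use equal-population blocks with an outside
  fraction k/n chosen at least 0.04 from the one-third cut.
* Low-income tracts are forced with margins on whichever arm is used
  (`prop_below_fpl` at least 0.02 past the threshold; income ratio in
  0.60–0.93 or 1.07–1.50 of the metro median). The two metropolitan
  areas have *equal* median incomes, so which metro is nearest cannot
  change a planted truth; nearest-metro selection itself is covered by
  unit tests.
* Demographic proportions are Beta(μ·60, (1−μ)·60) — the natural model
  for proportions, with no point mass at the boundaries. (An earlier
  clipped-normal draw piled mass at 0 for low-mean traits and made
  small-sample t tests anti-conservative; this was a generator defect,
  fixed.) A nonzero `demographic_effect` shifts desert-tract means by
  ±0.06 per unit effect.
* With `demographic_effect=0` desert and non-desert tracts are drawn
  from identical distributions, giving an exact null for
  false-discovery calibration. Calibration regions are sized to keep at
  least 9 desert tracts per replicate so the t approximation is
  adequate for skewed proportion data — a simulation-design choice, not
  a test tolerance.
* `perturb_add_pharmacy` adds one pharmacy to a named tract (at its
  center or a chosen block centroid) and recomputes planted truth by
  brute-force distances; its seed derives deterministically from the
  tract id via CRC-32, independent of process hash randomization.

**What passing on synthetic regions does not show.** The generator
intentionally avoids the hard parts of real geography: tracts never
share pharmacies, no block sits near a radius boundary, densities never
straddle the urbanicity cut-offs, and coordinates live on a tidy grid.
Success here demonstrates that the *logic* is correct under the stated
definition, not that the definition is robust to borderline real-world
inputs — boundary behavior is instead pinned down directly by unit
tests on hand-built edge cases (exact one-third shares, at-radius
blocks, at-threshold densities and incomes).

## 5. Comparison tables

Desert tracts (or pharmacies in desert tracts) are compared with the
classified non-desert group (`not_desert ∪ low_access_only`);
unclassified tracts are excluded. Continuous characteristics use the
unweighted tract-level mean and SD and a two-sample t test — Welch by
default (pooled-variance optional), with the Welch–Satterthwaite degrees
of freedom. Categorical cross-tabs use Pearson's chi-square without
continuity correction. Two identical constant samples are treated as a
degenerate case with p = 1 rather than 0/0.

P-values are adjusted by Benjamini–Hochberg step-up, implemented
in-package (stable sort; p·m/rank; reverse cumulative minimum; clipped
at 1) and cross-checked against `statsmodels` in tests. The default
family is **joint** across both tables — one experiment, one FDR budget;
`bh_family="per_table"` adjusts each table separately for studies that
report tables as separate families. Pharmacy service rows drop
pharmacies whose flag is unknown rather than imputing; a group with no
informative observations yields p = None with an explanatory note.

The national reference counts in `desertmap.reference_tables` reproduce
the published within-group percentages exactly and give raw chi-square
p-values below 0.001 where the source tabulation prints "< .001". The
source's *adjusted* p-values are not asserted: neither a per-table nor a
joint BH family reproduces them from the printed counts alone, so only
the raw-significance bounds are treated as reproducible.

## 6. Missing data and I/O conventions

Missing values are empty CSV fields, never zeros — a tract with unknown
`car_owner_count` simply never triggers the low-vehicle override.
Readers run in strict mode (raise, listing offending row ids) or
permissive mode (return accepted records plus a reject list with
reasons). GeoJSON uses (longitude, latitude) axis order on the wire;
everything internal is (latitude, longitude). Floats are written with
`repr` so a write → read round trip is value-identical. The pipeline
driver emits a manifest with the package version, the full policy and
SHA-256 checksums of every input.

## 7. Limitations

* Straight-line spherical distance, not travel time or road network;
  the radii are calibrated to that convention and are not interchangeable
  with drive-time thresholds.
* Block *centroids* stand in for population distribution within blocks;
  very large rural blocks can be misclassified near a radius boundary.
* Urbanicity from raw tract density is a simplification of official
  urban-area delineations; recalibrate `density_urban_min` /
  `density_rural_max` to your scheme's boundary values.
* The income criterion needs a metro reference; tracts in datasets with
  no metros fall back to the FPL arm only.
* The t test on tract-level proportions is approximate for very small
  desert groups (< ~10 tracts); consider exact or permutation tests
  there.
* Pharmacy data quality (duplicates, geocoding error, closed stores) is
  out of scope; the loaders validate structure, not ground truth.
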