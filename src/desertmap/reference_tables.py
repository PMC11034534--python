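"""Published national reference tabulations of pharmacy deserts.

Count data from the national 2022 cross-sectional tabulation of US
census tracts and community pharmacies by desert status (tract counts by
verdict, tract urbanicity and pharmacies-per-tract cross-tabs, pharmacy
ownership/urbanicity/service cross-tabs).  These counts serve as fixed
validation inputs: the package's table machinery must reproduce the
published within-group percentages and significance bounds from them.
All values are plain counts; nothing here is computed.
"""

from __future__ import annotations

# ------------------------------------------------------- tract-level counts
N_TRACTS_TOTAL = 84_414
N_TRACTS_DESERT = 4_679
N_TRACTS_NOT_DESERT = 78_723
N_TRACTS_NO_INCOME = 446
N_TRACTS_ZERO_POP = 566
N_TRACTS_ADDITIONAL_LOW_ACCESS = 7_536  # low access but not low income

POPULATION_IN_DESERTS_MILLIONS = 15.82
PCT_POPULATION_IN_DESERTS = 4.7

# tract urbanicity by desert status: {level: (desert, not_desert)}
TRACT_URBANICITY = {
    "urban": (2_692, 19_972),
    "suburban": (204, 30_264),
    "rural": (1_783, 28_487),
}

# pharmacies per tract, binned: {bin: (desert, not_desert)}
PHARMACIES_PER_TRACT = {
    "zero": (4_421, 43_249),
    "one": (34, 14_852),
    "two_or_more": (224, 20_622),
}

# ---------------------------------------------------- pharmacy-level counts
N_PHARMACIES_TOTAL = 60_475
N_PHARMACIES_DESERT = 294
N_PHARMACIES_NOT_DESERT = 60_175

PHARMACY_URBANICITY = {
    "urban": (179, 15_986),
    "suburban": (8, 26_922),
    "rural": (107, 17_206),
    "na_no_population": (0, 61),
}

PHARMACY_OWNERSHIP = {
    "independent": (121, 22_010),
    "chain": (165, 37_371),
    "franchise": (3, 659),
    "government": (5, 135),
}

# service availability: {flag: (desert yes, not-desert yes)}; denominators
# are the full group sizes above
PHARMACY_SERVICES = {
    "immunization": (221, 48_510),
    "ada_accessible": (290, 59_429),
    "multidose_packaging": (73, 12_056),
    "emergency_24h": (82, 17_841),
    "walk_in_clinic": (40, 3_923),
    "compounding": (172, 37_230),
    "dme": (219, 46_742),
}

# published within-group percentages used as spot checks
PUBLISHED_PERCENTS = {
    "desert_tracts_pct": 5.5,           # 4679 / 84414
    "desert_urban_pct": 57.5,           # 2692 / 4679
    "desert_zero_pharmacy_pct": 94.5,   # 4421 / 4679
    "pharmacies_in_deserts_pct": 0.5,   # 294 / 60475
    "desert_independent_pct": 41.2,     # 121 / 294
    "desert_walk_in_clinic_pct": 13.6,  # 40 / 294
    "non_desert_walk_in_clinic_pct": 6.5,
}
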