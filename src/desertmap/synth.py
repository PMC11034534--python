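"""Synthetic regions with ground-truth desert labels known by construction.

Emulates the structure of the real inputs — tracts of three density
regimes composed of blocks with heterogeneous populations, income values
straddling both low-income criteria, and pharmacy placement with
configurable coverage — without any geographic realism.  Tracts sit on a
sparse grid (30-mile spacing) so pharmacy radii never interact across
tracts; distances are controlled in miles and converted to degree
offsets with the local metric, and latitudes stay well below 60° to
bound the planar-approximation distortion.

Every planted quantity carries a margin: block centroids sit at most
0.4 x radius from their covering pharmacy or at least 1.1 x radius from
every pharmacy; forced income values clear their threshold by at least
0.02 (FPL arm) or 5% (relative-income arm); planted outside-population
fractions stay at least 0.04 away from the access cut.  Classification
of a synthetic region is therefore stable under coordinate
round-tripping through files, and the pipeline's verdicts must equal the
``truth`` map exactly.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .models import (
    SERVICE_FLAGS,
    Block,
    MetroArea,
    Ownership,
    Pharmacy,
    ThresholdPolicy,
    Tract,
    Urbanicity,
    ValidationError,
    Verdict,
)

MILES_PER_DEG_LAT = math.pi / 180.0 * 3958.8  # ~69.09

#: density targets strictly inside each class band (persons / sq mi)
_DENSITY_BANDS = {
    Urbanicity.URBAN: (6000.0, 12000.0),
    Urbanicity.SUBURBAN: (1500.0, 4000.0),
    Urbanicity.RURAL: (100.0, 800.0),
}

_DEMOGRAPHICS = (
    "high_school_or_less",
    "no_insurance",
    "public_insurance",
    "limited_english",
    "ambulatory_disability",
    "age_65_plus",
    "nh_white",
    "nh_black",
    "hispanic",
)

_DEMO_BASE = {
    "high_school_or_less": 0.28,
    "no_insurance": 0.10,
    "public_insurance": 0.35,
    "limited_english": 0.03,
    "ambulatory_disability": 0.08,
    "age_65_plus": 0.17,
    "nh_white": 0.61,
    "nh_black": 0.13,
    "hispanic": 0.17,
}

_SERVICE_BASE = {
    "immunization": 0.80,
    "ada_accessible": 0.98,
    "multidose_packaging": 0.20,
    "emergency_24h": 0.30,
    "walk_in_clinic": 0.07,
    "compounding": 0.60,
    "dme": 0.77,
}


class InfeasibleSpec(ValueError):
    """The requested region cannot be generated with the stated margins."""


@dataclass(frozen=True)
class RegionSpec:
    """Parameters of a synthetic region.

    ``planted_desert_fraction`` of the tracts are constructed to satisfy
    both desert criteria with margin; ``low_access_only_fraction`` meet
    only the spatial criterion.  ``demographic_effect`` scales the shift
    of desert-tract demographic means (0 gives a null generator with
    identical desert / non-desert demographic distributions, used for
    false-discovery calibration).  A fixed seed gives byte-identical
    output.
    """

    n_urban: int = 10
    n_suburban: int = 10
    n_rural: int = 10
    blocks_per_tract: tuple[int, int] = (4, 12)
    block_pop_median: float = 40.0
    block_pop_sigma: float = 0.8
    planted_desert_fraction: float = 0.2
    low_access_only_fraction: float = 0.1
    no_income_fraction: float = 0.0
    zero_pop_fraction: float = 0.0
    low_vehicle_fraction: float = 0.0
    missing_car_count_fraction: float = 0.1
    partial_fractions: tuple[float, ...] = (0.25, 0.5, 0.75)
    demographic_effect: float = 1.0
    ownership_independent_skew: float = 0.0
    seed: int = 0
    states: tuple[str, ...] = ("WA", "NM", "TX")
    policy: ThresholdPolicy = field(default_factory=ThresholdPolicy)

    def __post_init__(self) -> None:
        for name in (
            "planted_desert_fraction",
            "low_access_only_fraction",
            "no_income_fraction",
            "zero_pop_fraction",
            "low_vehicle_fraction",
            "missing_car_count_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} = {v} outside [0, 1]")
        if (
            self.planted_desert_fraction
            + self.low_access_only_fraction
            + self.no_income_fraction
            + self.zero_pop_fraction
        ) > 1.0 + 1e-9:
            raise ValidationError("category fractions exceed 1")
        if self.blocks_per_tract[0] < 2 or (
            self.blocks_per_tract[0] > self.blocks_per_tract[1]
        ):
            raise ValidationError("blocks_per_tract must be a range with min >= 2")

    @property
    def n_tracts(self) -> int:
        return self.n_urban + self.n_suburban + self.n_rural


@dataclass
class SyntheticRegion:
    """Generated entities plus the verdict each tract was built to earn."""

    blocks: list[Block]
    tracts: list[Tract]
    pharmacies: list[Pharmacy]
    metros: list[MetroArea]
    truth: dict[str, Verdict]
    planted: dict[str, dict]  # per-tract construction details
    spec: RegionSpec


def _offset(
    center: tuple[float, float], dx_miles: float, dy_miles: float
) -> tuple[float, float]:
    """Shift a (lat, lon) point by mile offsets using the local metric."""
    lat, lon = center
    dlat = dy_miles / MILES_PER_DEG_LAT
    dlon = dx_miles / (MILES_PER_DEG_LAT * math.cos(math.radians(lat)))
    return lat + dlat, lon + dlon


def _ring_point(
    rng: np.random.Generator,
    center: tuple[float, float],
    r_min: float,
    r_max: float,
) -> tuple[float, float]:
    r = rng.uniform(r_min, r_max)
    theta = rng.uniform(0.0, 2.0 * math.pi)
    return _offset(center, r * math.cos(theta), r * math.sin(theta))


def _partial_plan(
    spec: RegionSpec, rng: np.random.Generator, want_low_access: bool
) -> tuple[int, int]:
    """Pick (n_blocks, n_outside) so the outside fraction clears the
    access cut by >= 0.04 on the requested side."""
    cut = spec.policy.access_fraction
    lo, hi = spec.blocks_per_tract
    candidates = []
    for n in range(lo, hi + 1):
        for k in range(1, n):
            f = k / n
            if want_low_access and f >= cut + 0.04:
                candidates.append((n, k))
            elif not want_low_access and f <= cut - 0.04:
                candidates.append((n, k))
    if not candidates:
        raise InfeasibleSpec(
            "no (blocks, outside) split clears the access cut with margin "
            f"given blocks_per_tract={spec.blocks_per_tract}"
        )
    # bias toward the spec's preferred fractions when reachable
    prefer = [
        (n, k)
        for (n, k) in candidates
        if any(abs(k / n - f) < 0.02 for f in spec.partial_fractions)
    ]
    pool = prefer or candidates
    return pool[int(rng.integers(len(pool)))]


def _draw_services(rng: np.random.Generator, skew: float) -> dict[str, Optional[bool]]:
    out: dict[str, Optional[bool]] = {}
    for flag in SERVICE_FLAGS:
        p = _SERVICE_BASE[flag]
        if flag == "walk_in_clinic":
            p = min(0.95, p + skew)
        out[flag] = bool(rng.random() < p)
    return out


def _draw_ownership(rng: np.random.Generator, indep_prob: float) -> Ownership:
    u = rng.random()
    if u < indep_prob:
        return Ownership.INDEPENDENT
    if u < indep_prob + 0.02:
        return Ownership.FRANCHISE
    if u < indep_prob + 0.03:
        return Ownership.GOVERNMENT
    return Ownership.CHAIN


def generate_region(spec: RegionSpec) -> SyntheticRegion:
    """Build a region whose tract verdicts are forced by construction.

    Desert counts are exact: ``round(planted_desert_fraction * n_tracts)``
    tracts receive the desert verdict, assigned to urbanicity classes at
    random.  See the module docstring for the margin rules that make the
    truth analytically certain.
    """
    rng = np.random.default_rng(spec.seed)
    policy = spec.policy
    n = spec.n_tracts
    if n == 0:
        raise ValidationError("region must contain at least one tract")

    classes = (
        [Urbanicity.URBAN] * spec.n_urban
        + [Urbanicity.SUBURBAN] * spec.n_suburban
        + [Urbanicity.RURAL] * spec.n_rural
    )

    n_desert = round(spec.planted_desert_fraction * n)
    n_lao = round(spec.low_access_only_fraction * n)
    n_noinc = round(spec.no_income_fraction * n)
    n_zero = round(spec.zero_pop_fraction * n)
    if n_desert + n_lao + n_noinc + n_zero > n:
        raise InfeasibleSpec("category counts exceed tract count")
    categories = (
        [Verdict.DESERT] * n_desert
        + [Verdict.LOW_ACCESS_ONLY] * n_lao
        + [Verdict.UNCLASSIFIED_NO_INCOME] * n_noinc
        + [Verdict.UNCLASSIFIED_ZERO_POP] * n_zero
        + [Verdict.NOT_DESERT] * (n - n_desert - n_lao - n_noinc - n_zero)
    )
    order = rng.permutation(n)
    categories = [categories[i] for i in order]

    # Metros sit far outside the grid.  Their incomes are equal so the
    # forced income truth cannot depend on which one is nearest (the
    # nearest-metro rule itself is exercised by its own unit tests).
    base_lat, base_lon = 40.0, -100.0
    metros = [
        MetroArea("metro-east", *_offset((base_lat, base_lon), 400.0, 0.0), 75000.0),
        MetroArea("metro-west", *_offset((base_lat, base_lon), -250.0, 0.0), 75000.0),
    ]

    grid = math.ceil(math.sqrt(n))
    spacing = 30.0  # miles; max block offset is 13 mi, max radius 10 mi

    blocks: list[Block] = []
    tracts: list[Tract] = []
    pharmacies: list[Pharmacy] = []
    truth: dict[str, Verdict] = {}
    planted: dict[str, dict] = {}

    for i in range(n):
        urb = classes[i]
        category = categories[i]
        tid = f"T{i:04d}"
        state = spec.states[i % len(spec.states)]
        row, col = divmod(i, grid)
        center = _offset((base_lat, base_lon), col * spacing, row * spacing)

        # --- zero-population tracts -------------------------------------
        if category is Verdict.UNCLASSIFIED_ZERO_POP:
            nb = int(rng.integers(spec.blocks_per_tract[0], spec.blocks_per_tract[1] + 1))
            for j in range(nb):
                lat, lon = _ring_point(rng, center, 0.0, 0.3)
                blocks.append(Block(f"{tid}-B{j:03d}", tid, lat, lon, 0))
            tracts.append(
                Tract(tid, state, land_area=1.0, population=0,
                      median_income=70000.0, prop_below_fpl=0.10,
                      car_owner_count=0, demographics={})
            )
            truth[tid] = category
            planted[tid] = {"urbanicity": None, "coverage": "none"}
            continue

        # --- car-ownership override --------------------------------------
        low_vehicle = rng.random() < spec.low_vehicle_fraction
        if low_vehicle:
            car_count: Optional[int] = int(rng.integers(0, policy.low_vehicle_count))
            radius = policy.radius_low_vehicle
        else:
            if rng.random() < spec.missing_car_count_fraction:
                car_count = None
            else:
                car_count = int(rng.integers(500, 5001))
            radius = policy.radius_for_class(urb)

        # --- coverage plan ------------------------------------------------
        want_low_access = category in (Verdict.DESERT, Verdict.LOW_ACCESS_ONLY) or (
            category is Verdict.UNCLASSIFIED_NO_INCOME and rng.random() < 0.5
        )
        if want_low_access:
            coverage = "none" if rng.random() < 0.5 else "partial"
        else:
            coverage = "full" if rng.random() < 0.7 else "partial"

        if coverage == "partial":
            nb, n_outside = _partial_plan(spec, rng, want_low_access)
            pop_each = max(1, int(round(rng.lognormal(
                math.log(spec.block_pop_median), spec.block_pop_sigma))))
            pops = [pop_each] * nb
        else:
            nb = int(rng.integers(spec.blocks_per_tract[0], spec.blocks_per_tract[1] + 1))
            n_outside = nb if coverage == "none" else 0
            pops = [
                max(1, int(round(x)))
                for x in rng.lognormal(
                    math.log(spec.block_pop_median), spec.block_pop_sigma, nb
                )
            ]

        # --- block placement with margins --------------------------------
        inner = 0.4 * radius
        for j in range(nb):
            if coverage == "full" or (coverage == "partial" and j >= n_outside):
                lat, lon = _ring_point(rng, center, 0.0, inner)
            elif coverage == "partial":
                lat, lon = _ring_point(rng, center, 1.1 * radius, 1.3 * radius)
            else:  # none: anywhere near the center; isolation does the rest
                lat, lon = _ring_point(rng, center, 0.0, inner)
            blocks.append(Block(f"{tid}-B{j:03d}", tid, lat, lon, pops[j]))

        if coverage in ("full", "partial"):
            indep = 0.37 + (
                spec.ownership_independent_skew
                if category is Verdict.DESERT
                else 0.0
            )
            walkin_skew = (
                0.07 if category is Verdict.DESERT and spec.ownership_independent_skew
                else 0.0
            )
            pharmacies.append(
                Pharmacy(
                    f"{tid}-P0", *center,
                    ownership=_draw_ownership(rng, indep),
                    services=_draw_services(rng, walkin_skew),
                )
            )

        population = int(sum(pops))
        prop_outside = sum(pops[:n_outside]) / population

        # --- density band -> land area -----------------------------------
        d_lo, d_hi = _DENSITY_BANDS[urb]
        density = rng.uniform(d_lo + 1.0, d_hi - 1.0)
        land_area = population / density

        # --- income forced with margin -----------------------------------
        nearest = min(
            metros,
            key=lambda m: abs(m.longitude - center[1]),  # same latitude row scale
        )
        low_income = category is Verdict.DESERT or (
            category is Verdict.NOT_DESERT and rng.random() < 0.4
        )
        if category is Verdict.UNCLASSIFIED_NO_INCOME:
            median_income: Optional[float] = None
            prop_fpl: Optional[float] = None
        elif low_income:
            arm = rng.integers(3)  # 0 fpl, 1 income, 2 both
            if arm in (0, 2):
                prop_fpl = float(rng.uniform(policy.fpl_threshold + 0.02,
                                             policy.fpl_threshold + 0.25))
            else:
                prop_fpl = float(rng.uniform(0.02, policy.fpl_threshold - 0.05))
            if arm in (1, 2):
                median_income = float(
                    policy.metro_income_ratio * nearest.median_income
                    * rng.uniform(0.60, 0.93)
                )
            else:
                median_income = float(
                    policy.metro_income_ratio * nearest.median_income
                    * rng.uniform(1.07, 1.50)
                )
        else:
            prop_fpl = float(rng.uniform(0.02, policy.fpl_threshold - 0.05))
            median_income = float(
                policy.metro_income_ratio * nearest.median_income
                * rng.uniform(1.07, 1.50)
            )

        # --- demographics --------------------------------------------------
        # tract-level proportions are beta-distributed (right-skewed near
        # zero, no mass outside [0, 1]); desert tracts get a shifted mean
        is_desert = category is Verdict.DESERT
        demo = {}
        for name in _DEMOGRAPHICS:
            base = _DEMO_BASE[name]
            if is_desert and spec.demographic_effect:
                sign = -1.0 if name in ("nh_white", "age_65_plus") else 1.0
                base = float(np.clip(
                    base + sign * spec.demographic_effect * 0.06, 0.005, 0.995
                ))
            conc = 60.0  # concentration: sd ~ sqrt(m(1-m)/61)
            demo[name] = float(rng.beta(base * conc, (1.0 - base) * conc))

        tracts.append(
            Tract(
                tid, state, land_area=land_area, population=population,
                median_income=median_income, prop_below_fpl=prop_fpl,
                car_owner_count=car_count, demographics=demo,
            )
        )
        truth[tid] = category
        planted[tid] = {
            "urbanicity": urb,
            "coverage": coverage,
            "radius": radius,
            "prop_outside": prop_outside,
            "low_income": None if category is Verdict.UNCLASSIFIED_NO_INCOME
            else low_income,
            "low_vehicle": low_vehicle,
        }

    return SyntheticRegion(
        blocks=blocks, tracts=tracts, pharmacies=pharmacies, metros=metros,
        truth=truth, planted=planted, spec=spec,
    )


def perturb_add_pharmacy(
    region: SyntheticRegion,
    tract_id: str,
    placement: str = "at_tract_center",
    block_index: int = 0,
) -> SyntheticRegion:
    """Return a copy of the region with one pharmacy added in `tract_id`.

    ``placement`` is ``at_block_centroid`` (the tract's ``block_index``-th
    block) or ``at_tract_center`` (population-weighted block mean).  All
    other entities are untouched; the affected tract's access truth is
    recomputed by direct distance checks, independent of the pipeline.
    """
    from .access import great_circle_miles  # brute-force, no index

    tract_blocks = [b for b in region.blocks if b.tract_id == tract_id]
    if not tract_blocks:
        raise ValidationError(f"unknown tract {tract_id!r}")
    if placement == "at_block_centroid":
        loc = tract_blocks[block_index].centroid
    elif placement == "at_tract_center":
        pops = np.array([b.population for b in tract_blocks], dtype=float)
        w = pops / pops.sum() if pops.sum() else np.full(len(pops), 1 / len(pops))
        loc = (
            float(np.dot(w, [b.latitude for b in tract_blocks])),
            float(np.dot(w, [b.longitude for b in tract_blocks])),
        )
    else:
        raise ValidationError(f"unknown placement {placement!r}")

    rng = np.random.default_rng(
        (zlib.crc32(tract_id.encode()) ^ region.spec.seed) % 2**31
    )
    new_pharmacy = Pharmacy(
        f"{tract_id}-PX{len(region.pharmacies)}", loc[0], loc[1],
        ownership=_draw_ownership(rng, 0.37),
        services=_draw_services(rng, 0.0),
    )
    pharmacies = region.pharmacies + [new_pharmacy]

    truth = dict(region.truth)
    planted = {k: dict(v) for k, v in region.planted.items()}
    info = planted[tract_id]
    if truth[tract_id] not in (
        Verdict.UNCLASSIFIED_ZERO_POP, Verdict.UNCLASSIFIED_NO_INCOME
    ):
        radius = info["radius"]
        total = sum(b.population for b in tract_blocks)
        outside = sum(
            b.population
            for b in tract_blocks
            if all(
                great_circle_miles(b.centroid, p.location) >= radius
                for p in pharmacies
            )
        )
        prop = outside / total
        cut = region.spec.policy.access_fraction
        low_access = prop > cut if region.spec.policy.access_strict else prop >= cut
        info["prop_outside"] = prop
        if low_access and info["low_income"]:
            truth[tract_id] = Verdict.DESERT
        elif low_access:
            truth[tract_id] = Verdict.LOW_ACCESS_ONLY
        else:
            truth[tract_id] = Verdict.NOT_DESERT

    return SyntheticRegion(
        blocks=list(region.blocks), tracts=list(region.tracts),
        pharmacies=pharmacies, metros=list(region.metros),
        truth=truth, planted=planted, spec=region.spec,
    )
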