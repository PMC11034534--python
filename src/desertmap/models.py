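"""Domain types for tract-level pharmacy-desert classification.

The atoms of the analysis are census *blocks* (smallest unit carrying a
population count, represented by a centroid point), which nest inside
census *tracts* (the classification unit, carrying income, demographic,
land-area and car-ownership attributes). *Pharmacies* are service points
with an ownership class and a set of service flags; *metro areas* supply
the income benchmark for the relative-income arm of the low-income
criterion.  Every numeric constant of the desert definition lives in
:class:`ThresholdPolicy`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Optional


class ValidationError(ValueError):
    """A record violated a domain-type invariant."""


class SchemaError(ValueError):
    """An input file lacked a required column or had an unusable layout."""


class Ownership(str, enum.Enum):
    INDEPENDENT = "independent"
    CHAIN = "chain"
    FRANCHISE = "franchise"
    GOVERNMENT = "government"


#: canonical service-flag names carried by every Pharmacy record
SERVICE_FLAGS = (
    "immunization",
    "ada_accessible",
    "multidose_packaging",
    "emergency_24h",
    "walk_in_clinic",
    "compounding",
    "dme",
)


class Urbanicity(str, enum.Enum):
    URBAN = "urban"
    SUBURBAN = "suburban"
    RURAL = "rural"


class Verdict(str, enum.Enum):
    DESERT = "desert"
    LOW_ACCESS_ONLY = "low_access_only"
    NOT_DESERT = "not_desert"
    UNCLASSIFIED_NO_INCOME = "unclassified_no_income"
    UNCLASSIFIED_ZERO_POP = "unclassified_zero_pop"


def _check_lat_lon(lat: float, lon: float, ident: str) -> None:
    if not (-90.0 <= lat <= 90.0):
        raise ValidationError(f"{ident}: latitude {lat} outside [-90, 90]")
    if not (-180.0 <= lon <= 180.0):
        raise ValidationError(f"{ident}: longitude {lon} outside [-180, 180]")


@dataclass(frozen=True)
class Block:
    """Census block: centroid point plus population count.

    Coordinates are WGS84 decimal degrees, stored internally as
    (latitude, longitude).
    """

    block_id: str
    tract_id: str
    latitude: float
    longitude: float
    population: int

    def __post_init__(self) -> None:
        _check_lat_lon(self.latitude, self.longitude, f"block {self.block_id}")
        if self.population < 0:
            raise ValidationError(
                f"block {self.block_id}: population {self.population} < 0"
            )

    @property
    def centroid(self) -> tuple[float, float]:
        return (self.latitude, self.longitude)


@dataclass(frozen=True)
class Tract:
    """Census tract: the unit that receives a desert verdict.

    ``median_income``, ``prop_below_fpl`` and ``car_owner_count`` may be
    ``None`` (missing).  Missing income fields are never imputed: a tract
    with both income fields missing becomes *unclassified* downstream.
    ``demographics`` maps characteristic names to proportions in [0, 1].
    """

    tract_id: str
    state: str
    land_area: float  # square miles
    population: int
    median_income: Optional[float] = None
    prop_below_fpl: Optional[float] = None
    car_owner_count: Optional[int] = None
    demographics: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.land_area <= 0:
            raise ValidationError(
                f"tract {self.tract_id}: land_area {self.land_area} must be > 0"
            )
        if self.population < 0:
            raise ValidationError(
                f"tract {self.tract_id}: population {self.population} < 0"
            )
        if self.median_income is not None and self.median_income < 0:
            raise ValidationError(
                f"tract {self.tract_id}: median_income {self.median_income} < 0"
            )
        if self.prop_below_fpl is not None and not (0.0 <= self.prop_below_fpl <= 1.0):
            raise ValidationError(
                f"tract {self.tract_id}: prop_below_fpl {self.prop_below_fpl} "
                "outside [0, 1]"
            )
        if self.car_owner_count is not None and self.car_owner_count < 0:
            raise ValidationError(
                f"tract {self.tract_id}: car_owner_count {self.car_owner_count} < 0"
            )
        for name, value in self.demographics.items():
            if not (0.0 <= value <= 1.0):
                raise ValidationError(
                    f"tract {self.tract_id}: demographic {name!r} = {value} "
                    "outside [0, 1]"
                )

    @property
    def density(self) -> float:
        """Population density in persons per square mile."""
        return self.population / self.land_area


@dataclass(frozen=True)
class Pharmacy:
    """Licensed community pharmacy: location, ownership and service flags.

    Each service flag is True/False/None where None means *unknown*;
    unknowns are excluded from that flag's group contrast, never coerced
    to False.  ``tract_id`` is optional — when absent, the pharmacy is
    assigned to the tract of its nearest block centroid.
    """

    pharmacy_id: str
    latitude: float
    longitude: float
    ownership: Ownership
    services: Mapping[str, Optional[bool]] = field(default_factory=dict)
    tract_id: Optional[str] = None

    def __post_init__(self) -> None:
        _check_lat_lon(self.latitude, self.longitude, f"pharmacy {self.pharmacy_id}")
        if not isinstance(self.ownership, Ownership):
            raise ValidationError(
                f"pharmacy {self.pharmacy_id}: unknown ownership "
                f"{self.ownership!r}"
            )
        # every canonical flag present; absent -> explicit unknown
        svc = dict(self.services)
        for flag in SERVICE_FLAGS:
            svc.setdefault(flag, None)
        unknown = set(svc) - set(SERVICE_FLAGS)
        if unknown:
            raise ValidationError(
                f"pharmacy {self.pharmacy_id}: unrecognized service flags "
                f"{sorted(unknown)}"
            )
        object.__setattr__(self, "services", svc)

    @property
    def location(self) -> tuple[float, float]:
        return (self.latitude, self.longitude)


@dataclass(frozen=True)
class MetroArea:
    """Metropolitan area reference point with its median household income."""

    metro_id: str
    latitude: float
    longitude: float
    median_income: float

    def __post_init__(self) -> None:
        _check_lat_lon(self.latitude, self.longitude, f"metro {self.metro_id}")
        if self.median_income <= 0:
            raise ValidationError(
                f"metro {self.metro_id}: median_income must be > 0"
            )

    @property
    def centroid(self) -> tuple[float, float]:
        return (self.latitude, self.longitude)


@dataclass(frozen=True)
class ThresholdPolicy:
    """All numeric constants of the pharmacy-desert definition.

    Defaults encode the operational definition: a tract is *low income*
    if >= 20% of its population is below the Federal Poverty Level or its
    median household income is under 80% of the nearest metro's; it is
    *low access* if more than one-third of its population lives at or
    beyond the class radius (1 mi urban, 5 mi suburban, 10 mi rural,
    0.5 mi when fewer than 100 residents own a car) from every pharmacy.
    Urbanicity comes from population density: urban at >= 5000 persons
    per square mile, rural below 1000, suburban between.
    """

    fpl_threshold: float = 0.20
    metro_income_ratio: float = 0.80
    access_fraction: float = 1.0 / 3.0
    access_strict: bool = True  # low access iff prop_outside > fraction (strict)
    radius_urban: float = 1.0
    radius_suburban: float = 5.0
    radius_rural: float = 10.0
    radius_low_vehicle: float = 0.5
    low_vehicle_count: int = 100
    density_urban_min: float = 5000.0
    density_rural_max: float = 1000.0
    alpha: float = 0.01
    # "replace": the low-vehicle radius overrides the class radius;
    # "min": use the smaller of the two.  The definition's sentence
    # structure reads as replacement; "min" is offered as an alternative.
    car_override_mode: str = "replace"

    def __post_init__(self) -> None:
        if not (0.0 < self.access_fraction < 1.0):
            raise ValidationError("access_fraction must lie in (0, 1)")
        if not (
            self.radius_low_vehicle
            < self.radius_urban
            < self.radius_suburban
            < self.radius_rural
        ):
            raise ValidationError(
                "radii must satisfy low_vehicle < urban < suburban < rural"
            )
        if not self.density_rural_max < self.density_urban_min:
            raise ValidationError("density_rural_max must be < density_urban_min")
        if self.car_override_mode not in ("replace", "min"):
            raise ValidationError(
                f"car_override_mode must be 'replace' or 'min', "
                f"got {self.car_override_mode!r}"
            )
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError("alpha must lie in (0, 1)")

    def radius_for_class(self, urbanicity: Urbanicity) -> float:
        return {
            Urbanicity.URBAN: self.radius_urban,
            Urbanicity.SUBURBAN: self.radius_suburban,
            Urbanicity.RURAL: self.radius_rural,
        }[urbanicity]
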