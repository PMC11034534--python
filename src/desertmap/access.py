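"""Block-centroid areal interpolation of pharmacy coverage.

The spatial core of the pipeline: for a given access radius, each block
centroid is tested against every pharmacy in the dataset (not only those
inside its own tract — a neighboring tract's pharmacy counts), and the
tract's covered population is the sum over covered blocks.  The tract
meets the low-access criterion when more than ``access_fraction`` of its
population lies outside every pharmacy's radius.

Distances are great-circle (haversine) miles on a sphere of radius
3958.8 miles.  "Covered" means *strictly* less than the radius: a block
sitting exactly at the radius is counted as far from the pharmacy.

For speed, pharmacies are indexed with a k-d tree on unit-sphere 3-D
coordinates; the chord-length metric is a monotone transform of the
great-circle distance, so indexed nearest-neighbour results are exactly
those of a brute-force haversine scan.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .models import Block, Pharmacy, ThresholdPolicy, ValidationError

EARTH_RADIUS_MILES = 3958.8


def great_circle_miles(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Haversine distance in miles between two (lat, lon) points.

    Symmetric, non-negative, and zero iff the points coincide.
    """
    lat1, lon1 = a
    lat2, lon2 = b
    for lat, lon in ((lat1, lon1), (lat2, lon2)):
        if not (-90.0 <= lat <= 90.0) or not (-180.0 <= lon <= 180.0):
            raise ValidationError(f"invalid coordinate ({lat}, {lon})")
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    h = math.sin(dphi / 2.0) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(
        dlam / 2.0
    ) ** 2
    return 2.0 * EARTH_RADIUS_MILES * math.asin(min(1.0, math.sqrt(h)))


def _to_unit_xyz(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    phi = np.radians(lat)
    lam = np.radians(lon)
    return np.column_stack(
        (np.cos(phi) * np.cos(lam), np.cos(phi) * np.sin(lam), np.sin(phi))
    )


def _miles_to_chord(miles: float) -> float:
    """Great-circle miles -> Euclidean chord length on the unit sphere."""
    return 2.0 * math.sin(min(miles / EARTH_RADIUS_MILES, math.pi) / 2.0)


def _chord_to_miles(chord: np.ndarray) -> np.ndarray:
    return 2.0 * EARTH_RADIUS_MILES * np.arcsin(np.clip(chord / 2.0, 0.0, 1.0))


class PharmacyIndex:
    """Nearest-pharmacy queries, exactly equivalent to a brute-force scan.

    Points are embedded on the unit sphere; because chord length is a
    strictly increasing function of arc length, the chord-nearest
    neighbour is the haversine-nearest neighbour.
    """

    def __init__(self, pharmacies: Sequence[Pharmacy]):
        self.pharmacies = list(pharmacies)
        if self.pharmacies:
            lat = np.array([p.latitude for p in self.pharmacies])
            lon = np.array([p.longitude for p in self.pharmacies])
            self._tree: Optional[cKDTree] = cKDTree(_to_unit_xyz(lat, lon))
        else:
            self._tree = None

    def __len__(self) -> int:
        return len(self.pharmacies)

    def nearest_miles(self, lats: np.ndarray, lons: np.ndarray) -> np.ndarray:
        """Great-circle miles from each query point to its nearest pharmacy.

        Returns +inf everywhere when the index is empty.
        """
        lats = np.atleast_1d(np.asarray(lats, dtype=float))
        lons = np.atleast_1d(np.asarray(lons, dtype=float))
        if self._tree is None:
            return np.full(lats.shape, np.inf)
        chord, _ = self._tree.query(_to_unit_xyz(lats, lons))
        return _chord_to_miles(np.atleast_1d(chord))

    def covered(self, lats: np.ndarray, lons: np.ndarray, radius: float) -> np.ndarray:
        """Boolean mask: is each point strictly within `radius` miles of
        any pharmacy?"""
        if radius <= 0:
            raise ValidationError(f"radius must be > 0, got {radius}")
        return self.nearest_miles(lats, lons) < radius


def block_covered(
    block: Block, pharmacies: Iterable[Pharmacy], radius: float
) -> bool:
    """True iff the block centroid lies strictly within `radius` miles of
    at least one pharmacy (brute-force scan; an empty pharmacy set is
    vacuously uncovered, not an error)."""
    if radius <= 0:
        raise ValidationError(f"radius must be > 0, got {radius}")
    return any(
        great_circle_miles(block.centroid, p.location) < radius for p in pharmacies
    )


@dataclass(frozen=True)
class AccessResult:
    """Per-tract outcome of the coverage computation.

    For a zero-population tract access is undefined: ``prop_outside``
    and ``low_access`` are ``None`` and the classifier routes the tract
    to its zero-population verdict.
    """

    tract_id: str
    radius_used: float
    population_total: int
    population_outside: int
    prop_outside: Optional[float]
    low_access: Optional[bool]
    n_pharmacies_in_tract: int = 0

    def __post_init__(self) -> None:
        if self.population_outside > self.population_total:
            raise ValidationError(
                f"tract {self.tract_id}: population_outside exceeds total"
            )


def tract_access(
    tract_id: str,
    blocks: Sequence[Block],
    index: PharmacyIndex,
    radius: float,
    policy: ThresholdPolicy,
    n_pharmacies_in_tract: int = 0,
) -> AccessResult:
    """Population-weighted coverage for one tract.

    Blocks with zero population contribute to neither numerator nor
    denominator.  Low access holds when the uncovered share exceeds
    ``policy.access_fraction`` (strictly, by default).
    """
    for b in blocks:
        if b.tract_id != tract_id:
            raise ValidationError(
                f"block {b.block_id} belongs to tract {b.tract_id}, "
                f"not {tract_id}"
            )
    pops = np.array([b.population for b in blocks], dtype=np.int64)
    total = int(pops.sum())
    if total == 0:
        return AccessResult(
            tract_id=tract_id,
            radius_used=radius,
            population_total=0,
            population_outside=0,
            prop_outside=None,
            low_access=None,
            n_pharmacies_in_tract=n_pharmacies_in_tract,
        )
    lats = np.array([b.latitude for b in blocks])
    lons = np.array([b.longitude for b in blocks])
    covered = index.covered(lats, lons, radius)
    outside = int(pops[~covered].sum())
    prop = outside / total
    if policy.access_strict:
        low = prop > policy.access_fraction
    else:
        low = prop >= policy.access_fraction
    return AccessResult(
        tract_id=tract_id,
        radius_used=radius,
        population_total=total,
        population_outside=outside,
        prop_outside=prop,
        low_access=low,
        n_pharmacies_in_tract=n_pharmacies_in_tract,
    )
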