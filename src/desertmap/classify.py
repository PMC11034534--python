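"""Five-way tract verdicts from urbanicity, income and access indicators.

A tract is a *pharmacy desert* when it meets both the low-income and the
low-access criterion.  A tract meeting only the spatial criterion is
*low-access-only* (the category the sensitivity analysis counts when the
income gate is switched off).  Degenerate tracts fall out first: zero
population -> ``unclassified_zero_pop`` regardless of income; both income
fields missing (with population > 0) -> ``unclassified_no_income``
regardless of access.  These precedence rules make the five verdicts a
partition of the tract set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .access import PharmacyIndex, _to_unit_xyz, great_circle_miles, tract_access
from .models import (
    Block,
    MetroArea,
    Pharmacy,
    ThresholdPolicy,
    Tract,
    Urbanicity,
    ValidationError,
    Verdict,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TractClassification:
    """Verdict for one tract plus the intermediate quantities behind it.

    ``urbanicity`` is None for zero-population tracts; ``low_income`` and
    ``low_access`` are None when unknown.  ``income_partial`` marks tracts
    where only one of the two income inputs was available and the
    criterion was evaluated on that arm alone.
    """

    tract_id: str
    urbanicity: Optional[Urbanicity]
    low_income: Optional[bool]
    low_access: Optional[bool]
    verdict: Verdict
    prop_outside: Optional[float]
    radius_used: Optional[float]
    pharmacies_in_tract: int
    income_partial: bool = False


def classify_urbanicity(tract: Tract, policy: ThresholdPolicy) -> Urbanicity:
    """Urban at density >= 5000 persons/sq mi (inclusive), rural strictly
    below 1000, suburban in between (defaults; both cut-offs are policy
    fields)."""
    if tract.land_area <= 0:
        raise ValidationError(f"tract {tract.tract_id}: land_area must be > 0")
    density = tract.density
    if density >= policy.density_urban_min:
        return Urbanicity.URBAN
    if density < policy.density_rural_max:
        return Urbanicity.RURAL
    return Urbanicity.SUBURBAN


def radius_for(
    tract: Tract, urbanicity: Urbanicity, policy: ThresholdPolicy
) -> float:
    """Access radius: 1/5/10 miles by class; tracts with fewer than 100
    car-owning residents use the 0.5-mile radius instead.  A missing
    car-owner count never triggers the override."""
    class_radius = policy.radius_for_class(urbanicity)
    if (
        tract.car_owner_count is not None
        and tract.car_owner_count < policy.low_vehicle_count
    ):
        if policy.car_override_mode == "min":
            return min(class_radius, policy.radius_low_vehicle)
        return policy.radius_low_vehicle
    return class_radius


def tract_reference_point(
    tract: Tract, blocks: Sequence[Block]
) -> tuple[float, float]:
    """Population-weighted mean of block centroids (plain mean when the
    population is zero); the point used for nearest-metro lookup."""
    if not blocks:
        raise ValidationError(f"tract {tract.tract_id}: no blocks on file")
    lats = np.array([b.latitude for b in blocks], dtype=float)
    lons = np.array([b.longitude for b in blocks], dtype=float)
    pops = np.array([b.population for b in blocks], dtype=float)
    if pops.sum() > 0:
        w = pops / pops.sum()
    else:
        w = np.full(len(blocks), 1.0 / len(blocks))
    return float(np.dot(w, lats)), float(np.dot(w, lons))


def nearest_metro(
    tract: Tract, blocks: Sequence[Block], metros: Sequence[MetroArea]
) -> MetroArea:
    """Metro minimizing great-circle distance from the tract's reference
    point; exact ties break to the lexicographically smaller metro_id."""
    if not metros:
        raise ValidationError("metro list is empty")
    ref = tract_reference_point(tract, blocks)
    return min(
        metros,
        key=lambda m: (great_circle_miles(ref, m.centroid), m.metro_id),
    )


def is_low_income(
    tract: Tract, metro: MetroArea, policy: ThresholdPolicy
) -> tuple[Optional[bool], bool]:
    """Evaluate the two-arm low-income criterion.

    True if prop_below_fpl >= threshold (inclusive) OR median income is
    strictly below ``metro_income_ratio`` x the nearest metro's median.
    Returns ``(result, partial)`` where result is None when both inputs
    are missing and ``partial`` flags evaluation on a single arm: an OR
    with one unknown arm is True if the known arm is True, and False
    (not unknown) if the known arm is False.
    """
    fpl_arm: Optional[bool] = None
    income_arm: Optional[bool] = None
    if tract.prop_below_fpl is not None:
        fpl_arm = tract.prop_below_fpl >= policy.fpl_threshold
    if tract.median_income is not None:
        income_arm = (
            tract.median_income < policy.metro_income_ratio * metro.median_income
        )
    if fpl_arm is None and income_arm is None:
        return None, False
    partial = fpl_arm is None or income_arm is None
    return bool(fpl_arm) or bool(income_arm), partial


def assign_pharmacy_tracts(
    pharmacies: Sequence[Pharmacy], blocks: Sequence[Block]
) -> dict[str, Optional[str]]:
    """Map pharmacy_id -> containing tract_id.

    An explicit ``tract_id`` on the record wins; otherwise the pharmacy
    inherits the tract of its nearest block centroid.  With no blocks at
    all the assignment is None (an explicitly reported 'unassigned'
    bucket downstream).
    """
    out: dict[str, Optional[str]] = {}
    todo = [p for p in pharmacies if p.tract_id is None]
    for p in pharmacies:
        if p.tract_id is not None:
            out[p.pharmacy_id] = p.tract_id
    if todo:
        if not blocks:
            for p in todo:
                out[p.pharmacy_id] = None
        else:
            tree = cKDTree(
                _to_unit_xyz(
                    np.array([b.latitude for b in blocks]),
                    np.array([b.longitude for b in blocks]),
                )
            )
            lats = np.array([p.latitude for p in todo])
            lons = np.array([p.longitude for p in todo])
            _, idx = tree.query(_to_unit_xyz(lats, lons))
            for p, i in zip(todo, np.atleast_1d(idx)):
                out[p.pharmacy_id] = blocks[int(i)].tract_id
    return out


def classify_all(
    blocks: Sequence[Block],
    tracts: Sequence[Tract],
    pharmacies: Sequence[Pharmacy],
    metros: Sequence[MetroArea],
    policy: ThresholdPolicy,
    income_gate: bool = True,
) -> list[TractClassification]:
    """Classify every tract; exactly one verdict per tract.

    With ``income_gate=False`` (the sensitivity mode) the income
    criterion is bypassed and any classifiable low-access tract gets the
    desert verdict; unclassified rules are unchanged, so the gated
    deserts plus low-access-only tracts coincide with the gate-off
    low-access set.
    """
    blocks_by_tract: dict[str, list[Block]] = {t.tract_id: [] for t in tracts}
    for b in blocks:
        if b.tract_id in blocks_by_tract:
            blocks_by_tract[b.tract_id].append(b)
    assignment = assign_pharmacy_tracts(pharmacies, blocks)
    n_pharm: dict[str, int] = {}
    for tid in assignment.values():
        if tid is not None:
            n_pharm[tid] = n_pharm.get(tid, 0) + 1
    index = PharmacyIndex(pharmacies)

    results: list[TractClassification] = []
    for tract in tracts:
        tid = tract.tract_id
        tract_blocks = blocks_by_tract[tid]
        n_in_tract = n_pharm.get(tid, 0)
        if tract.population == 0:
            results.append(
                TractClassification(
                    tract_id=tid,
                    urbanicity=None,
                    low_income=None,
                    low_access=None,
                    verdict=Verdict.UNCLASSIFIED_ZERO_POP,
                    prop_outside=None,
                    radius_used=None,
                    pharmacies_in_tract=n_in_tract,
                )
            )
            continue

        urb = classify_urbanicity(tract, policy)
        radius = radius_for(tract, urb, policy)
        acc = tract_access(
            tid, tract_blocks, index, radius, policy, n_pharmacies_in_tract=n_in_tract
        )
        metro = nearest_metro(tract, tract_blocks, metros)
        low_inc, partial = is_low_income(tract, metro, policy)

        if low_inc is None and income_gate:
            verdict = Verdict.UNCLASSIFIED_NO_INCOME
        elif low_inc is None and not income_gate:
            # sensitivity mode keeps the same unclassified partition
            verdict = Verdict.UNCLASSIFIED_NO_INCOME
        elif not income_gate:
            verdict = Verdict.DESERT if acc.low_access else Verdict.NOT_DESERT
        elif acc.low_access and low_inc:
            verdict = Verdict.DESERT
        elif acc.low_access and not low_inc:
            verdict = Verdict.LOW_ACCESS_ONLY
        else:
            verdict = Verdict.NOT_DESERT

        logger.debug(
            "tract %s: urbanicity=%s radius=%.2f prop_outside=%s "
            "low_income=%s low_access=%s -> %s",
            tid, urb.value, radius, acc.prop_outside, low_inc,
            acc.low_access, verdict.value,
        )
        results.append(
            TractClassification(
                tract_id=tid,
                urbanicity=urb,
                low_income=low_inc,
                low_access=acc.low_access,
                verdict=verdict,
                prop_outside=acc.prop_outside,
                radius_used=radius,
                pharmacies_in_tract=n_in_tract,
                income_partial=partial,
            )
        )
    return results
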