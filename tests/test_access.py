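"""Great-circle distances, strict-boundary coverage, population-weighted
tract access, and exact equivalence of the spatial index with brute force."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from desertmap import (
    Block,
    Ownership,
    Pharmacy,
    PharmacyIndex,
    ThresholdPolicy,
    ValidationError,
    block_covered,
    great_circle_miles,
    tract_access,
)
from desertmap.access import EARTH_RADIUS_MILES

coords = st.tuples(
    st.floats(min_value=-89.0, max_value=89.0),
    st.floats(min_value=-179.0, max_value=179.0),
)


def _pharmacy(lat, lon, pid="p"):
    return Pharmacy(pid, lat, lon, Ownership.CHAIN)


class TestGreatCircle:
    def test_identity_is_zero(self):
        assert great_circle_miles((47.6, -122.3), (47.6, -122.3)) == 0.0

    def test_one_degree_of_latitude(self):
        # closed form: arc length of 1 degree on the stated sphere
        expected = math.radians(1.0) * EARTH_RADIUS_MILES
        assert great_circle_miles((0, 0), (1, 0)) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(69.09, abs=0.01)

    @settings(derandomize=True, max_examples=100)
    @given(a=coords, b=coords)
    def test_symmetric_and_nonnegative(self, a, b):
        d = great_circle_miles(a, b)
        assert d >= 0.0
        assert d == pytest.approx(great_circle_miles(b, a), abs=1e-9)

    def test_invalid_coordinate_rejected(self):
        with pytest.raises(ValidationError):
            great_circle_miles((100, 0), (0, 0))


class TestBlockCovered:
    def test_block_at_pharmacy_location_is_covered(self):
        b = Block("b", "t", 40.0, -100.0, 10)
        assert block_covered(b, [_pharmacy(40.0, -100.0)], radius=1.0)

    def test_block_at_exactly_radius_is_not_covered(self):
        """The boundary is strict: a block living exactly one radius away
        counts as far from the pharmacy."""
        b = Block("b", "t", 0.0, 0.0, 10)
        one_mile_lat = 1.0 / (math.radians(1.0) * EARTH_RADIUS_MILES)
        p = _pharmacy(one_mile_lat, 0.0)
        d = great_circle_miles(b.centroid, p.location)
        assert d == pytest.approx(1.0, rel=1e-9)
        assert not block_covered(b, [p], radius=d)
        assert block_covered(b, [p], radius=d * 1.0001)

    def test_nearest_of_three_pharmacies_decides(self):
        b = Block("b", "t", 40.0, -100.0, 10)
        mile_lat = 1.0 / (math.radians(1.0) * EARTH_RADIUS_MILES)
        pharms = [
            _pharmacy(40.0 + 0.9 * mile_lat, -100.0, "near"),
            _pharmacy(40.0 + 5 * mile_lat, -100.0, "mid"),
            _pharmacy(41.0, -100.0, "far"),
        ]
        # brute-force oracle: min distance 0.9 mi < 1.0 radius
        dmin = min(great_circle_miles(b.centroid, p.location) for p in pharms)
        assert dmin == pytest.approx(0.9, rel=1e-6)
        assert block_covered(b, pharms, radius=1.0)

    def test_empty_pharmacy_set_is_uncovered_not_error(self):
        b = Block("b", "t", 40.0, -100.0, 10)
        assert not block_covered(b, [], radius=1.0)


class TestTractAccess:
    def _blocks(self, pops, lat0=40.0, spread=0.02):
        return [
            Block(f"b{i}", "t", lat0 + i * spread, -100.0, p)
            for i, p in enumerate(pops)
        ]

    def test_two_of_three_covered_is_exactly_one_third_outside(self, policy):
        """prop_outside = 1/3 does NOT trip the 'more than one-third' cut."""
        blocks = self._blocks([10, 10, 10])
        index = PharmacyIndex(
            [_pharmacy(blocks[0].latitude, -100.0), _pharmacy(blocks[1].latitude, -100.0)]
        )
        res = tract_access("t", blocks, index, radius=1.0, policy=policy)
        assert res.prop_outside == pytest.approx(1 / 3)
        assert res.low_access is False

    def test_one_of_three_covered_is_low_access(self, policy):
        blocks = self._blocks([10, 10, 10])
        index = PharmacyIndex([_pharmacy(blocks[0].latitude, -100.0)])
        res = tract_access("t", blocks, index, radius=1.0, policy=policy)
        assert res.prop_outside == pytest.approx(2 / 3)
        assert res.low_access is True

    def test_no_pharmacies_anywhere(self, policy):
        blocks = self._blocks([5, 5])
        res = tract_access("t", blocks, PharmacyIndex([]), radius=1.0, policy=policy)
        assert res.prop_outside == 1.0 and res.low_access is True

    def test_zero_population_returns_sentinel(self, policy):
        blocks = self._blocks([0, 0])
        res = tract_access("t", blocks, PharmacyIndex([]), radius=1.0, policy=policy)
        assert res.population_total == 0
        assert res.prop_outside is None and res.low_access is None

    def test_zero_population_blocks_do_not_count(self, policy):
        """A populated covered block plus an empty uncovered block is full
        coverage: empty blocks enter neither numerator nor denominator."""
        blocks = [
            Block("b0", "t", 40.0, -100.0, 100),
            Block("b1", "t", 41.0, -100.0, 0),
        ]
        index = PharmacyIndex([_pharmacy(40.0, -100.0)])
        res = tract_access("t", blocks, index, radius=1.0, policy=policy)
        assert res.prop_outside == 0.0 and res.low_access is False

    def test_conservation(self, policy, small_region):
        index = PharmacyIndex(small_region.pharmacies)
        by_tract = {}
        for b in small_region.blocks:
            by_tract.setdefault(b.tract_id, []).append(b)
        for tid, blocks in by_tract.items():
            res = tract_access(tid, blocks, index, radius=5.0, policy=policy)
            total = sum(b.population for b in blocks)
            assert res.population_total == total
            assert 0 <= res.population_outside <= total

    def test_foreign_block_rejected(self, policy):
        blocks = [Block("b0", "other", 40.0, -100.0, 5)]
        with pytest.raises(ValidationError, match="other"):
            tract_access("t", blocks, PharmacyIndex([]), 1.0, policy)


class TestPharmacyIndex:
    def test_index_matches_brute_force_on_random_points(self):
        rng = np.random.default_rng(17)
        pharms = [
            _pharmacy(lat, lon, f"p{i}")
            for i, (lat, lon) in enumerate(
                zip(rng.uniform(30, 50, 50), rng.uniform(-120, -80, 50))
            )
        ]
        index = PharmacyIndex(pharms)
        lats = rng.uniform(30, 50, 1000)
        lons = rng.uniform(-120, -80, 1000)
        for radius in (1.0, 5.0, 10.0, 50.0):
            got = index.covered(lats, lons, radius)
            expected = np.array(
                [
                    min(
                        great_circle_miles((la, lo), p.location) for p in pharms
                    ) < radius
                    for la, lo in zip(lats, lons)
                ]
            )
            assert np.array_equal(got, expected)

    def test_empty_index_covers_nothing(self):
        index = PharmacyIndex([])
        assert not index.covered(np.array([40.0]), np.array([-100.0]), 10.0).any()

    def test_single_pharmacy_equals_direct_distance_test(self):
        p = _pharmacy(40.0, -100.0)
        index = PharmacyIndex([p])
        lats = np.array([40.0, 40.5, 42.0])
        lons = np.array([-100.0, -100.0, -100.0])
        d = index.nearest_miles(lats, lons)
        for i in range(3):
            assert d[i] == pytest.approx(
                great_circle_miles((lats[i], lons[i]), p.location), abs=1e-9
            )


class TestMonotonicity:
    def test_adding_pharmacy_never_increases_prop_outside(self, policy):
        rng = np.random.default_rng(5)
        blocks = [
            Block(f"b{i}", "t", 40 + rng.uniform(-0.2, 0.2),
                  -100 + rng.uniform(-0.2, 0.2), int(rng.integers(1, 50)))
            for i in range(30)
        ]
        pharms = []
        last = None
        for i in range(20):
            pharms.append(
                _pharmacy(40 + rng.uniform(-0.3, 0.3), -100 + rng.uniform(-0.3, 0.3),
                          f"p{i}")
            )
            res = tract_access("t", blocks, PharmacyIndex(pharms), 5.0, policy)
            if last is not None:
                assert res.prop_outside <= last
            last = res.prop_outside

    def test_prop_outside_nonincreasing_in_radius(self, policy):
        rng = np.random.default_rng(6)
        blocks = [
            Block(f"b{i}", "t", 40 + rng.uniform(-0.2, 0.2),
                  -100 + rng.uniform(-0.2, 0.2), int(rng.integers(1, 50)))
            for i in range(30)
        ]
        pharms = [
            _pharmacy(40 + rng.uniform(-0.3, 0.3), -100 + rng.uniform(-0.3, 0.3),
                      f"p{i}")
            for i in range(5)
        ]
        index = PharmacyIndex(pharms)
        props = [
            tract_access("t", blocks, index, r, policy).prop_outside
            for r in (0.5, 1.0, 2.0, 5.0, 10.0, 20.0, 50.0)
        ]
        assert all(a >= b for a, b in zip(props, props[1:]))
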