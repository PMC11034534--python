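"""t test and chi-square against hand-coded textbook formulas, the BH
step-up procedure against a hand application and an independent library,
and the desert vs non-desert table builders."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from desertmap import (
    RegionSpec,
    bh_adjust,
    build_pharmacy_table,
    build_population_table,
    chi_square_independence,
    classify_all,
    compare_all,
    generate_region,
    two_sample_t,
)
from desertmap.models import ValidationError
from desertmap.stats import ContingencyTable, pharmacies_per_tract_bin


# ------------------------------------------------- independent oracles

def welch_oracle(x, y):
    """Textbook Welch t: statistic, Welch–Satterthwaite df, two-sided p
    from the t distribution (scipy used only for the CDF)."""
    from scipy.stats import t as tdist

    x, y = np.asarray(x, float), np.asarray(y, float)
    vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
    stat = (x.mean() - y.mean()) / math.sqrt(vx + vy)
    df = (vx + vy) ** 2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))
    p = 2 * tdist.sf(abs(stat), df)
    return stat, df, p


def pearson_oracle(table):
    """Textbook Pearson chi-square from expected counts."""
    from scipy.stats import chi2

    obs = np.asarray(table, float)
    expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
    stat = ((obs - expected) ** 2 / expected).sum()
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return stat, df, chi2.sf(stat, df)


class TestTwoSampleT:
    def test_identical_samples_null(self):
        stat, df, p = two_sample_t([1, 2, 3, 4], [1, 2, 3, 4])
        assert stat == 0.0 and p == 1.0

    def test_shifted_sample_is_significant(self):
        stat, df, p = two_sample_t([1, 2, 3], [11, 12, 13])
        o_stat, o_df, o_p = welch_oracle([1, 2, 3], [11, 12, 13])
        assert stat == pytest.approx(o_stat, rel=1e-12)
        assert df == pytest.approx(o_df, rel=1e-12)
        assert p == pytest.approx(o_p, rel=1e-12)
        assert p < 0.01

    def test_pooled_equals_welch_for_balanced_equal_variance(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [2.5, 3.5, 4.5, 5.5]  # same spread, same n
        sw, dfw, pw = two_sample_t(x, y, variant="welch")
        sp, dfp, pp = two_sample_t(x, y, variant="pooled")
        assert sw == pytest.approx(sp, rel=1e-12)
        assert dfw == pytest.approx(dfp, rel=1e-12)
        assert pw == pytest.approx(pp, rel=1e-12)

    def test_matches_oracle_on_random_samples(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            x = rng.normal(0, 1 + rng.random(), rng.integers(3, 40))
            y = rng.normal(rng.normal(), 1 + rng.random(), rng.integers(3, 40))
            stat, df, p = two_sample_t(x, y)
            o_stat, o_df, o_p = welch_oracle(x, y)
            assert stat == pytest.approx(o_stat, rel=1e-10)
            assert df == pytest.approx(o_df, rel=1e-10)
            assert p == pytest.approx(o_p, rel=1e-10)

    def test_undersized_group_rejected(self):
        with pytest.raises(ValidationError):
            two_sample_t([1.0], [1.0, 2.0])


class TestChiSquare:
    def test_perfect_independence(self):
        stat, df, p = chi_square_independence([[10, 10], [10, 10]])
        assert stat == 0.0 and p == 1.0

    def test_ownership_reference_table_is_significant(self):
        """The national ownership cross-tab (independent/chain/franchise/
        government by desert status) is significant far below .001."""
        from desertmap.reference_tables import PHARMACY_OWNERSHIP

        table = [list(v) for v in PHARMACY_OWNERSHIP.values()]
        stat, df, p = chi_square_independence(table)
        assert df == 3
        assert p < 0.001

    def test_2x2_equals_squared_two_proportion_z(self):
        a, b, c, d = 40, 254, 3923, 56252
        stat, _, _ = chi_square_independence([[a, b], [c, d]])
        n1, n2 = a + b, c + d
        p1, p2 = a / n1, c / n2
        pooled = (a + c) / (n1 + n2)
        z = (p1 - p2) / math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
        assert stat == pytest.approx(z**2, rel=1e-10)

    def test_matches_oracle_on_random_tables(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            shape = (int(rng.integers(2, 5)), int(rng.integers(2, 5)))
            table = rng.integers(1, 200, shape)
            stat, df, p = chi_square_independence(table.tolist())
            o_stat, o_df, o_p = pearson_oracle(table)
            assert stat == pytest.approx(o_stat, rel=1e-10)
            assert df == o_df
            assert p == pytest.approx(o_p, rel=1e-10)

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValidationError):
            chi_square_independence([[0, 0], [5, 10]])
        with pytest.raises(ValidationError):
            ContingencyTable(("a",), ("x", "y"), ((1, 2),))


class TestBHAdjust:
    def test_hand_application_of_step_up(self):
        # ranks 1..3: 0.01*3/1=0.03, 0.02*3/2=0.03, 0.03*3/3=0.03
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.4]) == [0.4]

    def test_all_ones(self):
        assert bh_adjust([1.0, 1.0, 1.0]) == [1.0, 1.0, 1.0]

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(3)
        p = rng.random(50)
        adj = np.array(bh_adjust(p))
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.2])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=20),
           st.randoms(use_true_random=False))
    def test_permutation_equivariance(self, p, rand):
        idx = list(range(len(p)))
        rand.shuffle(idx)
        base = bh_adjust(p)
        shuffled = bh_adjust([p[i] for i in idx])
        for pos, i in enumerate(idx):
            assert shuffled[pos] == pytest.approx(base[i], abs=1e-12)

    def test_matches_independent_library(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(8)
        p = rng.random(40)
        _, expected, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(bh_adjust(p), expected, rtol=1e-12)


@pytest.fixture(scope="module")
def region_and_classes():
    spec = RegionSpec(
        n_urban=40, n_suburban=40, n_rural=40,
        planted_desert_fraction=0.3, low_access_only_fraction=0.1,
        demographic_effect=2.0, ownership_independent_skew=0.3, seed=5,
    )
    region = generate_region(spec)
    cls = classify_all(region.blocks, region.tracts, region.pharmacies,
                       region.metros, spec.policy)
    return region, cls


class TestTables:

    def test_generated_income_effect_is_detected(self, region_and_classes, policy):
        """Deserts are generated poorer; the table must show the higher
        desert-group FPL mean and flag it significant after BH."""
        region, cls = region_and_classes
        rows = build_population_table(
            region.tracts, cls, ["prop_below_fpl"], policy,
        )
        row = next(r for r in rows if r.characteristic == "prop_below_fpl")
        assert row.group_a_summary["mean"] > row.group_b_summary["mean"]
        assert row.p_adjusted < policy.alpha and row.significant

    def test_percentages_sum_to_100_within_group(self, region_and_classes, policy):
        region, cls = region_and_classes
        rows = build_population_table(region.tracts, cls, [], policy)
        for row in rows:
            for summary in (row.group_a_summary, row.group_b_summary):
                total = sum(v["percent"] for v in summary.values()
                            if v["percent"] is not None)
                assert total == pytest.approx(100.0)

    def test_pharmacies_per_tract_binning(self):
        assert pharmacies_per_tract_bin(0) == "zero"
        assert pharmacies_per_tract_bin(1) == "one"
        assert pharmacies_per_tract_bin(2) == "two_or_more"
        assert pharmacies_per_tract_bin(7) == "two_or_more"

    def test_reference_percent_reproduction(self):
        """121 independent pharmacies of a 294-pharmacy desert group is
        41.2% — the published within-group percent."""
        assert round(100 * 121 / 294, 1) == 41.2

    def test_ownership_skew_direction_recovered(self, region_and_classes, policy):
        region, cls = region_and_classes
        rows, unassigned = build_pharmacy_table(
            region.pharmacies, cls, policy, blocks=region.blocks,
        )
        assert unassigned == 0
        row = next(r for r in rows if r.characteristic == "ownership")
        indep_desert = row.group_a_summary["independent"]["percent"]
        indep_other = row.group_b_summary["independent"]["percent"]
        assert indep_desert > indep_other

    def test_degenerate_desert_group_skips_tests(self, policy):
        spec = RegionSpec(n_urban=8, n_suburban=8, n_rural=8,
                          planted_desert_fraction=0.0, seed=13)
        region = generate_region(spec)
        cls = classify_all(region.blocks, region.tracts, region.pharmacies,
                           region.metros, spec.policy)
        rows, _ = build_pharmacy_table(region.pharmacies, cls, policy,
                                       blocks=region.blocks)
        assert all(r.p_raw is None and r.note for r in rows)

    def test_unclassified_tracts_excluded_from_groups(self, policy):
        spec = RegionSpec(n_urban=8, n_suburban=8, n_rural=8,
                          planted_desert_fraction=0.25,
                          no_income_fraction=0.1, zero_pop_fraction=0.1, seed=21)
        region = generate_region(spec)
        cls = classify_all(region.blocks, region.tracts, region.pharmacies,
                           region.metros, spec.policy)
        rows = build_population_table(region.tracts, cls, [], policy)
        urb = next(r for r in rows if r.characteristic == "urbanicity")
        n_a = sum(v["count"] for v in urb.group_a_summary.values())
        n_b = sum(v["count"] for v in urb.group_b_summary.values())
        n_classified = sum(
            1 for c in cls if c.verdict.value in
            ("desert", "not_desert", "low_access_only")
        )
        assert n_a + n_b == n_classified < len(cls)

    def test_joint_family_adjusts_across_both_tables(self, region_and_classes, policy):
        region, cls = region_and_classes
        pop_rows, ph_rows, _ = compare_all(
            region.tracts, cls, region.pharmacies, ["prop_below_fpl"], policy,
            blocks=region.blocks, bh_family="joint",
        )
        raw = [r.p_raw for r in pop_rows + ph_rows if r.p_raw is not None]
        adjusted = [r.p_adjusted for r in pop_rows + ph_rows if r.p_raw is not None]
        assert np.allclose(adjusted, bh_adjust(raw))

    def test_absent_characteristic_errors(self, region_and_classes, policy):
        region, cls = region_and_classes
        with pytest.raises(ValidationError, match="not_a_column"):
            build_population_table(region.tracts, cls, ["not_a_column"], policy)
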