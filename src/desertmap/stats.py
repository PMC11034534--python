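"""Group contrasts between desert and non-desert units.

Builds the two standard comparison tables: tract-level population
characteristics (continuous rows via a two-sample t test, categorical
rows via a chi-square test of independence) and pharmacy characteristics
(ownership, urbanicity of location, service flags — all categorical).
All p-values in a family are corrected with the Benjamini–Hochberg
step-up procedure; the default family spans both tables jointly, with
per-table families available.

Conventions: the t test defaults to the Welch (unequal-variance)
variant; the chi-square statistic is Pearson's without continuity
correction; continuous summaries are unweighted tract-level mean (SD);
the comparison group is every classified non-desert tract — the two
unclassified verdicts are excluded from both columns.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .classify import TractClassification, assign_pharmacy_tracts
from .models import (
    SERVICE_FLAGS,
    Ownership,
    Pharmacy,
    ThresholdPolicy,
    Tract,
    Urbanicity,
    ValidationError,
    Verdict,
)


@dataclass(frozen=True)
class ComparisonRow:
    """One characteristic's desert vs non-desert contrast."""

    characteristic: str
    test: str  # "t" or "chi_square"
    group_a_summary: dict  # desert column
    group_b_summary: dict  # non-desert column
    statistic: Optional[float]
    df: Optional[float]
    p_raw: Optional[float]
    p_adjusted: Optional[float] = None
    significant: Optional[bool] = None
    note: str = ""  # reason when a test was skipped


@dataclass(frozen=True)
class ContingencyTable:
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValidationError("contingency table must be at least 2x2")
        if (arr < 0).any():
            raise ValidationError("contingency table counts must be >= 0")


def two_sample_t(
    x: Sequence[float], y: Sequence[float], variant: str = "welch"
) -> tuple[float, float, float]:
    """Two-sided two-sample t test; returns (statistic, df, p).

    ``variant`` is ``welch`` (unequal variances, Welch–Satterthwaite df)
    or ``pooled``.  Each group needs at least two non-missing values and
    the two groups together must carry positive variance.
    """
    x = np.asarray([v for v in x if v is not None and not np.isnan(v)], dtype=float)
    y = np.asarray([v for v in y if v is not None and not np.isnan(v)], dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError(
            f"two_sample_t needs >= 2 values per group, got {len(x)} and {len(y)}"
        )
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        if np.isclose(x.mean(), y.mean()):
            # degenerate but well-defined null: identical constants
            return 0.0, float(len(x) + len(y) - 2), 1.0
        raise ValidationError("two_sample_t: zero variance in both groups")
    if variant == "welch":
        res = sps.ttest_ind(x, y, equal_var=False)
        vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
        df = (vx + vy) ** 2 / (
            vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1)
        )
    elif variant == "pooled":
        res = sps.ttest_ind(x, y, equal_var=True)
        df = float(len(x) + len(y) - 2)
    else:
        raise ValidationError(f"unknown t-test variant {variant!r}")
    return float(res.statistic), float(df), float(res.pvalue)


def chi_square_independence(
    table: ContingencyTable | Sequence[Sequence[int]],
) -> tuple[float, float, float]:
    """Pearson chi-square test of independence, no continuity correction.

    Returns (statistic, df, p).  Rows or columns that are entirely zero
    make the expected counts degenerate and raise.
    """
    if isinstance(table, ContingencyTable):
        arr = np.asarray(table.counts, dtype=float)
    else:
        arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValidationError("contingency table must be at least 2x2")
    if (arr.sum(axis=1) == 0).any() or (arr.sum(axis=0) == 0).any():
        raise ValidationError("contingency table has an all-zero row or column")
    stat, p, df, _ = sps.chi2_contingency(arr, correction=False)
    return float(stat), float(df), float(p)


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved.

    adjusted_(i) = min_{j: rank_j >= rank_i} min(1, p_(j) * m / rank_j)
    over the ascending order statistics; ties are handled by stable
    ranking, so the result is invariant to input permutation (up to the
    same permutation).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    out = np.empty(m)
    out[order] = adjusted_sorted
    return out.tolist()


def apply_bh(rows: list[ComparisonRow], alpha: float) -> list[ComparisonRow]:
    """Adjust the testable rows of a family in place (skipped rows pass
    through untouched)."""
    testable = [i for i, r in enumerate(rows) if r.p_raw is not None]
    if not testable:
        return rows
    adjusted = bh_adjust([rows[i].p_raw for i in testable])
    out = list(rows)
    for i, adj in zip(testable, adjusted):
        out[i] = replace(rows[i], p_adjusted=adj, significant=adj < alpha)
    return out


# ----------------------------------------------------------- table builders

_DESERT = frozenset({Verdict.DESERT})
_NON_DESERT = frozenset({Verdict.NOT_DESERT, Verdict.LOW_ACCESS_ONLY})


def _split_tracts(
    tracts: Sequence[Tract], classifications: Sequence[TractClassification]
) -> tuple[list[tuple[Tract, TractClassification]], list[tuple[Tract, TractClassification]]]:
    by_id = {t.tract_id: t for t in tracts}
    desert, other = [], []
    for c in classifications:
        t = by_id.get(c.tract_id)
        if t is None:
            raise ValidationError(f"classification for unknown tract {c.tract_id!r}")
        if c.verdict in _DESERT:
            desert.append((t, c))
        elif c.verdict in _NON_DESERT:
            other.append((t, c))
    return desert, other


def _continuous_value(tract: Tract, name: str) -> Optional[float]:
    if name == "prop_below_fpl":
        return tract.prop_below_fpl
    if name == "median_income":
        return tract.median_income
    if name in tract.demographics:
        return tract.demographics[name]
    return None


def _continuous_row(
    name: str, desert: list, other: list, variant: str
) -> ComparisonRow:
    x = [v for t, _ in desert if (v := _continuous_value(t, name)) is not None]
    y = [v for t, _ in other if (v := _continuous_value(t, name)) is not None]
    if not x and not y:
        raise ValidationError(f"characteristic {name!r} absent from data")
    summary_a = {"n": len(x), "mean": float(np.mean(x)) if x else None,
                 "sd": float(np.std(x, ddof=1)) if len(x) > 1 else None}
    summary_b = {"n": len(y), "mean": float(np.mean(y)) if y else None,
                 "sd": float(np.std(y, ddof=1)) if len(y) > 1 else None}
    try:
        stat, df, p = two_sample_t(x, y, variant=variant)
        return ComparisonRow(name, "t", summary_a, summary_b, stat, df, p)
    except ValidationError as exc:
        return ComparisonRow(name, "t", summary_a, summary_b, None, None, None,
                             note=str(exc))


def _categorical_row(
    name: str, levels: Sequence[str],
    counts_a: dict[str, int], counts_b: dict[str, int],
) -> ComparisonRow:
    """Chi-square row over the given levels; percentages are within-group
    (summing to 100 across levels, up to rounding)."""
    a = [counts_a.get(lv, 0) for lv in levels]
    b = [counts_b.get(lv, 0) for lv in levels]
    tot_a, tot_b = sum(a), sum(b)
    summary_a = {
        lv: {"count": c, "percent": 100.0 * c / tot_a if tot_a else None}
        for lv, c in zip(levels, a)
    }
    summary_b = {
        lv: {"count": c, "percent": 100.0 * c / tot_b if tot_b else None}
        for lv, c in zip(levels, b)
    }
    # drop levels empty in both groups; the test needs no all-zero line
    kept = [(ca, cb) for ca, cb in zip(a, b) if ca + cb > 0]
    if tot_a == 0 or tot_b == 0 or len(kept) < 2:
        return ComparisonRow(
            name, "chi_square", summary_a, summary_b, None, None, None,
            note="degenerate group: contrast skipped",
        )
    table = [[ca for ca, _ in kept], [cb for _, cb in kept]]
    stat, df, p = chi_square_independence(np.asarray(table).T.tolist())
    return ComparisonRow(name, "chi_square", summary_a, summary_b, stat, df, p)


def pharmacies_per_tract_bin(n: int) -> str:
    if n == 0:
        return "zero"
    if n == 1:
        return "one"
    return "two_or_more"


def build_population_table(
    tracts: Sequence[Tract],
    classifications: Sequence[TractClassification],
    characteristics: Sequence[str],
    policy: ThresholdPolicy,
    variant: str = "welch",
    adjust: bool = True,
    include_categorical: bool = True,
) -> list[ComparisonRow]:
    """Tract-level comparison table (desert vs classified non-desert).

    ``characteristics`` names continuous rows: ``prop_below_fpl``,
    ``median_income`` or any demographic key.  Two categorical rows —
    urbanicity and pharmacies-per-tract binned {0, 1, >= 2} — are
    included by default (``include_categorical=False`` restricts the
    family to the named continuous rows).  With ``adjust`` the BH
    correction is applied across this table alone; pass ``adjust=False``
    and use :func:`apply_bh` to build a joint family with the pharmacy
    table.
    """
    desert, other = _split_tracts(tracts, classifications)
    rows: list[ComparisonRow] = []

    if include_categorical:
        urb_levels = [u.value for u in Urbanicity]
        rows.append(_categorical_row(
            "urbanicity", urb_levels,
            _count_by(desert, lambda tc: tc[1].urbanicity.value),
            _count_by(other, lambda tc: tc[1].urbanicity.value),
        ))
        rows.append(_categorical_row(
            "pharmacies_per_tract", ["zero", "one", "two_or_more"],
            _count_by(desert,
                      lambda tc: pharmacies_per_tract_bin(tc[1].pharmacies_in_tract)),
            _count_by(other,
                      lambda tc: pharmacies_per_tract_bin(tc[1].pharmacies_in_tract)),
        ))
    for name in characteristics:
        rows.append(_continuous_row(name, desert, other, variant))
    return apply_bh(rows, policy.alpha) if adjust else rows


def _count_by(pairs: list, key) -> dict[str, int]:
    out: dict[str, int] = {}
    for item in pairs:
        out[key(item)] = out.get(key(item), 0) + 1
    return out


def build_pharmacy_table(
    pharmacies: Sequence[Pharmacy],
    classifications: Sequence[TractClassification],
    policy: ThresholdPolicy,
    blocks=None,
    adjust: bool = True,
) -> tuple[list[ComparisonRow], int]:
    """Pharmacy-level comparison table (desert vs non-desert location).

    Each pharmacy takes the verdict of its containing tract (explicit
    ``tract_id`` or nearest block centroid).  Rows: urbanicity of
    location (with an ``na_no_population`` level for pharmacies in
    zero-population tracts), ownership, and one 2-level row per service
    flag with unknowns excluded from that flag's denominators.
    Pharmacies whose tract has no classification land in an explicit
    unassigned bucket, excluded from tests; its size is the second
    return value.
    """
    by_id = {c.tract_id: c for c in classifications}
    assignment = assign_pharmacy_tracts(pharmacies, blocks or [])
    desert_ph: list[Pharmacy] = []
    other_ph: list[Pharmacy] = []
    desert_cls: list[TractClassification] = []
    other_cls: list[TractClassification] = []
    unassigned = 0
    for p in pharmacies:
        tid = assignment.get(p.pharmacy_id)
        c = by_id.get(tid) if tid is not None else None
        if c is None:
            unassigned += 1
        elif c.verdict in _DESERT:
            desert_ph.append(p)
            desert_cls.append(c)
        else:
            # every non-desert verdict, including zero-population tracts,
            # counts on the non-desert side of the pharmacy table
            other_ph.append(p)
            other_cls.append(c)

    rows: list[ComparisonRow] = []

    def urb_level(c: TractClassification) -> str:
        if c.verdict is Verdict.UNCLASSIFIED_ZERO_POP or c.urbanicity is None:
            return "na_no_population"
        return c.urbanicity.value

    urb_levels = [u.value for u in Urbanicity] + ["na_no_population"]
    rows.append(_categorical_row(
        "urbanicity_of_location", urb_levels,
        _count_by(desert_cls, urb_level), _count_by(other_cls, urb_level),
    ))
    own_levels = [o.value for o in Ownership]
    rows.append(_categorical_row(
        "ownership", own_levels,
        _count_by(desert_ph, lambda p: p.ownership.value),
        _count_by(other_ph, lambda p: p.ownership.value),
    ))
    for flag in SERVICE_FLAGS:
        rows.append(_categorical_row(
            flag, ["yes", "no"],
            _count_by([p for p in desert_ph if p.services.get(flag) is not None],
                      lambda p: "yes" if p.services[flag] else "no"),
            _count_by([p for p in other_ph if p.services.get(flag) is not None],
                      lambda p: "yes" if p.services[flag] else "no"),
        ))
    if adjust:
        rows = apply_bh(rows, policy.alpha)
    return rows, unassigned


def compare_all(
    tracts: Sequence[Tract],
    classifications: Sequence[TractClassification],
    pharmacies: Sequence[Pharmacy],
    characteristics: Sequence[str],
    policy: ThresholdPolicy,
    blocks=None,
    variant: str = "welch",
    bh_family: str = "joint",
) -> tuple[list[ComparisonRow], list[ComparisonRow], int]:
    """Build both tables; BH family per ``bh_family`` ("joint" adjusts
    all rows of both tables as one family, "per_table" each alone)."""
    pop_rows = build_population_table(
        tracts, classifications, characteristics, policy,
        variant=variant, adjust=(bh_family == "per_table"),
    )
    ph_rows, unassigned = build_pharmacy_table(
        pharmacies, classifications, policy, blocks=blocks,
        adjust=(bh_family == "per_table"),
    )
    if bh_family == "joint":
        combined = apply_bh(pop_rows + ph_rows, policy.alpha)
        pop_rows = combined[: len(pop_rows)]
        ph_rows = combined[len(pop_rows):]
    elif bh_family != "per_table":
        raise ValidationError(f"unknown bh_family {bh_family!r}")
    return pop_rows, ph_rows, unassigned


def rows_to_records(rows: Sequence[ComparisonRow]) -> list[dict]:
    """Flatten rows for CSV export."""
    import json

    return [
        {
            "characteristic": r.characteristic,
            "test": r.test,
            "desert_summary": json.dumps(r.group_a_summary),
            "non_desert_summary": json.dumps(r.group_b_summary),
            "statistic": r.statistic,
            "df": r.df,
            "p_raw": r.p_raw,
            "p_adjusted": r.p_adjusted,
            "significant": r.significant,
            "note": r.note,
        }
        for r in rows
    ]
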