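"""Frequency summaries and exact association tests for alteration data.

The two-sided Fisher exact test is computed by exhaustive hypergeometric
enumeration in exact integer arithmetic (point-probability method: the
p-value sums the probabilities of every table with the observed margins
whose point probability does not exceed the observed table's).  Odds
ratios are raw cross-products; zero cells are flagged, never
continuity-corrected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from enum import Enum
from typing import Collection

__all__ = [
    "FrequencyResult",
    "ContingencyTable2x2",
    "AssociationResult",
    "Direction",
    "alteration_frequency",
    "fisher_exact_2x2",
    "odds_ratio_2x2",
    "cooccurrence_test",
    "subgroup_enrichment",
]


class ValidationError(ValueError):
    pass


@dataclass(frozen=True)
class FrequencyResult:
    """Alteration frequency with the percentage as printed in reports.

    ``percent_1dp`` rounds half-up to one decimal: 14/359 prints as 3.9.
    """

    n_altered: int
    n_total: int

    def __post_init__(self) -> None:
        if self.n_total < 1:
            raise ValidationError("n_total must be >= 1")
        if not (0 <= self.n_altered <= self.n_total):
            raise ValidationError("n_altered must lie in [0, n_total]")

    @property
    def fraction(self) -> float:
        return self.n_altered / self.n_total

    @property
    def percent_1dp(self) -> float:
        exact = Decimal(100 * self.n_altered) / Decimal(self.n_total)
        return float(exact.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def alteration_frequency(n_altered: int, n_total: int) -> FrequencyResult:
    return FrequencyResult(n_altered, n_total)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows = alteration present/absent, columns = group
    member/non-member."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def transpose(self) -> "ContingencyTable2x2":
        return ContingencyTable2x2(self.a, self.c, self.b, self.d)


class Direction(str, Enum):
    CO_OCCURRENCE = "co_occurrence"
    EXCLUSIVITY = "exclusivity"
    NONE = "none"


@dataclass(frozen=True)
class AssociationResult:
    table: ContingencyTable2x2
    p_two_sided: float
    odds_ratio: float  # math.inf flags a zero-cell denominator
    direction: Direction
    degenerate: bool = False
    zero_cell: bool = False


# Relative slack when comparing point probabilities, guarding against
# rounding when callers supply float-derived counts; comparisons are done
# in exact integers so ties are included deterministically.
_TIE_REL = 10**7


def fisher_exact_2x2(table: ContingencyTable2x2) -> tuple[float, bool]:
    """Two-sided Fisher exact p-value by full hypergeometric enumeration.

    Returns ``(p, degenerate)``; a table with an all-zero row or column has
    no free margin and yields p = 1 with the degenerate flag set.  All
    admissible tables share the unnormalized weight C(r1, k) * C(r2, c1-k);
    the p-value sums weights <= the observed weight (with a tiny relative
    tolerance for ties) over the common normalizer C(n, c1).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2 = a + b, c + d
    c1 = a + c
    n = table.n
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0, True
    w_obs = math.comb(r1, a) * math.comb(r2, c)
    k_min = max(0, c1 - r2)
    k_max = min(r1, c1)
    num = 0
    for k in range(k_min, k_max + 1):
        w = math.comb(r1, k) * math.comb(r2, c1 - k)
        if w * _TIE_REL <= w_obs * (_TIE_REL + 1):
            num += w
    p = num / math.comb(n, c1)
    return min(p, 1.0), False


def odds_ratio_2x2(table: ContingencyTable2x2) -> tuple[float, bool]:
    """Raw cross-product odds ratio (a*d)/(b*c).

    Returns ``(or, zero_cell)``: infinity when only the denominator is
    zero, 0 when only the numerator is, and 1 with the flag set when both
    vanish (no information).
    """
    num = table.a * table.d
    den = table.b * table.c
    if den == 0 and num == 0:
        return 1.0, True
    if den == 0:
        return math.inf, True
    if num == 0:
        return 0.0, True
    return num / den, False


def _associate(table: ContingencyTable2x2) -> AssociationResult:
    p, degenerate = fisher_exact_2x2(table)
    oratio, zero_cell = odds_ratio_2x2(table)
    if degenerate or oratio == 1.0:
        direction = Direction.NONE
    elif oratio > 1.0:
        direction = Direction.CO_OCCURRENCE
    else:
        direction = Direction.EXCLUSIVITY
    return AssociationResult(
        table=table,
        p_two_sided=p,
        odds_ratio=oratio,
        direction=direction,
        degenerate=degenerate,
        zero_cell=zero_cell,
    )


def _table_from_sets(
    set_rows: Collection[str], set_cols: Collection[str], all_samples: Collection[str]
) -> ContingencyTable2x2:
    universe = set(all_samples)
    if not universe:
        raise ValidationError("sample universe is empty")
    rows = set(set_rows)
    cols = set(set_cols)
    if not rows <= universe or not cols <= universe:
        raise ValidationError("alteration/group sets must be drawn from all_samples")
    a = len(rows & cols)
    b = len(rows - cols)
    c = len(cols - rows)
    d = len(universe - rows - cols)
    return ContingencyTable2x2(a, b, c, d)


def cooccurrence_test(
    samples_gene_a: Collection[str],
    samples_gene_b: Collection[str],
    all_samples: Collection[str],
) -> AssociationResult:
    """Test co-occurrence vs mutual exclusivity of two alteration sets.

    The 2x2 crosses membership in the two altered-sample sets over the
    cohort; the odds ratio orients the direction (>1 co-occurrence,
    <1 exclusivity).
    """
    return _associate(_table_from_sets(samples_gene_a, samples_gene_b, all_samples))


def subgroup_enrichment(
    altered_samples: Collection[str],
    subgroup_samples: Collection[str],
    all_samples: Collection[str],
) -> AssociationResult:
    """Test enrichment of an alteration in a sample subgroup (e.g. tumors
    with a high activation score, or the luminal subtype)."""
    universe = set(all_samples)
    if not set(subgroup_samples) <= universe:
        raise ValidationError("subgroup_samples must be a subset of all_samples")
    return _associate(_table_from_sets(altered_samples, subgroup_samples, all_samples))
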