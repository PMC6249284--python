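"""READ1 (DCDC2 intron-2 tandem repeat) allele groups and carrier coding.

READ1 alleles are grouped by copy-number structure of the first two repeat
units: RU1-1 (a single copy of repeat unit 1), RU2Long (eight or more copies
of repeat unit 2) and RU2Short (six or fewer copies of repeat unit 2).
Group membership is defined operationally by explicit allele-ID lists; a
copy-count rule engine is available for alleles outside the default lists.

A subject carries the group if at least one allele belongs to it.  The
2445 bp microdeletion spanning READ1 is coded by treating a hemizygous
subject as homozygous for the retained allele; subjects with a dual
deletion are excluded from analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Union

import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for the READ1 microdeletion in genotype tables.
DELETION = "DEL"

#: Sentinel returned by :func:`carrier_status` for dual-deletion subjects.
EXCLUDED = "EXCLUDED"


class AlleleGroup(str, Enum):
    RU1_1 = "RU1-1"
    RU2LONG = "RU2Long"
    RU2SHORT = "RU2Short"
    UNGROUPED = "UNGROUPED"


@dataclass(frozen=True)
class AlleleGroupTable:
    """Allele-ID membership lists defining the three functional groups."""

    ru1_1_alleles: frozenset = frozenset({2, 3, 8, 12, 25, 27})
    ru2long_alleles: frozenset = frozenset({5, 6, 13, 14, 19, 20, 22, 23})
    ru2short_alleles: frozenset = frozenset(
        {4, 10, 15, 16, 17, 21, 24, 26, 30, 37, 39}
    )

    def __post_init__(self) -> None:
        a, b, c = self.ru1_1_alleles, self.ru2long_alleles, self.ru2short_alleles
        if a & b or a & c or b & c:
            raise ValueError("allele group lists must be pairwise disjoint")

    @classmethod
    def from_dict(cls, d: dict) -> "AlleleGroupTable":
        return cls(
            ru1_1_alleles=frozenset(d.get("ru1_1_alleles", ())),
            ru2long_alleles=frozenset(d.get("ru2long_alleles", ())),
            ru2short_alleles=frozenset(d.get("ru2short_alleles", ())),
        )


DEFAULT_GROUP_TABLE = AlleleGroupTable()

AlleleId = Union[int, str]


@dataclass(frozen=True)
class Read1Call:
    """Unordered pair of READ1 allele identifiers; ``DEL`` marks the deletion.

    A call with both alleles deleted is retained in the container but is
    excluded from all carrier-based analyses.
    """

    allele_a: AlleleId
    allele_b: AlleleId

    @property
    def alleles(self) -> tuple:
        return (self.allele_a, self.allele_b)

    @property
    def is_dual_deletion(self) -> bool:
        return self.allele_a == DELETION and self.allele_b == DELETION

    def __eq__(self, other) -> bool:  # unordered
        if not isinstance(other, Read1Call):
            return NotImplemented
        return frozenset([self.allele_a, self.allele_b]) == frozenset(
            [other.allele_a, other.allele_b]
        )

    def __hash__(self) -> int:
        return hash(frozenset([self.allele_a, self.allele_b]))


def classify_allele(
    allele: AlleleId, table: AlleleGroupTable = DEFAULT_GROUP_TABLE
) -> AlleleGroup:
    """Map one allele ID to its functional group.

    The deletion sentinel is rejected: it is handled by substitution at the
    genotype level (see :func:`carrier_status`), never as a group of its own.
    Unknown IDs return ``UNGROUPED`` with a warning.
    """
    if allele == DELETION:
        raise ValueError("DELETION is not an allele group; handle at call level")
    if allele in table.ru1_1_alleles:
        return AlleleGroup.RU1_1
    if allele in table.ru2long_alleles:
        return AlleleGroup.RU2LONG
    if allele in table.ru2short_alleles:
        return AlleleGroup.RU2SHORT
    logger.warning("READ1 allele %r not in any group table; marking UNGROUPED", allele)
    return AlleleGroup.UNGROUPED


def classify_by_copy_number(ru1_copies: int, ru2_copies: int,
                            ru2long_min: int = 8,
                            ru2short_max: int = 6) -> AlleleGroup:
    """Copy-count rule engine for alleles outside the default lists.

    RU1-1 requires exactly one copy of repeat unit 1; RU2Long/RU2Short are
    defined by repeat-unit-2 copy thresholds.  This is an extrapolation of
    the published allele lists and is flagged as such in the log.
    """
    logger.info("copy-number grouping is an extrapolation beyond the allele lists")
    if ru1_copies == 1:
        return AlleleGroup.RU1_1
    if ru2_copies >= ru2long_min:
        return AlleleGroup.RU2LONG
    if ru2_copies <= ru2short_max:
        return AlleleGroup.RU2SHORT
    return AlleleGroup.UNGROUPED


def carrier_status(
    call: Read1Call,
    group: AlleleGroup,
    table: AlleleGroupTable = DEFAULT_GROUP_TABLE,
):
    """True iff at least one allele (after deletion substitution) is in *group*.

    One deleted chromosome is coded as homozygosity for the retained allele,
    so a (DEL, x) call carries exactly the groups x carries.  Dual deletions
    return :data:`EXCLUDED`.
    """
    if call.is_dual_deletion:
        return EXCLUDED
    alleles = [a for a in call.alleles if a != DELETION]
    return any(classify_allele(a, table) == group for a in alleles)


def carrier_flags(
    calls: Iterable[Read1Call],
    group: AlleleGroup = AlleleGroup.RU2SHORT,
    table: AlleleGroupTable = DEFAULT_GROUP_TABLE,
) -> list:
    """Vectorized :func:`carrier_status`; preserves EXCLUDED markers."""
    return [carrier_status(c, group, table) for c in calls]


def call_rate(calls: Iterable) -> float:
    """Fraction of non-missing genotype calls (None/NaN count as missing)."""
    calls = list(calls)
    if not calls:
        raise ValueError("call_rate requires at least one subject")
    n_called = sum(1 for c in calls if c is not None and isinstance(c, Read1Call))
    return n_called / len(calls)


def calls_from_frame(df: pd.DataFrame) -> list:
    """Parse a genotype table (subject_id, allele_a, allele_b) into calls.

    Missing calls (NaN in either allele column) become ``None``.  Numeric
    allele IDs are coerced to int; the string ``"DEL"`` is the deletion.
    """
    out = []
    for _, row in df.iterrows():
        a, b = row["allele_a"], row["allele_b"]
        if pd.isna(a) or pd.isna(b):
            out.append(None)
            continue
        out.append(Read1Call(_coerce(a), _coerce(b)))
    return out


def _coerce(x) -> AlleleId:
    if isinstance(x, str):
        x = x.strip()
        if x == DELETION:
            return DELETION
        return int(float(x))
    return int(x)
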