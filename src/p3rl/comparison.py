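"""Similarity and staged agreement classification on encrypted values.

Names: Bloom filters are first tested for full (bit-identical) agreement;
otherwise the Dice coefficient 2h/(a+b) is compared against a cut-off to
separate partial agreement from disagreement, and first/surname pairs are
additionally checked for transposition.  Dates: a four-step cascade tests,
in order, exact agreement (plain year + day and month digests), swapped day
and month (via the shared-framing auxiliary digests), ±1-day difference
(full-date digest against the neighbours' digests), and single-digit or
adjacent-transposition errors in the plain year.  The cascade order is
authoritative: a Dec 31 / Jan 1 pair is ±1 day, not a year error.

Comparators for names and dates receive only filters and digests — never a
plain sensitive value.  The ``*_plain`` variants at the bottom implement the
same outcome taxonomy on plain cleaned values (equality / edit distance);
they exist to benchmark what linkage quality costs when run encrypted.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .datamodel import MISSING
from .encryption import BloomFilterValue, ConfigError, EncryptedDate


class AgreementLevel(str, Enum):
    FULL = "full"
    PARTIAL = "partial"
    DISAGREE = "disagree"
    MISSING = "missing"


class DateOutcome(str, Enum):
    EXACT = "exact"
    DAY_MONTH_SWAPPED = "day_month_swapped"
    PLUS_MINUS_ONE_DAY = "plus_minus_one_day"
    YEAR_ONE_DIGIT = "year_one_digit"
    YEAR_TRANSPOSED = "year_transposed"
    DISAGREE = "disagree"
    MISSING = "missing"


@dataclass(frozen=True)
class DiceCutoffs:
    """Similarity band limits; full agreement is reserved for identical bits."""
    partial_min: float = 0.80

    def __post_init__(self) -> None:
        if not 0 < self.partial_min < 1:
            raise ValueError("partial_min must lie in (0, 1)")


@dataclass(frozen=True)
class DiceComputation:
    h: int
    a: int
    b: int

    @property
    def d(self) -> float:
        return 2 * self.h / (self.a + self.b)


def dice(bf_a: BloomFilterValue, bf_b: BloomFilterValue) -> DiceComputation:
    """Dice coefficient of two filters; a+b = 0 is flagged by the caller."""
    if bf_a.m != bf_b.m:
        raise ConfigError("Bloom filter lengths differ "
                          "(encryption parameter divergence)")
    h = int(np.bitwise_and(bf_a.bits, bf_b.bits).sum())
    return DiceComputation(h=h, a=bf_a.popcount, b=bf_b.popcount)


def compare_name(bf_a: BloomFilterValue | None,
                 bf_b: BloomFilterValue | None,
                 cut: DiceCutoffs) -> tuple[AgreementLevel, float | None]:
    """Staged name comparison: identity, then Dice against the cut-off."""
    if bf_a is None or bf_b is None or not bf_a.popcount or not bf_b.popcount:
        return AgreementLevel.MISSING, None
    if np.array_equal(bf_a.bits, bf_b.bits):
        return AgreementLevel.FULL, 1.0
    d = dice(bf_a, bf_b).d
    if d >= cut.partial_min:
        return AgreementLevel.PARTIAL, d
    return AgreementLevel.DISAGREE, d


def check_name_transposition(first_a: BloomFilterValue | None,
                             sur_a: BloomFilterValue | None,
                             first_b: BloomFilterValue | None,
                             sur_b: BloomFilterValue | None,
                             cut: DiceCutoffs) -> bool:
    """True when first and surname appear swapped between the records.

    Both cross-comparisons must reach at least partial agreement while the
    direct comparisons do not both reach it.
    """
    if any(v is None for v in (first_a, sur_a, first_b, sur_b)):
        return False
    at_least_partial = (AgreementLevel.FULL, AgreementLevel.PARTIAL)
    cross1, _ = compare_name(first_a, sur_b, cut)
    if cross1 not in at_least_partial:
        return False
    cross2, _ = compare_name(sur_a, first_b, cut)
    if cross2 not in at_least_partial:
        return False
    direct1, _ = compare_name(first_a, first_b, cut)
    direct2, _ = compare_name(sur_a, sur_b, cut)
    return not (direct1 in at_least_partial and direct2 in at_least_partial)


# ---------------------------------------------------------------------------
# Year-string error tests (plain years travel unencrypted by design)
# ---------------------------------------------------------------------------

def _one_digit_apart(y_a: str, y_b: str) -> bool:
    return (len(y_a) == len(y_b)
            and sum(c1 != c2 for c1, c2 in zip(y_a, y_b)) == 1)


def _adjacent_transposition(y_a: str, y_b: str) -> bool:
    if len(y_a) != len(y_b) or y_a == y_b:
        return False
    for i in range(len(y_a) - 1):
        swapped = y_a[:i] + y_a[i + 1] + y_a[i] + y_a[i + 2:]
        if swapped == y_b:
            return True
    return False


def compare_date(ed_a: EncryptedDate, ed_b: EncryptedDate) -> DateOutcome:
    """Four-step cascade over encrypted date sections; order is decisive."""
    if ed_a.missing or ed_b.missing:
        return DateOutcome.MISSING
    year_eq = ed_a.plain_year == ed_b.plain_year
    # (1) full agreement: plain year plus day and month digests
    if year_eq and ed_a.h_day == ed_b.h_day and ed_a.h_month == ed_b.h_month:
        return DateOutcome.EXACT
    # (2) swapped day and month, via shared-framing auxiliary digests
    if year_eq and ed_a.x_day == ed_b.x_month and ed_a.x_month == ed_b.x_day:
        return DateOutcome.DAY_MONTH_SWAPPED
    # (3) +/- 1 day, including across month and year boundaries
    if (ed_a.h_full == ed_b.h_minus1 or ed_a.h_full == ed_b.h_plus1
            or ed_b.h_full == ed_a.h_minus1 or ed_b.h_full == ed_a.h_plus1):
        return DateOutcome.PLUS_MINUS_ONE_DAY
    # (4) year errors with agreeing day and month
    if ed_a.h_day == ed_b.h_day and ed_a.h_month == ed_b.h_month:
        y_a, y_b = str(ed_a.plain_year), str(ed_b.plain_year)
        if _one_digit_apart(y_a, y_b):
            return DateOutcome.YEAR_ONE_DIGIT
        if _adjacent_transposition(y_a, y_b):
            return DateOutcome.YEAR_TRANSPOSED
    return DateOutcome.DISAGREE


def compare_plain(v_a: str, v_b: str) -> AgreementLevel:
    """Equality after trimming and case-folding; no similarity scoring."""
    a, b = v_a.strip().casefold(), v_b.strip().casefold()
    if not a or not b:
        return AgreementLevel.MISSING
    return AgreementLevel.FULL if a == b else AgreementLevel.DISAGREE


# ---------------------------------------------------------------------------
# Comparison vectors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariableSpec:
    """One configured linkage variable."""
    name: str
    kind: str                 # "name" | "date" | "plain"
    cutoff: float = 0.80


@dataclass
class ComparisonVector:
    """Per-variable agreement outcomes for one candidate pair."""
    outcomes: dict[str, AgreementLevel | DateOutcome]
    dices: dict[str, float | None]
    transposed: bool = False


def build_comparison_vector(rec_a: dict, rec_b: dict,
                            variables: list[VariableSpec],
                            transposition_pair: tuple[str, str] | None = None,
                            ) -> ComparisonVector:
    """Compare two encrypted records variable by variable.

    ``rec_a``/``rec_b`` map variable names to decoded values: Bloom filters
    for names, :class:`EncryptedDate` for dates, strings for plain variables.
    ``transposition_pair`` names the (firstname, surname) slots checked once
    per name block.
    """
    outcomes: dict = {}
    dices: dict = {}
    for var in variables:
        va, vb = rec_a[var.name], rec_b[var.name]
        if var.kind == "name":
            lvl, d = compare_name(va, vb, DiceCutoffs(var.cutoff))
            outcomes[var.name] = lvl
            dices[var.name] = d
        elif var.kind == "date":
            outcomes[var.name] = compare_date(va, vb)
        else:
            outcomes[var.name] = compare_plain(va, vb)
    transposed = False
    if transposition_pair is not None:
        fn, sn = transposition_pair
        cut = DiceCutoffs(next(v.cutoff for v in variables if v.name == fn))
        transposed = check_name_transposition(
            rec_a.get(fn), rec_a.get(sn), rec_b.get(fn), rec_b.get(sn), cut)
    return ComparisonVector(outcomes=outcomes, dices=dices,
                            transposed=transposed)


# ---------------------------------------------------------------------------
# Plain-value comparators (benchmark engine only)
# ---------------------------------------------------------------------------

def edit_similarity(a: str, b: str) -> float:
    """1 - levenshtein/max(len); the plain analogue of Bloom Dice."""
    import edlib
    if a == b:
        return 1.0
    dist = edlib.align(a, b)["editDistance"]
    return 1.0 - dist / max(len(a), len(b))


def compare_name_plain(v_a: str, v_b: str,
                       cut: DiceCutoffs) -> tuple[AgreementLevel, float | None]:
    if not v_a or not v_b:
        return AgreementLevel.MISSING, None
    if v_a == v_b:
        return AgreementLevel.FULL, 1.0
    sim = edit_similarity(v_a, v_b)
    if sim >= cut.partial_min:
        return AgreementLevel.PARTIAL, sim
    return AgreementLevel.DISAGREE, sim


def check_name_transposition_plain(first_a: str, sur_a: str,
                                   first_b: str, sur_b: str,
                                   cut: DiceCutoffs) -> bool:
    if not (first_a and sur_a and first_b and sur_b):
        return False
    ok = (AgreementLevel.FULL, AgreementLevel.PARTIAL)
    if compare_name_plain(first_a, sur_b, cut)[0] not in ok:
        return False
    if compare_name_plain(sur_a, first_b, cut)[0] not in ok:
        return False
    d1 = compare_name_plain(first_a, first_b, cut)[0]
    d2 = compare_name_plain(sur_a, sur_b, cut)[0]
    return not (d1 in ok and d2 in ok)


def compare_date_plain(iso_a: str, iso_b: str) -> DateOutcome:
    """The four-step cascade evaluated on plain ISO dates."""
    if iso_a == MISSING or iso_b == MISSING:
        return DateOutcome.MISSING
    da, db = _dt.date.fromisoformat(iso_a), _dt.date.fromisoformat(iso_b)
    if da == db:
        return DateOutcome.EXACT
    if (da.year == db.year and da.day == db.month and da.month == db.day):
        return DateOutcome.DAY_MONTH_SWAPPED
    if abs((da - db).days) == 1:
        return DateOutcome.PLUS_MINUS_ONE_DAY
    if da.day == db.day and da.month == db.month:
        y_a, y_b = str(da.year), str(db.year)
        if _one_digit_apart(y_a, y_b):
            return DateOutcome.YEAR_ONE_DIGIT
        if _adjacent_transposition(y_a, y_b):
            return DateOutcome.YEAR_TRANSPOSED
    return DateOutcome.DISAGREE


def build_comparison_vector_plain(rec_a: dict, rec_b: dict,
                                  variables: list[VariableSpec],
                                  transposition_pair: tuple[str, str] | None
                                  = None) -> ComparisonVector:
    outcomes: dict = {}
    dices: dict = {}
    for var in variables:
        va, vb = rec_a[var.name], rec_b[var.name]
        if var.kind == "name":
            lvl, d = compare_name_plain(va, vb, DiceCutoffs(var.cutoff))
            outcomes[var.name] = lvl
            dices[var.name] = d
        elif var.kind == "date":
            outcomes[var.name] = compare_date_plain(va, vb)
        else:
            outcomes[var.name] = compare_plain(va, vb)
    transposed = False
    if transposition_pair is not None:
        fn, sn = transposition_pair
        cut = DiceCutoffs(next(v.cutoff for v in variables if v.name == fn))
        transposed = check_name_transposition_plain(
            rec_a.get(fn, ""), rec_a.get(sn, ""),
            rec_b.get(fn, ""), rec_b.get(sn, ""), cut)
    return ComparisonVector(outcomes=outcomes, dices=dices,
                            transposed=transposed)
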