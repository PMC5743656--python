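"""Criterion-B rule engine: (EOO, AOO, n_locations) -> preliminary category.

Criterion B has two subcriteria — B1 keyed on extent of occurrence, B2 on
area of occupancy — each with CR/EN/VU area thresholds, plus conditions.
Condition (a) is implemented through the number of locations; condition
b(iii) (continuing decline in habitat quality) is *assumed* to hold for
every taxon, which is what makes a batch preliminary assessment possible at
all, and is recorded in each result rather than silently applied.

For a subcriterion to support a threat level, both its range-size threshold
and the locations threshold must be met at that level, so the subcriterion
category is the LESS severe of the range rank and the locations rank.  The
final category is the MORE severe of the evaluated subcriteria.  NT and LC
are not distinguished (no rule exists to split them from distribution data
alone).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum


class SeverityRank(IntEnum):
    """Threat severity, ordered so that greater means more threatened."""

    NT_OR_LC = 0
    VU = 1
    EN = 2
    CR = 3

    @property
    def label(self) -> str:
        return {self.CR: "CR", self.EN: "EN", self.VU: "VU", self.NT_OR_LC: "NT or LC"}[self]

    @property
    def is_threatened(self) -> bool:
        return self >= SeverityRank.VU


B3_ASSUMPTION_NOTE = (
    "condition b(iii) (continuing decline in habitat quality, observed, "
    "inferred or projected) assumed to hold for all taxa"
)


@dataclass(frozen=True)
class ThresholdTable:
    """Criterion-B numeric thresholds (IUCN 2012 / SPS 2016 guideline values).

    Areas use strict ``<`` ("less than"); locations use ``<=`` ("no more
    than").  All values are overridable so a guideline revision is a
    one-line change; the effective table is echoed into every output.
    """

    eoo_cr_km2: float = 100.0
    eoo_en_km2: float = 5_000.0
    eoo_vu_km2: float = 20_000.0
    aoo_cr_km2: float = 10.0
    aoo_en_km2: float = 500.0
    aoo_vu_km2: float = 2_000.0
    loc_cr: int = 1
    loc_en: int = 5
    loc_vu: int = 10

    def __post_init__(self):
        for a, b, c, what in (
            (self.eoo_cr_km2, self.eoo_en_km2, self.eoo_vu_km2, "EOO"),
            (self.aoo_cr_km2, self.aoo_en_km2, self.aoo_vu_km2, "AOO"),
            (self.loc_cr, self.loc_en, self.loc_vu, "locations"),
        ):
            if not (a < b < c):
                raise ValueError(f"{what} thresholds must be strictly increasing CR < EN < VU")


@dataclass
class CategoryResult:
    """Per-subcriterion and final preliminary category with criterion code."""

    category_B1: SeverityRank | None  # None = not evaluated (EOO undefined)
    category_B2: SeverityRank
    final_category: SeverityRank
    criterion_code: str
    assumptions_note: str = B3_ASSUMPTION_NOTE


def _area_rank(area: float, cr: float, en: float, vu: float) -> SeverityRank:
    if area < cr:
        return SeverityRank.CR
    if area < en:
        return SeverityRank.EN
    if area < vu:
        return SeverityRank.VU
    return SeverityRank.NT_OR_LC


def rank_from_eoo(
    eoo_km2: float | None, thresholds: ThresholdTable = ThresholdTable()
) -> SeverityRank | None:
    """EOO severity rank; None (not evaluated) when EOO is undefined."""
    if eoo_km2 is None:
        return None
    if eoo_km2 < 0:
        raise ValueError("EOO area cannot be negative")
    return _area_rank(eoo_km2, thresholds.eoo_cr_km2, thresholds.eoo_en_km2, thresholds.eoo_vu_km2)


def rank_from_aoo(aoo_km2: float, thresholds: ThresholdTable = ThresholdTable()) -> SeverityRank:
    """AOO severity rank (AOO is always defined: at least one occupied cell)."""
    if aoo_km2 < 0:
        raise ValueError("AOO area cannot be negative")
    return _area_rank(aoo_km2, thresholds.aoo_cr_km2, thresholds.aoo_en_km2, thresholds.aoo_vu_km2)


def rank_from_locations(
    n_locations: int, thresholds: ThresholdTable = ThresholdTable()
) -> SeverityRank:
    """Locations severity rank under condition (a); inclusive thresholds."""
    if n_locations < 1:
        raise ValueError("number of locations must be >= 1")
    if n_locations <= thresholds.loc_cr:
        return SeverityRank.CR
    if n_locations <= thresholds.loc_en:
        return SeverityRank.EN
    if n_locations <= thresholds.loc_vu:
        return SeverityRank.VU
    return SeverityRank.NT_OR_LC


def combine(
    eoo_rank: SeverityRank | None,
    aoo_rank: SeverityRank,
    loc_rank: SeverityRank,
) -> CategoryResult:
    """Combine per-metric ranks into subcriterion and final categories.

    B1 = min(EOO rank, locations rank) — not evaluated if EOO is undefined;
    B2 = min(AOO rank, locations rank); final = max of the evaluated
    subcriteria.  The criterion code lists every subcriterion whose category
    equals the final one (``B1a``/``B2a``, joined by ``+``).
    """
    cat_b1 = None if eoo_rank is None else SeverityRank(min(eoo_rank, loc_rank))
    cat_b2 = SeverityRank(min(aoo_rank, loc_rank))
    evaluated = [c for c in (cat_b1, cat_b2) if c is not None]
    final = SeverityRank(max(evaluated))
    codes = []
    if cat_b1 is not None and cat_b1 == final:
        codes.append("B1a")
    if cat_b2 == final:
        codes.append("B2a")
    return CategoryResult(cat_b1, cat_b2, final, "+".join(codes))


def categorize(
    eoo_km2: float | None,
    aoo_km2: float,
    n_locations: int,
    thresholds: ThresholdTable = ThresholdTable(),
) -> CategoryResult:
    """One-call convenience: metric values in, CategoryResult out."""
    return combine(
        rank_from_eoo(eoo_km2, thresholds),
        rank_from_aoo(aoo_km2, thresholds),
        rank_from_locations(n_locations, thresholds),
    )
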