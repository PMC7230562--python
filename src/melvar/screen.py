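"""Carrier-frequency screening of candidate variants across study groups.

For each candidate variant the screen counts carriers (>=1 alternate allele)
in three groups — MPM patients (exome-sequenced plus screened cases),
familial-melanoma index cases, and healthy population controls — and reports
``(carriers/denominator) percent`` cells, where the denominator is the number
of group samples with a defined genotype for that variant (so denominators
may differ across variants within a group).

Two downstream rules act on the table:

* **rarity classification** from the control carrier frequency — rare below
  1%, common above 5%, polymorphism in between (boundaries belong to the
  polymorphism class);
* **dominant-consistency exclusion** — a candidate observed homozygous in a
  healthy control is excluded, since a dominantly acting susceptibility
  allele should not appear in two copies in an unaffected individual.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

from melvar.model import AnnotatedVariant, CohortDesign, SampleGroup

logger = logging.getLogger(__name__)

#: Screening group labels, in report column order.
GROUPS = ("MPM", "INDEX", "CONTROL")

_GROUP_MEMBERS = {
    "MPM": (SampleGroup.WES_CASE, SampleGroup.MPM_SCREEN),
    "INDEX": (SampleGroup.FAMILIAL_INDEX,),
    "CONTROL": (SampleGroup.HEALTHY_CONTROL,),
}


class RarityClass(enum.IntEnum):
    """Ordered rarity classes (RARE < POLYMORPHISM < COMMON)."""

    RARE = 0
    POLYMORPHISM = 1
    COMMON = 2


def carrier_frequency(carriers: int, denominator: int) -> float:
    """Carrier percentage, half-up rounded to one decimal.

    >>> carrier_frequency(4, 26)
    15.4
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= carriers <= denominator:
        raise ValueError(f"carriers {carriers} outside [0, {denominator}]")
    pct = Decimal(100 * carriers) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def classify_rarity(control_freq: float) -> RarityClass:
    """Classify a control carrier frequency (a fraction in [0, 1]).

    Boundaries are inclusive to POLYMORPHISM: exactly 1% or exactly 5% are
    polymorphisms.
    """
    if not 0.0 <= control_freq <= 1.0:
        raise ValueError("control_freq must lie in [0, 1]")
    if control_freq < 0.01:
        return RarityClass.RARE
    if control_freq > 0.05:
        return RarityClass.COMMON
    return RarityClass.POLYMORPHISM


@dataclass(frozen=True)
class CarrierCell:
    carriers: int
    denominator: int
    percent: float

    @classmethod
    def from_counts(cls, carriers: int, denominator: int) -> "CarrierCell":
        return cls(carriers, denominator, carrier_frequency(carriers, denominator))

    @property
    def frequency(self) -> float:
        return self.carriers / self.denominator


@dataclass
class CarrierTable:
    """Per-variant, per-group carrier counts (the screening-table object)."""

    rows: dict[tuple[str, int, str, str], dict[str, CarrierCell]] = field(default_factory=dict)
    groups: tuple[str, ...] = GROUPS

    def cell(self, key: tuple[str, int, str, str], group: str) -> Optional[CarrierCell]:
        return self.rows.get(key, {}).get(group)

    def self_consistent(self) -> bool:
        """Every percent field matches its own counts."""
        return all(
            cell.percent == carrier_frequency(cell.carriers, cell.denominator)
            for row in self.rows.values()
            for cell in row.values()
        )


def dominant_consistency_filter(
    variants: Sequence[AnnotatedVariant],
    cohort: CohortDesign,
) -> tuple[list[AnnotatedVariant], list[tuple[AnnotatedVariant, str]]]:
    """Partition variants by control homozygosity.

    Returns ``(kept, excluded)`` where each excluded entry carries a reason
    naming the homozygous control sample. The two partitions are disjoint and
    cover the input.
    """
    controls = cohort.controls
    if not controls:
        logger.warning("dominant-consistency filter: no control samples; keeping all variants")
    kept: list[AnnotatedVariant] = []
    excluded: list[tuple[AnnotatedVariant, str]] = []
    for v in variants:
        hom = [s for s in controls if v.call(s).allele_count == 2]
        if hom:
            excluded.append(
                (v, f"homozygous in healthy control(s) {','.join(sorted(hom))}")
            )
        else:
            kept.append(v)
    return kept, excluded


@dataclass
class ScreenResult:
    table: CarrierTable
    rarity: dict[tuple[str, int, str, str], RarityClass]
    kept: list[AnnotatedVariant]
    excluded: list[tuple[AnnotatedVariant, str]]


def screen(
    candidates: Sequence[AnnotatedVariant],
    cohort: CohortDesign,
) -> ScreenResult:
    """Build the carrier table, classify rarity and apply the dominant rule.

    The denominator of each cell is the number of group samples with a
    defined genotype at that variant; samples with undefined genotypes are
    treated as untyped, which is how mixed control denominators arise.
    Groups with zero samples are omitted with a warning. Rarity is classified
    from the CONTROL frequency (unclassified when controls are absent).
    """
    if not candidates:
        raise ValueError("screen requires a nonempty candidate list")
    members = {g: cohort.ids(*_GROUP_MEMBERS[g]) for g in GROUPS}
    active_groups = tuple(g for g in GROUPS if members[g])
    for g in GROUPS:
        if not members[g]:
            logger.warning("screen: group %s has no samples; column omitted", g)

    table = CarrierTable(groups=active_groups)
    rarity: dict[tuple[str, int, str, str], RarityClass] = {}
    for v in sorted(candidates, key=lambda v: v.sort_key):
        row: dict[str, CarrierCell] = {}
        for g in active_groups:
            typed = [s for s in members[g] if not v.call(s).is_missing]
            if not typed:
                logger.warning("screen: %s has no typed %s samples", v.label, g)
                continue
            carriers = len(v.carriers(typed))
            row[g] = CarrierCell.from_counts(carriers, len(typed))
        table.rows[v.key] = row
        if "CONTROL" in row:
            rarity[v.key] = classify_rarity(row["CONTROL"].frequency)

    kept, excluded = dominant_consistency_filter(candidates, cohort)
    return ScreenResult(table=table, rarity=rarity, kept=kept, excluded=excluded)
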