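"""The variant-selection cascade.

Candidate variants for a dominantly inherited melanoma predisposition are
selected from a pedigree-structured exome cohort through an ordered funnel:

1. **quality gate** — keep variants whose exome-case genotypes are all
   defined and pass the genotype-level quality flag;
2. **cohort sharing** — Criteria 1 (carried by both members of the sibling
   pair plus at least one other exome case) and/or Criteria 2 (carried by at
   least two exome cases who are not the two members of one sibling pair);
3. **annotation selection** — the broad approach keeps all exonic variants,
   the stringent approach keeps exonic and intronic variants with at least
   one line of support (Ensembl high-quality call, any ClinVar record, or a
   damaging verdict from SIFT / PolyPhen-2 / MetaSVM / MetaLR);
4. **exclusions** — common variants (population allele frequency at or above
   the threshold in any selected population; an unknown frequency never
   excludes), synonymous variants, and all variants of genes harbouring at
   least ``max_variants_per_gene`` surviving variants;
5. **final selection** — variants carried by at least ``min_final_carriers``
   patients (exome plus screened cases) and supported by at least
   ``min_damaging_tools`` pathogenicity databases (a damaging predictor call
   or a pathogenic/likely-pathogenic ClinVar record each count as one).

Every step is monotone (output is a subset of input) and idempotent, and the
whole cascade is deterministic: outputs are sorted by (chrom, pos, ref, alt)
and no step uses randomness.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from melvar.model import (
    STRINGENT_PREDICTORS,
    AnnotatedVariant,
    ClinvarClass,
    CohortDesign,
    Consequence,
)

logger = logging.getLogger(__name__)

Variants = list[AnnotatedVariant]


class CriteriaMode(enum.Enum):
    CRITERIA1 = "criteria1"  # both siblings + >=1 other exome case
    CRITERIA2 = "criteria2"  # >=2 exome cases who are not one sibling pair
    UNION = "union"


class Approach(enum.Enum):
    BROAD = "broad"          # all exonic variants
    STRINGENT = "stringent"  # exonic+intronic with >=1 line of support
    UNION = "union"


@dataclass(frozen=True)
class CascadeConfig:
    """Tunable thresholds of the selection cascade.

    ``af_threshold`` is inclusive by default (frequency >= 1% excluded);
    ``keep_synonymous`` disables the synonymous exclusion for study designs
    where a recurrent synonymous variant is of interest.
    """

    criteria_mode: CriteriaMode = CriteriaMode.UNION
    approach: Approach = Approach.UNION
    af_threshold: float = 0.01
    af_inclusive: bool = True
    af_populations: tuple[str, ...] = ("global", "european")
    max_variants_per_gene: int = 4
    min_final_carriers: int = 3          # "present in more than two patients"
    min_damaging_tools: int = 1
    keep_synonymous: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.af_threshold < 1.0:
            raise ValueError("af_threshold must lie in (0, 1)")
        if self.min_final_carriers < 1:
            raise ValueError("min_final_carriers must be >= 1")
        if self.max_variants_per_gene < 1:
            raise ValueError("max_variants_per_gene must be >= 1")
        bad = set(self.af_populations) - {"global", "european"}
        if bad:
            raise ValueError(f"unknown population(s): {sorted(bad)}")


@dataclass
class FunnelReport:
    """Ordered per-step input/output variant counts."""

    steps: list[tuple[str, int, int]] = field(default_factory=list)

    def add(self, name: str, n_in: int, n_out: int) -> None:
        if n_out > n_in:
            raise ValueError(f"step {name!r}: output {n_out} exceeds input {n_in}")
        if self.steps and self.steps[-1][2] != n_in:
            raise ValueError(f"step {name!r}: input {n_in} does not chain")
        self.steps.append((name, n_in, n_out))

    def as_rows(self) -> list[dict]:
        return [{"step": s, "variants_in": i, "variants_out": o} for s, i, o in self.steps]


def _sorted(variants: Iterable[AnnotatedVariant]) -> Variants:
    return sorted(variants, key=lambda v: v.sort_key)


# ---------------------------------------------------------------------------
# individual steps
# ---------------------------------------------------------------------------

def quality_filter(variants: Sequence[AnnotatedVariant], cohort: CohortDesign) -> Variants:
    """Keep variants whose exome-case genotypes are all defined and pass QC."""
    wes = cohort.wes_cases
    kept = []
    for v in variants:
        calls = [v.call(s) for s in wes]
        if all(not c.is_missing and c.quality_pass for c in calls):
            kept.append(v)
    return _sorted(kept)


def sharing_filter(
    variants: Sequence[AnnotatedVariant],
    cohort: CohortDesign,
    mode: CriteriaMode = CriteriaMode.UNION,
) -> Variants:
    """Apply the cohort-sharing criteria over exome-case carriers."""
    pairs = cohort.sibling_pairs
    if mode in (CriteriaMode.CRITERIA1, CriteriaMode.UNION) and not pairs:
        if mode is CriteriaMode.CRITERIA1:
            raise ValueError("Criteria 1 requires a sibling pair in the cohort")
    wes = cohort.wes_cases

    def passes_c1(carriers: set[str]) -> bool:
        for a, b in pairs.values():
            if a in carriers and b in carriers and carriers - {a, b}:
                return True
        return False

    def passes_c2(carriers: set[str]) -> bool:
        carrier_list = sorted(carriers)
        for i, a in enumerate(carrier_list):
            for b in carrier_list[i + 1:]:
                if not cohort.are_siblings(a, b):
                    return True
        return False

    kept = []
    for v in variants:
        carriers = set(v.carriers(wes))
        ok1 = passes_c1(carriers) if pairs else False
        ok2 = passes_c2(carriers)
        if mode is CriteriaMode.CRITERIA1 and ok1:
            kept.append(v)
        elif mode is CriteriaMode.CRITERIA2 and ok2:
            kept.append(v)
        elif mode is CriteriaMode.UNION and (ok1 or ok2):
            kept.append(v)
    return _sorted(kept)


def annotation_selection(
    variants: Sequence[AnnotatedVariant],
    approach: Approach = Approach.UNION,
) -> Variants:
    """Broad (all exonic) and/or stringent (exonic+intronic with support) selection."""

    def broad(v: AnnotatedVariant) -> bool:
        return v.annotation.consequence.is_exonic

    def stringent(v: AnnotatedVariant) -> bool:
        ann = v.annotation
        if not (ann.consequence.is_exonic or ann.consequence is Consequence.INTRONIC):
            return False
        return (
            ann.ensembl_high_quality
            or ann.clinvar is not ClinvarClass.ABSENT
            or ann.n_damaging(STRINGENT_PREDICTORS) >= 1
        )

    if approach is Approach.BROAD:
        keep = broad
    elif approach is Approach.STRINGENT:
        keep = stringent
    else:
        def keep(v: AnnotatedVariant) -> bool:
            return broad(v) or stringent(v)

    return _sorted(v for v in variants if keep(v))


def exclude_common(
    variants: Sequence[AnnotatedVariant],
    af_threshold: float = 0.01,
    populations: tuple[str, ...] = ("global", "european"),
    inclusive: bool = True,
) -> Variants:
    """Drop variants common in ANY selected population; unknown AF never excludes."""
    if not 0.0 < af_threshold <= 1.0:
        raise ValueError("af_threshold must lie in (0, 1]")

    def is_common(v: AnnotatedVariant) -> bool:
        afs = []
        if "global" in populations:
            afs.append(v.annotation.af_global)
        if "european" in populations:
            afs.append(v.annotation.af_european)
        for af in afs:
            if af is None:
                continue
            if (af >= af_threshold) if inclusive else (af > af_threshold):
                return True
        return False

    return _sorted(v for v in variants if not is_common(v))


def exclude_synonymous(variants: Sequence[AnnotatedVariant]) -> Variants:
    return _sorted(
        v for v in variants
        if v.annotation.consequence is not Consequence.EXONIC_SYNONYMOUS
    )


def exclude_polyvariant_genes(
    variants: Sequence[AnnotatedVariant],
    max_variants_per_gene: int = 4,
) -> Variants:
    """Remove all variants of genes with >= ``max_variants_per_gene`` survivors.

    Counts are taken among the variants passed in (i.e. the survivors of the
    preceding steps), not genome-wide, so this step is order-sensitive with
    respect to the exclusions before it.
    """
    if max_variants_per_gene < 1:
        raise ValueError("max_variants_per_gene must be >= 1")
    counts: dict[str, int] = {}
    for v in variants:
        counts[v.gene] = counts.get(v.gene, 0) + 1
    return _sorted(v for v in variants if counts[v.gene] < max_variants_per_gene)


def select_candidates(
    variants: Sequence[AnnotatedVariant],
    cohort: CohortDesign,
    min_final_carriers: int = 3,
    min_damaging_tools: int = 1,
) -> Variants:
    """Final recurrence + pathogenicity selection.

    Carriers are counted over all patients (exome-sequenced plus screened
    MPM cases). Pathogenicity support counts damaging calls across the
    seven-predictor panel plus one vote for a pathogenic/likely-pathogenic
    ClinVar record.
    """
    patients = cohort.mpm_patients
    kept = []
    for v in variants:
        n_carriers = len(v.carriers(patients))
        support = v.annotation.n_damaging()
        if v.annotation.clinvar is ClinvarClass.PATHOGENIC_OR_LIKELY:
            support += 1
        if n_carriers >= min_final_carriers and support >= min_damaging_tools:
            kept.append(v)
    return _sorted(kept)


# ---------------------------------------------------------------------------
# full cascade
# ---------------------------------------------------------------------------

#: Canonical step order of the funnel.
STEP_NAMES = (
    "quality_filter",
    "sharing_filter",
    "annotation_selection",
    "exclude_common",
    "exclude_synonymous",
    "exclude_polyvariant_genes",
    "select_candidates",
)


def run_cascade(
    variants: Sequence[AnnotatedVariant],
    cohort: CohortDesign,
    config: Optional[CascadeConfig] = None,
) -> tuple[Variants, FunnelReport]:
    """Run the full selection cascade; returns (candidates, funnel report)."""
    config = config or CascadeConfig()
    funnel = FunnelReport()
    current = _sorted(variants)

    def step(name: str, fn) -> None:
        nonlocal current
        n_in = len(current)
        current = fn(current)
        funnel.add(name, n_in, len(current))
        logger.info("cascade %-26s %6d -> %6d", name, n_in, len(current))

    step("quality_filter", lambda vs: quality_filter(vs, cohort))
    step("sharing_filter", lambda vs: sharing_filter(vs, cohort, config.criteria_mode))
    step("annotation_selection", lambda vs: annotation_selection(vs, config.approach))
    step(
        "exclude_common",
        lambda vs: exclude_common(
            vs, config.af_threshold, config.af_populations, config.af_inclusive
        ),
    )
    if config.keep_synonymous:
        step("exclude_synonymous", lambda vs: _sorted(vs))
    else:
        step("exclude_synonymous", exclude_synonymous)
    step(
        "exclude_polyvariant_genes",
        lambda vs: exclude_polyvariant_genes(vs, config.max_variants_per_gene),
    )
    step(
        "select_candidates",
        lambda vs: select_candidates(
            vs, cohort, config.min_final_carriers, config.min_damaging_tools
        ),
    )
    return current, funnel
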