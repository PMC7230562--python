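"""Core domain model: variants, annotations, genotypes and cohort design.

Conventions
-----------
* Coordinates are 1-based; variants are bi-allelic after multi-allelic
  splitting, so ``(chrom, pos, ref, alt)`` is a unique key.
* A genotype allele count of ``None`` means the genotype is undefined
  (``./.`` in VCF); it is distinct from homozygous reference.
* Population allele frequencies are tri-state: a ``None`` frequency is
  *unknown* and is never coerced to 0 — rare, previously unobserved variants
  typically have no database entry, and treating absence as zero would
  silently change filter semantics.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional


class Consequence(enum.Enum):
    """Collapsed functional consequence class of a variant."""

    EXONIC_MISSENSE = "exonic_missense"
    EXONIC_SYNONYMOUS = "exonic_synonymous"
    EXONIC_OTHER = "exonic_other"
    INTRONIC = "intronic"
    OTHER = "other"

    @property
    def is_exonic(self) -> bool:
        return self in (
            Consequence.EXONIC_MISSENSE,
            Consequence.EXONIC_SYNONYMOUS,
            Consequence.EXONIC_OTHER,
        )


class PredictorCall(enum.Enum):
    """Verdict of one in-silico pathogenicity predictor."""

    DAMAGING = "damaging"
    TOLERATED = "tolerated"
    UNKNOWN = "unknown"


class ClinvarClass(enum.Enum):
    """Collapsed ClinVar clinical significance."""

    PATHOGENIC_OR_LIKELY = "pathogenic_or_likely"
    UNCERTAIN = "uncertain"
    BENIGN_OR_LIKELY = "benign_or_likely"
    ABSENT = "absent"


class SampleGroup(enum.Enum):
    """Role of a sample in the study design."""

    WES_CASE = "WES_CASE"            # exome-sequenced multiple-primary-melanoma case
    MPM_SCREEN = "MPM_SCREEN"        # additional MPM case screened for candidates
    FAMILIAL_INDEX = "FAMILIAL_INDEX"  # index case of a familial-melanoma family
    HEALTHY_CONTROL = "HEALTHY_CONTROL"


#: The seven-predictor panel consumed by the cascade, in canonical order.
PREDICTOR_PANEL = (
    "SIFT",
    "PolyPhen2",
    "MetaSVM",
    "MetaLR",
    "Provean",
    "MutationTaster",
    "FATHMM",
)

#: Predictors whose damaging call qualifies a variant for the stringent
#: annotation-selection approach.
STRINGENT_PREDICTORS = ("SIFT", "PolyPhen2", "MetaSVM", "MetaLR")


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's genotype at one variant.

    ``allele_count`` is the number of alternate alleles (0, 1 or 2) or
    ``None`` when the genotype is undefined. ``quality_pass`` is the
    genotype-level quality flag; it is irrelevant when the genotype is
    undefined.
    """

    sample_id: str
    allele_count: Optional[int]
    quality_pass: bool = True

    def __post_init__(self) -> None:
        if self.allele_count is not None and self.allele_count not in (0, 1, 2):
            raise ValueError(
                f"allele_count must be 0, 1, 2 or None; got {self.allele_count!r}"
            )

    @property
    def is_missing(self) -> bool:
        return self.allele_count is None

    @property
    def is_carrier(self) -> bool:
        """Carrier = at least one alternate allele (het or hom)."""
        return self.allele_count is not None and self.allele_count >= 1


@dataclass(frozen=True)
class AnnotationBundle:
    """Annotation payload of one variant (annotations are inputs, never computed)."""

    consequence: Consequence = Consequence.OTHER
    af_global: Optional[float] = None
    af_european: Optional[float] = None
    predictor_calls: Mapping[str, PredictorCall] = field(default_factory=dict)
    clinvar: ClinvarClass = ClinvarClass.ABSENT
    ensembl_high_quality: bool = False

    def __post_init__(self) -> None:
        for name, value in (("af_global", self.af_global), ("af_european", self.af_european)):
            if value is not None and not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1] or be None; got {value!r}")
        unknown = set(self.predictor_calls) - set(PREDICTOR_PANEL)
        if unknown:
            raise ValueError(f"unknown predictor name(s): {sorted(unknown)}")

    def predictor(self, name: str) -> PredictorCall:
        return self.predictor_calls.get(name, PredictorCall.UNKNOWN)

    def n_damaging(self, panel: Iterable[str] = PREDICTOR_PANEL) -> int:
        """Number of damaging calls among ``panel``."""
        return sum(1 for p in panel if self.predictor(p) is PredictorCall.DAMAGING)


_CHROM_ORDER = {str(i): i for i in range(1, 23)}
_CHROM_ORDER.update({"X": 23, "Y": 24, "MT": 25, "M": 25})


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    """Natural chromosome ordering: 1..22, X, Y, MT, then lexicographic."""
    name = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return (_CHROM_ORDER.get(name, 99), name)


@dataclass
class AnnotatedVariant:
    """One bi-allelic, annotated variant with per-sample genotype calls."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    hgvs_c: str = ""
    hgvs_p: str = ""
    annotation: AnnotationBundle = field(default_factory=AnnotationBundle)
    genotypes: dict[str, GenotypeCall] = field(default_factory=dict)
    validated: bool = False  # orthogonal confirmation flag (e.g. Sanger)

    def __post_init__(self) -> None:
        if not re.fullmatch(r"[ACGTN]+", self.ref) or not re.fullmatch(r"[ACGTN*]+", self.alt):
            raise ValueError(f"malformed alleles {self.ref!r}>{self.alt!r}")
        if "," in self.alt:
            raise ValueError("AnnotatedVariant must be bi-allelic (single ALT)")
        for sid, call in self.genotypes.items():
            if call.sample_id != sid:
                raise ValueError(f"genotype keyed {sid!r} but call names {call.sample_id!r}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def sort_key(self) -> tuple[tuple[int, str], int, str, str]:
        return (chrom_sort_key(self.chrom), self.pos, self.ref, self.alt)

    @property
    def label(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"

    def call(self, sample_id: str) -> GenotypeCall:
        return self.genotypes.get(sample_id, GenotypeCall(sample_id, None))

    def carriers(self, sample_ids: Iterable[str]) -> list[str]:
        """Sample ids among ``sample_ids`` carrying >=1 alternate allele."""
        return [s for s in sample_ids if self.call(s).is_carrier]


@dataclass(frozen=True)
class Sample:
    sample_id: str
    group: SampleGroup
    sibling_pair_id: Optional[str] = None


class CohortError(ValueError):
    """Invalid cohort design."""


@dataclass
class CohortDesign:
    """Sample roles and sibling-pair structure of the cohort.

    Invariants enforced at construction: sample ids are unique, and any
    sibling-pair id is shared by exactly two exome-sequenced cases.
    """

    samples: list[Sample]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortError(f"duplicate sample_id(s): {dupes}")
        pairs: dict[str, list[Sample]] = {}
        for s in self.samples:
            if s.sibling_pair_id is not None:
                pairs.setdefault(s.sibling_pair_id, []).append(s)
        for pid, members in pairs.items():
            if len(members) != 2:
                raise CohortError(
                    f"sibling_pair_id {pid!r} used by {len(members)} samples (expected 2)"
                )
            if any(m.group is not SampleGroup.WES_CASE for m in members):
                raise CohortError(f"sibling_pair_id {pid!r} assigned to a non-WES-case sample")

    # -- group accessors -------------------------------------------------
    def ids(self, *groups: SampleGroup) -> list[str]:
        want = set(groups) if groups else set(SampleGroup)
        return [s.sample_id for s in self.samples if s.group in want]

    @property
    def wes_cases(self) -> list[str]:
        return self.ids(SampleGroup.WES_CASE)

    @property
    def screened_cases(self) -> list[str]:
        return self.ids(SampleGroup.MPM_SCREEN)

    @property
    def mpm_patients(self) -> list[str]:
        """All MPM cases: exome-sequenced plus screened."""
        return self.ids(SampleGroup.WES_CASE, SampleGroup.MPM_SCREEN)

    @property
    def indexes(self) -> list[str]:
        return self.ids(SampleGroup.FAMILIAL_INDEX)

    @property
    def controls(self) -> list[str]:
        return self.ids(SampleGroup.HEALTHY_CONTROL)

    @property
    def sibling_pairs(self) -> dict[str, tuple[str, str]]:
        pairs: dict[str, list[str]] = {}
        for s in self.samples:
            if s.sibling_pair_id is not None:
                pairs.setdefault(s.sibling_pair_id, []).append(s.sample_id)
        return {pid: (m[0], m[1]) for pid, m in pairs.items()}

    def are_siblings(self, a: str, b: str) -> bool:
        for m in self.sibling_pairs.values():
            if {a, b} == set(m):
                return True
        return False

    def __len__(self) -> int:
        return len(self.samples)
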