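"""Synthetic annotated-cohort generation and case/control genotype simulators.

The cohort generator emulates the statistical structure the prioritization
cascade assumes: a small set of exome-sequenced melanoma cases containing one
sibling pair, additional screened cases, familial-melanoma index cases and
healthy population controls; a background of common polymorphisms and rare
variants; and a set of *planted* variants whose genotype sharing patterns,
annotations and population frequencies realize known fates in the cascade.
Every planted (and decoy) variant is listed in a truth table naming the step
at which it should survive or fall, which turns the full pipeline into a
closed-loop test with precision and recall both expected to be 1.

Background variants are constructed so they cannot masquerade as candidates:
common polymorphisms carry their true (above-threshold) allele frequency and
are removed by the frequency exclusion, while rare background variants are
drawn with at most one exome-case carrier so they can never satisfy the
sharing criteria. This is a structural property of the generator, not a
filter: the generator defines ground truth, and the truth table records it.

All randomness flows through one seeded NumPy generator; a fixed
configuration and seed give byte-identical output files.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from melvar.model import (
    PREDICTOR_PANEL,
    AnnotatedVariant,
    AnnotationBundle,
    ClinvarClass,
    CohortDesign,
    Consequence,
    GenotypeCall,
    PredictorCall,
    Sample,
    SampleGroup,
)
from melvar.vcfio import AnnotationDialect, write_sample_sheet, write_vcf


class SharingPattern(enum.Enum):
    SIBS_PLUS_ONE = "SIBS_PLUS_ONE"  # both siblings + one other exome case
    TWO_NONSIB = "TWO_NONSIB"        # two unrelated exome cases
    SIBS_ONLY = "SIBS_ONLY"          # both siblings, nobody else (fails both criteria)


@dataclass(frozen=True)
class PlantedVariant:
    """Specification of one deliberately constructed variant."""

    name: str
    pattern: SharingPattern
    consequence: Consequence = Consequence.EXONIC_MISSENSE
    damaging_tools: tuple[str, ...] = ("SIFT", "PolyPhen2")
    af_global: Optional[float] = None       # None = unknown to the databases
    af_european: Optional[float] = None
    n_screen_carriers: int = 2              # extra carriers among screened cases
    n_index_carriers: int = 0
    n_control_carriers: int = 1
    control_hom: bool = False               # plant one homozygous control
    quality_fail: bool = False              # one exome-case genotype undefined
    ensembl_high_quality: bool = True
    gene: Optional[str] = None              # defaults to the variant name
    expected_fate: str = "kept"             # "kept" or the dropping step name


def default_planted() -> tuple[PlantedVariant, ...]:
    """Eight true candidates plus decoys pinned to each cascade step."""
    kept = tuple(
        PlantedVariant(
            name=f"CAND{i}",
            pattern=(SharingPattern.SIBS_PLUS_ONE if i % 2 else SharingPattern.TWO_NONSIB),
            damaging_tools=("SIFT",) if i % 3 == 0 else ("SIFT", "PolyPhen2"),
            af_global=None if i % 2 else 0.001,
            n_screen_carriers=1 + i % 3,
            n_control_carriers=i % 3,
        )
        for i in range(1, 9)
    )
    decoys = (
        PlantedVariant(
            name="DQUAL", pattern=SharingPattern.SIBS_PLUS_ONE, quality_fail=True,
            expected_fate="quality_filter",
        ),
        PlantedVariant(
            name="DSHARE", pattern=SharingPattern.SIBS_ONLY, n_screen_carriers=0,
            expected_fate="sharing_filter",
        ),
        PlantedVariant(
            name="DANNO", pattern=SharingPattern.TWO_NONSIB,
            consequence=Consequence.INTRONIC, damaging_tools=(),
            ensembl_high_quality=False, expected_fate="annotation_selection",
        ),
        PlantedVariant(
            name="DCOMMON", pattern=SharingPattern.TWO_NONSIB, af_global=0.02,
            expected_fate="exclude_common",
        ),
        PlantedVariant(
            name="DSYN", pattern=SharingPattern.SIBS_PLUS_ONE,
            consequence=Consequence.EXONIC_SYNONYMOUS,
            expected_fate="exclude_synonymous",
        ),
        # four shared damaging variants in one gene: all fall together
        *(
            PlantedVariant(
                name=f"DPOLY{k}", gene="DPOLYGENE", pattern=SharingPattern.TWO_NONSIB,
                expected_fate="exclude_polyvariant_genes",
            )
            for k in range(1, 5)
        ),
        PlantedVariant(
            name="DFEWCARR", pattern=SharingPattern.TWO_NONSIB, n_screen_carriers=0,
            expected_fate="select_candidates",
        ),
        PlantedVariant(
            name="DNODMG", pattern=SharingPattern.TWO_NONSIB, damaging_tools=(),
            expected_fate="select_candidates",
        ),
    )
    return kept + decoys


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort sizes, background model and planted-variant roster.

    The default cohort mirrors the study design the pipeline targets: 8
    exome-sequenced cases including one sibling pair, 18 screened cases, 37
    familial indexes and 100 healthy controls. Background polymorphism
    minor-allele fractions are drawn from a Beta(0.5, 3) truncated to
    [0.01, 0.5]; rare background fractions are uniform on [0.001, 0.009],
    exercising both sides of the 1% frequency filter.
    """

    n_wes_cases: int = 8
    n_screen_cases: int = 18
    n_indexes: int = 37
    n_controls: int = 100
    n_background_variants: int = 500
    rare_background_fraction: float = 0.3
    predictor_noise_rate: float = 0.1  # per-tool chance of a spurious damaging call
    planted: tuple[PlantedVariant, ...] = field(default_factory=default_planted)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_wes_cases < 3:
            raise ValueError("need >= 3 exome cases (a sibling pair plus one more)")
        for n in (self.n_screen_cases, self.n_indexes, self.n_controls,
                  self.n_background_variants):
            if n < 0:
                raise ValueError("cohort sizes must be >= 0")
        names = [p.name for p in self.planted]
        if len(names) != len(set(names)):
            raise ValueError("planted variant names must be unique")
        for p in self.planted:
            if p.n_screen_carriers > self.n_screen_cases:
                raise ValueError(f"{p.name}: more screened carriers than screened cases")
            if p.n_index_carriers > self.n_indexes:
                raise ValueError(f"{p.name}: more index carriers than indexes")
            if p.n_control_carriers + int(p.control_hom) > self.n_controls:
                raise ValueError(f"{p.name}: more control carriers than controls")


@dataclass
class TruthRecord:
    key: tuple[str, int, str, str]
    name: str
    pattern: str
    expected_fate: str


@dataclass
class TruthTable:
    records: list[TruthRecord]

    @property
    def kept_keys(self) -> set[tuple[str, int, str, str]]:
        return {r.key for r in self.records if r.expected_fate == "kept"}

    def write(self, path: str | Path) -> None:
        lines = ["chrom\tpos\tref\talt\tname\tpattern\texpected_fate"]
        for r in self.records:
            lines.append(
                f"{r.key[0]}\t{r.key[1]}\t{r.key[2]}\t{r.key[3]}\t"
                f"{r.name}\t{r.pattern}\t{r.expected_fate}"
            )
        Path(path).write_text("\n".join(lines) + "\n")


def build_cohort(config: SimulationConfig) -> CohortDesign:
    samples = [
        Sample("WES01", SampleGroup.WES_CASE, "SP1"),
        Sample("WES02", SampleGroup.WES_CASE, "SP1"),
    ]
    samples += [
        Sample(f"WES{i:02d}", SampleGroup.WES_CASE)
        for i in range(3, config.n_wes_cases + 1)
    ]
    samples += [
        Sample(f"SCR{i:02d}", SampleGroup.MPM_SCREEN)
        for i in range(1, config.n_screen_cases + 1)
    ]
    samples += [
        Sample(f"IDX{i:02d}", SampleGroup.FAMILIAL_INDEX)
        for i in range(1, config.n_indexes + 1)
    ]
    samples += [
        Sample(f"CTL{i:03d}", SampleGroup.HEALTHY_CONTROL)
        for i in range(1, config.n_controls + 1)
    ]
    return CohortDesign(samples)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

_BASES = ("A", "C", "G", "T")


def _planted_variant(
    spec: PlantedVariant,
    cohort: CohortDesign,
    chrom: str,
    pos: int,
    rng: np.random.Generator,
) -> AnnotatedVariant:
    ref, alt = rng.choice(_BASES, size=2, replace=False)
    wes = cohort.wes_cases
    sib_a, sib_b = cohort.sibling_pairs["SP1"]
    non_sib = [s for s in wes if s not in (sib_a, sib_b)]

    carriers: set[str] = set()
    if spec.pattern is SharingPattern.SIBS_PLUS_ONE:
        carriers |= {sib_a, sib_b, non_sib[int(rng.integers(len(non_sib)))]}
    elif spec.pattern is SharingPattern.SIBS_ONLY:
        carriers |= {sib_a, sib_b}
    else:
        pick = rng.choice(len(non_sib), size=2, replace=False)
        carriers |= {non_sib[pick[0]], non_sib[pick[1]]}
    carriers |= set(
        np.array(cohort.screened_cases)[
            rng.choice(len(cohort.screened_cases), size=spec.n_screen_carriers,
                       replace=False)
        ]
    ) if spec.n_screen_carriers else set()
    carriers |= set(
        np.array(cohort.indexes)[
            rng.choice(len(cohort.indexes), size=spec.n_index_carriers, replace=False)
        ]
    ) if spec.n_index_carriers else set()
    controls = cohort.controls
    ctl_pick = rng.choice(
        len(controls),
        size=spec.n_control_carriers + int(spec.control_hom),
        replace=False,
    )
    hom_control = controls[ctl_pick[0]] if spec.control_hom else None
    het_controls = {
        controls[i] for i in ctl_pick[int(spec.control_hom):]
    }
    carriers |= het_controls

    genotypes: dict[str, GenotypeCall] = {}
    for sid in (s.sample_id for s in cohort.samples):
        if sid == hom_control:
            genotypes[sid] = GenotypeCall(sid, 2)
        elif sid in carriers:
            genotypes[sid] = GenotypeCall(sid, 1)
        else:
            genotypes[sid] = GenotypeCall(sid, 0)
    if spec.quality_fail:
        victim = sorted(carriers & set(wes))[0]
        genotypes[victim] = GenotypeCall(victim, None)

    predictor_calls = {t: PredictorCall.DAMAGING for t in spec.damaging_tools}
    for t in PREDICTOR_PANEL:
        predictor_calls.setdefault(t, PredictorCall.TOLERATED)
    gene = spec.gene or spec.name
    return AnnotatedVariant(
        chrom=chrom,
        pos=pos,
        ref=str(ref),
        alt=str(alt),
        gene=gene,
        hgvs_c=f"c.{pos % 1000 + 1}{ref}>{alt}",
        hgvs_p="p.?" if spec.consequence is not Consequence.EXONIC_SYNONYMOUS else "p.=",
        annotation=AnnotationBundle(
            consequence=spec.consequence,
            af_global=spec.af_global,
            af_european=spec.af_european,
            predictor_calls=predictor_calls,
            clinvar=ClinvarClass.ABSENT,
            ensembl_high_quality=spec.ensembl_high_quality,
        ),
        genotypes=genotypes,
    )


def _background_variant(
    cohort: CohortDesign,
    chrom: str,
    pos: int,
    rare: bool,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> AnnotatedVariant:
    ref, alt = rng.choice(_BASES, size=2, replace=False)
    sample_ids = [s.sample_id for s in cohort.samples]
    wes = set(cohort.wes_cases)

    if rare:
        maf = float(rng.uniform(0.001, 0.009))
        af_global = None if rng.random() < 0.5 else maf
    else:
        maf = float(np.clip(rng.beta(0.5, 3.0), 0.01, 0.5))
        af_global = maf
    counts = rng.binomial(2, maf, size=len(sample_ids))

    if rare:
        # structural guarantee: rare background never satisfies the sharing
        # criteria — at most one exome-case carrier
        wes_idx = [i for i, s in enumerate(sample_ids) if s in wes]
        carriers = [i for i in wes_idx if counts[i] > 0]
        for i in carriers[1:]:
            counts[i] = 0

    consequence = rng.choice(
        np.array(
            [
                Consequence.EXONIC_MISSENSE,
                Consequence.EXONIC_SYNONYMOUS,
                Consequence.INTRONIC,
                Consequence.OTHER,
            ],
            dtype=object,
        ),
        p=[0.35, 0.2, 0.3, 0.15],
    )
    predictor_calls = {}
    for tool in PREDICTOR_PANEL:
        u = rng.random()
        if u < config.predictor_noise_rate:
            predictor_calls[tool] = PredictorCall.DAMAGING
        elif u < 0.7:
            predictor_calls[tool] = PredictorCall.TOLERATED
        else:
            predictor_calls[tool] = PredictorCall.UNKNOWN

    genotypes = {
        sid: GenotypeCall(sid, int(c)) for sid, c in zip(sample_ids, counts)
    }
    gene = f"BG{pos % 100000:05d}"
    return AnnotatedVariant(
        chrom=chrom,
        pos=pos,
        ref=str(ref),
        alt=str(alt),
        gene=gene,
        hgvs_c=f"c.{pos % 1000 + 1}{ref}>{alt}",
        hgvs_p="",
        annotation=AnnotationBundle(
            consequence=consequence,
            af_global=af_global,
            af_european=af_global,
            predictor_calls=predictor_calls,
            clinvar=ClinvarClass.ABSENT,
            ensembl_high_quality=bool(rng.random() < 0.5),
        ),
        genotypes=genotypes,
    )


def generate(
    config: SimulationConfig,
    out_dir: str | Path,
    dialect: Optional[AnnotationDialect] = None,
) -> tuple[Path, Path, TruthTable]:
    """Write VCF + sample sheet + truth table; returns their paths/table.

    Deterministic under ``config.seed``: the same configuration and seed
    produce byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    cohort = build_cohort(config)

    n_total = config.n_background_variants + len(config.planted)
    chroms = rng.integers(1, 23, size=n_total)
    positions = rng.choice(np.arange(10_000, 5_000_000), size=n_total, replace=False)

    variants: list[AnnotatedVariant] = []
    records: list[TruthRecord] = []
    n_rare = int(round(config.n_background_variants * config.rare_background_fraction))
    for i in range(config.n_background_variants):
        variants.append(
            _background_variant(
                cohort, str(chroms[i]), int(positions[i]), rare=(i < n_rare),
                config=config, rng=rng,
            )
        )
    for j, spec in enumerate(config.planted):
        idx = config.n_background_variants + j
        v = _planted_variant(spec, cohort, str(chroms[idx]), int(positions[idx]), rng)
        variants.append(v)
        records.append(
            TruthRecord(
                key=v.key, name=spec.name, pattern=spec.pattern.value,
                expected_fate=spec.expected_fate,
            )
        )

    vcf_path = out_dir / "cohort.vcf"
    sheet_path = out_dir / "samples.tsv"
    write_vcf(variants, [s.sample_id for s in cohort.samples], vcf_path, dialect)
    write_sample_sheet(cohort, sheet_path)
    truth = TruthTable(records)
    truth.write(out_dir / "truth.tsv")
    return vcf_path, sheet_path, truth


# ---------------------------------------------------------------------------
# genotype/phenotype simulators for test calibration
# ---------------------------------------------------------------------------

def simulate_null_case_control(
    n_case: int,
    n_ctrl: int,
    m: int,
    mafs: Sequence[float],
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Genotypes independent of phenotype: G ~ Binomial(2, maf), y fixed labels."""
    mafs = np.asarray(mafs, dtype=float)
    if mafs.shape != (m,):
        raise ValueError("mafs must have length m")
    if np.any(mafs <= 0) or np.any(mafs > 0.5):
        raise ValueError("mafs must lie in (0, 0.5]")
    rng = np.random.default_rng(seed)
    G = rng.binomial(2, mafs, size=(n_case + n_ctrl, m)).astype(float)
    y = np.r_[np.ones(n_case), np.zeros(n_ctrl)]
    return G, y


def simulate_effect_case_control(
    n_case: int,
    n_ctrl: int,
    m: int,
    mafs: Sequence[float],
    odds_ratios: Sequence[float],
    seed: int = 0,
    prevalence: float = 0.1,
    batch: int = 4096,
) -> tuple[np.ndarray, np.ndarray]:
    """Retrospective sampling under a logistic disease model.

    Population genotypes are drawn at the stated minor-allele fractions,
    disease status follows ``logit P(y=1|g) = alpha + sum_j log(OR_j) g_j``
    with ``alpha`` set so the genotype-free disease probability equals
    ``prevalence``, and cases/controls are accumulated until both groups are
    full (case-control ascertainment).
    """
    mafs = np.asarray(mafs, dtype=float)
    log_or = np.log(np.asarray(odds_ratios, dtype=float))
    if mafs.shape != (m,) or log_or.shape != (m,):
        raise ValueError("mafs and odds_ratios must have length m")
    if np.any(mafs <= 0) or np.any(mafs > 0.5):
        raise ValueError("mafs must lie in (0, 0.5]")
    rng = np.random.default_rng(seed)
    alpha = np.log(prevalence / (1.0 - prevalence))

    cases: list[np.ndarray] = []
    ctrls: list[np.ndarray] = []
    n_case_have = n_ctrl_have = 0
    while n_case_have < n_case or n_ctrl_have < n_ctrl:
        G = rng.binomial(2, mafs, size=(batch, m)).astype(float)
        eta = alpha + G @ log_or
        disease = rng.random(batch) < 1.0 / (1.0 + np.exp(-eta))
        if n_case_have < n_case:
            take = G[disease][: n_case - n_case_have]
            cases.append(take)
            n_case_have += len(take)
        if n_ctrl_have < n_ctrl:
            take = G[~disease][: n_ctrl - n_ctrl_have]
            ctrls.append(take)
            n_ctrl_have += len(take)
    G = np.vstack([np.vstack(cases), np.vstack(ctrls)])
    y = np.r_[np.ones(n_case), np.zeros(n_ctrl)]
    return G, y
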