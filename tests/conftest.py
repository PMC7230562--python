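"""Shared fixtures: the published carrier-count screening table and a
genotype-level reconstruction of it, plus small cohort helpers."""

from __future__ import annotations

import numpy as np
import pytest

from melvar.model import (
    AnnotatedVariant,
    AnnotationBundle,
    CohortDesign,
    Consequence,
    GenotypeCall,
    PredictorCall,
    Sample,
    SampleGroup,
)

# ---------------------------------------------------------------------------
# The candidate-variant screening table: 13 validated variants with carrier
# counts over 26 MPM patients, 37 familial indexes and 100-300 healthy
# controls. BMX and CFAP47 (chromosome X) were observed homozygous in a
# healthy control and are therefore excluded by the dominant-consistency rule.
# Layout per row: gene, hgvs_c, hgvs_p, chrom,
#                 (MPM carriers, n), (index carriers, n), (control carriers, n),
#                 expected percent strings for the three groups.
# ---------------------------------------------------------------------------
TABLE1 = [
    ("NTN4", "c.1182C>T", "p.Pro394=", "12", (4, 26), (0, 37), (5, 200),
     (15.4, 0.0, 2.5)),
    ("MTCL1", "c.4315G>A", "p.Gly1439Ser", "18", (5, 26), (2, 37), (4, 100),
     (19.2, 5.4, 4.0)),
    ("MAP2K3", "c.77G>C", "p.Arg26Thr", "17", (22, 26), (33, 37), (92, 100),
     (84.6, 89.2, 92.0)),
    ("CAND2", "c.992A>T", "p.Glu331Val", "3", (3, 26), (1, 37), (3, 100),
     (11.5, 2.7, 3.0)),
    ("RPL32", "c.98G>A", "p.Arg33His", "3", (3, 26), (1, 37), (2, 100),
     (11.5, 2.7, 2.0)),
    ("FNDC1", "c.3332G>A", "p.Asp1112Asn", "6", (3, 26), (1, 37), (5, 100),
     (11.5, 2.7, 5.0)),
    ("CDH23", "c.1096G>A", "p.Ala366Thr", "10", (2, 26), (0, 37), (2, 300),
     (7.7, 0.0, 0.7)),
    ("CFAP47", "c.4589A>C", "p.His1530Pro", "X", (3, 26), (2, 37), (3, 100),
     (11.5, 5.4, 3.0)),
    ("BMX", "c.851C>T", "p.Ser284Leu", "X", (3, 26), (1, 37), (1, 100),
     (11.5, 2.7, 1.0)),
    ("ITIH3", "c.1130G>A", "p.Arg377Gln", "3", (4, 26), (0, 37), (2, 100),
     (15.4, 0.0, 2.0)),
    ("RNF213", "c.2122C>G", "p.His708Asp", "17", (4, 26), (2, 37), (3, 100),
     (15.4, 5.4, 3.0)),
    ("ARHGEF40", "c.2500C>T", "p.Arg834Cys", "14", (3, 26), (0, 37), (0, 100),
     (11.5, 0.0, 0.0)),
    ("BRD9", "c.183G>C", "p.Glu61Asp", "5", (4, 26), (0, 37), (0, 100),
     (15.4, 0.0, 0.0)),
]

#: Genes excluded for homozygosity in a healthy control.
HOM_EXCLUDED = ("BMX", "CFAP47")

#: The three rare candidates (control carrier frequency below 1%).
RARE_GENES = ("CDH23", "ARHGEF40", "BRD9")

#: The seven genes entering the aggregation analysis.
AGGREGATION_GENES = ("NTN4", "MTCL1", "CAND2", "RPL32", "FNDC1", "ITIH3", "RNF213")


@pytest.fixture(scope="session")
def table1_rows():
    return TABLE1


@pytest.fixture(scope="session")
def screen_cohort() -> CohortDesign:
    """8 exome cases (one sibling pair) + 18 screened + 37 indexes + 300 controls."""
    samples = [
        Sample("WES01", SampleGroup.WES_CASE, "SP1"),
        Sample("WES02", SampleGroup.WES_CASE, "SP1"),
    ]
    samples += [Sample(f"WES{i:02d}", SampleGroup.WES_CASE) for i in range(3, 9)]
    samples += [Sample(f"SCR{i:02d}", SampleGroup.MPM_SCREEN) for i in range(1, 19)]
    samples += [Sample(f"IDX{i:02d}", SampleGroup.FAMILIAL_INDEX) for i in range(1, 38)]
    samples += [Sample(f"CTL{i:03d}", SampleGroup.HEALTHY_CONTROL) for i in range(1, 301)]
    return CohortDesign(samples)


@pytest.fixture(scope="session")
def table1_variants(screen_cohort) -> list[AnnotatedVariant]:
    """Genotype-level encoding of the screening table.

    Carriers are heterozygous and assigned to the leading samples of each
    group; control genotypes beyond a variant's denominator are undefined
    (untyped), which reproduces the mixed 100/200/300 denominators. For the
    two excluded genes the first control carrier is homozygous.
    """
    mpm_ids = screen_cohort.mpm_patients
    idx_ids = screen_cohort.indexes
    ctl_ids = screen_cohort.controls
    variants = []
    for pos, (gene, hgvs_c, hgvs_p, chrom, mpm, idx, ctl, _pct) in enumerate(
        TABLE1, start=1
    ):
        genotypes: dict[str, GenotypeCall] = {}
        for k, (ids, (carriers, denom)) in enumerate(
            [(mpm_ids, mpm), (idx_ids, idx), (ctl_ids, ctl)]
        ):
            for i, sid in enumerate(ids):
                if i >= denom:
                    genotypes[sid] = GenotypeCall(sid, None)
                elif i < carriers:
                    hom = gene in HOM_EXCLUDED and k == 2 and i == 0
                    genotypes[sid] = GenotypeCall(sid, 2 if hom else 1)
                else:
                    genotypes[sid] = GenotypeCall(sid, 0)
        variants.append(
            AnnotatedVariant(
                chrom=chrom,
                pos=1000 + pos,
                ref="A",
                alt="G",
                gene=gene,
                hgvs_c=hgvs_c,
                hgvs_p=hgvs_p,
                annotation=AnnotationBundle(
                    consequence=(
                        Consequence.EXONIC_SYNONYMOUS
                        if hgvs_p.endswith("=")
                        else Consequence.EXONIC_MISSENSE
                    ),
                    predictor_calls={"SIFT": PredictorCall.DAMAGING},
                ),
                genotypes=genotypes,
                validated=True,
            )
        )
    return variants


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
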