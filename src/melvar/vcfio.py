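"""Reading and writing the pipeline's file formats.

Input is a multi-sample VCF 4.2 whose functional annotations live either in a
VEP-style ``CSQ`` transcript string (the default dialect) or in a tabular
sidecar file; the mapping from annotation subfields to the internal
:class:`~melvar.model.AnnotationBundle` is configurable through
:class:`AnnotationDialect`. Multi-allelic records are split into bi-allelic
variants, alleles are taken as recorded (left-normalized input assumed), and
``./.`` genotypes become undefined calls.

Predictor verdicts and ClinVar significance arrive as tool-specific
vocabulary; the fixed mapping tables below collapse them onto the tri-state
damaging / tolerated / unknown and the four-level ClinVar scale. The tables
are deliberately explicit because no common cutoff convention exists across
tools.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from cyvcf2 import VCF

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
    chrom_sort_key,
)

logger = logging.getLogger(__name__)


class VcfParseError(ValueError):
    """Malformed VCF content; the message names the offending line."""


class SampleSheetError(ValueError):
    """Malformed sample sheet."""


# ---------------------------------------------------------------------------
# vocabulary mappings
# ---------------------------------------------------------------------------

#: VEP-style consequence terms collapsed onto the internal classes.
CONSEQUENCE_TERMS: dict[str, Consequence] = {
    "missense_variant": Consequence.EXONIC_MISSENSE,
    "synonymous_variant": Consequence.EXONIC_SYNONYMOUS,
    "stop_gained": Consequence.EXONIC_OTHER,
    "stop_lost": Consequence.EXONIC_OTHER,
    "start_lost": Consequence.EXONIC_OTHER,
    "frameshift_variant": Consequence.EXONIC_OTHER,
    "inframe_insertion": Consequence.EXONIC_OTHER,
    "inframe_deletion": Consequence.EXONIC_OTHER,
    "coding_sequence_variant": Consequence.EXONIC_OTHER,
    "intron_variant": Consequence.INTRONIC,
    "splice_region_variant": Consequence.INTRONIC,
    # internal enum values accepted verbatim
    **{c.value: c for c in Consequence},
}

#: Per-tool damaging/tolerated vocabularies (lower-cased tokens).
_DAMAGING_TOKENS: dict[str, set[str]] = {
    "SIFT": {"deleterious", "deleterious_low_confidence", "d", "damaging"},
    "PolyPhen2": {"probably_damaging", "possibly_damaging", "d", "p", "damaging"},
    "MetaSVM": {"d", "damaging", "deleterious"},
    "MetaLR": {"d", "damaging", "deleterious"},
    "Provean": {"d", "deleterious", "damaging"},
    "MutationTaster": {"a", "d", "disease_causing", "disease_causing_automatic", "damaging"},
    "FATHMM": {"d", "deleterious", "damaging"},
}
_TOLERATED_TOKENS: dict[str, set[str]] = {
    "SIFT": {"tolerated", "tolerated_low_confidence", "t"},
    "PolyPhen2": {"benign", "b", "tolerated"},
    "MetaSVM": {"t", "tolerated", "benign"},
    "MetaLR": {"t", "tolerated", "benign"},
    "Provean": {"n", "neutral", "tolerated"},
    "MutationTaster": {"n", "p", "polymorphism", "polymorphism_automatic", "tolerated"},
    "FATHMM": {"t", "tolerated", "benign"},
}

_CLINVAR_PATHOGENIC = {"pathogenic", "likely_pathogenic", "pathogenic/likely_pathogenic",
                       "pathogenic_or_likely"}
_CLINVAR_BENIGN = {"benign", "likely_benign", "benign/likely_benign", "benign_or_likely"}
_CLINVAR_UNCERTAIN = {"uncertain_significance", "uncertain", "vus",
                      "conflicting_interpretations_of_pathogenicity"}


def parse_predictor(tool: str, token: str) -> PredictorCall:
    token = token.strip().lower()
    if not token or token in {".", "unknown", "na", "nan"}:
        return PredictorCall.UNKNOWN
    # strip VEP-style score suffix, e.g. "deleterious(0.01)"
    token = token.split("(")[0].strip()
    if token in _DAMAGING_TOKENS.get(tool, {"damaging"}):
        return PredictorCall.DAMAGING
    if token in _TOLERATED_TOKENS.get(tool, {"tolerated"}):
        return PredictorCall.TOLERATED
    return PredictorCall.UNKNOWN


def parse_clinvar(token: str) -> ClinvarClass:
    token = token.strip().lower().replace(" ", "_")
    if not token or token in {".", "absent", "not_provided"}:
        return ClinvarClass.ABSENT
    if token in _CLINVAR_PATHOGENIC:
        return ClinvarClass.PATHOGENIC_OR_LIKELY
    if token in _CLINVAR_BENIGN:
        return ClinvarClass.BENIGN_OR_LIKELY
    if token in _CLINVAR_UNCERTAIN:
        return ClinvarClass.UNCERTAIN
    return ClinvarClass.UNCERTAIN  # any other submitted significance: treat as uncertain


def _parse_af(token: str) -> Optional[float]:
    token = token.strip()
    if not token or token in {".", "NA", "nan"}:
        return None
    value = float(token)
    if not 0.0 <= value <= 1.0:
        raise VcfParseError(f"allele frequency {value} outside [0, 1]")
    return value


# ---------------------------------------------------------------------------
# dialect
# ---------------------------------------------------------------------------

#: Default CSQ subfield order written and read by this package.
DEFAULT_CSQ_FIELDS = (
    "Allele", "Consequence", "SYMBOL", "HGVSc", "HGVSp", "AF", "EUR_AF",
    "SIFT", "PolyPhen2", "MetaSVM", "MetaLR", "Provean", "MutationTaster",
    "FATHMM", "CLIN_SIG", "ENSEMBL_HQ",
)


@dataclass
class AnnotationDialect:
    """Maps VCF annotation content onto :class:`AnnotationBundle` fields.

    The default reads a pipe-separated ``CSQ`` INFO string with subfields in
    :data:`DEFAULT_CSQ_FIELDS` order (one comma-separated entry per ALT
    allele). Setting ``sidecar`` to a TSV path switches to tabular sidecar
    annotation keyed by (chrom, pos, ref, alt).
    """

    csq_key: str = "CSQ"
    csq_fields: Sequence[str] = DEFAULT_CSQ_FIELDS
    sidecar: Optional[Path] = None
    _sidecar_index: dict[tuple[str, int, str, str], dict[str, str]] = field(
        default_factory=dict, repr=False
    )

    def __post_init__(self) -> None:
        if self.sidecar is not None:
            with open(self.sidecar, newline="") as fh:
                for row in csv.DictReader(fh, delimiter="\t"):
                    key = (row["chrom"], int(row["pos"]), row["ref"], row["alt"])
                    self._sidecar_index[key] = row

    def csq_header_line(self) -> str:
        fmt = "|".join(self.csq_fields)
        return (
            f'##INFO=<ID={self.csq_key},Number=.,Type=String,'
            f'Description="Consequence annotations. Format: {fmt}">'
        )

    # -- reading --------------------------------------------------------
    def bundle_for(
        self,
        chrom: str,
        pos: int,
        ref: str,
        alt: str,
        csq_value: Optional[str],
    ) -> tuple[AnnotationBundle, str, str, str]:
        """Return (bundle, gene, hgvs_c, hgvs_p) for one split alt allele."""
        fields: Optional[dict[str, str]] = None
        if self.sidecar is not None:
            fields = self._sidecar_index.get((chrom, pos, ref, alt))
        elif csq_value:
            for entry in csq_value.split(","):
                values = entry.split("|")
                record = dict(zip(self.csq_fields, values))
                if record.get("Allele", alt) in (alt, ""):
                    fields = record
                    break
        if fields is None:
            return AnnotationBundle(), "", "", ""

        def get(name: str) -> str:
            return (fields.get(name) or "").strip()

        consequence = Consequence.OTHER
        for term in get("Consequence").replace("&", ",").split(","):
            if term.strip() in CONSEQUENCE_TERMS:
                consequence = CONSEQUENCE_TERMS[term.strip()]
                break
        predictor_calls = {
            tool: parse_predictor(tool, get(tool))
            for tool in PREDICTOR_PANEL
            if get(tool)
        }
        bundle = AnnotationBundle(
            consequence=consequence,
            af_global=_parse_af(get("AF")),
            af_european=_parse_af(get("EUR_AF")),
            predictor_calls=predictor_calls,
            clinvar=parse_clinvar(get("CLIN_SIG")),
            ensembl_high_quality=get("ENSEMBL_HQ") in {"1", "true", "True", "YES"},
        )
        return bundle, get("SYMBOL"), get("HGVSc"), get("HGVSp")

    # -- writing --------------------------------------------------------
    def csq_entry(self, variant: AnnotatedVariant) -> str:
        ann = variant.annotation
        values = {
            "Allele": variant.alt,
            "Consequence": ann.consequence.value,
            "SYMBOL": variant.gene,
            "HGVSc": variant.hgvs_c,
            "HGVSp": variant.hgvs_p,
            "AF": "" if ann.af_global is None else format(ann.af_global, "g"),
            "EUR_AF": "" if ann.af_european is None else format(ann.af_european, "g"),
            "CLIN_SIG": "" if ann.clinvar is ClinvarClass.ABSENT else ann.clinvar.value,
            "ENSEMBL_HQ": "1" if ann.ensembl_high_quality else "",
        }
        for tool in PREDICTOR_PANEL:
            call = ann.predictor(tool)
            values[tool] = "" if call is PredictorCall.UNKNOWN else call.value
        return "|".join(values.get(f, "") for f in self.csq_fields)


# ---------------------------------------------------------------------------
# VCF reading
# ---------------------------------------------------------------------------

def _prevalidate(path: Path) -> None:
    """Cheap structural check so parse errors can name a line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 8:
                raise VcfParseError(
                    f"{path}: line {lineno}: expected >=8 tab-separated fields, got {len(parts)}"
                )
            try:
                int(parts[1])
            except ValueError:
                raise VcfParseError(
                    f"{path}: line {lineno}: POS {parts[1]!r} is not an integer"
                ) from None


def read_vcf(
    path: str | Path,
    dialect: Optional[AnnotationDialect] = None,
    cohort: Optional[CohortDesign] = None,
) -> list[AnnotatedVariant]:
    """Read a multi-sample VCF into normalized bi-allelic annotated variants.

    Multi-allelic records are split per ALT allele, with per-sample allele
    counts recomputed against each alt. Genotypes ``./.`` (or any genotype
    with a missing allele) become undefined calls; the genotype-level quality
    flag is taken from ``FORMAT/FT`` (PASS or absent = pass). The result is
    sorted by (chrom, pos, ref, alt).
    """
    path = Path(path)
    dialect = dialect or AnnotationDialect()
    _prevalidate(path)

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    if cohort is not None:
        extra = set(samples) - {s.sample_id for s in cohort.samples}
        if extra:
            raise VcfParseError(
                f"{path}: VCF sample(s) absent from cohort design: {sorted(extra)}"
            )

    variants: list[AnnotatedVariant] = []
    seen: set[tuple[str, int, str, str]] = set()
    for record in vcf:
        alts = record.ALT or []
        try:
            ft = record.format("FT")
        except KeyError:
            ft = None
        csq = record.INFO.get(dialect.csq_key)
        genotype_rows = record.genotypes  # [allele_a, allele_b, phased]
        for alt_index, alt in enumerate(alts, start=1):
            genotypes: dict[str, GenotypeCall] = {}
            for i, sid in enumerate(samples):
                alleles = genotype_rows[i][:-1]
                if any(a < 0 for a in alleles):
                    count: Optional[int] = None
                else:
                    count = sum(1 for a in alleles if a == alt_index)
                passed = True
                if ft is not None:
                    token = ft[i]
                    if isinstance(token, bytes):
                        token = token.decode()
                    passed = token in ("PASS", ".", "", None)
                genotypes[sid] = GenotypeCall(sid, count, passed)
            bundle, gene, hgvs_c, hgvs_p = dialect.bundle_for(
                record.CHROM, record.POS, record.REF, alt, csq
            )
            key = (record.CHROM, record.POS, record.REF, alt)
            if key in seen:
                raise VcfParseError(f"{path}: duplicate variant {key}")
            seen.add(key)
            variants.append(
                AnnotatedVariant(
                    chrom=record.CHROM,
                    pos=record.POS,
                    ref=record.REF,
                    alt=alt,
                    gene=gene,
                    hgvs_c=hgvs_c,
                    hgvs_p=hgvs_p,
                    annotation=bundle,
                    genotypes=genotypes,
                )
            )
    variants.sort(key=lambda v: v.sort_key)
    return variants


# ---------------------------------------------------------------------------
# VCF writing (used by the simulator and for round-trip checks)
# ---------------------------------------------------------------------------

def write_vcf(
    variants: Sequence[AnnotatedVariant],
    sample_ids: Sequence[str],
    path: str | Path,
    dialect: Optional[AnnotationDialect] = None,
) -> None:
    """Write bi-allelic variants as a VCF 4.2 text file with GT:FT genotypes."""
    dialect = dialect or AnnotationDialect()
    gt_text = {0: "0/0", 1: "0/1", 2: "1/1", None: "./."}
    contigs = sorted({v.chrom for v in variants}, key=chrom_sort_key)
    lines = [
        "##fileformat=VCFv4.2",
        dialect.csq_header_line(),
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=FT,Number=1,Type=String,Description="Genotype-level filter">',
        *(f"##contig=<ID={c}>" for c in contigs),
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids),
    ]
    for v in sorted(variants, key=lambda v: v.sort_key):
        info = f"{dialect.csq_key}={dialect.csq_entry(v)}"
        cells = []
        for sid in sample_ids:
            call = v.call(sid)
            ft = "PASS" if call.quality_pass else "LOWQ"
            cells.append(f"{gt_text[call.allele_count]}:{ft}")
        lines.append(
            "\t".join(
                [v.chrom, str(v.pos), ".", v.ref, v.alt, ".", "PASS", info, "GT:FT", *cells]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------

def read_sample_sheet(path: str | Path) -> CohortDesign:
    """Read a tab-separated sample sheet (sample_id, group, sibling_pair_id)."""
    path = Path(path)
    samples: list[Sample] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"sample_id", "group", "sibling_pair_id"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise SampleSheetError(
                f"{path}: header must contain columns {sorted(required)}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                group = SampleGroup(row["group"].strip())
            except ValueError:
                raise SampleSheetError(
                    f"{path}: line {lineno}: unknown group {row['group']!r}"
                ) from None
            pair = row["sibling_pair_id"].strip() or None
            if pair in {".", "NA"}:
                pair = None
            samples.append(Sample(row["sample_id"].strip(), group, pair))
    try:
        return CohortDesign(samples)
    except ValueError as exc:
        raise SampleSheetError(f"{path}: {exc}") from exc


def write_sample_sheet(cohort: CohortDesign, path: str | Path) -> None:
    lines = ["sample_id\tgroup\tsibling_pair_id"]
    for s in cohort.samples:
        lines.append(f"{s.sample_id}\t{s.group.value}\t{s.sibling_pair_id or ''}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# candidate report
# ---------------------------------------------------------------------------

def write_candidates(
    variants: Sequence[AnnotatedVariant],
    table: "CarrierTable",
    path_prefix: str | Path,
) -> tuple[Path, Path]:
    """Write the per-group carrier report as TSV plus machine-readable JSON.

    Cells use the ``(k/n) pct%`` layout. ``path_prefix`` yields
    ``<prefix>.tsv`` and ``<prefix>.json``. Returns both paths.
    """
    from melvar.screen import CarrierTable  # local import avoids a cycle

    assert isinstance(table, CarrierTable)
    variant_keys = {v.key for v in variants}
    if variant_keys != set(table.rows):
        missing = variant_keys ^ set(table.rows)
        raise ValueError(f"variant/table key mismatch: {sorted(missing)[:5]}")

    prefix = Path(path_prefix)
    tsv_path = prefix.with_suffix(".tsv")
    json_path = prefix.with_suffix(".json")

    groups = table.groups
    header = ["gene", "hgvs_c", "hgvs_p"] + list(groups)
    lines = ["\t".join(header)]
    payload: list[dict] = []
    for v in sorted(variants, key=lambda v: v.sort_key):
        row = table.rows[v.key]
        cells = []
        entry = {
            "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
            "gene": v.gene, "hgvs_c": v.hgvs_c, "hgvs_p": v.hgvs_p, "groups": {},
        }
        for g in groups:
            cell = row.get(g)
            if cell is None:
                cells.append("")
                continue
            cells.append(f"({cell.carriers}/{cell.denominator}) {cell.percent}%")
            entry["groups"][g] = {
                "carriers": cell.carriers,
                "denominator": cell.denominator,
                "percent": cell.percent,
            }
        lines.append("\t".join([v.gene, v.hgvs_c, v.hgvs_p] + cells))
        payload.append(entry)
    tsv_path.write_text("\n".join(lines) + "\n")
    json_path.write_text(json.dumps(payload, indent=2) + "\n")
    return tsv_path, json_path


def read_candidates_json(path: str | Path) -> list[dict]:
    with open(path) as fh:
        return json.load(fh)
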