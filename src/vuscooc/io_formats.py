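"""Readers and writers for the four input file families.

Cohort genotypes and sites frequencies are VCF 4.x (read through cyvcf2);
classification, phenotype and score tables are delimited text read through
pandas. A minimal VCF text writer is provided for fixtures and round-trip
tests only.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .model import (
    MISSING,
    OUTSIDE_GENE,
    ClassificationTable,
    CohortGenotypes,
    ConfigurationError,
    DuplicateEntryError,
    FormatError,
    GenomeBuild,
    PhenotypeRecord,
    PhenotypeTable,
    ReceptorStatus,
    SchemaError,
    SitesFrequencies,
    ValidationError,
    VariantKey,
    normalize_chromosome,
)

logger = logging.getLogger(__name__)

_COORD_RE = re.compile(
    r"^(?P<chrom>chr[^:]+):(?P<pos>g\.[^:]+):(?P<alleles>[^:]+)$", re.IGNORECASE
)


def parse_coordinate_string(s: str, build: GenomeBuild) -> VariantKey:
    """Parse a ``chrN:g.POS:REF>ALT`` coordinate string into a VariantKey.

    The chromosome must carry a ``chr`` prefix, the position a ``g.`` prefix,
    and the alleles must be separated by ``>``. Alleles are uppercased and the
    chromosome prefix stripped during normalization.
    """
    if not isinstance(s, str):
        raise FormatError(f"coordinate must be a string, got {type(s).__name__}")
    m = _COORD_RE.match(s.strip())
    if m is None:
        raise FormatError(
            f"malformed coordinate {s!r}: expected 'chrN:g.POS:REF>ALT'")
    pos_token = m.group("pos")
    if not pos_token.lower().startswith("g."):
        raise FormatError(f"malformed coordinate {s!r}: missing 'g.' in {pos_token!r}")
    pos_str = pos_token[2:]
    try:
        position = int(pos_str)
    except ValueError:
        raise FormatError(f"malformed coordinate {s!r}: non-integer position {pos_str!r}")
    alleles = m.group("alleles")
    if ">" not in alleles:
        raise FormatError(f"malformed coordinate {s!r}: missing '>' in {alleles!r}")
    ref, _, alt = alleles.partition(">")
    if not ref or not alt:
        raise FormatError(f"malformed coordinate {s!r}: empty allele in {alleles!r}")
    return VariantKey(m.group("chrom")[3:], position, ref, alt, build)


def format_coordinate_string(key: VariantKey) -> str:
    return key.coordinate_string()


def read_cohort_vcf(
    path: str,
    gene_intervals: dict[str, tuple[str, int, int]],
    build: GenomeBuild,
) -> CohortGenotypes:
    """Read a cohort VCF into a CohortGenotypes container.

    ``gene_intervals`` maps gene symbol -> (chromosome, start, end), 1-based
    inclusive. Multi-allelic records are split into one VariantKey per
    alternate allele; per-haplotype alleles record carriage of that allele
    only. Variants outside every configured interval are flagged
    OUTSIDE_GENE. Phase is read from the genotype separator.
    """
    if not gene_intervals:
        raise ConfigurationError("gene_intervals must be non-empty")
    intervals = {
        gene: (normalize_chromosome(chrom), int(start), int(end))
        for gene, (chrom, start, end) in gene_intervals.items()
    }

    try:
        vcf = VCF(path, gts012=False)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad files
        raise SchemaError(f"cannot read VCF {path!r}: {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        raise SchemaError(f"VCF {path!r} carries no genotype (GT) columns")

    variants: list[VariantKey] = []
    allele_rows: list[np.ndarray] = []
    phased_rows: list[np.ndarray] = []
    gene_assignment: dict[VariantKey, str] = {}
    n_outside = 0
    known_contigs = {c for c, _, _ in intervals.values()}

    for record in vcf:
        chrom = normalize_chromosome(record.CHROM)
        gts = record.genotypes  # [[a, b, phased], ...]
        for alt_index, alt in enumerate(record.ALT, start=1):
            if alt in {".", "*", ""}:
                continue
            key = VariantKey(chrom, record.POS, record.REF, alt, build)
            row = np.zeros((len(samples), 2), dtype=np.int8)
            prow = np.zeros(len(samples), dtype=bool)
            for si, gt in enumerate(gts):
                a, b = gt[0], gt[1]
                prow[si] = bool(gt[2]) if len(gt) > 2 else False
                row[si, 0] = MISSING if a < 0 else int(a == alt_index)
                row[si, 1] = MISSING if b < 0 else int(b == alt_index)
            gene = _assign_gene(key, intervals)
            if gene == OUTSIDE_GENE:
                n_outside += 1
                if chrom not in known_contigs:
                    logger.warning(
                        "contig %s absent from gene intervals; %s flagged OUTSIDE_GENE",
                        chrom, key.coordinate_string())
            variants.append(key)
            allele_rows.append(row)
            phased_rows.append(prow)
            gene_assignment[key] = gene

    alleles = (
        np.stack(allele_rows) if allele_rows
        else np.zeros((0, len(samples), 2), dtype=np.int8)
    )
    phased = (
        np.stack(phased_rows) if phased_rows
        else np.zeros((0, len(samples)), dtype=bool)
    )
    logger.info(
        "read %d variants x %d samples from %s (%d outside configured genes)",
        len(variants), len(samples), path, n_outside)
    return CohortGenotypes(samples, variants, alleles, phased, gene_assignment, build)


def _assign_gene(key: VariantKey, intervals: dict[str, tuple[str, int, int]]) -> str:
    for gene, (chrom, start, end) in intervals.items():
        if key.chromosome == chrom and start <= key.position <= end:
            return gene
    return OUTSIDE_GENE


def write_cohort_vcf(cohort: CohortGenotypes, path: str) -> None:
    """Write a CohortGenotypes back out as VCF 4.2 text (fixtures/round-trips only).

    Each (already split) VariantKey becomes one single-alt record; output is
    byte-deterministic for a given cohort.
    """
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    for contig in sorted({v.chromosome for v in cohort.variants}):
        lines.append(f"##contig=<ID={contig}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(cohort.sample_ids))
    order = sorted(range(cohort.n_variants),
                   key=lambda i: (cohort.variants[i].chromosome,
                                  cohort.variants[i].position,
                                  cohort.variants[i].ref,
                                  cohort.variants[i].alt))
    for i in order:
        v = cohort.variants[i]
        calls = []
        for si in range(cohort.n_samples):
            a, b = cohort.alleles[i, si]
            sep = "|" if cohort.phased[i, si] else "/"
            calls.append(f"{_gt(a)}{sep}{_gt(b)}")
        lines.append(
            f"{v.chromosome}\t{v.position}\t.\t{v.ref}\t{v.alt}\t.\t.\t.\tGT\t"
            + "\t".join(calls))
    with open(path, "w", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def _gt(allele: int) -> str:
    return "." if allele < 0 else str(int(allele))


_BUILD_COLUMN = {
    GenomeBuild.GRCH37: "Genomic_Coordinate_hg37",
    GenomeBuild.GRCH38: "Genomic_Coordinate_hg38",
}


def read_classification_table(path: str, build: GenomeBuild) -> ClassificationTable:
    """Read a delimited classification table (Clinical_significance + coordinates).

    The coordinate column for the requested build is parsed with
    :func:`parse_coordinate_string`; significance strings are kept verbatim.
    Duplicate coordinates are an error.
    """
    try:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    except Exception as exc:
        raise SchemaError(f"cannot read classification table {path!r}: {exc}") from exc
    coord_col = _BUILD_COLUMN[build]
    for col in ("Clinical_significance", coord_col):
        if col not in df.columns:
            raise SchemaError(
                f"classification table {path!r} lacks required column {col!r}")
    entries: dict[VariantKey, str] = {}
    first_row: dict[VariantKey, int] = {}
    for idx, row in df.iterrows():
        key = parse_coordinate_string(row[coord_col], build)
        if key in entries:
            raise DuplicateEntryError(
                f"duplicate coordinate {row[coord_col]!r} in rows "
                f"{first_row[key]} and {idx}")
        entries[key] = "" if pd.isna(row["Clinical_significance"]) else str(
            row["Clinical_significance"])
        first_row[key] = idx
    return ClassificationTable(entries, build)


@dataclass
class PhenotypeFieldMap:
    """Maps phenotype TSV columns and their encodings onto typed record fields.

    Mirrors the JSON field-definition file: each entry names the source
    column and, for coded fields, which raw tokens mean what.
    """

    case_control_column: str = "case_control"
    control_values: tuple[str, ...] = ("0", "control")
    case_values: tuple[str, ...] = ("1", "case")
    er_column: str = "ER"
    pr_column: str = "PR"
    her2_column: str = "HER2"
    positive_values: tuple[str, ...] = ("1", "positive", "+")
    negative_values: tuple[str, ...] = ("0", "negative", "-")
    age_at_diagnosis_column: str = "age_at_diagnosis"
    age_at_entry_column: str = "age_at_entry"
    missing_tokens: tuple[str, ...] = ("NA", "", ".", "NaN", "nan", "None")

    @classmethod
    def from_json(cls, path: str) -> "PhenotypeFieldMap":
        with open(path) as fh:
            raw = json.load(fh)
        kwargs = {}
        for f in cls.__dataclass_fields__:
            if f in raw:
                v = raw[f]
                kwargs[f] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)


def read_phenotype_table(
    path: str, field_map: PhenotypeFieldMap | None = None
) -> PhenotypeTable:
    """Read a tab-separated phenotype table keyed by its ``ID`` column.

    Typed fields are coerced per the field map; unparseable cells become
    UNKNOWN and are tallied per column in ``n_unparseable``.
    """
    fm = field_map or PhenotypeFieldMap()
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:
        raise SchemaError(f"cannot read phenotype table {path!r}: {exc}") from exc
    if "ID" not in df.columns:
        raise SchemaError(f"phenotype table {path!r} lacks required column 'ID'")
    if df["ID"].duplicated().any():
        dupes = sorted(df.loc[df["ID"].duplicated(), "ID"].unique())
        raise DuplicateEntryError(f"duplicate phenotype IDs: {dupes}")

    unparseable: dict[str, int] = {}

    def _tally(col: str) -> None:
        unparseable[col] = unparseable.get(col, 0) + 1

    def _cell(row, col: str) -> str | None:
        if col not in df.columns:
            return None
        v = row[col]
        if pd.isna(v) or str(v).strip() in fm.missing_tokens:
            return None
        return str(v).strip()

    def _receptor(row, col: str) -> ReceptorStatus:
        v = _cell(row, col)
        if v is None:
            return ReceptorStatus.UNKNOWN
        if v.lower() in {t.lower() for t in fm.positive_values}:
            return ReceptorStatus.POSITIVE
        if v.lower() in {t.lower() for t in fm.negative_values}:
            return ReceptorStatus.NEGATIVE
        _tally(col)
        return ReceptorStatus.UNKNOWN

    def _age(row, col: str) -> float | None:
        v = _cell(row, col)
        if v is None:
            return None
        try:
            age = float(v)
        except ValueError:
            _tally(col)
            return None
        return age

    typed_cols = {
        "ID", fm.case_control_column, fm.er_column, fm.pr_column, fm.her2_column,
        fm.age_at_diagnosis_column, fm.age_at_entry_column,
    }
    records: dict[str, PhenotypeRecord] = {}
    for _, row in df.iterrows():
        sid = str(row["ID"])
        v = _cell(row, fm.case_control_column)
        if v is None:
            is_control = None
        elif v.lower() in {t.lower() for t in fm.control_values}:
            is_control = True
        elif v.lower() in {t.lower() for t in fm.case_values}:
            is_control = False
        else:
            _tally(fm.case_control_column)
            is_control = None
        extra = {c: ("" if pd.isna(row[c]) else str(row[c]))
                 for c in df.columns if c not in typed_cols}
        records[sid] = PhenotypeRecord(
            id=sid,
            is_control=is_control,
            er_status=_receptor(row, fm.er_column),
            pr_status=_receptor(row, fm.pr_column),
            her2_status=_receptor(row, fm.her2_column),
            age_at_diagnosis=_age(row, fm.age_at_diagnosis_column),
            age_at_entry=_age(row, fm.age_at_entry_column),
            extra=extra,
        )
    return PhenotypeTable(records, unparseable)


def read_sites_frequencies(
    path: str, field_name: str = "AF", build: GenomeBuild = GenomeBuild.GRCH38
) -> SitesFrequencies:
    """Read per-variant allele frequencies from a sites VCF INFO field.

    Records lacking the field are skipped and counted; a frequency outside
    [0, 1] is a validation error. Multi-allelic sites contribute one entry per
    alternate allele (the INFO field is Number=A).
    """
    try:
        vcf = VCF(path)
    except Exception as exc:
        raise SchemaError(f"cannot read sites VCF {path!r}: {exc}") from exc
    try:
        vcf.get_header_type(field_name)
    except KeyError:
        raise SchemaError(
            f"INFO field {field_name!r} absent from header of {path!r}")
    entries: dict[VariantKey, float] = {}
    n_skipped = 0
    for record in vcf:
        raw = record.INFO.get(field_name)
        if raw is None:
            n_skipped += 1
            continue
        values = raw if isinstance(raw, tuple) else (raw,)
        for alt, af in zip(record.ALT, values):
            if af is None:
                n_skipped += 1
                continue
            af = float(af)
            if not (0.0 <= af <= 1.0):
                raise ValidationError(
                    f"{field_name}={af} outside [0,1] at "
                    f"{record.CHROM}:{record.POS}")
            key = VariantKey(record.CHROM, record.POS, record.REF, alt, build)
            entries[key] = af
    if n_skipped:
        logger.warning("%d sites records lacked %s and were skipped",
                       n_skipped, field_name)
    return SitesFrequencies(entries, field_name, n_skipped)


def read_scores_table(path: str, score_column: str = "BayesDel") -> dict[str, float]:
    """Read a per-variant in-silico score table (coordinate string -> score).

    Expects a delimited file with a coordinate column (``Genomic_Coordinate``,
    or the first column) and the named score column; unparseable scores are
    skipped.
    """
    try:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    except Exception as exc:
        raise SchemaError(f"cannot read scores table {path!r}: {exc}") from exc
    if score_column not in df.columns:
        raise SchemaError(f"scores table {path!r} lacks column {score_column!r}")
    coord_col = "Genomic_Coordinate" if "Genomic_Coordinate" in df.columns else df.columns[0]
    scores: dict[str, float] = {}
    for _, row in df.iterrows():
        try:
            scores[str(row[coord_col])] = float(row[score_column])
        except (TypeError, ValueError):
            continue
    return scores
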