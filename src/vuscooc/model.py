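"""Shared data model: variant identity, genotype containers, evidence enums.

All genomic positions are 1-based (VCF convention). Chromosome names are
normalized by stripping any ``chr`` prefix, uppercasing, and unifying the
mitochondrial names ``M``/``MT`` to ``MT``, so that keys parsed from
``chrN:g.POS:REF>ALT`` coordinate strings and keys read from VCF records
compare equal component-wise.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Hashable, Mapping

import numpy as np

OUTSIDE_GENE = "OUTSIDE_GENE"
MISSING = -1  # dosage / allele sentinel


class VuscoocError(Exception):
    """Base class for all package errors."""


class FormatError(VuscoocError):
    """A value does not follow its declared grammar (e.g. coordinate string)."""


class SchemaError(VuscoocError):
    """An input file lacks a required column/field or cannot be read as declared."""


class DuplicateEntryError(SchemaError):
    """Two rows define the same primary key."""


class ConfigurationError(VuscoocError):
    """Inconsistent or invalid run configuration (builds, control sets, ...)."""


class ValidationError(VuscoocError):
    """A parsed value violates its domain (e.g. allele frequency outside [0,1])."""


class AbsentVariantError(VuscoocError):
    """A variant was requested that the cohort does not contain."""


class GenomeBuild(enum.Enum):
    GRCH37 = "GRCh37"
    GRCH38 = "GRCh38"

    @classmethod
    def from_string(cls, s: str | int) -> "GenomeBuild":
        token = str(s).strip().lower()
        if token in {"37", "grch37", "hg19", "hg37"}:
            return cls.GRCH37
        if token in {"38", "grch38", "hg38"}:
            return cls.GRCH38
        raise ConfigurationError(f"unknown genome build: {s!r}")


def normalize_chromosome(chrom: str) -> str:
    c = chrom.strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    c = c.upper()
    if c == "M":
        c = "MT"
    if not c:
        raise FormatError("empty chromosome name")
    return c


@dataclass(frozen=True)
class VariantKey:
    """Normalized identity of one substitution or indel.

    Alleles are kept verbatim as left-anchored VCF ref/alt strings (uppercased,
    no trimming); a multi-allelic VCF record yields one key per alternate
    allele.
    """

    chromosome: str
    position: int
    ref: str
    alt: str
    build: GenomeBuild

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromosome", normalize_chromosome(self.chromosome))
        object.__setattr__(self, "ref", self.ref.strip().upper())
        object.__setattr__(self, "alt", self.alt.strip().upper())
        if self.position < 1:
            raise ValidationError(f"position must be >= 1, got {self.position}")
        if not self.ref or not self.alt:
            raise ValidationError("ref and alt alleles must be non-empty")
        if self.ref == self.alt:
            raise ValidationError(f"ref and alt identical at {self.chromosome}:{self.position}")

    def coordinate_string(self) -> str:
        """Render back to the ``chrN:g.POS:REF>ALT`` grammar."""
        return f"chr{self.chromosome}:g.{self.position}:{self.ref}>{self.alt}"


class PathogenicityClass(enum.Enum):
    PATHOGENIC = "PATHOGENIC"
    BENIGN = "BENIGN"
    VUS = "VUS"


class FrequencyCode(enum.Enum):
    BA1 = "BA1"  # stand-alone benign: frequency above the BA1 threshold
    BS1 = "BS1"  # strong benign: above the BS1 threshold but not BA1
    PM2 = "PM2"  # moderate pathogenic: absent from the evaluated population
    NONE = "NONE"


class InSilicoCode(enum.Enum):
    BP4 = "BP4"  # computational evidence of benign impact
    PP3 = "PP3"  # computational evidence of pathogenic impact
    NONE = "NONE"


class CombinedClass(enum.Enum):
    BENIGN = "B"
    LIKELY_BENIGN = "LB"
    VUS = "VUS"


class ReceptorStatus(enum.Enum):
    POSITIVE = "POSITIVE"
    NEGATIVE = "NEGATIVE"
    UNKNOWN = "UNKNOWN"


@dataclass
class CohortGenotypes:
    """Per-sample genotypes for a cohort, split to one row per alternate allele.

    ``alleles`` has shape (n_variants, n_samples, 2) with entries in
    {0, 1, MISSING}: 1 where that haplotype carries the row's alternate
    allele. ``phased`` marks calls whose haplotype order is meaningful.
    """

    sample_ids: list[str]
    variants: list[VariantKey]
    alleles: np.ndarray
    phased: np.ndarray
    gene_assignment: dict[VariantKey, str]
    build: GenomeBuild

    def __post_init__(self) -> None:
        nv, ns = len(self.variants), len(self.sample_ids)
        if self.alleles.shape != (nv, ns, 2):
            raise ValidationError(
                f"alleles shape {self.alleles.shape} != ({nv}, {ns}, 2)")
        if self.phased.shape != (nv, ns):
            raise ValidationError(f"phased shape {self.phased.shape} != ({nv}, {ns})")
        if len(set(self.sample_ids)) != ns:
            raise ValidationError("sample IDs are not unique")
        self._index: dict[VariantKey, int] = {v: i for i, v in enumerate(self.variants)}

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_index(self, key: VariantKey) -> int:
        try:
            return self._index[key]
        except KeyError:
            raise AbsentVariantError(f"variant not in cohort: {key.coordinate_string()}")

    @property
    def dosage(self) -> np.ndarray:
        """(n_variants, n_samples) alt-allele dosage; MISSING where any haplotype is missing."""
        d = self.alleles.sum(axis=2, dtype=np.int16)
        d[(self.alleles == MISSING).any(axis=2)] = MISSING
        return d.astype(np.int8)

    def gene_of(self, key: VariantKey) -> str:
        return self.gene_assignment.get(key, OUTSIDE_GENE)


@dataclass
class ClassificationTable:
    """Variant -> raw clinical-significance string, from one classification source."""

    entries: dict[VariantKey, str]
    source_build: GenomeBuild


@dataclass
class SitesFrequencies:
    """Reference-population allele frequencies from a sites VCF.

    Absence of a key is meaningful: the variant was not observed in the
    reference population.
    """

    entries: dict[VariantKey, float]
    field_name: str = "AF"
    n_skipped: int = 0

    def lookup(self, key: VariantKey) -> float | None:
        return self.entries.get(key)


@dataclass
class PhenotypeRecord:
    id: str
    is_control: bool | None = None
    er_status: ReceptorStatus = ReceptorStatus.UNKNOWN
    pr_status: ReceptorStatus = ReceptorStatus.UNKNOWN
    her2_status: ReceptorStatus = ReceptorStatus.UNKNOWN
    age_at_diagnosis: float | None = None
    age_at_entry: float | None = None
    extra: dict[str, str] = field(default_factory=dict)


@dataclass
class PhenotypeTable:
    records: dict[str, PhenotypeRecord]
    n_unparseable: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid, rec in self.records.items():
            if sid != rec.id:
                raise ValidationError(f"record keyed {sid!r} has id {rec.id!r}")

    def get(self, sample_id: str) -> PhenotypeRecord | None:
        return self.records.get(sample_id)

    @property
    def control_ids(self) -> list[str]:
        return [sid for sid, r in self.records.items() if r.is_control is True]

    @property
    def case_ids(self) -> list[str]:
        return [sid for sid, r in self.records.items() if r.is_control is False]


class CooccurrenceKind(enum.Enum):
    HOMOZYGOUS = "HOMOZYGOUS"
    COMPOUND_WITH_PATHOGENIC = "COMPOUND_WITH_PATHOGENIC"


@dataclass
class CooccurrenceRecord:
    """One observation of a VUS co-occurring with itself (homozygous) or with a
    pathogenic partner in the same gene, in one carrier sample.

    Variant identifiers are VariantKeys in the pipeline but any hashable
    identifier (e.g. a cDNA HGVS string) is accepted for evidence-stage use.
    """

    vus: Hashable
    kind: CooccurrenceKind
    sample_id: str
    gene: str
    partner: Hashable | None = None
    age_at_diagnosis: float | None = None
    age_at_entry: float | None = None
    phase_known: bool = False
    trans_confirmed: bool = False

    def __post_init__(self) -> None:
        if self.kind is CooccurrenceKind.HOMOZYGOUS and self.partner is not None:
            raise ValidationError("homozygous record cannot have a partner")
        if self.kind is CooccurrenceKind.COMPOUND_WITH_PATHOGENIC and self.partner is None:
            raise ValidationError("compound record requires a partner")


@dataclass
class TransInference:
    """Per-VUS aggregation of co-occurrence observations into BS2 eligibility."""

    vus: Hashable
    distinct_pathogenic_partners: frozenset
    homozygous_observed: bool
    phased_trans_observed: bool
    n_samples: int

    @property
    def bs2_eligible(self) -> bool:
        return (
            self.homozygous_observed
            or len(self.distinct_pathogenic_partners) >= 2
            or self.phased_trans_observed
        )


@dataclass(frozen=True)
class EvidenceThresholds:
    """ACMG/AMP frequency and in-silico thresholds (BRCA VCEP proposed rules)."""

    ba1: float = 0.001
    bs1: float = 0.0001
    bayesdel_cut: float = 0.3

    def __post_init__(self) -> None:
        if not (0 < self.bs1 < self.ba1 < 1):
            raise ConfigurationError(
                f"thresholds must satisfy 0 < bs1 < ba1 < 1, got bs1={self.bs1}, ba1={self.ba1}")


@dataclass
class EvidenceBundle:
    """Per-VUS evidence: control AF, frequency + in-silico codes, combined class.

    ``bs2_eligible`` is carried as supplementary support and never folded into
    ``combined_class`` (which reflects frequency + bioinformatics only).
    """

    variant: Hashable
    control_af: float
    freq_code: FrequencyCode
    bayesdel: float | None
    insilico_code: InSilicoCode
    combined_class: CombinedClass
    bs2_eligible: bool = False
    gene: str | None = None
    external_af: Mapping[str, float | None] | None = None
    external_codes: Mapping[str, FrequencyCode] | None = None
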