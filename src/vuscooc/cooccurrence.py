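"""Per-sample variant lists, VUS co-occurrence detection, and in-trans inference.

A VUS observed homozygous, or heterozygous together with a known pathogenic
variant in the same gene, in an adult without Fanconi anemia features, argues
against pathogenicity (BS2). With unphased genotypes a single co-occurrence is
ambiguous (cis or trans), but a VUS seen with two *different* pathogenic
partners guarantees at least one trans relationship; homozygosity is trans by
definition; phased genotypes resolve trans directly.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping

from .model import (
    OUTSIDE_GENE,
    CohortGenotypes,
    CooccurrenceKind,
    CooccurrenceRecord,
    PathogenicityClass,
    PhenotypeTable,
    TransInference,
    VariantKey,
)


@dataclass
class SampleVariantLists:
    """Per-sample partition of carried variants into benign / pathogenic / VUS.

    Only carriers appear (dosage >= 1); dosage and phase flags are retained
    per entry as (variant, dosage, phased) triples.
    """

    benign: dict[str, list[tuple[VariantKey, int, bool]]] = field(default_factory=dict)
    pathogenic: dict[str, list[tuple[VariantKey, int, bool]]] = field(default_factory=dict)
    vus: dict[str, list[tuple[VariantKey, int, bool]]] = field(default_factory=dict)
    sample_ids: list[str] = field(default_factory=list)

    def lists_for(self, sample_id: str) -> dict[str, list[tuple[VariantKey, int, bool]]]:
        return {
            "benign": self.benign.get(sample_id, []),
            "pathogenic": self.pathogenic.get(sample_id, []),
            "vus": self.vus.get(sample_id, []),
        }


_BUCKET = {
    PathogenicityClass.BENIGN: "benign",
    PathogenicityClass.PATHOGENIC: "pathogenic",
    PathogenicityClass.VUS: "vus",
}


def build_sample_variant_lists(
    cohort: CohortGenotypes,
    classes: Mapping[VariantKey, PathogenicityClass],
) -> SampleVariantLists:
    """Partition each sample's carried variants (dosage >= 1) by class."""
    missing = [v for v in cohort.variants if v not in classes]
    if missing:
        raise KeyError(
            f"{len(missing)} cohort variants lack a class, e.g. "
            f"{missing[0].coordinate_string()}")
    lists = SampleVariantLists(sample_ids=list(cohort.sample_ids))
    dosage = cohort.dosage
    for vi, variant in enumerate(cohort.variants):
        bucket = getattr(lists, _BUCKET[classes[variant]])
        for si in (dosage[vi] >= 1).nonzero()[0]:
            sid = cohort.sample_ids[si]
            bucket.setdefault(sid, []).append(
                (variant, int(dosage[vi, si]), bool(cohort.phased[vi, si])))
    return lists


def find_cooccurrences(
    lists: SampleVariantLists,
    gene_assignment: Mapping[VariantKey, str],
    cohort: CohortGenotypes | None = None,
) -> list[CooccurrenceRecord]:
    """Detect homozygous VUS and same-gene VUS–pathogenic co-occurrences.

    Emits one HOMOZYGOUS record per (sample, VUS with dosage 2) and one
    COMPOUND record per (sample, VUS, pathogenic partner sharing the VUS's
    gene); cross-gene pairs are excluded. When the cohort is supplied and
    both calls are phased, trans status is read from the haplotype indices.
    """
    records: list[CooccurrenceRecord] = []
    for sid in lists.sample_ids:
        vus_entries = lists.vus.get(sid, [])
        path_entries = lists.pathogenic.get(sid, [])
        for vus, dosage, vus_phased in vus_entries:
            gene = gene_assignment.get(vus)
            if dosage == 2:
                records.append(CooccurrenceRecord(
                    vus=vus, kind=CooccurrenceKind.HOMOZYGOUS, sample_id=sid,
                    gene=gene, phase_known=vus_phased, trans_confirmed=True))
            if gene is None or gene == OUTSIDE_GENE:
                # compound pairing is defined within a gene only
                continue
            for partner, _pdos, p_phased in path_entries:
                if gene_assignment.get(partner) != gene:
                    continue
                phase_known = vus_phased and p_phased and cohort is not None
                trans = False
                if phase_known:
                    trans = _phased_in_trans(cohort, vus, partner, sid)
                records.append(CooccurrenceRecord(
                    vus=vus, kind=CooccurrenceKind.COMPOUND_WITH_PATHOGENIC,
                    sample_id=sid, gene=gene, partner=partner,
                    phase_known=phase_known, trans_confirmed=trans))
    return records


def _phased_in_trans(
    cohort: CohortGenotypes, vus: VariantKey, partner: VariantKey, sample_id: str
) -> bool:
    si = cohort.sample_ids.index(sample_id)
    a = cohort.alleles[cohort.variant_index(vus), si]
    b = cohort.alleles[cohort.variant_index(partner), si]
    # trans: some haplotype carries the VUS while the other carries the partner
    return bool((a[0] == 1 and b[1] == 1) or (a[1] == 1 and b[0] == 1))


def infer_trans(records: Iterable[CooccurrenceRecord]) -> dict[Hashable, TransInference]:
    """Aggregate co-occurrence records per VUS into BS2 eligibility.

    Eligible iff a homozygote was observed, or >= 2 distinct pathogenic
    partners were seen (the same VUS–partner pair in several samples counts
    once), or phase directly confirmed a trans configuration. A single
    unphased co-occurrence never yields eligibility.
    """
    by_vus: dict[Hashable, list[CooccurrenceRecord]] = defaultdict(list)
    for rec in records:
        by_vus[rec.vus].append(rec)
    out: dict[Hashable, TransInference] = {}
    for vus, recs in by_vus.items():
        partners = frozenset(
            r.partner for r in recs
            if r.kind is CooccurrenceKind.COMPOUND_WITH_PATHOGENIC)
        out[vus] = TransInference(
            vus=vus,
            distinct_pathogenic_partners=partners,
            homozygous_observed=any(
                r.kind is CooccurrenceKind.HOMOZYGOUS for r in recs),
            phased_trans_observed=any(
                r.phase_known and r.trans_confirmed
                and r.kind is CooccurrenceKind.COMPOUND_WITH_PATHOGENIC
                for r in recs),
            n_samples=len({r.sample_id for r in recs}),
        )
    return out


def annotate_ages(
    records: Iterable[CooccurrenceRecord], phenotypes: PhenotypeTable
) -> list[CooccurrenceRecord]:
    """Attach carrier ages from the phenotype table; unmatched carriers keep
    UNKNOWN ages and no record is dropped — age-based review (e.g. against
    Fanconi anemia expectations) is a curator decision."""
    annotated = []
    for rec in records:
        pheno = phenotypes.get(rec.sample_id)
        if pheno is not None:
            rec.age_at_diagnosis = pheno.age_at_diagnosis
            rec.age_at_entry = pheno.age_at_entry
        annotated.append(rec)
    return annotated
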