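"""End-to-end orchestration: read inputs, classify, detect co-occurrences,
assign evidence codes, and assemble the shareable reports."""

from __future__ import annotations

import logging
from dataclasses import dataclass

from . import classification, cooccurrence, evidence, io_formats, reports
from .model import (
    CohortGenotypes,
    EvidenceThresholds,
    GenomeBuild,
    PhenotypeTable,
    SitesFrequencies,
)

logger = logging.getLogger(__name__)


@dataclass
class AnalysisResult:
    cohort: CohortGenotypes
    classes: dict
    lists: cooccurrence.SampleVariantLists
    records: list
    trans: dict
    bundles: list
    evidence_report: dict
    cooccurrence_report: dict
    genotype_phenotype_report: dict | None


def run_cooccurrence_analysis(
    vcf_path: str,
    classification_path: str,
    gene_intervals: dict[str, tuple[str, int, int]],
    build: GenomeBuild,
    control_ids: list[str] | None = None,
    phenotype_path: str | None = None,
    field_map: io_formats.PhenotypeFieldMap | None = None,
    scores_path: str | None = None,
    sites: dict[str, SitesFrequencies] | None = None,
    thresholds: EvidenceThresholds | None = None,
    suppress_sample_ids: bool = False,
) -> AnalysisResult:
    """Run the full variant frequency + co-occurrence analysis.

    Controls default to the phenotype table's control flags when a phenotype
    TSV is supplied and no explicit control set is given. Sites files (e.g.
    reference-population exome/genome frequencies) are annotated alongside,
    never folded into the combined class.
    """
    thresholds = thresholds or EvidenceThresholds()
    cohort = io_formats.read_cohort_vcf(vcf_path, gene_intervals, build)
    table = io_formats.read_classification_table(classification_path, build)
    classes = classification.classify_cohort(cohort, table)

    phenotypes: PhenotypeTable | None = None
    if phenotype_path is not None:
        phenotypes = io_formats.read_phenotype_table(phenotype_path, field_map)
        if control_ids is None:
            control_ids = [s for s in phenotypes.control_ids if s in set(cohort.sample_ids)]
    if not control_ids:
        control_ids = list(cohort.sample_ids)
        logger.warning("no control set supplied; using all %d samples as the "
                       "frequency denominator", len(control_ids))

    scores_by_coord = (
        io_formats.read_scores_table(scores_path) if scores_path else {}
    )
    scores = {
        v: scores_by_coord[v.coordinate_string()]
        for v in cohort.variants if v.coordinate_string() in scores_by_coord
    }

    lists = cooccurrence.build_sample_variant_lists(cohort, classes)
    records = cooccurrence.find_cooccurrences(lists, cohort.gene_assignment, cohort)
    if phenotypes is not None:
        records = cooccurrence.annotate_ages(records, phenotypes)
    trans = cooccurrence.infer_trans(records)

    bundles = evidence.build_evidence_table(
        cohort, classes, control_ids, scores, thresholds, trans, sites)

    gp_report = (
        reports.genotype_phenotype_report(cohort, phenotypes)
        if phenotypes is not None else None
    )
    return AnalysisResult(
        cohort=cohort,
        classes=classes,
        lists=lists,
        records=records,
        trans=trans,
        bundles=bundles,
        evidence_report=reports.evidence_report(bundles),
        cooccurrence_report=reports.cooccurrence_report(
            records, trans, suppress_sample_ids=suppress_sample_ids),
        genotype_phenotype_report=gp_report,
    )


def pathogenic_carrier_status(
    result: AnalysisResult, phenotypes: PhenotypeTable
) -> dict[str, bool]:
    """Per-sample flag: carries at least one pathogenic variant."""
    carriers = set(result.lists.pathogenic)
    return {sid: sid in carriers for sid in phenotypes.records
            if sid in set(result.cohort.sample_ids)}
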