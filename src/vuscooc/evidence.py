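"""Control allele frequencies and ACMG/AMP evidence-code assignment.

Thresholds follow the proposed BRCA expert-panel rules: BA1 (stand-alone
benign) above an allele frequency of 0.001, BS1 (strong benign) above 0.0001,
PM2 (moderate pathogenic) for absence from the evaluated controls, and
BP4/PP3 from a BayesDel score below/above 0.3. The combined class uses
frequency and bioinformatics only; BS2 eligibility from co-occurrence is
reported alongside as supplementary support.
"""

from __future__ import annotations

from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np

from .model import (
    MISSING,
    AbsentVariantError,
    CohortGenotypes,
    CombinedClass,
    ConfigurationError,
    EvidenceBundle,
    EvidenceThresholds,
    FrequencyCode,
    InSilicoCode,
    PathogenicityClass,
    SitesFrequencies,
    TransInference,
    ValidationError,
    VariantKey,
)

DEFAULT_THRESHOLDS = EvidenceThresholds()


def control_allele_frequency(
    variant: VariantKey, cohort: CohortGenotypes, control_ids: Sequence[str]
) -> float:
    """Alt-allele frequency among controls, excluding missing genotypes.

    AF = (sum of non-missing control dosages) / (2 x controls with a
    non-missing call). Returns 0.0 when no control carries the allele.
    """
    if not control_ids:
        raise ConfigurationError("control set is empty")
    id_set = set(cohort.sample_ids)
    unknown = [c for c in control_ids if c not in id_set]
    if unknown:
        raise ConfigurationError(
            f"{len(unknown)} control IDs absent from cohort, e.g. {unknown[0]!r}")
    vi = cohort.variant_index(variant)
    cols = [cohort.sample_ids.index(c) for c in control_ids]
    dosages = cohort.dosage[vi, cols]
    called = dosages != MISSING
    n_called = int(called.sum())
    if n_called == 0:
        return 0.0
    return float(dosages[called].sum()) / (2 * n_called)


def frequency_code(
    af: float, thresholds: EvidenceThresholds = DEFAULT_THRESHOLDS
) -> FrequencyCode:
    """Assign the population-frequency evidence code for one allele frequency.

    BA1 strictly above the BA1 threshold, BS1 strictly above the BS1
    threshold (inclusive of the BA1 bound), PM2 at exactly zero, NONE in
    between.
    """
    if not (0.0 <= af <= 1.0) or not np.isfinite(af):
        raise ValidationError(f"allele frequency {af} outside [0,1]")
    if af > thresholds.ba1:
        return FrequencyCode.BA1
    if af > thresholds.bs1:
        return FrequencyCode.BS1
    if af == 0.0:
        return FrequencyCode.PM2
    return FrequencyCode.NONE


def insilico_code(
    score: float | None, thresholds: EvidenceThresholds = DEFAULT_THRESHOLDS
) -> InSilicoCode:
    """BP4 below the BayesDel cut, PP3 above it; NONE at the cut or unknown."""
    if score is None:
        return InSilicoCode.NONE
    if score < thresholds.bayesdel_cut:
        return InSilicoCode.BP4
    if score > thresholds.bayesdel_cut:
        return InSilicoCode.PP3
    return InSilicoCode.NONE


def combine_class(freq: FrequencyCode, insilico: InSilicoCode) -> CombinedClass:
    """Combine frequency + bioinformatic codes into {B, LB, VUS}.

    BA1 is stand-alone benign regardless of the in-silico code; BS1 plus BP4
    reaches likely benign; everything else stays VUS.
    """
    if freq is FrequencyCode.BA1:
        return CombinedClass.BENIGN
    if freq is FrequencyCode.BS1 and insilico is InSilicoCode.BP4:
        return CombinedClass.LIKELY_BENIGN
    return CombinedClass.VUS


def build_evidence_table(
    cohort: CohortGenotypes,
    classes: Mapping[VariantKey, PathogenicityClass],
    control_ids: Sequence[str],
    scores: Mapping[VariantKey, float],
    thresholds: EvidenceThresholds = DEFAULT_THRESHOLDS,
    trans: Mapping[Hashable, TransInference] | None = None,
    external: Mapping[str, SitesFrequencies] | None = None,
) -> list[EvidenceBundle]:
    """One EvidenceBundle per VUS observed in the cohort.

    External reference-population frequencies (e.g. exome and genome sites
    files) are annotated side by side, each with its own code; they never
    enter the combined class. BS2 eligibility is carried from the
    co-occurrence stage as supplementary support only.
    """
    trans = trans or {}
    external = external or {}
    bundles: list[EvidenceBundle] = []
    for variant in cohort.variants:
        if classes.get(variant) is not PathogenicityClass.VUS:
            continue
        af = control_allele_frequency(variant, cohort, control_ids)
        fcode = frequency_code(af, thresholds)
        score = scores.get(variant)
        icode = insilico_code(score, thresholds)
        ext_af = {name: sites.lookup(variant) for name, sites in external.items()}
        ext_codes = {
            name: frequency_code(f if f is not None else 0.0, thresholds)
            for name, f in ext_af.items()
        }
        ti = trans.get(variant)
        bundles.append(EvidenceBundle(
            variant=variant,
            control_af=af,
            freq_code=fcode,
            bayesdel=score,
            insilico_code=icode,
            combined_class=combine_class(fcode, icode),
            bs2_eligible=bool(ti.bs2_eligible) if ti is not None else False,
            gene=cohort.gene_of(variant),
            external_af=ext_af,
            external_codes=ext_codes,
        ))
    return bundles


def class_counts(bundles: Iterable[EvidenceBundle]) -> dict[str, int]:
    counts = {c.value: 0 for c in CombinedClass}
    for b in bundles:
        counts[b.combined_class.value] += 1
    return counts
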