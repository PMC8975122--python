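"""Three-valued pathogenicity classification from clinical-significance strings.

The mapping is total: four pathogenic spellings, four benign spellings, and
everything else — including conflicting interpretations, "Unknown", the empty
string, and variants absent from the classification source — is a VUS.
"""

from __future__ import annotations

import logging

from .model import (
    ClassificationTable,
    CohortGenotypes,
    ConfigurationError,
    PathogenicityClass,
    VariantKey,
)

logger = logging.getLogger(__name__)

PATHOGENIC_SPELLINGS = frozenset({
    "Pathogenic",
    "Likely pathogenic",
    "Likely_pathogenic",
    "Pathogenic/Likely_pathogenic",
})

BENIGN_SPELLINGS = frozenset({
    "Benign",
    "Likely benign",
    "Likely_benign",
    "Benign/Likely_benign",
})

_PATHOGENIC_FOLDED = frozenset(s.casefold() for s in PATHOGENIC_SPELLINGS)
_BENIGN_FOLDED = frozenset(s.casefold() for s in BENIGN_SPELLINGS)


def map_significance(raw: str, case_insensitive: bool = False) -> PathogenicityClass:
    """Map one clinical-significance string to {PATHOGENIC, BENIGN, VUS}.

    Matching is case-sensitive on the enumerated spellings after stripping
    surrounding whitespace; ``case_insensitive=True`` enables a folded
    fallback match. Total: any unrecognized value is VUS.
    """
    s = raw.strip() if isinstance(raw, str) else ""
    if s in PATHOGENIC_SPELLINGS:
        return PathogenicityClass.PATHOGENIC
    if s in BENIGN_SPELLINGS:
        return PathogenicityClass.BENIGN
    if case_insensitive:
        if s.casefold() in _PATHOGENIC_FOLDED:
            return PathogenicityClass.PATHOGENIC
        if s.casefold() in _BENIGN_FOLDED:
            return PathogenicityClass.BENIGN
    return PathogenicityClass.VUS


def classify_cohort(
    cohort: CohortGenotypes,
    table: ClassificationTable,
    case_insensitive: bool = False,
) -> dict[VariantKey, PathogenicityClass]:
    """Label every cohort variant; variants absent from the table are VUS."""
    if cohort.build is not table.source_build:
        raise ConfigurationError(
            f"build mismatch: cohort {cohort.build.value} vs "
            f"classification table {table.source_build.value}")
    labels: dict[VariantKey, PathogenicityClass] = {}
    for key in cohort.variants:
        raw = table.entries.get(key)
        labels[key] = (
            PathogenicityClass.VUS if raw is None
            else map_significance(raw, case_insensitive=case_insensitive)
        )
    counts = {c: 0 for c in PathogenicityClass}
    for c in labels.values():
        counts[c] += 1
    logger.info(
        "classified %d variants: %d pathogenic, %d benign, %d VUS",
        len(labels), counts[PathogenicityClass.PATHOGENIC],
        counts[PathogenicityClass.BENIGN], counts[PathogenicityClass.VUS])
    return labels
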