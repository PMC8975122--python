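from __future__ import annotations

import pytest

from vuscooc.model import GenomeBuild, VariantKey
from vuscooc.synthetic import FixtureSpec, Planting, PlantedVariant, generate_fixture

BUILD = GenomeBuild.GRCH38

# GRCh38 gene spans (rounded to the kb)
GENES = {
    "BRCA1": ("17", 43044000, 43126000),
    "BRCA2": ("13", 32315000, 32400000),
}


def vk(chrom: str, pos: int, ref: str, alt: str) -> VariantKey:
    return VariantKey(chrom, pos, ref, alt, BUILD)


@pytest.fixture(scope="session")
def planted_spec() -> FixtureSpec:
    """Cohort with one BS2-eligible VUS (two distinct pathogenic partners in
    two carriers), one homozygous VUS, one single-partner VUS, one benign
    variant, and a common-benign frequency ladder for the code thresholds."""
    p1 = vk("13", 32332000, "A", "T")
    p2 = vk("13", 32340000, "G", "C")
    p3 = vk("17", 43100000, "C", "T")
    v_two_partners = vk("13", 32320000, "C", "G")
    v_hom = vk("17", 43050000, "G", "A")
    v_single = vk("13", 32360000, "T", "A")
    benign = vk("13", 32350000, "T", "C")
    return FixtureSpec(
        n_cases=6,
        n_controls=10,
        genes=GENES,
        planted=[
            PlantedVariant(p1, "Pathogenic"),
            PlantedVariant(p2, "Likely_pathogenic"),
            PlantedVariant(p3, "Pathogenic"),
            PlantedVariant(
                v_two_partners, None, control_af_target=0.05, bayesdel=-0.5,
                plantings=(
                    Planting("case_0001", "het", (p1,)),
                    Planting("case_0002", "het", (p2,)),
                )),
            PlantedVariant(
                v_hom, "Conflicting_interpretations_of_pathogenicity",
                control_af_target=0.1, bayesdel=-0.3,
                plantings=(Planting("case_0003", "hom"),)),
            PlantedVariant(
                v_single, None, control_af_target=0.0, bayesdel=0.5,
                plantings=(Planting("case_0004", "het", (p1,)),)),
            PlantedVariant(benign, "Benign", control_af_target=0.2, bayesdel=-0.9),
        ],
        n_background=4,
        seed=11,
    )


@pytest.fixture(scope="session")
def fixture_paths(planted_spec, tmp_path_factory):
    out = tmp_path_factory.mktemp("fixture")
    return generate_fixture(planted_spec, str(out))
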