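from __future__ import annotations

import numpy as np
import pytest

from vuscooc.cooccurrence import (
    annotate_ages,
    build_sample_variant_lists,
    find_cooccurrences,
    infer_trans,
)
from vuscooc.model import (
    CohortGenotypes,
    CooccurrenceKind,
    CooccurrenceRecord,
    GenomeBuild,
    PathogenicityClass,
    PhenotypeRecord,
    PhenotypeTable,
    VariantKey,
)

from conftest import BUILD, vk
from helpers import brute_force_cooccurrences, random_cohort_and_classes, record_set


def make_cohort(sample_ids, entries, phased=False):
    """entries: {(variant, gene): {sample_id: (hap0, hap1)}}"""
    variants = [v for v, _ in entries]
    gene_assignment = {v: g for v, g in entries}
    alleles = np.zeros((len(variants), len(sample_ids), 2), dtype=np.int8)
    for vi, ((variant, _), calls) in enumerate(zip(entries, entries.values())):
        for sid, (a, b) in calls.items():
            alleles[vi, sample_ids.index(sid)] = (a, b)
    phased_arr = np.full((len(variants), len(sample_ids)), phased, dtype=bool)
    return CohortGenotypes(list(sample_ids), variants, alleles, phased_arr,
                           gene_assignment, BUILD)


def test_build_sample_variant_lists_partitions_carriers():
    vus = vk("13", 32320000, "C", "G")
    path = vk("13", 32332000, "A", "T")
    ben = vk("13", 32350000, "T", "C")
    cohort = make_cohort(
        ["s1", "s2", "s3"],
        {
            (vus, "BRCA2"): {"s1": (0, 1)},
            (path, "BRCA2"): {"s1": (0, 1), "s2": (1, 1)},
            (ben, "BRCA2"): {"s3": (0, 1)},
        })
    classes = {vus: PathogenicityClass.VUS, path: PathogenicityClass.PATHOGENIC,
               ben: PathogenicityClass.BENIGN}
    lists = build_sample_variant_lists(cohort, classes)
    assert [v for v, _, _ in lists.vus["s1"]] == [vus]
    assert [v for v, _, _ in lists.pathogenic["s1"]] == [path]
    assert lists.pathogenic["s2"] == [(path, 2, False)]
    assert lists.benign["s3"] == [(ben, 1, False)]
    # all-reference sample appears in no list
    assert "s3" not in lists.vus and "s3" not in lists.pathogenic
    assert "s2" not in lists.vus


def test_build_sample_variant_lists_requires_full_classes():
    vus = vk("13", 32320000, "C", "G")
    cohort = make_cohort(["s1"], {(vus, "BRCA2"): {"s1": (0, 1)}})
    with pytest.raises(KeyError):
        build_sample_variant_lists(cohort, {})


def test_find_cooccurrences_homozygous_and_compound():
    vus = vk("13", 32320000, "C", "G")
    hom_vus = vk("17", 43050000, "G", "A")
    p1 = vk("13", 32332000, "A", "T")
    p2 = vk("13", 32340000, "G", "C")
    p_other_gene = vk("17", 43100000, "C", "T")
    cohort = make_cohort(
        ["s1", "s2"],
        {
            (vus, "BRCA2"): {"s1": (0, 1)},
            (hom_vus, "BRCA1"): {"s2": (1, 1)},
            (p1, "BRCA2"): {"s1": (0, 1)},
            (p2, "BRCA2"): {"s1": (0, 1)},
            (p_other_gene, "BRCA1"): {"s1": (0, 1)},
        })
    classes = {vus: PathogenicityClass.VUS, hom_vus: PathogenicityClass.VUS,
               p1: PathogenicityClass.PATHOGENIC, p2: PathogenicityClass.PATHOGENIC,
               p_other_gene: PathogenicityClass.PATHOGENIC}
    lists = build_sample_variant_lists(cohort, classes)
    records = find_cooccurrences(lists, cohort.gene_assignment, cohort)
    got = record_set(records)
    # one VUS het + two same-gene pathogenic hets -> two compound records;
    # the BRCA1 pathogenic is cross-gene for this VUS and excluded
    assert got == {
        ("COMPOUND_WITH_PATHOGENIC", vus, p1, "s1"),
        ("COMPOUND_WITH_PATHOGENIC", vus, p2, "s1"),
        ("HOMOZYGOUS", hom_vus, None, "s2"),
    }


@pytest.mark.parametrize("seed", range(12))
def test_find_cooccurrences_matches_brute_force(seed):
    cohort, classes = random_cohort_and_classes(seed, n_samples=25, n_variants=40)
    lists = build_sample_variant_lists(cohort, classes)
    records = find_cooccurrences(lists, cohort.gene_assignment, cohort)
    assert record_set(records) == brute_force_cooccurrences(cohort, classes)


# --- in-trans inference -----------------------------------------------------

def compound(vus, partner, sample):
    return CooccurrenceRecord(
        vus=vus, kind=CooccurrenceKind.COMPOUND_WITH_PATHOGENIC,
        sample_id=sample, gene="BRCA", partner=partner)


def test_infer_trans_footnote_partner_sets():
    """Two distinct pathogenic partners guarantee one in-trans relationship;
    a single unphased co-occurrence never does."""
    records = [
        compound("c.4729T>C", "c.1518del", "sA"),
        compound("c.4729T>C", "c.188T>A", "sB"),
        compound("c.964A>C", "c.6952C>T", "sC"),
        compound("c.964A>C", "c.5645C>A", "sD"),
        compound("c.964A>C", "c.6244G>T", "sE"),
        compound("c.5660C>T", "c.1261C>T", "sF"),
        compound("c.4365A>G", "c.7480C>T", "sG"),
    ]
    trans = infer_trans(records)
    assert trans["c.4729T>C"].bs2_eligible is True
    assert trans["c.964A>C"].bs2_eligible is True
    assert len(trans["c.964A>C"].distinct_pathogenic_partners) == 3
    assert trans["c.5660C>T"].bs2_eligible is False
    assert trans["c.4365A>G"].bs2_eligible is False


def test_infer_trans_homozygote_and_repeated_pair():
    hom = CooccurrenceRecord(vus="v", kind=CooccurrenceKind.HOMOZYGOUS,
                             sample_id="s1", gene="BRCA", trans_confirmed=True)
    assert infer_trans([hom])["v"].bs2_eligible is True
    # same VUS-partner pair in two samples counts once
    repeated = [compound("v", "p", "s1"), compound("v", "p", "s2")]
    ti = infer_trans(repeated)["v"]
    assert len(ti.distinct_pathogenic_partners) == 1
    assert ti.bs2_eligible is False
    assert ti.n_samples == 2


def test_infer_trans_monotone_in_partners():
    """Adding a pathogenic partner never turns eligibility off."""
    base = [compound("v", "p1", "s1")]
    for extra in ["p1", "p2", "p3"]:
        bigger = base + [compound("v", extra, "s9")]
        before = infer_trans(base)["v"].bs2_eligible
        after = infer_trans(bigger)["v"].bs2_eligible
        assert after >= before
        base = bigger
    assert infer_trans(base)["v"].bs2_eligible is True


def test_phased_single_cooccurrence_resolves_trans():
    vus = vk("13", 32320000, "C", "G")
    p1 = vk("13", 32332000, "A", "T")
    cis_vus = vk("13", 32360000, "T", "A")
    cohort = make_cohort(
        ["s1"],
        {
            (vus, "BRCA2"): {"s1": (0, 1)},
            (p1, "BRCA2"): {"s1": (1, 0)},      # opposite haplotype: trans
            (cis_vus, "BRCA2"): {"s1": (1, 0)},  # same haplotype as p1: cis
        },
        phased=True)
    classes = {vus: PathogenicityClass.VUS, cis_vus: PathogenicityClass.VUS,
               p1: PathogenicityClass.PATHOGENIC}
    lists = build_sample_variant_lists(cohort, classes)
    records = find_cooccurrences(lists, cohort.gene_assignment, cohort)
    trans = infer_trans(records)
    assert trans[vus].phased_trans_observed is True
    assert trans[vus].bs2_eligible is True
    # cis configuration: partner on the same haplotype as the VUS
    assert trans[cis_vus].phased_trans_observed is False
    assert trans[cis_vus].bs2_eligible is False


def test_annotate_ages_attaches_and_retains():
    recs = [compound("v", "p", "s1"), compound("v", "p", "s2")]
    phenotypes = PhenotypeTable({
        "s1": PhenotypeRecord(id="s1", age_at_diagnosis=62, age_at_entry=64),
    })
    out = annotate_ages(recs, phenotypes)
    assert len(out) == 2  # unmatched carrier retained
    assert out[0].age_at_diagnosis == 62
    assert out[1].age_at_diagnosis is None
    # empty phenotype table: everything retained with unknown ages
    out2 = annotate_ages([compound("v", "p", "s3")], PhenotypeTable({}))
    assert len(out2) == 1 and out2[0].age_at_entry is None
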