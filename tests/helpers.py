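"""Independent oracles and small utilities shared across the test suite.

These deliberately avoid the code paths they check: the co-occurrence oracle
is a plain quadratic scan over the dosage matrix, and the Fisher oracle is a
direct hypergeometric enumeration with exact rational-free arithmetic.
"""

from __future__ import annotations

from math import comb

from vuscooc.model import (
    OUTSIDE_GENE,
    CohortGenotypes,
    CooccurrenceKind,
    PathogenicityClass,
)


def brute_force_cooccurrences(cohort: CohortGenotypes, classes) -> set[tuple]:
    """Exhaustive per-sample scan; returns {(kind, vus, partner, sample_id)}."""
    found = set()
    dosage = cohort.dosage
    for si, sid in enumerate(cohort.sample_ids):
        carried = [(cohort.variants[vi], int(dosage[vi, si]))
                   for vi in range(cohort.n_variants) if dosage[vi, si] >= 1]
        for vus, dos in carried:
            if classes[vus] is not PathogenicityClass.VUS:
                continue
            if dos == 2:
                found.add(("HOMOZYGOUS", vus, None, sid))
            gene = cohort.gene_assignment.get(vus)
            if gene is None or gene == OUTSIDE_GENE:
                continue
            for partner, _ in carried:
                if partner is vus:
                    continue
                if classes[partner] is not PathogenicityClass.PATHOGENIC:
                    continue
                if cohort.gene_assignment.get(partner) != gene:
                    continue
                found.add(("COMPOUND_WITH_PATHOGENIC", vus, partner, sid))
    return found


def record_set(records) -> set[tuple]:
    return {
        (r.kind.value, r.vus,
         r.partner if r.kind is CooccurrenceKind.COMPOUND_WITH_PATHOGENIC else None,
         r.sample_id)
        for r in records
    }


def random_cohort_and_classes(seed: int, n_samples: int, n_variants: int):
    """Random cohort (with missingness) + random class labels for oracle tests."""
    import numpy as np

    from vuscooc.model import GenomeBuild, VariantKey

    rng = np.random.default_rng(seed)
    build = GenomeBuild.GRCH38
    genes = {"G1": ("1", 1, 10_000), "G2": ("2", 1, 10_000)}
    positions = rng.choice(10_000, size=n_variants, replace=False) + 1
    chroms = rng.choice(["1", "2", "9"], size=n_variants)  # chrom 9 -> outside
    variants = [
        VariantKey(c, int(p), "A", "T", build) for c, p in zip(chroms, positions)
    ]
    alleles = rng.choice([0, 0, 0, 1, -1], size=(n_variants, n_samples, 2),
                         p=[0.6, 0.15, 0.1, 0.1, 0.05]).astype("int8")
    phased = np.zeros((n_variants, n_samples), dtype=bool)
    gene_assignment = {}
    for v in variants:
        gene_assignment[v] = next(
            (g for g, (c, s, e) in genes.items()
             if v.chromosome == c and s <= v.position <= e),
            OUTSIDE_GENE)
    sample_ids = [f"s{i}" for i in range(n_samples)]
    cohort = CohortGenotypes(sample_ids, variants, alleles, phased,
                             gene_assignment, build)
    labels = rng.choice(list(PathogenicityClass), size=n_variants,
                        p=[0.3, 0.2, 0.5])
    classes = dict(zip(variants, labels))
    return cohort, classes


def random_planted_spec(seed: int):
    """Random FixtureSpec with planted co-occurrence structure.

    Pathogenic variants get zero control frequency and plantings use distinct
    case samples, so the expected record set is derivable from the spec
    alone: every planting yields exactly its homozygous/compound records.
    """
    import numpy as np

    from vuscooc.model import GenomeBuild, VariantKey
    from vuscooc.synthetic import FixtureSpec, PlantedVariant, Planting

    rng = np.random.default_rng(seed)
    build = GenomeBuild.GRCH38
    genes = {"BRCA1": ("17", 43044000, 43126000),
             "BRCA2": ("13", 32315000, 32400000)}
    gene_names = sorted(genes)

    def fresh_position(gene, used):
        chrom, start, end = genes[gene]
        while True:
            pos = int(rng.integers(start, end + 1))
            if (chrom, pos) not in used:
                used.add((chrom, pos))
                return chrom, pos

    used: set = set()
    pathogenic: dict[str, list[VariantKey]] = {g: [] for g in gene_names}
    planted = []
    for g in gene_names:
        for _ in range(int(rng.integers(1, 4))):
            chrom, pos = fresh_position(g, used)
            key = VariantKey(chrom, pos, "A", "T", build)
            pathogenic[g].append(key)
            planted.append(PlantedVariant(key, "Pathogenic"))

    n_vus = int(rng.integers(1, 4))
    plantings_per_vus = [int(rng.integers(0, 3)) for _ in range(n_vus)]
    n_cases = max(4, sum(plantings_per_vus))
    n_controls = int(rng.integers(5, 21))
    case_ids = [f"case_{i:04d}" for i in range(1, n_cases + 1)]
    next_case = iter(case_ids)

    for k in range(n_vus):
        g = gene_names[int(rng.integers(len(gene_names)))]
        chrom, pos = fresh_position(g, used)
        key = VariantKey(chrom, pos, "C", "G", build)
        plantings = []
        for _ in range(plantings_per_vus[k]):
            sid = next(next_case)
            zygosity = "hom" if rng.random() < 0.3 else "het"
            n_partners = int(rng.integers(0, len(pathogenic[g]) + 1))
            partners = tuple(
                pathogenic[g][i]
                for i in rng.choice(len(pathogenic[g]), size=n_partners,
                                    replace=False)) if n_partners else ()
            plantings.append(Planting(sid, zygosity, partners))
        planted.append(PlantedVariant(
            key, None,
            control_af_target=float(rng.choice([0.0, 0.05, 0.1, 0.2])),
            plantings=tuple(plantings)))

    return FixtureSpec(
        n_cases=n_cases, n_controls=n_controls, genes=genes,
        planted=planted, n_background=int(rng.integers(0, 6)),
        seed=seed, build=build)


def expected_planted_records(spec) -> set[tuple]:
    """Records implied by the plantings alone, in brute-force oracle form."""
    expected = set()
    for pv in spec.planted:
        for pl in pv.plantings:
            if pl.zygosity == "hom":
                expected.add(("HOMOZYGOUS", pv.key, None, pl.sample_id))
            for partner in pl.partners:
                expected.add(("COMPOUND_WITH_PATHOGENIC", pv.key, partner,
                              pl.sample_id))
    return expected


def fisher_enumeration_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full enumeration over the hypergeometric support.

    Probabilities are computed from binomial coefficients; tables whose point
    probability is at most the observed one (1e-7 relative slack) are summed.
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)

    def pmf(x: int) -> float:
        return comb(r1, x) * comb(r2, c1 - x) / denom

    p_obs = pmf(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(pmf(x) for x in range(lo, hi + 1)
               if pmf(x) <= p_obs * (1 + 1e-7))
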