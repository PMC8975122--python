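"""Synthetic fixture generation: cohort VCF + phenotype TSV + classification
and score tables with planted structure, plus the transcribed 19-variant
worked example used for end-to-end verification.

The generator emulates the shape of a case-control breast-cancer cohort:
anonymized sample IDs, controls at least 60 years old with no cancer
phenotype, tumor receptor statuses for cases, and gene-restricted variants.
Genotype placement is deterministic given the seed, so realized control
allele counts hit their targets exactly and identical seeds yield
byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import write_cohort_vcf
from .model import (
    CohortGenotypes,
    ConfigurationError,
    GenomeBuild,
    VariantKey,
    normalize_chromosome,
)


@dataclass(frozen=True)
class Planting:
    """Place a variant in a named case sample, optionally with het partners."""

    sample_id: str
    zygosity: str  # "het" | "hom"
    partners: tuple[VariantKey, ...] = ()

    def __post_init__(self) -> None:
        if self.zygosity not in {"het", "hom"}:
            raise ConfigurationError(f"zygosity must be het|hom, got {self.zygosity!r}")


@dataclass(frozen=True)
class PlantedVariant:
    key: VariantKey
    significance: str | None  # None -> absent from the classification table
    control_af_target: float = 0.0
    bayesdel: float | None = None
    plantings: tuple[Planting, ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.control_af_target <= 1.0):
            raise ConfigurationError(
                f"target AF {self.control_af_target} outside [0,1]")


@dataclass
class FixtureSpec:
    n_cases: int
    n_controls: int
    genes: dict[str, tuple[str, int, int]]
    planted: list[PlantedVariant] = field(default_factory=list)
    n_background: int = 0
    seed: int = 0
    build: GenomeBuild = GenomeBuild.GRCH38
    phased: bool = False

    @property
    def case_ids(self) -> list[str]:
        return [f"case_{i:04d}" for i in range(1, self.n_cases + 1)]

    @property
    def control_ids(self) -> list[str]:
        return [f"control_{i:04d}" for i in range(1, self.n_controls + 1)]

    @classmethod
    def from_json(cls, path: str) -> "FixtureSpec":
        with open(path) as fh:
            raw = json.load(fh)
        build = GenomeBuild.from_string(raw.get("build", "38"))
        genes = {g: (c, int(s), int(e)) for g, (c, s, e) in raw["genes"].items()}
        planted = []
        for p in raw.get("planted", []):
            key = VariantKey(p["chromosome"], int(p["position"]),
                             p["ref"], p["alt"], build)
            plantings = tuple(
                Planting(
                    sample_id=pl["sample_id"],
                    zygosity=pl["zygosity"],
                    partners=tuple(
                        VariantKey(q["chromosome"], int(q["position"]),
                                   q["ref"], q["alt"], build)
                        for q in pl.get("partners", [])),
                )
                for pl in p.get("plantings", []))
            planted.append(PlantedVariant(
                key=key,
                significance=p.get("significance"),
                control_af_target=float(p.get("control_af_target", 0.0)),
                bayesdel=p.get("bayesdel"),
                plantings=plantings,
            ))
        return cls(
            n_cases=int(raw["n_cases"]),
            n_controls=int(raw["n_controls"]),
            genes=genes,
            planted=planted,
            n_background=int(raw.get("n_background", 0)),
            seed=int(raw.get("seed", 0)),
            build=build,
            phased=bool(raw.get("phased", False)),
        )


def build_cohort(spec: FixtureSpec) -> CohortGenotypes:
    """Construct the in-memory cohort the fixture files serialize.

    Control allele counts equal round(target_af x 2 x n_controls) exactly:
    alt alleles are packed deterministically into the leading control
    samples (hets first, then homozygotes once every control is a carrier).
    Named plantings go into case samples only, so they never perturb the
    realized control frequency. Background variants are drawn at low allele
    counts from the seeded generator.
    """
    rng = np.random.default_rng(spec.seed)
    sample_ids = spec.case_ids + spec.control_ids
    n_samples = len(sample_ids)
    sample_index = {s: i for i, s in enumerate(sample_ids)}
    control_offset = spec.n_cases

    variant_keys: list[VariantKey] = []
    seen: set[VariantKey] = set()

    def _add(key: VariantKey) -> None:
        if key not in seen:
            seen.add(key)
            variant_keys.append(key)

    for pv in spec.planted:
        _add(pv.key)
        for pl in pv.plantings:
            for partner in pl.partners:
                _add(partner)

    planted_by_key = {pv.key: pv for pv in spec.planted}

    # background variants at unique positions inside configured genes
    background: list[VariantKey] = []
    if spec.n_background:
        gene_list = sorted(spec.genes)
        used_pos = {(k.chromosome, k.position) for k in seen}
        bases = np.array(list("ACGT"))
        while len(background) < spec.n_background:
            gene = gene_list[int(rng.integers(len(gene_list)))]
            chrom, start, end = spec.genes[gene]
            pos = int(rng.integers(start, end + 1))
            if (normalize_chromosome(chrom), pos) in used_pos:
                continue
            ref, alt = rng.choice(bases, size=2, replace=False)
            key = VariantKey(chrom, pos, str(ref), str(alt), spec.build)
            used_pos.add((key.chromosome, key.position))
            background.append(key)
            _add(key)

    n_variants = len(variant_keys)
    alleles = np.zeros((n_variants, n_samples, 2), dtype=np.int8)
    vindex = {k: i for i, k in enumerate(variant_keys)}

    for pv in spec.planted:
        count = int(round(pv.control_af_target * 2 * spec.n_controls))
        if count > 2 * spec.n_controls:
            raise ConfigurationError(
                f"target allele count {count} exceeds 2 x {spec.n_controls} controls "
                f"for {pv.key.coordinate_string()}")
        vi = vindex[pv.key]
        if count <= spec.n_controls:
            for j in range(count):
                alleles[vi, control_offset + j, 1] = 1
        else:
            n_hom = count - spec.n_controls
            for j in range(spec.n_controls):
                alleles[vi, control_offset + j, 1] = 1
                if j < n_hom:
                    alleles[vi, control_offset + j, 0] = 1
        for pl in pv.plantings:
            si = sample_index.get(pl.sample_id)
            if si is None:
                raise ConfigurationError(f"unknown planting sample {pl.sample_id!r}")
            if si >= control_offset:
                raise ConfigurationError(
                    f"planting sample {pl.sample_id!r} must be a case "
                    "(control genotypes are reserved for AF targets)")
            alleles[vi, si, 1] = 1
            if pl.zygosity == "hom":
                alleles[vi, si, 0] = 1
            for k, partner in enumerate(pl.partners):
                # partner goes on the opposite haplotype from the VUS
                alleles[vindex[partner], si, 0] = 1

    for key in background:
        vi = vindex[key]
        n_carriers = int(rng.integers(1, 4))
        carriers = rng.choice(n_samples, size=min(n_carriers, n_samples), replace=False)
        for si in carriers:
            alleles[vi, si, 1] = 1

    phased = np.full((n_variants, n_samples), spec.phased, dtype=bool)
    gene_assignment = {
        k: _gene_of(k, spec.genes) for k in variant_keys
    }
    return CohortGenotypes(sample_ids, variant_keys, alleles, phased,
                           gene_assignment, spec.build)


def _gene_of(key: VariantKey, genes: dict[str, tuple[str, int, int]]) -> str:
    from .model import OUTSIDE_GENE
    for gene, (chrom, start, end) in genes.items():
        if key.chromosome == normalize_chromosome(chrom) and start <= key.position <= end:
            return gene
    return OUTSIDE_GENE


def build_phenotypes(spec: FixtureSpec) -> pd.DataFrame:
    """Phenotype TSV contents: cases with tumor features and ages at
    diagnosis; controls aged >= 60 with no cancer phenotype."""
    rng = np.random.default_rng(spec.seed + 1)
    rows = []
    for sid in spec.case_ids:
        age_dx = int(rng.integers(25, 76))
        rows.append({
            "ID": sid,
            "case_control": 1,
            "ER": int(rng.integers(0, 2)),
            "PR": int(rng.integers(0, 2)),
            "HER2": int(rng.integers(0, 2)),
            "age_at_diagnosis": age_dx,
            "age_at_entry": age_dx + int(rng.integers(0, 6)),
        })
    for sid in spec.control_ids:
        rows.append({
            "ID": sid,
            "case_control": 0,
            "ER": "NA",
            "PR": "NA",
            "HER2": "NA",
            "age_at_diagnosis": "NA",
            "age_at_entry": 60 + int(rng.integers(0, 21)),
        })
    return pd.DataFrame(rows)


_COORD_COLUMN = {
    GenomeBuild.GRCH37: "Genomic_Coordinate_hg37",
    GenomeBuild.GRCH38: "Genomic_Coordinate_hg38",
}


@dataclass
class FixturePaths:
    vcf: str
    phenotype: str
    classification: str
    scores: str


def generate_fixture(spec: FixtureSpec, out_dir: str) -> FixturePaths:
    """Write the four fixture files; identical specs yield identical bytes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = build_cohort(spec)

    vcf_path = out / "cohort.vcf"
    write_cohort_vcf(cohort, str(vcf_path))

    pheno_path = out / "phenotype.tsv"
    build_phenotypes(spec).to_csv(pheno_path, sep="\t", index=False, lineterminator="\n")

    coord_col = _COORD_COLUMN[spec.build]
    class_rows = [
        {coord_col: pv.key.coordinate_string(),
         "Clinical_significance": pv.significance}
        for pv in spec.planted if pv.significance is not None
    ]
    class_path = out / "classification.tsv"
    pd.DataFrame(class_rows, columns=[coord_col, "Clinical_significance"]).to_csv(
        class_path, sep="\t", index=False, lineterminator="\n")

    score_rows = [
        {"Genomic_Coordinate": pv.key.coordinate_string(), "BayesDel": pv.bayesdel}
        for pv in spec.planted if pv.bayesdel is not None
    ]
    scores_path = out / "scores.tsv"
    pd.DataFrame(score_rows, columns=["Genomic_Coordinate", "BayesDel"]).to_csv(
        scores_path, sep="\t", index=False, lineterminator="\n")

    return FixturePaths(str(vcf_path), str(pheno_path), str(class_path),
                        str(scores_path))


# ---------------------------------------------------------------------------
# the transcribed 19-variant worked example


@dataclass(frozen=True)
class Table1Variant:
    """One row of the published 19-variant summary, keyed by cDNA HGVS.

    Frequencies are the BioBank Japan control allele frequencies; gnomAD
    East-Asian frequencies and the gnomAD-derived code are carried as input
    annotations (their derivation rule is upstream, not recomputed here).
    ``printed_frequency_code`` and ``printed_class`` transcribe the published
    call for comparison; the pipeline recomputes both from the inputs.
    """

    gene: str
    cdna: str
    protein: str
    clinvar: str
    gnomad_exome_af: float | None
    gnomad_genome_af: float | None
    gnomad_code: str
    control_af: float
    bayesdel: float
    partners: tuple[str, ...]
    printed_frequency_code: str
    printed_class: str


def table1_fixture() -> list[Table1Variant]:
    """The 19 uninterpreted BRCA1/2 variants of the worked example.

    Control allele frequencies, BayesDel scores, gnomAD annotations and the
    compound-heterozygous partner sets (from the table footnote) are
    transcribed; ``None`` marks absence from gnomAD.
    """
    rows = [
        # gene, cdna, protein, clinvar, gnomad_ex, gnomad_ge, gnomad_code,
        # control_af, bayesdel, partners, printed_code, printed_class
        ("BRCA2", "c.6325G>A", "p.A2351G", "B/LB", 2.55e-3, 2.39e-3, "BA1",
         1.46e-2, -0.61, (), "BA1", "B"),
        ("BRCA2", "c.7052C>G", "p.A2351G", "B/LB", 1.87e-3, 2.02e-3, "BA1",
         3.16e-3, -0.24, (), "BA1", "B"),
        ("BRCA2", "c.943T>A", "p.C315S", "B/LB", 5.30e-3, 5.03e-3, "BA1",
         1.56e-3, -0.41, (), "BA1", "B"),
        ("BRCA1", "c.4729T>C", "p.S1577P", "B/LB", 2.65e-4, 2.02e-4, "BS1",
         1.14e-2, 0.03, ("c.1518del", "c.188T>A"), "BA1", "B"),
        ("BRCA2", "c.4365A>G", "p.A2351G", "LB", None, 2.01e-3, "BS1",
         4.64e-4, -0.52, ("c.7480C>T",), "BS1", "LB"),
        ("BRCA2", "c.6131G>T", "p.G2044V", "Conflict", 4.52e-4, 4.52e-3, "BA1",
         3.29e-2, -0.16, (), "BA1", "B"),
        ("BRCA2", "c.964A>C", "p.K322Q", "Conflict", 4.31e-4, 2.41e-3, "BA1",
         2.31e-3, -0.08, ("c.6952C>T", "c.5645C>A", "c.6244G>T"), "BA1", "B"),
        ("BRCA1", "c.154C>T", "p.L52F", "Conflict", 1.36e-3, 4.03e-4, "BA1",
         6.78e-3, 0.14, (), "BA1", "B"),
        ("BRCA1", "c.811G>A", "p.V271M", "Conflict", 1.32e-3, 1.21e-3, "BA1",
         6.28e-3, 0.06, (), "BA1", "B"),
        ("BRCA2", "c.5969A>C", "p.D1990A", "Conflict", 0.0, 4.03e-4, "BS1",
         2.61e-3, -0.08, (), "BA1", "B"),
        ("BRCA2", "c.3395A>G", "p.K1132R", "VUS", None, 2.01e-4, "BS1",
         3.75e-3, -0.2, (), "BA1", "B"),
        ("BRCA2", "c.9733T>G", "p.S3245A", "VUS", None, None, "PM2",
         1.01e-3, -0.47, (), "BA1", "B"),
        ("BRCA2", "c.5660C>T", "p.T1887M", "VUS", 1.13e-4, None, "BS1",
         1.69e-4, -0.29, ("c.1261C>T",), "BS1", "LB"),
        ("BRCA2", "c.2672T>A", "p.V891D", "VUS", None, None, "PM2",
         9.69e-4, -0.05, (), "BS1", "LB"),
        ("BRCA2", "c.587G>T", "p.S196I", "VUS", 1.78e-4, None, "BS1",
         4.64e-4, -0.22, (), "BS1", "LB"),
        ("BRCA2", "c.8040C>G", "p.D2680E", "VUS", None, 2.02e-4, "BS1",
         9.69e-4, -0.05, (), "BS1", "LB"),
        ("BRCA2", "c.358G>A", "p.V120M", "Absent", None, None, "PM2",
         0.0, -0.48, (), "PM2", "VUS"),
        ("BRCA2", "c.3983G>A", "p.S1328N", "Conflict", 0.0, None, "PM2",
         0.0, -0.57, (), "PM2", "VUS"),
        ("BRCA2", "c.6637T>C", "p.S2213P", "Conflict", None, None, "PM2",
         0.0, -0.06, (), "PM2", "VUS"),
    ]
    return [Table1Variant(*row) for row in rows]
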