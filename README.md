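# vuscooc

Evidence mining for variants of uncertain significance (VUS) from a
case-control cohort, designed for federated use: the analysis runs where the
patient-level data lives (a cohort VCF plus a phenotype TSV) and emits only
summary-level reports that can be shared with external curators.

## Who this is for

Variant-curation teams that need population-frequency and co-occurrence
evidence from cohorts they cannot access directly — for example BRCA1/2
curation against a national biobank. The package reads:

- a **cohort VCF** (phased or unphased, anonymized sample IDs),
- a **classification table** (`Clinical_significance` +
  `Genomic_Coordinate_hg37`/`hg38` columns, coordinates like
  `chr13:g.32314514:C>T`),
- a **phenotype TSV** keyed by an `ID` column (case/control flag, ER/PR/HER2
  receptor status, ages),
- optional **sites VCFs** with reference-population allele frequencies and a
  per-variant **BayesDel score table**,

and produces four reports: data quality, genotype–phenotype intersection,
variant frequency + co-occurrence with ACMG/AMP evidence codes, and a tumor
pathology report stratified by pathogenic-carrier status.

## The evidence model

Every cohort variant is labeled pathogenic / benign / VUS from its
clinical-significance string (exact spellings such as
`Pathogenic/Likely_pathogenic`; anything unrecognized or absent is a VUS).
For each VUS the package computes:

- **Control allele frequency** `AF = Σ dosage / (2 · n_called controls)`,
  with missing genotypes excluded from the denominator.
- **Frequency code**: BA1 if `AF > 0.001` (stand-alone benign), BS1 if
  `0.0001 < AF ≤ 0.001` (strong benign), PM2 if `AF = 0` (absent from
  controls), otherwise no code. Thresholds are configurable.
- **In-silico code**: BP4 if BayesDel `< 0.3`, PP3 if `> 0.3`.
- **Combined class**: Benign if BA1; Likely Benign if BS1 ∧ BP4; VUS
  otherwise.
- **BS2 eligibility** from co-occurrence: a VUS observed homozygous, or with
  ≥ 2 *distinct* pathogenic partners in the same gene, or phase-confirmed in
  trans, is eligible for BS2 (a healthy adult compound
  heterozygote/homozygote for BRCA1/2 would be expected to show Fanconi
  anemia). A single unphased co-occurrence is never sufficient — it may be
  in cis. BS2 is reported as supplementary support, never folded into the
  combined class; carrier ages are attached for curator review.

Contingency statistics in the pathology report use two-sided Fisher's exact
tests and Woolf logit 95% confidence intervals with Haldane–Anscombe
zero-cell correction.

## Worked example

The package ships a transcribed 19-variant summary (BioBank-Japan-style
control frequencies, BayesDel scores, reference-population annotations and
co-occurrence partner lists) as `vuscooc.synthetic.table1_fixture()`:

```python
from vuscooc.evidence import combine_class, frequency_code, insilico_code
from vuscooc.synthetic import table1_fixture

rows = table1_fixture()
classes = [combine_class(frequency_code(r.control_af),
                         insilico_code(r.bayesdel)).value for r in rows]
print({c: classes.count(c) for c in ("B", "LB", "VUS")})
```

prints

```
{'B': 11, 'LB': 5, 'VUS': 3}
```

i.e. 11 variants reach stand-alone benign frequency evidence (BA1), 5 reach
Likely Benign from BS1 + BP4 combined, and 3 stay uncertain (absent from
controls, PM2). Of the four VUS with recorded co-occurrences, exactly the
two with multiple distinct pathogenic partners (`c.4729T>C`, `c.964A>C`)
are BS2-eligible.

## Command line

```bash
vuscooc fixture --spec spec.json --out fx/          # synthetic cohort with planted structure
vuscooc quality --table fx/phenotype.tsv --config fields.json --out reports/
vuscooc cooccur --vcf fx/cohort.vcf --classification fx/classification.tsv \
    --pheno fx/phenotype.tsv --scores fx/scores.tsv \
    --gene BRCA1:17:43044000-43126000 --gene BRCA2:13:32315000-32400000 \
    --build 38 --out reports/
vuscooc pathology --vcf fx/cohort.vcf --classification fx/classification.tsv \
    --pheno fx/phenotype.tsv --gene BRCA2:13:32315000-32400000 --out reports/
```

All reports are deterministic JSON (plus TSV mirrors); identical inputs give
byte-identical outputs.

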