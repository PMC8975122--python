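# Methods

## Scope and data model

The package mines a case-control cohort for evidence bearing on variants of
uncertain significance (VUS): population-frequency evidence, in-silico
prediction evidence, and co-occurrence evidence, in the ACMG/AMP coding
vocabulary (BA1, BS1, PM2, BP4, PP3, BS2). It is built for a federated
setting: all outputs are summary-level, and the pathology and quality
reports contain no sample identifiers at all (the co-occurrence report lists
anonymized carrier IDs for curator review; a flag suppresses them).

Variant identity is a normalized tuple (chromosome, 1-based position, ref,
alt, build). Both input coordinate dialects — VCF records and
`chrN:g.POS:REF>ALT` strings — are 1-based, so no coordinate shifting is
ever performed. Chromosomes are compared after stripping the `chr` prefix,
uppercasing, and unifying `M`/`MT`. Multi-allelic VCF records are split into
one key per alternate allele; the per-sample dosage of a split key counts
only that allele, which conserves the total alternate-allele count across
the split. Indel alleles are kept exactly as written (left-anchored,
untrimmed): matching between the classification table and the cohort VCF is
exact-string, and representation mismatches are the data preparer's
responsibility — they surface as "variant absent from table → VUS", visible
in the classification counts.

Missing genotypes (`./.`) are excluded from every allele-frequency
denominator rather than imputed; with genotypes missing at random this
leaves the frequency estimate unbiased.

## Classification

Clinical-significance strings map to a three-valued class. Exactly four
spellings are pathogenic (`Pathogenic`, `Likely pathogenic`,
`Likely_pathogenic`, `Pathogenic/Likely_pathogenic`) and four benign
(the `Benign` analogues); everything else — conflicting interpretations,
"Unknown", empty, or absence from the table — is VUS. Matching is
case-sensitive after whitespace stripping because the source vocabularies
use these exact spellings; a case-insensitive fallback exists behind a flag
(default off) for sloppier inputs. Merging multiple classification sources
(e.g. an expert panel overriding single submitters) is deliberately left
upstream: the tool takes one table so the labeling rule stays auditable.

## Evidence codes and the combiner

Thresholds default to the proposed BRCA expert-panel values: BA1 at allele
frequency > 0.001, BS1 at > 0.0001, BayesDel cut at 0.3. All three are
configurable. Boundary behavior: both frequency thresholds are strict, so a
frequency exactly equal to the BA1 threshold earns BS1, and a frequency of
1.01e-3 earns BA1; a BayesDel score exactly at the cut earns neither BP4 nor
PP3. PM2 here means "absent from the evaluated control population"
(AF = 0); absence from external reference populations is computed and
reported separately per sites file, never merged into a single code, because
reference-population code rules (popmax, filtering allele frequency) are
source-specific and are treated as input annotations when provided.

The combined class is intentionally minimal: Benign iff BA1 (stand-alone by
definition), Likely Benign iff BS1 and BP4 together, otherwise VUS. BS2
eligibility is never folded in — co-occurrence evidence is reported beside
the class so curators weigh it explicitly. No Bayesian points-based
combining is attempted.

## Co-occurrence and in-trans inference

Per sample, carried variants (dosage ≥ 1) are partitioned into benign /
pathogenic / VUS lists. A co-occurrence record is emitted for every
(sample, VUS) homozygote and every (sample, VUS, pathogenic partner) pair
within one gene; cross-gene pairs and variants outside the configured gene
intervals are excluded from pairing. Gene membership comes from configured
intervals, not a transcript database, keeping the tool self-contained and
the interval provenance explicit.

BS2 eligibility per VUS is: homozygous observed, OR ≥ 2 distinct pathogenic
partner variants, OR phase-confirmed trans configuration. Distinctness is by
variant identity — the same VUS–partner pair seen in many samples counts
once, since recurring co-occurrence of one pair may simply be a cis
haplotype segregating in the population. The two-distinct-partner rule is
applied regardless of whether the partners were seen in one patient or two:
with two different partners at most one can share a haplotype with the VUS,
so at least one co-occurrence is in trans. Sample multiplicity is recorded
in the report so curators can audit this. When the VCF is phased, trans
status is read directly from haplotype indices and overrides the counting
heuristic. Ages at diagnosis and entry are attached to every co-occurrence
record where the phenotype table has them; no age filtering is automated —
ruling out Fanconi anemia in an adult biallelic carrier is a curator
judgment.

## Reports and statistics

The quality report computes, per configured field, counts of missing and
unexpected values and (for numeric fields) min/max/mean/median/mode over
valid values only; mode ties report the smallest value and set a tie flag.
"Unexpected" means outside the configured range or unparseable for numeric
fields, and outside the allowed set for categorical fields. The report works
on header-less files through config-declared column positions.

The pathology report stratifies tumor features by pathogenic-carrier status
over case samples (tumor features are undefined for cancer-free controls; a
flag widens the stratification to all samples). Per feature it reports 2×2
counts, per-stratum proportions, an odds ratio with Woolf logit 95% CI, and
a two-sided Fisher's exact p. The Fisher test uses the minimum-likelihood
two-sided rule (sum of hypergeometric point probabilities ≤ the observed
one, with 1e-7 relative slack for floating-point ties); the test suite
checks it against a full enumeration oracle on all tables with margins ≤ 12.
The odds-ratio CI method, unspecified by convention, is the Woolf logit
interval with the Haldane–Anscombe 0.5 correction applied to all cells when
any cell is zero: closed-form and zero-cell-safe. Triple-negative status
requires ER, PR and HER2 all negative, with the denominator restricted to
samples where all three are known. Age comparisons between strata use
Welch's two-sided t-test, since equal variances across carrier strata cannot
be assumed. Raw p values are reported without multiple-testing correction,
matching how such per-feature pathology summaries are conventionally read.

All reports serialize to JSON with sorted keys; identical inputs yield
byte-identical files.

## Synthetic fixtures

The generator emulates the shape of the intended input pair — a cohort VCF
and a phenotype TSV with anonymized IDs — with planted structure: target
control allele frequencies, planted homozygous/compound-heterozygous
co-occurrences with chosen partner sets, and a classification and score
table to match. Controls are written as ≥ 60 years old with no tumor
phenotype; cases get receptor statuses and ages at diagnosis. Genotype
placement is fully deterministic given the seed: the realized control allele
count is exactly `round(target_af · 2 · n_controls)` packed into the leading
control samples (hets first), so threshold tests can place frequencies
precisely relative to the code boundaries, and the same seed yields
byte-identical files. Plantings are restricted to case samples so they never
perturb control frequencies. Background variants with small random carrier
counts exercise the no-code paths.

What the generator does **not** emulate: linkage disequilibrium and realistic
haplotype structure, sequencing error, genotyping batch effects, realistic
site-frequency spectra, or relatedness between samples. Passing tests on
these fixtures demonstrate correctness of the counting, inference and
reporting logic under clean inputs — not robustness to the artifacts of real
sequencing data.

A transcribed 19-variant summary (control allele frequencies, BayesDel
scores, reference-population code annotations, and footnote partner lists)
serves as an end-to-end worked example at realistic magnitudes: the
recomputed code row is 11 BA1 / 5 BS1 / 3 PM2, all 19 BayesDel scores fall
in the BP4 range, the combined classes are 11 Benign / 5 Likely Benign /
3 VUS, and exactly the two multi-partner VUS are BS2-eligible.

## Problem sizes and numerical choices

Default test fixtures use cohorts of 6–50 samples and up to ~100 variants,
sizes at which the co-occurrence detector can be verified against an
exhaustive quadratic scan; the detector itself is linear in carried
genotypes and scales to biobank cohorts. The Fisher oracle comparison runs
over every 2×2 table with margins ≤ 12 at 1e-10 absolute tolerance.
Frequency comparisons in tests use exact rational targets
(`count / (2·n_controls)`) to avoid float-boundary ambiguity; the code
thresholds themselves are compared with strict inequalities as defined
above. Degenerate inputs fail loudly and specifically: zero-margin 2×2
tables, empty control sets, all-zero tables, and frequencies outside [0, 1]
raise typed errors rather than returning sentinel numbers.

## Known limitations

- Exact-string allele matching between classification table and cohort VCF;
  no indel normalization or liftover between builds.
- Gene assignment by configured intervals only; no transcript-aware
  annotation (exonic/intronic, consequence).
- The distinct-partner heuristic infers *existence* of a trans relationship,
  not which observation is trans; with phased data this is resolved exactly.
- BayesDel scores are inputs; the package does not compute in-silico
  predictions.
- Reference-population evidence codes are recomputed only as
  absence/frequency against each supplied sites file; source-specific
  popmax/filtering-allele-frequency rules are out of scope.
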