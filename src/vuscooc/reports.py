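"""Shareable summary reports: data quality, genotype-phenotype intersection,
variant frequency + co-occurrence, and the tumor-pathology report.

Reports hold only aggregates and variant-level lines; sample identifiers
never appear in the quality or pathology reports. The co-occurrence report
lists carrier IDs for curator review (anonymized upstream) unless suppressed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Hashable, Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .model import (
    CohortGenotypes,
    CooccurrenceKind,
    CooccurrenceRecord,
    EvidenceBundle,
    PhenotypeRecord,
    PhenotypeTable,
    ReceptorStatus,
    SchemaError,
    TransInference,
    ValidationError,
)

SCHEMA_VERSION = "1"

NOT_EVALUABLE = "NOT_EVALUABLE"


# ---------------------------------------------------------------------------
# data quality report


@dataclass
class FieldSpec:
    """Declares one column of interest for the quality report.

    ``column`` selects by position for header-less files; otherwise the
    field name is the column name. Numeric fields may bound the expected
    range; categorical fields enumerate allowed values.
    """

    name: str
    ftype: str  # numeric | categorical | identifier
    allowed_values: tuple[str, ...] | None = None
    min_value: float | None = None
    max_value: float | None = None
    missing_tokens: tuple[str, ...] = ("NA", "", ".")
    column: int | None = None

    def __post_init__(self) -> None:
        if self.ftype not in {"numeric", "categorical", "identifier"}:
            raise ValidationError(f"unknown field type {self.ftype!r} for {self.name!r}")
        if self.ftype == "categorical" and not self.allowed_values:
            raise ValidationError(f"categorical field {self.name!r} must enumerate allowed values")


@dataclass
class FieldConfig:
    fields: list[FieldSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [f.name for f in self.fields]
        if len(set(names)) != len(names):
            raise ValidationError("field names must be unique")

    @classmethod
    def from_json(cls, path: str) -> "FieldConfig":
        with open(path) as fh:
            raw = json.load(fh)
        specs = []
        for entry in raw["fields"]:
            entry = dict(entry)
            for k in ("allowed_values", "missing_tokens"):
                if k in entry and entry[k] is not None:
                    entry[k] = tuple(str(v) for v in entry[k])
            specs.append(FieldSpec(**entry))
        return cls(specs)


def data_quality_report(
    path: str,
    config: FieldConfig,
    delimiter: str = "\t",
    header: bool = True,
) -> dict:
    """Per-field basic statistics plus missing/unexpected value tallies.

    For each configured field: n = n_valid + n_missing + n_unexpected;
    numeric statistics (min, max, mean, mode, median) are computed over valid
    values only, with mode ties broken toward the smallest value and flagged.
    Works with or without a header row via config-declared column positions.
    """
    try:
        df = pd.read_csv(path, sep=delimiter, dtype=str,
                         header=0 if header else None)
    except Exception as exc:
        raise SchemaError(f"cannot read table {path!r}: {exc}") from exc
    report: dict = {"schema_version": SCHEMA_VERSION, "n_rows": int(len(df)), "fields": {}}
    for spec in config.fields:
        if header:
            if spec.name not in df.columns:
                raise SchemaError(f"configured column {spec.name!r} absent from {path!r}")
            series = df[spec.name]
        else:
            if spec.column is None or spec.column >= df.shape[1]:
                raise SchemaError(
                    f"configured column index {spec.column!r} for {spec.name!r} "
                    f"out of range for {path!r}")
            series = df.iloc[:, spec.column]
        report["fields"][spec.name] = _field_stats(series, spec)
    return report


def _field_stats(series: pd.Series, spec: FieldSpec) -> dict:
    n = int(len(series))
    raw = series.astype(object)
    is_missing = raw.isna() | raw.astype(str).str.strip().isin(spec.missing_tokens)
    present = raw[~is_missing].astype(str).str.strip()

    unexpected: dict[str, int] = {}
    valid_numeric: list[float] = []
    n_valid = 0
    for value in present:
        if spec.ftype == "numeric":
            try:
                x = float(value)
            except ValueError:
                unexpected[value] = unexpected.get(value, 0) + 1
                continue
            if (spec.min_value is not None and x < spec.min_value) or (
                    spec.max_value is not None and x > spec.max_value):
                unexpected[value] = unexpected.get(value, 0) + 1
                continue
            valid_numeric.append(x)
            n_valid += 1
        elif spec.ftype == "categorical":
            if value not in spec.allowed_values:
                unexpected[value] = unexpected.get(value, 0) + 1
            else:
                n_valid += 1
        else:  # identifier: any non-missing token is valid
            n_valid += 1

    out: dict = {
        "type": spec.ftype,
        "n": n,
        "n_valid": n_valid,
        "n_missing": int(is_missing.sum()),
        "n_unexpected": int(sum(unexpected.values())),
        "unexpected_values": dict(sorted(unexpected.items())),
    }
    if spec.ftype == "numeric" and valid_numeric:
        arr = np.asarray(valid_numeric, dtype=float)
        values, counts = np.unique(arr, return_counts=True)
        top = counts.max()
        modes = values[counts == top]
        out["stats"] = {
            "min": float(arr.min()),
            "max": float(arr.max()),
            "mean": float(arr.mean()),
            "median": float(np.median(arr)),
            "mode": float(modes.min()),
            "mode_tied": bool(len(modes) > 1),
        }
    return out


# ---------------------------------------------------------------------------
# genotype-phenotype intersection


def genotype_phenotype_report(
    cohort: CohortGenotypes, phenotypes: PhenotypeTable
) -> dict:
    """Join each sample's carried variants with its phenotype record.

    One record per (sample, carried variant); samples present on only one
    side are counted as unmatched, not joined.
    """
    dosage = cohort.dosage
    pheno_ids = set(phenotypes.records)
    cohort_ids = set(cohort.sample_ids)
    records = []
    for si, sid in enumerate(cohort.sample_ids):
        pheno = phenotypes.get(sid)
        if pheno is None:
            continue
        for vi in (dosage[:, si] >= 1).nonzero()[0]:
            v = cohort.variants[vi]
            records.append({
                "sample_id": sid,
                "variant": v.coordinate_string(),
                "gene": cohort.gene_of(v),
                "dosage": int(dosage[vi, si]),
                "is_control": pheno.is_control,
                "er_status": pheno.er_status.value,
                "pr_status": pheno.pr_status.value,
                "her2_status": pheno.her2_status.value,
                "age_at_diagnosis": pheno.age_at_diagnosis,
                "age_at_entry": pheno.age_at_entry,
            })
    return {
        "schema_version": SCHEMA_VERSION,
        "n_joined_records": len(records),
        "n_unmatched_cohort_samples": len(cohort_ids - pheno_ids),
        "n_unmatched_phenotype_samples": len(pheno_ids - cohort_ids),
        "records": records,
    }


# ---------------------------------------------------------------------------
# 2x2 statistics


def _validate_table(a: int, b: int, c: int, d: int) -> None:
    for x in (a, b, c, d):
        if int(x) != x or x < 0:
            raise ValidationError(f"cell counts must be non-negative integers, got {(a, b, c, d)}")


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for the 2x2 table [[a, b], [c, d]].

    Sums the hypergeometric probabilities of all tables with the same margins
    whose point probability does not exceed the observed table's (with a
    1e-7 relative tolerance for floating-point ties). Requires positive
    margins; a zero margin leaves the test undefined.
    """
    _validate_table(a, b, c, d)
    if min(a + b, c + d, a + c, b + d) == 0:
        raise ValidationError(f"undefined test: zero margin in table {(a, b, c, d)}")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(p)


def odds_ratio_ci(a: int, b: int, c: int, d: int) -> tuple[float, float, float]:
    """Odds ratio with Woolf 95% CI; Haldane-Anscombe 0.5 correction on zeros.

    OR = (a*d)/(b*c) after adding 0.5 to every cell when any cell is zero;
    the interval is exp(log OR +/- 1.96 * sqrt(sum of reciprocal cells)).
    """
    _validate_table(a, b, c, d)
    if a == b == c == d == 0:
        raise ValidationError("odds ratio undefined for the all-zero table")
    cells = [float(a), float(b), float(c), float(d)]
    if 0 in (a, b, c, d):
        cells = [x + 0.5 for x in cells]
    ca, cb, cc, cd = cells
    or_ = (ca * cd) / (cb * cc)
    se = math.sqrt(sum(1.0 / x for x in cells))
    log_or = math.log(or_)
    return or_, math.exp(log_or - 1.96 * se), math.exp(log_or + 1.96 * se)


# ---------------------------------------------------------------------------
# tumor pathology report

FeatureFn = Callable[[PhenotypeRecord], bool | None]


def _receptor_feature(attr: str) -> FeatureFn:
    def fn(rec: PhenotypeRecord) -> bool | None:
        status = getattr(rec, attr)
        if status is ReceptorStatus.UNKNOWN:
            return None
        return status is ReceptorStatus.POSITIVE
    return fn


def is_tnbc(rec: PhenotypeRecord) -> bool | None:
    """Triple-negative: ER, PR and HER2 all negative; None unless all known."""
    statuses = (rec.er_status, rec.pr_status, rec.her2_status)
    if ReceptorStatus.UNKNOWN in statuses:
        return None
    return all(s is ReceptorStatus.NEGATIVE for s in statuses)


DEFAULT_FEATURES: dict[str, FeatureFn] = {
    "ER_positive": _receptor_feature("er_status"),
    "PR_positive": _receptor_feature("pr_status"),
    "HER2_positive": _receptor_feature("her2_status"),
    "TNBC": is_tnbc,
}


def categorical_feature(column: str, positive_values: Iterable[str]) -> FeatureFn:
    """Build a feature from an extra phenotype column (e.g. family-history flags)."""
    positives = {str(v) for v in positive_values}

    def fn(rec: PhenotypeRecord) -> bool | None:
        v = rec.extra.get(column)
        if v is None or str(v).strip() in {"", "NA", "."}:
            return None
        return str(v).strip() in positives
    return fn


def pathology_report(
    phenotypes: PhenotypeTable,
    carrier_status: Mapping[str, bool],
    features: Mapping[str, FeatureFn] | None = None,
    cases_only: bool = True,
) -> dict:
    """Stratify pathology features by pathogenic-carrier status.

    Per feature: 2x2 counts (carrier/non-carrier x feature present/absent
    over samples where the feature is determinable), proportions per stratum,
    odds ratio with Woolf 95% CI (zero-cell corrected) and two-sided Fisher's
    exact p. Adds the TNBC count/proportion over samples with all three
    receptor statuses known, and mean ages per stratum with a two-sided
    Welch comparison. Strata with no samples render the feature
    NOT_EVALUABLE. No sample identifiers appear in the output.
    """
    features = dict(features) if features is not None else dict(DEFAULT_FEATURES)
    samples = [
        rec for sid, rec in phenotypes.records.items()
        if sid in carrier_status and (not cases_only or rec.is_control is False)
    ]
    carriers = [r for r in samples if carrier_status[r.id]]
    noncarriers = [r for r in samples if not carrier_status[r.id]]

    report: dict = {
        "schema_version": SCHEMA_VERSION,
        "n_samples": len(samples),
        "n_carriers": len(carriers),
        "n_noncarriers": len(noncarriers),
        "features": {},
    }

    for name, fn in features.items():
        report["features"][name] = _feature_stats(fn, carriers, noncarriers)

    tnbc_flags = [is_tnbc(r) for r in samples]
    evaluable = [f for f in tnbc_flags if f is not None]
    report["tnbc"] = {
        "n_tnbc": sum(evaluable),
        "n_receptor_status_known": len(evaluable),
        "proportion": (sum(evaluable) / len(evaluable)) if evaluable else None,
    }
    report["ages"] = {
        "age_at_diagnosis": _age_comparison(carriers, noncarriers, "age_at_diagnosis"),
        "age_at_entry": _age_comparison(carriers, noncarriers, "age_at_entry"),
    }
    return report


def _feature_stats(fn: FeatureFn, carriers, noncarriers) -> dict:
    def count(group):
        flags = [fn(r) for r in group]
        flags = [f for f in flags if f is not None]
        return sum(flags), len(flags) - sum(flags)

    a, b = count(carriers)
    c, d = count(noncarriers)
    out: dict = {
        "carriers": {"with_feature": a, "without_feature": b,
                     "proportion": a / (a + b) if (a + b) else None},
        "noncarriers": {"with_feature": c, "without_feature": d,
                        "proportion": c / (c + d) if (c + d) else None},
    }
    if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
        out["status"] = NOT_EVALUABLE
        return out
    or_, low, high = odds_ratio_ci(a, b, c, d)
    out.update({
        "status": "OK",
        "odds_ratio": or_,
        "ci95": [low, high],
        "fisher_p": fisher_exact_two_sided(a, b, c, d),
    })
    return out


def _age_comparison(carriers, noncarriers, attr: str) -> dict:
    x = [getattr(r, attr) for r in carriers if getattr(r, attr) is not None]
    y = [getattr(r, attr) for r in noncarriers if getattr(r, attr) is not None]
    out: dict = {
        "carriers": {"n": len(x), "mean": float(np.mean(x)) if x else None},
        "noncarriers": {"n": len(y), "mean": float(np.mean(y)) if y else None},
    }
    if len(x) >= 2 and len(y) >= 2:
        t, p = stats.ttest_ind(x, y, equal_var=False)
        out["welch_p"] = float(p)
    else:
        out["welch_p"] = None
    return out


# ---------------------------------------------------------------------------
# variant frequency + co-occurrence report, evidence TSV mirror


def cooccurrence_report(
    records: Iterable[CooccurrenceRecord],
    trans: Mapping[Hashable, TransInference],
    suppress_sample_ids: bool = False,
) -> dict:
    """Per-VUS co-occurrence summary: partner list, per-sample zygosity,
    carrier ages, and the BS2-eligibility flag with its rationale fields."""
    by_vus: dict[str, dict] = {}
    for rec in sorted(records, key=lambda r: (_vkey(r.vus), r.sample_id)):
        entry = by_vus.setdefault(_vkey(rec.vus), {
            "gene": rec.gene, "observations": [], "partners": [],
        })
        obs = {
            "kind": rec.kind.value,
            "zygosity": "homozygous" if rec.kind is CooccurrenceKind.HOMOZYGOUS
                        else "heterozygous",
            "partner": _vkey(rec.partner) if rec.partner is not None else None,
            "age_at_diagnosis": rec.age_at_diagnosis,
            "age_at_entry": rec.age_at_entry,
            "phase_known": rec.phase_known,
            "trans_confirmed": rec.trans_confirmed,
        }
        if not suppress_sample_ids:
            obs["sample_id"] = rec.sample_id
        entry["observations"].append(obs)
    for vus, entry in by_vus.items():
        ti = trans.get(_unkey(vus, trans))
        partners = sorted({o["partner"] for o in entry["observations"] if o["partner"]})
        entry["partners"] = partners
        entry["n_distinct_pathogenic_partners"] = len(partners)
        entry["bs2_eligible"] = bool(ti.bs2_eligible) if ti is not None else False
        entry["n_carrier_samples"] = (
            ti.n_samples if ti is not None
            else len({o.get("sample_id") for o in entry["observations"]}))
    return {"schema_version": SCHEMA_VERSION, "vus": by_vus}


def _vkey(v) -> str:
    return v.coordinate_string() if hasattr(v, "coordinate_string") else str(v)


def _unkey(rendered: str, trans: Mapping[Hashable, TransInference]):
    for k in trans:
        if _vkey(k) == rendered:
            return k
    return None


def evidence_report(bundles: Iterable[EvidenceBundle]) -> dict:
    """JSON variant-evidence report mirroring the summary-table layout."""
    rows = []
    for b in sorted(bundles, key=lambda b: _vkey(b.variant)):
        rows.append({
            "variant": _vkey(b.variant),
            "gene": b.gene,
            "control_af": b.control_af,
            "frequency_code": b.freq_code.value,
            "bayesdel": b.bayesdel,
            "insilico_code": b.insilico_code.value,
            "combined_class": b.combined_class.value,
            "bs2_eligible": b.bs2_eligible,
            "external_af": dict(b.external_af or {}),
            "external_codes": {k: v.value for k, v in (b.external_codes or {}).items()},
        })
    counts: dict[str, int] = {}
    for r in rows:
        counts[r["combined_class"]] = counts.get(r["combined_class"], 0) + 1
    return {"schema_version": SCHEMA_VERSION, "class_counts": counts, "variants": rows}


def evidence_table_tsv(bundles: Iterable[EvidenceBundle], path: str) -> None:
    """TSV mirror of the evidence report (one variant per row)."""
    rows = evidence_report(bundles)["variants"]
    df = pd.DataFrame(rows, columns=[
        "variant", "gene", "control_af", "frequency_code", "bayesdel",
        "insilico_code", "combined_class", "bs2_eligible"])
    df.to_csv(path, sep="\t", index=False)


def write_json_report(report: dict, path: str) -> None:
    """Serialize a report deterministically (sorted keys, fixed layout)."""
    with open(path, "w", newline="\n") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, allow_nan=False)
        fh.write("\n")
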