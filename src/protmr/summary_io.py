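"""Read, validate and write GWAS/pQTL summary statistics; harmonize alleles.

Two-sample MR consumes two summary-statistics tables per test — the
SNP-exposure (pQTL) associations and the SNP-outcome (phenotype GWAS)
associations — which generally come from different studies and may report
effects on different allele orientations or genome strands.  This module
parses those tables into validated records, aligns exposure/outcome pairs
onto the exposure effect allele (sign-flipping, strand-complementing, and
dropping strand-ambiguous palindromic variants), maps protein assays to
their encoding genes, and serializes the per-protein sensitivity reports
produced by the pipeline.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InputError, UsageError

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical column names; a column_map translates file headers onto these
MANDATORY_COLUMNS = (
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "pvalue",
    "n",
)
OPTIONAL_COLUMNS = ("eaf", "protein_id")

#: fixed header of the "gwas_vcf_lite" dialect (effect allele is ALT,
#: LP is -log10 p) — a flat-text echo of GWAS-VCF conventions
_VCF_LITE_MAP = {
    "variant_id": "ID",
    "chrom": "#CHROM",
    "pos": "POS",
    "other_allele": "REF",
    "effect_allele": "ALT",
    "eaf": "AF",
    "beta": "ES",
    "se": "SE",
    "pvalue": "LP",
    "n": "SS",
}


@dataclass(slots=True)
class VariantAssociation:
    """One variant's association record in one GWAS.

    ``beta`` is the additive per-effect-allele effect (log odds ratio for
    binary outcomes); ``eaf`` is the effect-allele frequency and may be
    None when the source table omits it.
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    n: float
    eaf: float | None = None
    protein_id: str | None = None

    def validation_failure(self) -> str | None:
        """First violated invariant, or None if the record is valid."""
        if not (self.se > 0):
            return "nonpositive_se"
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            return "bad_allele"
        if self.effect_allele == self.other_allele:
            return "same_alleles"
        if self.eaf is not None and not (0.0 < self.eaf < 1.0):
            return "bad_eaf"
        if not (0.0 < self.pvalue <= 1.0):
            return "bad_pvalue"
        if not (self.n > 0):
            return "nonpositive_n"
        if not (self.pos >= 1):
            return "bad_pos"
        return None

    def pz_log10_gap(self) -> float:
        """|log10 reported p − log10 p implied by beta/se| (normal approx)."""
        z = abs(self.beta) / self.se
        logp = stats.norm.logsf(z) + math.log(2.0)
        log10_implied = logp / math.log(10.0)
        if log10_implied < -300.0:  # beyond float64 p-value resolution
            return 0.0
        return abs(math.log10(self.pvalue) - log10_implied)


@dataclass(slots=True)
class ProteinTarget:
    """A protein assay and the genomic span of its encoding gene (1-based,
    inclusive); the reference for cis/trans pQTL classification."""

    protein_id: str
    gene_symbol: str
    chrom: str
    gene_start: int
    gene_end: int
    cohort_id: str = ""


@dataclass(slots=True)
class HarmonizedInstrument:
    """An exposure/outcome-aligned instrument on the exposure effect allele.

    ``drop_reason`` is set exactly when the instrument is excluded from
    estimation (strand-ambiguous palindrome, irreconcilable alleles,
    missing outcome record, or an exclusion-list hit).
    """

    variant_id: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    eaf: float | None = None
    is_cis: bool | None = None
    drop_reason: str | None = None

    @property
    def usable(self) -> bool:
        return self.drop_reason is None


DROP_REASONS = frozenset(
    {
        "palindromic_ambiguous",
        "allele_mismatch",
        "missing_outcome",
        "excluded_confounder",
        "excluded_phewas",
    }
)


@dataclass
class SummaryStats:
    """Ordered, validated records plus bookkeeping of rejected rows."""

    records: list[VariantAssociation]
    rejects: list[tuple[int, str]] = field(default_factory=list)
    n_input: int = 0
    build: str | None = None

    def __iter__(self) -> Iterator[VariantAssociation]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def by_variant(self) -> dict[str, VariantAssociation]:
        return {r.variant_id: r for r in self.records}

    def by_protein(self) -> dict[str, list[VariantAssociation]]:
        """Group records by their protein_id column (exposure panels)."""
        groups: dict[str, list[VariantAssociation]] = {}
        for r in self.records:
            groups.setdefault(r.protein_id or "", []).append(r)
        return groups


def read_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    dialect: str = "tsv",
    build: str | None = None,
    pz_tolerance: float = 0.5,
) -> SummaryStats:
    """Parse a tab-separated summary-statistics table.

    ``column_map`` maps canonical names (``variant_id``, ``chrom``, ``pos``,
    ``effect_allele``, ``other_allele``, ``beta``, ``se``, ``pvalue``, ``n``,
    optionally ``eaf`` and ``protein_id``) onto the file's headers; canonical
    headers need no entry.  Malformed rows are rejected with a reason and
    counted, never silently dropped.  A reported p-value inconsistent with
    |beta/se| beyond ``pz_tolerance`` on the log10 scale triggers a warning
    only.

    Raises ConfigurationError for unresolvable mandatory columns and
    InputError when no row survives validation.
    """
    path = Path(path)
    if dialect in ("gwas_vcf_lite", "gwas_vcf-lite"):
        cmap = dict(_VCF_LITE_MAP)
    elif dialect == "tsv":
        cmap = {c: c for c in MANDATORY_COLUMNS + OPTIONAL_COLUMNS}
        if column_map:
            cmap.update(column_map)
    else:
        raise ConfigurationError(f"unknown dialect {dialect!r}")

    df = pd.read_csv(path, sep="\t", dtype={cmap["chrom"]: str})
    missing = [c for c in MANDATORY_COLUMNS if cmap[c] not in df.columns]
    if missing:
        raise ConfigurationError(
            f"{path}: cannot resolve mandatory column(s) {missing} "
            f"via column map {[cmap[c] for c in missing]}"
        )
    has_eaf = cmap.get("eaf") in df.columns
    has_protein = cmap.get("protein_id") in df.columns
    is_vcf_lite = dialect.startswith("gwas_vcf")

    records: list[VariantAssociation] = []
    rejects: list[tuple[int, str]] = []
    n_pz_warn = 0
    for i, row in enumerate(df.itertuples(index=False, name=None)):
        row = dict(zip(df.columns, row))
        try:
            pval = float(row[cmap["pvalue"]])
            if is_vcf_lite:
                pval = 10.0 ** (-pval)
            eaf = float(row[cmap["eaf"]]) if has_eaf else math.nan
            rec = VariantAssociation(
                variant_id=str(row[cmap["variant_id"]]),
                chrom=str(row[cmap["chrom"]]),
                pos=int(row[cmap["pos"]]),
                effect_allele=str(row[cmap["effect_allele"]]).upper(),
                other_allele=str(row[cmap["other_allele"]]).upper(),
                beta=float(row[cmap["beta"]]),
                se=float(row[cmap["se"]]),
                pvalue=pval,
                n=float(row[cmap["n"]]),
                eaf=None if math.isnan(eaf) else eaf,
                protein_id=str(row[cmap["protein_id"]]) if has_protein else None,
            )
        except (ValueError, TypeError):
            rejects.append((i, "unparseable_row"))
            continue
        reason = rec.validation_failure()
        if reason is not None:
            rejects.append((i, reason))
            continue
        if rec.pz_log10_gap() > pz_tolerance:
            n_pz_warn += 1
        records.append(rec)

    if n_pz_warn:
        logger.warning(
            "%s: %d record(s) with reported p inconsistent with |beta/se| "
            "beyond %.1f log10 units (kept)",
            path,
            n_pz_warn,
            pz_tolerance,
        )
    if not records:
        raise InputError(f"{path}: zero valid rows ({len(rejects)} rejected)")
    return SummaryStats(records=records, rejects=rejects, n_input=len(df), build=build)


def _is_palindromic(a1: str, a2: str) -> bool:
    return COMPLEMENT[a1] == a2


def harmonize_pair(
    exposure: VariantAssociation,
    outcome: VariantAssociation,
    palindrome_maf_limit: float = 0.42,
) -> HarmonizedInstrument:
    """Align one outcome record onto the exposure's effect allele.

    Alignment allows at most one allele swap (flipping the outcome beta and
    complementing its frequency) and at most one strand complement.
    Palindromic variants (A/T, C/G), whose strand cannot be inferred from
    the alleles, are kept only when both frequencies are informative: both
    present, both outside [limit, 1-limit], and on the same side of 0.5
    after textual alignment; otherwise they are dropped as ambiguous.
    """
    if exposure.variant_id != outcome.variant_id:
        raise UsageError(
            f"harmonize_pair called on different variants "
            f"{exposure.variant_id!r} vs {outcome.variant_id!r}"
        )
    ea_x, oa_x = exposure.effect_allele, exposure.other_allele
    ea_y, oa_y = outcome.effect_allele, outcome.other_allele
    palindromic = _is_palindromic(ea_x, oa_x)

    flip: bool | None
    if (ea_y, oa_y) == (ea_x, oa_x):
        flip = False
    elif (ea_y, oa_y) == (oa_x, ea_x):
        flip = True
    elif not palindromic and (COMPLEMENT[ea_y], COMPLEMENT[oa_y]) == (ea_x, oa_x):
        flip = False
    elif not palindromic and (COMPLEMENT[ea_y], COMPLEMENT[oa_y]) == (oa_x, ea_x):
        flip = True
    else:
        flip = None

    inst = HarmonizedInstrument(
        variant_id=exposure.variant_id,
        beta_exposure=exposure.beta,
        se_exposure=exposure.se,
        beta_outcome=math.nan,
        se_outcome=outcome.se,
        eaf=exposure.eaf,
    )
    if flip is None:
        inst.drop_reason = "allele_mismatch"
        return inst

    beta_y = -outcome.beta if flip else outcome.beta
    eaf_y = outcome.eaf
    if flip and eaf_y is not None:
        eaf_y = 1.0 - eaf_y

    if palindromic:
        lo, hi = palindrome_maf_limit, 1.0 - palindrome_maf_limit
        informative = (
            exposure.eaf is not None
            and eaf_y is not None
            and not (lo <= exposure.eaf <= hi)
            and not (lo <= eaf_y <= hi)
            and ((exposure.eaf < 0.5) == (eaf_y < 0.5))
        )
        if not informative:
            inst.drop_reason = "palindromic_ambiguous"
            return inst

    inst.beta_outcome = beta_y
    return inst


def harmonize(
    exposure_records: Iterable[VariantAssociation],
    outcome_by_variant: Mapping[str, VariantAssociation],
    palindrome_maf_limit: float = 0.42,
) -> list[HarmonizedInstrument]:
    """Harmonize a set of exposure records against an outcome lookup.

    Exposure variants absent from the outcome table become instruments
    with drop_reason="missing_outcome" so the loss is visible downstream.
    """
    out: list[HarmonizedInstrument] = []
    for exp in exposure_records:
        oc = outcome_by_variant.get(exp.variant_id)
        if oc is None:
            out.append(
                HarmonizedInstrument(
                    variant_id=exp.variant_id,
                    beta_exposure=exp.beta,
                    se_exposure=exp.se,
                    beta_outcome=math.nan,
                    se_outcome=math.nan,
                    eaf=exp.eaf,
                    drop_reason="missing_outcome",
                )
            )
        else:
            out.append(harmonize_pair(exp, oc, palindrome_maf_limit))
    return out


@dataclass
class AnnotationMap:
    """Protein annotation lookup keyed by (protein_id, cohort_id)."""

    targets: dict[tuple[str, str], ProteinTarget]
    rejects: list[tuple[int, str]] = field(default_factory=list)

    def get(self, protein_id: str, cohort_id: str = "") -> ProteinTarget:
        key = (protein_id, cohort_id)
        if key not in self.targets:
            raise InputError(f"unknown protein {protein_id!r} (cohort {cohort_id!r})")
        return self.targets[key]

    def __len__(self) -> int:
        return len(self.targets)


def map_protein_targets(annotations: pd.DataFrame | str | Path) -> AnnotationMap:
    """Build the protein → gene-coordinate lookup from an annotation table.

    Expects columns protein_id, gene_symbol, chrom, gene_start, gene_end and
    optionally cohort_id.  Rows with gene_start > gene_end are rejected with
    a reason; a duplicate (protein_id, cohort_id) key raises InputError.
    """
    if not isinstance(annotations, pd.DataFrame):
        annotations = pd.read_csv(annotations, sep="\t", dtype={"chrom": str})
    targets: dict[tuple[str, str], ProteinTarget] = {}
    rejects: list[tuple[int, str]] = []
    has_cohort = "cohort_id" in annotations.columns
    for i, row in enumerate(annotations.itertuples(index=False)):
        start, end = int(row.gene_start), int(row.gene_end)
        if start > end:
            rejects.append((i, "gene_start_gt_gene_end"))
            continue
        cohort = str(row.cohort_id) if has_cohort else ""
        key = (str(row.protein_id), cohort)
        if key in targets:
            raise InputError(f"duplicate annotation key {key}")
        targets[key] = ProteinTarget(
            protein_id=str(row.protein_id),
            gene_symbol=str(row.gene_symbol),
            chrom=str(row.chrom),
            gene_start=start,
            gene_end=end,
            cohort_id=cohort,
        )
    return AnnotationMap(targets=targets, rejects=rejects)


# ---------------------------------------------------------------------------
# results serialization

#: battery methods serialized per report, in column order
BATTERY_METHODS = (
    "ivw_robust",
    "egger",
    "weighted_median",
    "weighted_mode",
    "conmix",
    "presso",
    "cml",
)

_BASE_COLUMNS = [
    "protein_id",
    "gene_symbol",
    "phenotype",
    "cohort_id",
    "instrument_class",
    "n_snps",
    "primary_method",
    "theta",
    "se",
    "ci_low",
    "ci_high",
    "pvalue",
    "het_q",
    "het_p",
    "egger_intercept",
    "egger_intercept_p",
    "steiger_r2_exposure",
    "steiger_r2_outcome",
    "steiger_direction",
    "steiger_p",
    "reverse_theta",
    "reverse_p",
    "flags",
    "tier",
]


def _fmt(x) -> str:
    if x is None:
        return ""
    if isinstance(x, float):
        if math.isnan(x):
            return ""
        return f"{x:.12g}"
    return str(x)


def results_columns() -> list[str]:
    cols = list(_BASE_COLUMNS)
    for m in BATTERY_METHODS:
        cols += [f"{m}_theta", f"{m}_se", f"{m}_p"]
    cols += ["rerun_excluded_confounder_theta", "rerun_excluded_confounder_p",
             "rerun_excluded_phewas_theta", "rerun_excluded_phewas_p"]
    return cols


def report_to_row(report) -> dict[str, object]:
    """Flatten a SensitivityReport into one TSV row (dict of columns)."""
    pr = report.primary
    row: dict[str, object] = {c: None for c in results_columns()}
    row.update(
        protein_id=report.protein_id,
        gene_symbol=report.gene_symbol,
        phenotype=report.phenotype,
        cohort_id=report.cohort_id,
        instrument_class=report.instrument_class,
        n_snps=pr.n_snps,
        primary_method=pr.method,
        theta=pr.theta_hat,
        se=pr.se_theta,
        ci_low=pr.ci_low,
        ci_high=pr.ci_high,
        pvalue=pr.pvalue,
        het_q=pr.extras.get("Q"),
        het_p=pr.extras.get("p_Q"),
        flags=";".join(sorted(report.flags)),
        tier=report.tier,
    )
    eg = report.battery.get("egger")
    if eg is not None:
        row["egger_intercept"] = eg.extras.get("intercept")
        row["egger_intercept_p"] = eg.extras.get("p_intercept")
    if report.steiger is not None:
        st = report.steiger
        row.update(
            steiger_r2_exposure=st.r2_exposure,
            steiger_r2_outcome=st.r2_outcome,
            steiger_direction=st.direction,
            steiger_p=st.pvalue,
        )
    if report.reverse is not None:
        row["reverse_theta"] = report.reverse.theta_hat
        row["reverse_p"] = report.reverse.pvalue
    for m in BATTERY_METHODS:
        res = report.battery.get(m)
        if res is not None:
            row[f"{m}_theta"] = res.theta_hat
            row[f"{m}_se"] = res.se_theta
            row[f"{m}_p"] = res.pvalue
    for reason, res in report.exclusion_reruns.items():
        if res is not None:
            row[f"rerun_{reason}_theta"] = res.theta_hat
            row[f"rerun_{reason}_p"] = res.pvalue
    return row


def write_results(
    reports: Iterable,
    path: str | Path,
    run_config: Mapping | None = None,
    seed: int | None = None,
) -> Path:
    """Write one TSV row per report plus a JSON manifest sidecar.

    Floats are rendered with 12 significant digits so a write/read round
    trip preserves them to that precision.  An empty collection yields a
    header-only table.  The manifest (<stem>.manifest.json) records the
    run configuration and master seed for provenance.
    """
    path = Path(path)
    cols = results_columns()
    lines = ["\t".join(cols)]
    n = 0
    for rep in reports:
        row = report_to_row(rep)
        lines.append("\t".join(_fmt(row[c]) for c in cols))
        n += 1
    path.write_text("\n".join(lines) + "\n")
    manifest = {
        "n_reports": n,
        "seed": seed,
        "config": dict(run_config) if run_config else {},
        "columns": cols,
    }
    manifest_path = path.with_suffix(".manifest.json")
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a results TSV back (numeric columns parsed as floats)."""
    return pd.read_csv(path, sep="\t")


def read_exclusion_list(path: str | Path) -> set[str]:
    """One variant id per line; blank lines and '#' comments ignored."""
    ids: set[str] = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            ids.add(line)
    return ids
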