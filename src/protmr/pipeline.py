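"""Study orchestration: per-protein MR with the sensitivity battery,
reverse-direction MR, cross-cohort meta-analysis, and two-tier
multiple-testing control.

The unit of work is one protein x phenotype x cohort x instrument-class
run: instruments are selected and harmonized, the primary estimate is the
IVW delta method (Wald ratio when a single instrument survives), the
battery of pleiotropy-robust estimators is applied whenever its minimum
instrument count is met, the Steiger test fixes the causal direction, and
confounder/PheWAS exclusion lists trigger recomputed estimates.  Results
from the two proteomics platforms are combined by fixed-effect
inverse-variance meta-analysis keyed on gene symbol, and significance is
reported on two tiers: Bonferroni (family-wise, per instrument class) and
Benjamini-Hochberg FDR (within phenotype x class strata).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from . import estimators as est
from ._utils import Z95, derive_seed, two_sided_p
from .errors import (
    ConfigurationError,
    InsufficientDataError,
    InsufficientOverlapError,
    PreconditionError,
    ProtMRError,
    UsageError,
)
from .instruments import (
    InstrumentSelectionConfig,
    LDMatrix,
    apply_snp_exclusions,
    select_instruments,
)
from .summary_io import (
    AnnotationMap,
    HarmonizedInstrument,
    ProteinTarget,
    VariantAssociation,
    harmonize,
    map_protein_targets,
    read_exclusion_list,
    read_summary_stats,
    write_results,
)

logger = logging.getLogger(__name__)

#: minimum usable instruments per battery method
BATTERY_MIN_J = {
    "ivw_robust": 3,
    "egger": 3,
    "weighted_median": 3,
    "weighted_mode": 3,
    "conmix": 3,
    "cml": 3,
    "presso": 4,
}
DEFAULT_BATTERY = tuple(BATTERY_MIN_J)


@dataclass
class EstimatorConfig:
    """Settings shared by the stochastic/sensitivity estimators."""

    n_boot: int = 1000
    presso_n_sim: int = 1000
    outlier_alpha: float = 0.05
    conmix_psi: float | None = None
    bandwidth_factor: float = 1.0
    weights: str = "second"
    battery: tuple[str, ...] = DEFAULT_BATTERY

    def __post_init__(self) -> None:
        unknown = set(self.battery) - set(BATTERY_MIN_J)
        if unknown:
            raise ConfigurationError(f"unknown battery method(s) {sorted(unknown)}")


@dataclass
class PipelineConfig:
    selection: InstrumentSelectionConfig = field(
        default_factory=InstrumentSelectionConfig
    )
    estimators: EstimatorConfig = field(default_factory=EstimatorConfig)
    palindrome_maf_limit: float = 0.42
    alpha: float = 0.05
    reverse_mode: str = "on_flag"  # on_flag | always | never


@dataclass
class SensitivityReport:
    """Full evidence record for one protein-phenotype-cohort-class run."""

    protein_id: str
    gene_symbol: str
    phenotype: str
    cohort_id: str
    instrument_class: str
    primary: est.MRResult
    battery: dict[str, est.MRResult] = field(default_factory=dict)
    steiger: est.SteigerResult | None = None
    reverse: est.MRResult | None = None
    exclusion_reruns: dict[str, est.MRResult] = field(default_factory=dict)
    flags: set[str] = field(default_factory=set)
    tier: str = "none"  # none | fdr | bonferroni
    instrument_ids: list[str] = field(default_factory=list)
    stage_counts: dict[str, int] = field(default_factory=dict)
    removal_logs: dict[str, list[str]] = field(default_factory=dict)
    battery_errors: dict[str, str] = field(default_factory=dict)


@dataclass
class SkipRecord:
    protein_id: str
    phenotype: str
    cohort_id: str
    instrument_class: str
    reason: str


@dataclass
class StudyResults:
    reports: list[SensitivityReport]
    skips: list[SkipRecord] = field(default_factory=list)
    meta: dict[tuple[str, str, str], est.MRResult] = field(default_factory=dict)
    bonferroni_alpha: dict[str, float] = field(default_factory=dict)
    fdr_thresholds: dict[tuple[str, str], float | None] = field(default_factory=dict)
    tallies: dict[str, dict[str, int]] = field(default_factory=dict)


def _median_n(records: Sequence[VariantAssociation]) -> float:
    return float(np.median([r.n for r in records]))


def _run_battery(
    instruments: list[HarmonizedInstrument],
    cfg: EstimatorConfig,
    seed: int,
    n: float | None = None,
) -> tuple[dict[str, est.MRResult], dict[str, str]]:
    j = len(est.usable(instruments))
    battery: dict[str, est.MRResult] = {}
    errors: dict[str, str] = {}
    for method in cfg.battery:
        if j < BATTERY_MIN_J[method]:
            continue
        try:
            if method == "ivw_robust":
                battery[method] = est.ivw_robust(instruments)
            elif method == "egger":
                battery[method] = est.egger(instruments)
            elif method == "weighted_median":
                battery[method] = est.weighted_median(
                    instruments, n_boot=cfg.n_boot, seed=seed, weights=cfg.weights
                )
            elif method == "weighted_mode":
                battery[method] = est.weighted_mode(
                    instruments,
                    bandwidth_factor=cfg.bandwidth_factor,
                    n_boot=cfg.n_boot,
                    seed=seed,
                    weights=cfg.weights,
                )
            elif method == "conmix":
                battery[method] = est.conmix(
                    instruments, psi=cfg.conmix_psi, weights=cfg.weights
                )
            elif method == "cml":
                battery[method] = est.mr_cml(instruments, seed=seed, n=n)
            elif method == "presso":
                battery[method] = est.mr_presso(
                    instruments,
                    n_sim=cfg.presso_n_sim,
                    seed=seed,
                    outlier_alpha=cfg.outlier_alpha,
                )
        except ProtMRError as exc:
            errors[method] = f"{type(exc).__name__}: {exc}"
            logger.warning("battery method %s failed: %s", method, exc)
    return battery, errors


def _primary(
    instruments: list[HarmonizedInstrument], weights: str
) -> est.MRResult:
    """IVW for J >= 2 (multiplicative random effects from J >= 4), Wald
    ratio for a single instrument."""
    ok = est.usable(instruments)
    if len(ok) >= 2:
        re = "multiplicative" if len(ok) >= 4 else "fixed"
        return est.ivw(ok, random_effects=re, weights=weights)
    return est.wald_ratio(ok[0], order=weights)


def run_protein_mr(
    exposure: Sequence[VariantAssociation],
    outcome_by_variant: Mapping[str, VariantAssociation],
    target: ProteinTarget,
    cfg: PipelineConfig,
    *,
    phenotype: str,
    cohort_id: str,
    mode: str = "cis",
    ld: LDMatrix | None = None,
    exclusions: Mapping[str, set[str]] | None = None,
    outcome_type: str = "quantitative",
    seed: int = 0,
) -> SensitivityReport | SkipRecord:
    """One complete MR run for a single protein.

    Selection -> harmonization -> primary estimate -> battery -> Steiger
    -> flags -> exclusion-list reruns.  Returns a SkipRecord (never
    raises) when no usable instrument survives.
    """
    sel = select_instruments(exposure, target, ld, cfg.selection, mode=mode)
    if not sel.variant_ids:
        return SkipRecord(
            target.protein_id, phenotype, cohort_id, mode, "no_instruments"
        )
    harmonized = harmonize(
        sel.variants, outcome_by_variant, cfg.palindrome_maf_limit
    )
    usable = est.usable(harmonized)
    if not usable:
        return SkipRecord(
            target.protein_id, phenotype, cohort_id, mode, "no_usable_after_harmonization"
        )

    report = SensitivityReport(
        protein_id=target.protein_id,
        gene_symbol=target.gene_symbol,
        phenotype=phenotype,
        cohort_id=cohort_id,
        instrument_class=mode,
        primary=_primary(usable, cfg.estimators.weights),
        instrument_ids=[i.variant_id for i in usable],
        stage_counts={
            "input": sel.counts.n_input,
            "significant": sel.counts.n_significant,
            "in_class": sel.counts.n_in_class,
            "clumped": sel.counts.n_clumped,
            "strong": sel.counts.n_strong,
            "harmonized_usable": len(usable),
        },
    )
    n_exp = _median_n([r for r in sel.variants])
    n_out = _median_n([outcome_by_variant[i.variant_id] for i in usable])
    j = len(usable)
    if j == 1:
        report.flags.add("single_instrument")
    else:
        report.battery, report.battery_errors = _run_battery(
            usable, cfg.estimators, seed, n=min(n_exp, n_out)
        )

    try:
        report.steiger = est.steiger_direction(usable, n_exp, n_out, outcome_type)
    except (PreconditionError, InsufficientDataError) as exc:
        logger.warning("steiger unavailable for %s: %s", target.protein_id, exc)

    # flags
    p_q = report.primary.extras.get("p_Q")
    if p_q is not None and p_q < 0.05:
        report.flags.add("heterogeneity_p_lt_0.05")
    eg = report.battery.get("egger")
    if eg is not None and eg.extras.get("p_intercept", 1.0) < 0.05:
        report.flags.add("egger_intercept_p_lt_0.05")
    if report.steiger is not None and report.steiger.pvalue > 0.05:
        report.flags.add("steiger_p_gt_0.05")

    # exclusion-list reruns: primary recomputed after dropping listed SNPs
    for reason, ids in (exclusions or {}).items():
        marked, log = apply_snp_exclusions(usable, ids, reason)
        if not log.count:
            continue
        report.removal_logs[reason] = log.removed_ids
        still = est.usable(marked)
        if still:
            report.exclusion_reruns[reason] = _primary(still, cfg.estimators.weights)
        else:
            report.battery_errors[f"rerun_{reason}"] = "no_instruments_left"
    return report


def reverse_mr(
    phenotype_exposure: Sequence[VariantAssociation],
    protein_outcome_by_variant: Mapping[str, VariantAssociation],
    cfg: PipelineConfig,
    ld: LDMatrix | None = None,
    exclude_ids: set[str] | None = None,
) -> est.MRResult | str:
    """MR in the reverse direction: phenotype as exposure, protein as
    outcome, IVW on the phenotype's genome-wide significant clumped
    instruments.  ``exclude_ids`` (typically the forward run's pQTL
    instruments) are removed from the candidate pool so the reverse
    estimate is not driven by the very variants under scrutiny.  Returns
    a skip-reason string when no instrument survives."""
    pool = [v for v in phenotype_exposure if not exclude_ids or v.variant_id not in exclude_ids]
    sel = select_instruments(pool, None, ld, cfg.selection, mode="all")
    if not sel.variant_ids:
        return "no_phenotype_instruments"
    harmonized = harmonize(
        sel.variants, protein_outcome_by_variant, cfg.palindrome_maf_limit
    )
    usable = est.usable(harmonized)
    if not usable:
        return "no_usable_after_harmonization"
    return _primary(usable, cfg.estimators.weights)


def meta_analyze(
    results_by_cohort: Mapping[str, est.MRResult],
    phenotype_by_cohort: Mapping[str, str] | None = None,
) -> est.MRResult:
    """Fixed-effect inverse-variance meta-analysis across cohorts.

    theta_meta = sum(theta_c / se_c^2) / sum(1 / se_c^2);
    se_meta = sqrt(1 / sum(1 / se_c^2)).  A single cohort passes through.
    """
    if not results_by_cohort:
        raise UsageError("meta_analyze requires >= 1 cohort result")
    if phenotype_by_cohort is not None:
        labels = set(phenotype_by_cohort.values())
        if len(labels) > 1:
            raise UsageError(f"mismatched phenotype labels in meta-analysis: {labels}")
    results = list(results_by_cohort.values())
    if len(results) == 1:
        r = results[0]
        return est.MRResult(
            method="meta",
            theta_hat=r.theta_hat,
            se_theta=r.se_theta,
            ci_low=r.ci_low,
            ci_high=r.ci_high,
            pvalue=r.pvalue,
            n_snps=r.n_snps,
            extras={"n_cohorts": 1, "cohorts": list(results_by_cohort)},
        )
    w = np.array([1.0 / r.se_theta**2 for r in results])
    th = np.array([r.theta_hat for r in results])
    theta = float(np.sum(w * th) / np.sum(w))
    se = math.sqrt(1.0 / float(np.sum(w)))
    z = theta / se
    q = float(np.sum(w * (th - theta) ** 2))
    return est.MRResult(
        method="meta",
        theta_hat=theta,
        se_theta=se,
        ci_low=theta - Z95 * se,
        ci_high=theta + Z95 * se,
        pvalue=float(two_sided_p(z)),
        n_snps=int(sum(r.n_snps for r in results)),
        extras={
            "n_cohorts": len(results),
            "cohorts": list(results_by_cohort),
            "Q_between": q,
            "p_Q_between": float(sps.chi2.sf(q, len(results) - 1)),
        },
    )


def adjust_pvalues(
    reports: Iterable[SensitivityReport], alpha: float = 0.05
) -> StudyResults:
    """Two-tier multiple-testing control.

    Bonferroni: alpha / (number of tests actually run), counted separately
    for cis and trans runs.  BH-FDR: within each phenotype x class
    stratum; the realized per-stratum p-value threshold (largest rejected
    p) is reported.  Tiers are monotone: bonferroni implies fdr.
    """
    reports = list(reports)
    results = StudyResults(reports=reports)
    by_class: dict[str, list[SensitivityReport]] = {}
    for r in reports:
        by_class.setdefault(r.instrument_class, []).append(r)
    for cls, cls_reports in by_class.items():
        results.bonferroni_alpha[cls] = alpha / len(cls_reports)

    strata: dict[tuple[str, str], list[SensitivityReport]] = {}
    for r in reports:
        strata.setdefault((r.phenotype, r.instrument_class), []).append(r)
    for key, members in strata.items():
        pvals = np.array([m.primary.pvalue for m in members])
        rejected, _, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
        results.fdr_thresholds[key] = (
            float(np.max(pvals[rejected])) if rejected.any() else None
        )
        bonf = results.bonferroni_alpha[key[1]]
        for m, rej in zip(members, rejected):
            if m.primary.pvalue <= bonf:
                m.tier = "bonferroni"
            elif rej:
                m.tier = "fdr"
            else:
                m.tier = "none"

    for r in reports:
        tally = results.tallies.setdefault(
            r.phenotype, {"tested": 0, "fdr": 0, "bonferroni": 0}
        )
        tally["tested"] += 1
        if r.tier in ("fdr", "bonferroni"):
            tally["fdr"] += 1
        if r.tier == "bonferroni":
            tally["bonferroni"] += 1
    return results


def cross_platform_correlation(
    reports_a: Iterable[SensitivityReport],
    reports_b: Iterable[SensitivityReport],
) -> tuple[float, int]:
    """Pearson correlation of per-protein primary effect sizes between two
    platforms, matched by (gene_symbol, phenotype).

    Assay collisions (several aptamers per gene) keep the run with the
    most instruments.  Raises InsufficientOverlapError below 3 shared
    keys.
    """

    def index(reports):
        out: dict[tuple[str, str], SensitivityReport] = {}
        for r in reports:
            key = (r.gene_symbol, r.phenotype)
            if key not in out or r.primary.n_snps > out[key].primary.n_snps:
                out[key] = r
        return out

    a, b = index(reports_a), index(reports_b)
    shared = sorted(set(a) & set(b))
    if len(shared) < 3:
        raise InsufficientOverlapError(
            f"only {len(shared)} shared (gene, phenotype) keys; need >= 3"
        )
    x = [a[k].primary.theta_hat for k in shared]
    y = [b[k].primary.theta_hat for k in shared]
    r, _ = sps.pearsonr(x, y)
    return float(r), len(shared)


# ---------------------------------------------------------------------------
# full study


def _load_config(config: str | Path | Mapping) -> tuple[dict, Path]:
    if isinstance(config, (str, Path)):
        path = Path(config)
        raw = yaml.safe_load(path.read_text())
        base = path.parent
    else:
        raw = dict(config)
        base = Path(raw.get("base_dir", "."))
    if not isinstance(raw, dict):
        raise ConfigurationError("config must be a mapping")
    for key in ("cohorts", "phenotypes", "annotations"):
        if key not in raw:
            raise ConfigurationError(f"config missing required field {key!r}")
    for ph, spec in raw["phenotypes"].items():
        ot = spec.get("outcome_type")
        if ot not in ("quantitative", "binary"):
            raise ConfigurationError(
                f"phenotypes.{ph}.outcome_type: unknown value {ot!r} "
                "(expected 'quantitative' or 'binary')"
            )
        if "outcome_path" not in spec:
            raise ConfigurationError(f"phenotypes.{ph}: missing outcome_path")
    for cls in raw.get("classes", ["cis"]):
        if cls not in ("cis", "trans"):
            raise ConfigurationError(f"classes: unknown instrument class {cls!r}")
    return raw, base


def _pipeline_config(raw: dict) -> PipelineConfig:
    sel = InstrumentSelectionConfig(**(raw.get("selection") or {}))
    est_kwargs = dict(raw.get("estimators") or {})
    if "battery" in est_kwargs and est_kwargs["battery"] is not None:
        est_kwargs["battery"] = tuple(est_kwargs["battery"])
    estc = EstimatorConfig(**est_kwargs)
    return PipelineConfig(
        selection=sel,
        estimators=estc,
        palindrome_maf_limit=raw.get("palindrome_maf_limit", 0.42),
        alpha=raw.get("alpha", 0.05),
        reverse_mode=raw.get("reverse_mode", "on_flag"),
    )


def run_study(
    config: str | Path | Mapping,
    out_dir: str | Path | None = None,
    seed: int | None = None,
) -> StudyResults:
    """Run the full study described by a YAML config.

    Orchestrates selection, harmonization, estimation and the sensitivity
    battery across all proteins, phenotypes, cohorts and instrument
    classes; meta-analyzes cohorts; applies the two-tier significance
    scheme; and writes results.tsv plus a JSON manifest (per-stage counts,
    realized Bonferroni denominators, per-stratum FDR thresholds) when
    ``out_dir`` is given.  Deterministic for a fixed master seed.
    """
    raw, base = _load_config(config)
    cfg = _pipeline_config(raw)
    master_seed = int(seed if seed is not None else raw.get("seed", 0))
    classes = list(raw.get("classes", ["cis"]))

    annotations = map_protein_targets(base / raw["annotations"])
    ld = None
    if raw.get("ld_matrix"):
        ld = LDMatrix.from_tsv(base / raw["ld_matrix"])
    exclusions: dict[str, set[str]] = {}
    for reason, path in (raw.get("exclusions") or {}).items():
        if reason not in ("excluded_confounder", "excluded_phewas"):
            raise ConfigurationError(f"exclusions: unknown reason {reason!r}")
        exclusions[reason] = read_exclusion_list(base / path)

    outcome_tables: dict[str, dict[str, VariantAssociation]] = {}
    outcome_records: dict[str, list[VariantAssociation]] = {}
    for ph, spec in raw["phenotypes"].items():
        stats_in = read_summary_stats(base / spec["outcome_path"])
        outcome_tables[ph] = stats_in.by_variant()
        outcome_records[ph] = stats_in.records

    reports: list[SensitivityReport] = []
    skips: list[SkipRecord] = []
    for cohort_id, cspec in raw["cohorts"].items():
        exposure = read_summary_stats(base / cspec["exposure_path"])
        for protein_id, records in sorted(exposure.by_protein().items()):
            try:
                target = annotations.get(protein_id, cohort_id)
            except ProtMRError:
                skips.append(
                    SkipRecord(protein_id, "*", cohort_id, "*", "unannotated_protein")
                )
                continue
            for ph in sorted(raw["phenotypes"]):
                outcome_type = raw["phenotypes"][ph]["outcome_type"]
                for mode in classes:
                    res = run_protein_mr(
                        records,
                        outcome_tables[ph],
                        target,
                        cfg,
                        phenotype=ph,
                        cohort_id=cohort_id,
                        mode=mode,
                        ld=ld,
                        exclusions=exclusions,
                        outcome_type=outcome_type,
                        seed=derive_seed(master_seed, protein_id, ph, cohort_id, mode),
                    )
                    if isinstance(res, SkipRecord):
                        skips.append(res)
                    else:
                        reports.append(res)

    # reverse-direction MR where the Steiger verdict is uncertain
    if cfg.reverse_mode != "never":
        for r in reports:
            if cfg.reverse_mode == "on_flag" and "steiger_p_gt_0.05" not in r.flags:
                continue
            cohort_exposure = read_summary_stats(
                base / raw["cohorts"][r.cohort_id]["exposure_path"]
            )
            protein_records = [
                rec
                for rec in cohort_exposure.records
                if rec.protein_id == r.protein_id
            ]
            rev = reverse_mr(
                outcome_records[r.phenotype],
                {rec.variant_id: rec for rec in protein_records},
                cfg,
                ld=ld,
                exclude_ids=set(r.instrument_ids),
            )
            if isinstance(rev, str):
                r.battery_errors["reverse"] = rev
            else:
                r.reverse = rev
                if rev.pvalue < 0.05:
                    r.flags.add("reverse_significant")

    results = adjust_pvalues(reports, alpha=cfg.alpha)
    results.skips = skips

    # cross-cohort meta-analysis keyed by gene symbol
    grouped: dict[tuple[str, str, str], dict[str, est.MRResult]] = {}
    best_j: dict[tuple[str, str, str, str], int] = {}
    for r in reports:
        key = (r.gene_symbol, r.phenotype, r.instrument_class)
        jkey = key + (r.cohort_id,)
        if jkey in best_j and r.primary.n_snps <= best_j[jkey]:
            continue
        best_j[jkey] = r.primary.n_snps
        grouped.setdefault(key, {})[r.cohort_id] = r.primary
    for key, per_cohort in grouped.items():
        results.meta[key] = meta_analyze(per_cohort)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_results(
            reports, out_dir / "results.tsv", run_config=raw, seed=master_seed
        )
        manifest = {
            "seed": master_seed,
            "n_reports": len(reports),
            "n_skips": len(skips),
            "bonferroni_alpha": results.bonferroni_alpha,
            "bonferroni_denominators": {
                cls: round(cfg.alpha / a)
                for cls, a in results.bonferroni_alpha.items()
            },
            "fdr_thresholds": {
                f"{ph}:{cls}": thr
                for (ph, cls), thr in results.fdr_thresholds.items()
            },
            "tallies": results.tallies,
            "skip_reasons": sorted({s.reason for s in skips}),
        }
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
    return results
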