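"""Synthetic two-cohort pQTL and outcome-GWAS summary statistics.

The generator emulates the statistical structure of a proteome-wide MR
study: per protein, J independent instruments whose true effects are
scaled to explain a chosen fraction of exposure variance; observed
exposure effects with sampling noise matching the pQTL panel size;
outcome associations generated under a true causal effect theta plus a
configurable horizontal-pleiotropy regime; binary outcomes on the
log-odds scale with case/control sampling noise; and two proteomics
platforms ("cohorts") whose per-protein causal effects are correlated.

Every latent quantity is recorded in a truth table, so estimator
calibration, bias, directionality, and cross-platform concordance are
all checkable offline against known ground truth.

Default cohort and outcome sample sizes follow the study design this
package models: two plasma-proteomics panels of ~34,600 and ~35,600
individuals, and psychiatric/cognitive outcome GWAS up to ~670k samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._utils import derive_seed, two_sided_p
from .errors import ConfigurationError, InputError
from .summary_io import VariantAssociation

PLEIOTROPY_REGIMES = ("none", "balanced", "directional", "correlated")

#: outcome phenotypes of the modelled study with their GWAS sample sizes
DEFAULT_PHENOTYPES: dict[str, dict] = {
    "SCZ": {"outcome_type": "binary", "n_case": 67_323, "n_control": 93_456},
    "BIP": {"outcome_type": "binary", "n_case": 40_463, "n_control": 313_436},
    "MDD": {"outcome_type": "binary", "n_case": 166_773, "n_control": 507_679},
    "CTP": {"outcome_type": "quantitative", "n": 215_333},
}


def expected_se(
    maf: float,
    n: float,
    outcome_type: str = "quantitative",
    n_case: float | None = None,
    n_control: float | None = None,
) -> float:
    """Expected GWAS standard error for a variant of given frequency.

    Quantitative (unit-variance trait): se = 1/sqrt(2 p q n).
    Binary (log-odds scale):            se = 1/sqrt(2 p q n_case n_control / n).
    """
    if not (0.0 < maf < 1.0):
        raise ConfigurationError("maf must be in (0,1)")
    if not (n > 1):
        raise ConfigurationError("n must be > 1")
    pq2 = 2.0 * maf * (1.0 - maf)
    if outcome_type == "quantitative":
        return 1.0 / math.sqrt(pq2 * n)
    if outcome_type == "binary":
        if not n_case or not n_control:
            raise ConfigurationError("binary outcome needs n_case and n_control")
        return 1.0 / math.sqrt(pq2 * n_case * n_control / n)
    raise ConfigurationError(f"unknown outcome_type {outcome_type!r}")


@dataclass
class SyntheticScenario:
    """Complete parameterization of the generative model for one protein.

    theta is the true causal effect of the (unit-variance) protein on the
    outcome; pleiotropy regimes act on a fraction ``prop_invalid`` of
    instruments: "balanced" alpha_j ~ N(0, sd^2), "directional"
    alpha_j ~ N(mean, sd^2), "correlated" alpha_j proportional to the true
    exposure effect (violating InSIDE).  ``reverse_causal`` swaps the
    generative arrow: the instruments act on the outcome phenotype and the
    protein responds with effect theta.
    """

    theta: float = 0.0
    J: int = 30
    maf_range: tuple[float, float] = (0.05, 0.5)
    exposure_r2_total: float = 0.05
    n_exposure: float = 34_557
    n_outcome: float = 215_333
    outcome_type: str = "quantitative"
    n_case: float | None = None
    n_control: float | None = None
    pleiotropy: str = "none"
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    prop_invalid: float = 0.0
    n_cohorts: int = 1
    between_cohort_effect_corr: float = 0.5
    reverse_causal: bool = False
    seed: int = 0
    theta_by_cohort: tuple[float, ...] | None = None
    outcome_seed: int = 0
    chrom: str = "1"
    gene_start: int = 1_000_000
    gene_end: int = 1_050_000
    variant_prefix: str = "rs"
    # the phenotype's own polygenic instruments (trans to the gene), used
    # by reverse-direction MR; they affect the protein only when
    # reverse_causal is set
    n_phenotype_snps: int = 0
    phenotype_r2_total: float = 0.1
    phenotype_chrom: str = "22"
    phenotype_pos0: int = 50_000_000
    # per-variant effect-size law (before rescaling to exposure_r2_total):
    # "selected_normal" (default): N(0,1) conditioned on |x| >= 0.5 —
    #   instruments are genome-wide significant by construction, so their
    #   effects are heterogeneous yet bounded away from zero;
    # "equal_r2": every instrument explains r2_total/J (random sign);
    # "normal": unconditioned N(0,1) (admits near-zero instruments that
    #   real significance selection would remove)
    effect_distribution: str = "selected_normal"

    def __post_init__(self) -> None:
        if not (0.0 <= self.prop_invalid <= 1.0):
            raise ConfigurationError("prop_invalid must be in [0,1]")
        if not (0.0 < self.exposure_r2_total < 1.0):
            raise ConfigurationError("exposure_r2_total must be in (0,1)")
        if not (-1.0 <= self.between_cohort_effect_corr <= 1.0):
            raise ConfigurationError("between_cohort_effect_corr must be in [-1,1]")
        if self.pleiotropy not in PLEIOTROPY_REGIMES:
            raise ConfigurationError(f"unknown pleiotropy regime {self.pleiotropy!r}")
        if self.outcome_type == "binary":
            if not self.n_case or not self.n_control:
                raise ConfigurationError("binary outcome needs n_case and n_control")
            self.n_outcome = float(self.n_case) + float(self.n_control)
        if self.J < 1:
            raise ConfigurationError("J must be >= 1")
        if self.exposure_r2_total / self.J > 0.5:
            raise ConfigurationError(
                "infeasible variance split: exposure_r2_total/J > 0.5"
            )


@dataclass
class CohortSim:
    """One cohort's generated tables plus the latent truth."""

    cohort_id: str
    exposure: list[VariantAssociation]
    outcome: list[VariantAssociation]
    truth: dict


def _records(
    ids, chrom, pos, mafs, betas, ses, n, protein_id=None
) -> list[VariantAssociation]:
    out = []
    for i in range(len(ids)):
        z = betas[i] / ses[i]
        out.append(
            VariantAssociation(
                variant_id=ids[i],
                chrom=chrom,
                pos=int(pos[i]),
                effect_allele="A",
                other_allele="G",
                beta=float(betas[i]),
                se=float(ses[i]),
                pvalue=float(max(two_sided_p(z), 5e-324)),
                n=float(n),
                eaf=float(mafs[i]),
                protein_id=protein_id,
            )
        )
    return out


def simulate_protein_scenario(scn: SyntheticScenario) -> list[CohortSim]:
    """Generate per-cohort exposure and outcome summary statistics.

    True per-variant exposure effects are drawn N(0,1) and rescaled so the
    instruments jointly explain ``exposure_r2_total`` of a unit-variance
    exposure; observed effects add sampling noise with the SE implied by
    maf and sample size; outcome effects are theta * gamma_j + alpha_j
    observed with outcome-GWAS noise.  Cohorts get distinct variants and
    independently drawn effects; per-cohort causal effects can be set via
    ``theta_by_cohort`` (the study-level generator draws them correlated).

    Deterministic: the same scenario (same seed) reproduces identical
    tables; exposure draws do not depend on theta or the outcome seed, so
    one protein's pQTL table is shared across outcome phenotypes.
    """
    thetas = scn.theta_by_cohort or tuple([scn.theta] * scn.n_cohorts)
    if len(thetas) != scn.n_cohorts:
        raise ConfigurationError("theta_by_cohort length must equal n_cohorts")
    sims: list[CohortSim] = []
    span = max(scn.gene_end - scn.gene_start, 1)
    for c in range(scn.n_cohorts):
        rng_exp = np.random.default_rng([scn.seed, 13, c])
        mafs = rng_exp.uniform(*scn.maf_range, size=scn.J)
        pq2 = 2.0 * mafs * (1.0 - mafs)
        if scn.effect_distribution == "equal_r2":
            gamma_raw = rng_exp.choice([-1.0, 1.0], size=scn.J) / np.sqrt(pq2)
        elif scn.effect_distribution == "normal":
            gamma_raw = rng_exp.normal(size=scn.J)
        elif scn.effect_distribution == "selected_normal":
            gamma_raw = rng_exp.normal(size=scn.J)
            while True:
                weak = np.abs(gamma_raw) < 0.5
                if not weak.any():
                    break
                gamma_raw[weak] = rng_exp.normal(size=int(weak.sum()))
        else:
            raise ConfigurationError(
                f"unknown effect_distribution {scn.effect_distribution!r}"
            )
        gamma = gamma_raw * math.sqrt(
            scn.exposure_r2_total / float(np.sum(pq2 * gamma_raw**2))
        )

        n_invalid = int(round(scn.prop_invalid * scn.J))
        invalid_idx = rng_exp.permutation(scn.J)[:n_invalid]
        alpha = np.zeros(scn.J)
        rng_out = np.random.default_rng([scn.seed, 17, c, scn.outcome_seed])
        if n_invalid and scn.pleiotropy != "none":
            if scn.pleiotropy == "balanced":
                alpha[invalid_idx] = rng_out.normal(
                    0.0, scn.pleiotropy_sd, size=n_invalid
                )
            elif scn.pleiotropy == "directional":
                # directional means: aligned with the exposure-increasing
                # allele, hence the sign(gamma) factor (a nonzero mean on an
                # arbitrary allele orientation would cancel out)
                alpha[invalid_idx] = rng_out.normal(
                    scn.pleiotropy_mean, scn.pleiotropy_sd, size=n_invalid
                ) * np.sign(gamma[invalid_idx])
            else:  # correlated with instrument strength: violates InSIDE
                g = gamma[invalid_idx]
                denom = float(np.std(g)) or 1.0
                kappa = (scn.pleiotropy_sd or abs(scn.pleiotropy_mean) or 0.05) / denom
                alpha[invalid_idx] = kappa * g

        se_x = np.array([expected_se(m, scn.n_exposure) for m in mafs])
        se_y = np.array(
            [
                expected_se(
                    m, scn.n_outcome, scn.outcome_type, scn.n_case, scn.n_control
                )
                for m in mafs
            ]
        )
        theta_c = thetas[c]
        if scn.reverse_causal:
            # instruments act on the phenotype; the protein responds
            true_y = gamma
            true_x = theta_c * gamma + alpha
        else:
            true_x = gamma
            true_y = theta_c * gamma + alpha
        beta_x = true_x + rng_exp.normal(0.0, se_x)
        beta_y = true_y + rng_out.normal(0.0, se_y)

        ids = [f"{scn.variant_prefix}{c}_{j}" for j in range(scn.J)]
        pos = scn.gene_start + (np.arange(scn.J) * span) // max(scn.J - 1, 1)
        exposure = _records(ids, scn.chrom, pos, mafs, beta_x, se_x, scn.n_exposure)
        outcome = _records(ids, scn.chrom, pos, mafs, beta_y, se_y, scn.n_outcome)

        phenotype_ids: list[str] = []
        if scn.n_phenotype_snps:
            k = scn.n_phenotype_snps
            rng_ph = np.random.default_rng([scn.seed, 19, c, scn.outcome_seed])
            mafs_ph = rng_ph.uniform(*scn.maf_range, size=k)
            delta_raw = rng_ph.normal(size=k)
            pq2_ph = 2.0 * mafs_ph * (1.0 - mafs_ph)
            delta = delta_raw * math.sqrt(
                scn.phenotype_r2_total / float(np.sum(pq2_ph * delta_raw**2))
            )
            se_x_ph = np.array([expected_se(m, scn.n_exposure) for m in mafs_ph])
            se_y_ph = np.array(
                [
                    expected_se(
                        m, scn.n_outcome, scn.outcome_type, scn.n_case, scn.n_control
                    )
                    for m in mafs_ph
                ]
            )
            # protein responds to phenotype liability only under reverse causality
            true_x_ph = theta_c * delta if scn.reverse_causal else np.zeros(k)
            bx_ph = true_x_ph + rng_ph.normal(0.0, se_x_ph)
            by_ph = delta + rng_ph.normal(0.0, se_y_ph)
            phenotype_ids = [f"{scn.variant_prefix}{c}_ph{j}" for j in range(k)]
            pos_ph = scn.phenotype_pos0 + np.arange(k) * 1_000_000
            exposure += _records(
                phenotype_ids, scn.phenotype_chrom, pos_ph, mafs_ph, bx_ph, se_x_ph,
                scn.n_exposure,
            )
            outcome += _records(
                phenotype_ids, scn.phenotype_chrom, pos_ph, mafs_ph, by_ph, se_y_ph,
                scn.n_outcome,
            )

        sims.append(
            CohortSim(
                cohort_id=f"cohort{c}",
                exposure=exposure,
                outcome=outcome,
                truth={
                    "theta": theta_c,
                    "gamma": gamma,
                    "alpha": alpha,
                    "invalid_ids": [ids[i] for i in sorted(invalid_idx)],
                    "reverse_causal": scn.reverse_causal,
                    "variant_ids": ids,
                    "phenotype_variant_ids": phenotype_ids,
                },
            )
        )
    return sims


def _correlated_thetas(
    rng: np.random.Generator, n_cohorts: int, sd: float, rho: float
) -> np.ndarray:
    """Equicorrelated normal effects across cohorts with marginal sd."""
    shared = rng.normal()
    own = rng.normal(size=n_cohorts)
    r = math.sqrt(abs(rho))
    thetas = r * shared + math.sqrt(1 - abs(rho)) * own
    if rho < 0 and n_cohorts == 2:
        thetas = np.array([r * shared + math.sqrt(1 + rho) * own[0],
                           -r * shared + math.sqrt(1 + rho) * own[1]])
    return thetas * sd


@dataclass
class StudyBundle:
    """Paths and truth table of a written synthetic study."""

    out_dir: Path
    config_path: Path
    annotation_path: Path
    exposure_paths: dict[str, Path]
    outcome_paths: dict[str, Path]
    truth_path: Path
    truth: pd.DataFrame
    ld_path: Path | None = None


def _write_stats_tsv(records: list[VariantAssociation], path: Path) -> None:
    cols = [
        "variant_id",
        "chrom",
        "pos",
        "effect_allele",
        "other_allele",
        "eaf",
        "beta",
        "se",
        "pvalue",
        "n",
        "protein_id",
    ]
    rows = []
    for r in records:
        rows.append(
            {
                "variant_id": r.variant_id,
                "chrom": r.chrom,
                "pos": r.pos,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "eaf": r.eaf,
                "beta": r.beta,
                "se": r.se,
                "pvalue": r.pvalue,
                "n": r.n,
                "protein_id": r.protein_id or "",
            }
        )
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def simulate_study(
    n_proteins: int,
    template: SyntheticScenario,
    out_dir: str | Path,
    seed: int = 0,
    theta_sd: float = 0.15,
    phenotypes: dict[str, dict] | None = None,
    cohort_names: tuple[str, ...] = ("ukb", "decode"),
    force: bool = False,
) -> StudyBundle:
    """Write a complete multi-protein, multi-phenotype, two-cohort input
    bundle (exposure/outcome TSVs, annotations, config stub, truth table)
    consumable by the pipeline.

    Per protein and phenotype, cohort causal effects are drawn from an
    equicorrelated normal with marginal sd ``theta_sd`` and correlation
    ``template.between_cohort_effect_corr``.  Per-protein seeds derive
    from (seed, protein index) so adding proteins never changes existing
    proteins' draws.  Refuses to write into a non-empty directory unless
    ``force``.
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise InputError(f"output dir {out_dir} exists and is not empty (use force)")
    out_dir.mkdir(parents=True, exist_ok=True)
    phenotypes = phenotypes or DEFAULT_PHENOTYPES
    n_cohorts = len(cohort_names)

    ann_rows = []
    exposures: dict[str, list[VariantAssociation]] = {c: [] for c in cohort_names}
    outcomes: dict[str, list[VariantAssociation]] = {p: [] for p in phenotypes}
    truth_rows = []
    for i in range(n_proteins):
        gene = f"GENE{i:04d}"
        chrom = str((i % 22) + 1)
        gene_start = 1_000_000 + (i // 22) * 3_000_000
        gene_end = gene_start + 50_000
        for c, cname in enumerate(cohort_names):
            ann_rows.append(
                {
                    "protein_id": f"{cname}_P{i:04d}",
                    "gene_symbol": gene,
                    "chrom": chrom,
                    "gene_start": gene_start,
                    "gene_end": gene_end,
                    "cohort_id": cname,
                }
            )
        exposure_written = {c: False for c in cohort_names}
        for p_idx, (ph, spec) in enumerate(sorted(phenotypes.items())):
            rng_theta = np.random.default_rng(derive_seed(seed, "theta", i, ph))
            thetas = _correlated_thetas(
                rng_theta, n_cohorts, theta_sd, template.between_cohort_effect_corr
            )
            scn = replace(
                template,
                n_cohorts=n_cohorts,
                theta_by_cohort=tuple(float(t) for t in thetas),
                seed=derive_seed(seed, "protein", i),
                outcome_seed=p_idx,
                chrom=chrom,
                gene_start=gene_start,
                gene_end=gene_end,
                variant_prefix=f"rs{i:04d}_",
                outcome_type=spec["outcome_type"],
                n_case=spec.get("n_case"),
                n_control=spec.get("n_control"),
                n_outcome=spec.get("n", 0.0)
                or float(spec.get("n_case", 0)) + float(spec.get("n_control", 0)),
            )
            sims = simulate_protein_scenario(scn)
            for c, (cname, sim) in enumerate(zip(cohort_names, sims)):
                pid = f"{cname}_P{i:04d}"
                if not exposure_written[cname]:
                    for r in sim.exposure:
                        r.protein_id = pid
                    exposures[cname].extend(sim.exposure)
                    exposure_written[cname] = True
                outcomes[ph].extend(sim.outcome)
                truth_rows.append(
                    {
                        "protein_id": pid,
                        "gene_symbol": gene,
                        "phenotype": ph,
                        "cohort_id": cname,
                        "theta": sim.truth["theta"],
                        "n_invalid": len(sim.truth["invalid_ids"]),
                    }
                )

    annotation_path = out_dir / "annotations.tsv"
    pd.DataFrame(ann_rows).to_csv(annotation_path, sep="\t", index=False)
    exposure_paths = {}
    for cname, recs in exposures.items():
        path = out_dir / f"exposure_{cname}.tsv"
        _write_stats_tsv(recs, path)
        exposure_paths[cname] = path
    outcome_paths = {}
    for ph, recs in outcomes.items():
        path = out_dir / f"outcome_{ph}.tsv"
        _write_stats_tsv(recs, path)
        outcome_paths[ph] = path
    truth = pd.DataFrame(truth_rows)
    truth_path = out_dir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False, float_format="%.12g")

    config = {
        "schema_version": 1,
        "seed": seed,
        "annotations": annotation_path.name,
        "ld_matrix": None,
        "cohorts": {
            cname: {"exposure_path": p.name} for cname, p in exposure_paths.items()
        },
        "phenotypes": {
            ph: {**phenotypes[ph], "outcome_path": outcome_paths[ph].name}
            for ph in phenotypes
        },
        "classes": ["cis"],
        "selection": {},
        "estimators": {},
    }
    config_path = out_dir / "config.yaml"
    config_path.write_text(yaml.safe_dump(config, sort_keys=True))
    return StudyBundle(
        out_dir=out_dir,
        config_path=config_path,
        annotation_path=annotation_path,
        exposure_paths=exposure_paths,
        outcome_paths=outcome_paths,
        truth_path=truth_path,
        truth=truth,
    )
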