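"""Instrument selection per protein: significance filter, cis/trans
classification, greedy LD clumping, and weak-instrument screening.

The validity of inverse-variance-weighted MR rests on (approximately)
independent instruments, so candidate pQTLs are clumped greedily by
p-value against a user-supplied LD (r^2) matrix.  Instruments are split
into cis (within a window of the protein's encoding gene) and trans
(elsewhere), which the study analyses separately, and weak instruments
are screened out by the summary-statistic F approximation (beta/se)^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .summary_io import HarmonizedInstrument, ProteinTarget, VariantAssociation

logger = logging.getLogger(__name__)


@dataclass(slots=True)
class InstrumentSelectionConfig:
    """Thresholds of the selection pipeline.

    Defaults: genome-wide significance 5e-8, a +/-1 Mb cis window around
    the gene body, clumping at r^2 < 0.01 within 10 Mb, and a minimum
    F-statistic of 10 (the conventional weak-instrument cutoff).
    """

    p_threshold: float = 5e-8
    cis_window_bp: int = 1_000_000
    clump_r2: float = 0.01
    clump_window_bp: int = 10_000_000
    min_f: float = 10.0

    def __post_init__(self) -> None:
        if not (0.0 < self.p_threshold < 1.0):
            raise ConfigurationError("p_threshold must be in (0,1)")
        if self.cis_window_bp < 0:
            raise ConfigurationError("cis_window_bp must be >= 0")
        if not (0.0 <= self.clump_r2 < 1.0):
            raise ConfigurationError("clump_r2 must be in [0,1)")
        if self.min_f < 0:
            raise ConfigurationError("min_f must be >= 0")


class LDMatrix:
    """Symmetric r^2 lookup keyed by variant id.

    Variants absent from the matrix are treated as unlinked (r^2 = 0) —
    partial LD panels are the norm — but the first such query is logged.
    """

    def __init__(self, variant_ids: Sequence[str], r2: np.ndarray):
        r2 = np.asarray(r2, dtype=float)
        if r2.shape != (len(variant_ids), len(variant_ids)):
            raise InputError("LD matrix shape does not match variant id count")
        if not np.allclose(r2, r2.T, atol=1e-8):
            raise InputError("LD matrix is not symmetric")
        if np.any((r2 < -1e-12) | (r2 > 1 + 1e-12)):
            raise InputError("LD r^2 values outside [0,1]")
        if not np.allclose(np.diag(r2), 1.0, atol=1e-6):
            raise InputError("LD matrix diagonal is not 1")
        self.variant_ids = list(variant_ids)
        self._index = {v: i for i, v in enumerate(self.variant_ids)}
        self._r2 = np.clip(r2, 0.0, 1.0)
        self._warned_missing = False

    @classmethod
    def identity(cls, variant_ids: Sequence[str]) -> "LDMatrix":
        return cls(variant_ids, np.eye(len(variant_ids)))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LDMatrix":
        """Square TSV with a header row and an id index column."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        if list(df.index.astype(str)) != [str(c) for c in df.columns]:
            raise InputError(f"{path}: LD matrix row/column ids differ")
        return cls([str(c) for c in df.columns], df.to_numpy(dtype=float))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self._r2, index=self.variant_ids, columns=self.variant_ids).to_csv(
            path, sep="\t", float_format="%.6g"
        )

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        ia, ib = self._index.get(a), self._index.get(b)
        if ia is None or ib is None:
            if not self._warned_missing:
                missing = a if ia is None else b
                logger.warning(
                    "variant %s absent from LD matrix; treating as unlinked", missing
                )
                self._warned_missing = True
            return 0.0
        return float(self._r2[ia, ib])


def classify_cis_trans(
    variant: VariantAssociation, target: ProteinTarget, cis_window_bp: int = 1_000_000
) -> str:
    """cis iff on the gene's chromosome within the window around the gene
    body [gene_start - window, gene_end + window]; trans otherwise."""
    if variant.chrom != target.chrom:
        return "trans"
    if target.gene_start - cis_window_bp <= variant.pos <= target.gene_end + cis_window_bp:
        return "cis"
    return "trans"


def ld_clump(
    variants: Sequence[VariantAssociation],
    ld: LDMatrix | None,
    clump_r2: float = 0.01,
    clump_window_bp: int = 10_000_000,
) -> list[VariantAssociation]:
    """Greedy best-p-first clumping.

    Variants are visited by ascending (pvalue, variant_id); each is kept
    unless it lies within ``clump_window_bp`` of an already-kept variant on
    the same chromosome with r^2 above ``clump_r2``.  ld=None means all
    variants unlinked (returns the input re-sorted only by visit order of
    survivors, i.e. the original ordering is preserved in the output).
    """
    order = sorted(variants, key=lambda v: (v.pvalue, v.variant_id))
    kept: list[VariantAssociation] = []
    for v in order:
        linked = False
        if ld is not None:
            for k in kept:
                if k.chrom == v.chrom and abs(k.pos - v.pos) <= clump_window_bp:
                    if ld.r2(k.variant_id, v.variant_id) > clump_r2:
                        linked = True
                        break
        if not linked:
            kept.append(v)
    kept_ids = {v.variant_id for v in kept}
    return [v for v in variants if v.variant_id in kept_ids]


def f_statistic(instrument: HarmonizedInstrument | VariantAssociation) -> float:
    """Summary-statistic F approximation (beta/se)^2 on the exposure side."""
    if isinstance(instrument, HarmonizedInstrument):
        beta, se = instrument.beta_exposure, instrument.se_exposure
    else:
        beta, se = instrument.beta, instrument.se
    return (beta / se) ** 2


@dataclass(slots=True)
class StageCounts:
    """Per-stage retention counts of the selection pipeline."""

    n_input: int = 0
    n_significant: int = 0
    n_in_class: int = 0
    n_clumped: int = 0
    n_strong: int = 0


@dataclass
class SelectionResult:
    """Ordered selected variant ids plus per-stage bookkeeping."""

    variant_ids: list[str]
    counts: StageCounts
    variants: list[VariantAssociation] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.variant_ids)


def select_instruments(
    exposure: Iterable[VariantAssociation],
    target: ProteinTarget | None,
    ld: LDMatrix | None,
    cfg: InstrumentSelectionConfig,
    mode: str = "cis",
) -> SelectionResult:
    """Compose the selection pipeline for one protein (or one phenotype,
    in reverse-direction MR with mode="all").

    Stages: p-value threshold -> cis/trans classification (skipped for
    mode="all") -> greedy LD clumping -> F >= min_f.  The returned ids are
    ordered by genomic coordinate; selection is fully deterministic.
    """
    if mode not in ("cis", "trans", "all"):
        raise ConfigurationError(f"unknown selection mode {mode!r}")
    if mode != "all" and target is None:
        raise ConfigurationError("cis/trans selection requires a protein target")
    pool = list(exposure)
    counts = StageCounts(n_input=len(pool))

    sig = [v for v in pool if v.pvalue <= cfg.p_threshold]
    counts.n_significant = len(sig)

    if mode == "all":
        in_class = sig
    else:
        in_class = [
            v for v in sig if classify_cis_trans(v, target, cfg.cis_window_bp) == mode
        ]
    counts.n_in_class = len(in_class)

    clumped = ld_clump(in_class, ld, cfg.clump_r2, cfg.clump_window_bp)
    counts.n_clumped = len(clumped)

    strong = [v for v in clumped if f_statistic(v) >= cfg.min_f]
    counts.n_strong = len(strong)

    strong.sort(key=lambda v: (v.chrom, v.pos, v.variant_id))
    return SelectionResult(
        variant_ids=[v.variant_id for v in strong], counts=counts, variants=strong
    )


@dataclass
class RemovalLog:
    reason: str
    removed_ids: list[str]

    @property
    def count(self) -> int:
        return len(self.removed_ids)


def apply_snp_exclusions(
    instruments: Sequence[HarmonizedInstrument],
    exclusion_ids: set[str],
    reason: str,
) -> tuple[list[HarmonizedInstrument], RemovalLog]:
    """Mark instruments on an exclusion list (confounder-GWAS or PheWAS
    hits) with the given drop_reason; returns new instruments + a log.

    The input is not mutated, so pre- and post-exclusion estimates can be
    compared side by side.
    """
    if reason not in ("excluded_confounder", "excluded_phewas"):
        raise ConfigurationError(f"unknown exclusion reason {reason!r}")
    out: list[HarmonizedInstrument] = []
    removed: list[str] = []
    for inst in instruments:
        if inst.variant_id in exclusion_ids and inst.drop_reason is None:
            from dataclasses import replace

            out.append(replace(inst, drop_reason=reason))
            removed.append(inst.variant_id)
        else:
            out.append(inst)
    return out, RemovalLog(reason=reason, removed_ids=removed)
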