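"""Over-representation testing of gene lists against GMT gene sets.

The statistic is the hypergeometric upper tail (equivalently one-sided
Fisher's exact test) of the overlap between a query gene list (e.g. the
Bonferroni-significant proteins for one phenotype) and each gene set
within a background universe, with Benjamini-Hochberg correction across
sets.  The background defaults to the full set of proteins tested in the
MR run — the selection universe — rather than the genome, which would
inflate enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError, PreconditionError

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets with descriptions; symbols uppercased on load."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    rejects: list[tuple[int, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class EnrichmentResult:
    set_name: str
    k: int  # query hits in set
    K: int  # set size within background
    n: int  # query size
    N: int  # background size
    pvalue: float
    qvalue: float
    odds_ratio: float


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file (tab-separated: name, description, members...).

    Lines with no members are rejected with a reason; duplicate set names
    are suffixed (_2, _3, ...) and logged.
    """
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    rejects: list[tuple[int, str]] = []
    lines = Path(path).read_text().splitlines()
    for i, line in enumerate(lines):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3 or not any(p.strip() for p in parts[2:]):
            rejects.append((i, "no_members"))
            continue
        name, desc = parts[0].strip(), parts[1].strip()
        members = {p.strip().upper() for p in parts[2:] if p.strip()}
        if name in sets:
            suffix = 2
            while f"{name}_{suffix}" in sets:
                suffix += 1
            logger.warning("duplicate gene-set name %r -> %r", name, f"{name}_{suffix}")
            name = f"{name}_{suffix}"
        sets[name] = members
        descriptions[name] = desc
    if not sets:
        raise InputError(f"{path}: no gene sets loaded")
    return GeneSetCollection(sets=sets, descriptions=descriptions, rejects=rejects)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = []
    for name, members in collection.sets.items():
        desc = collection.descriptions.get(name, "")
        lines.append("\t".join([name, desc] + sorted(members)))
    Path(path).write_text("\n".join(lines) + "\n")


def hypergeometric_enrichment(
    query: Sequence[str],
    background: Sequence[str],
    sets: GeneSetCollection,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of the query in each gene set.

    p = P[X >= k] for X ~ Hypergeom(N, |set & background|, n); q-values
    are BH across the tested sets.  Sets with zero background overlap are
    skipped (noted in the log).  Query genes absent from the background
    raise PreconditionError naming the first offender.
    """
    bg = {g.upper() for g in background}
    q = {g.upper() for g in query}
    for g in sorted(q):
        if g not in bg:
            raise PreconditionError(f"query gene {g!r} absent from background")
    n_bg, n_q = len(bg), len(q)

    rows: list[EnrichmentResult] = []
    for name in sets.sets:
        members = sets.sets[name] & bg
        big_k = len(members)
        if big_k == 0:
            logger.info("gene set %r has no background overlap; skipped", name)
            continue
        k = len(members & q)
        p = float(stats.hypergeom.sf(k - 1, n_bg, big_k, n_q))
        a, b = k, big_k - k
        c, d = n_q - k, n_bg - big_k - (n_q - k)
        odds = (a * d) / (b * c) if b * c > 0 else float("inf")
        rows.append(
            EnrichmentResult(
                set_name=name,
                k=k,
                K=big_k,
                n=n_q,
                N=n_bg,
                pvalue=min(p, 1.0),
                qvalue=1.0,
                odds_ratio=odds,
            )
        )
    if rows:
        _, qvals, _, _ = multipletests(
            [r.pvalue for r in rows], method="fdr_bh"
        )
        for r, qv in zip(rows, qvals):
            r.qvalue = float(qv)
    rows.sort(key=lambda r: (r.pvalue, r.set_name))
    return rows


def write_enrichment_tsv(
    results: Iterable[EnrichmentResult], path: str | Path
) -> None:
    header = "set\tk\tK\tn\tN\tp\tq\todds_ratio"
    lines = [header]
    for r in results:
        lines.append(
            f"{r.set_name}\t{r.k}\t{r.K}\t{r.n}\t{r.N}\t"
            f"{r.pvalue:.6g}\t{r.qvalue:.6g}\t{r.odds_ratio:.6g}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
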