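"""Per-term over-representation testing.

Each GO term with at least one propagated target gene is scored with the
upper tail of the hypergeometric distribution — the probability of drawing
at least ``x`` annotated genes when ``n`` genes are sampled without
replacement from a background of ``N`` genes of which ``K`` carry the term:

    P(X >= x) = sum_{j=x}^{min(K,n)} C(K,j) C(N-K, n-j) / C(N,n)

Multiplicity is handled with the Benjamini-Hochberg step-up procedure over
the tested terms; only terms with at least one target gene are tested, which
defines the number of hypotheses m. The effect measure is the enrichment
size: observed target count divided by its expectation n*K/N.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .annotations import AnnotationSet, EmptyGeneSetError
from .ontology import OntologyDAG

__all__ = [
    "ContingencyCounts",
    "EnrichmentResult",
    "hypergeom_upper_tail",
    "bh_adjust",
    "enrichment_size",
    "score_terms",
    "run_enrichment",
    "DEFAULT_FDR",
]

DEFAULT_FDR = 0.05


@dataclass(frozen=True)
class ContingencyCounts:
    """Hypergeometric counts for one term.

    N: background size; K: background genes carrying the term (propagated);
    n: target size; x: target genes carrying the term.
    """

    N: int
    K: int
    n: int
    x: int

    def __post_init__(self) -> None:
        if not (0 <= self.K <= self.N and 0 <= self.n <= self.N):
            raise ValueError(f"inconsistent counts: {self}")
        if not (0 <= self.x <= min(self.K, self.n)):
            raise ValueError(f"x out of range: {self}")


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    counts: ContingencyCounts
    pvalue: float
    qvalue: float
    enrichment_size: float
    genes: tuple[str, ...]


def hypergeom_upper_tail(c: ContingencyCounts) -> float:
    """P(X >= x) under Hypergeom(N, K, n), via the survival function."""
    if c.x == 0:
        return 1.0
    return float(hypergeom.sf(c.x - 1, c.N, c.K, c.n))


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted values, in the input order.

    q_(i) = min_{j>=i} p_(j) * m / j, clipped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def enrichment_size(c: ContingencyCounts) -> float:
    """Observed over expected target count: x / (n*K/N)."""
    if c.n * c.K == 0:
        raise ValueError("expected count is zero (n*K = 0)")
    return c.x / (c.n * c.K / c.N)


def score_terms(
    target: Iterable[str],
    background: Iterable[str],
    ann: AnnotationSet,
    dag: OntologyDAG,
) -> list[EnrichmentResult]:
    """Score every term overlapping the target set; no FDR filtering.

    The returned list (sorted by term id) covers exactly the hypotheses the
    BH correction was run over, with both raw and adjusted values filled in.
    """
    bg = frozenset(background) & ann.universe
    tgt = [g for g in dict.fromkeys(target) if g in bg]
    if not tgt:
        raise EmptyGeneSetError("target set is empty after background filtering")
    tgt_set = frozenset(tgt)
    N, n = len(bg), len(tgt_set)

    rows: list[tuple[str, ContingencyCounts, tuple[str, ...]]] = []
    for tid in sorted(ann.propagated):
        genes_bg = ann.propagated[tid] & bg
        hits = genes_bg & tgt_set
        if not hits:
            continue
        c = ContingencyCounts(N=N, K=len(genes_bg), n=n, x=len(hits))
        rows.append((tid, c, tuple(sorted(hits))))

    pvals = [hypergeom_upper_tail(c) for _, c, _ in rows]
    qvals = bh_adjust(pvals)
    return [
        EnrichmentResult(
            term_id=tid,
            counts=c,
            pvalue=p,
            qvalue=q,
            enrichment_size=enrichment_size(c),
            genes=genes,
        )
        for (tid, c, genes), p, q in zip(rows, pvals, qvals)
    ]


def run_enrichment(
    target: Iterable[str],
    background: Iterable[str],
    ann: AnnotationSet,
    dag: OntologyDAG,
    fdr_threshold: float = DEFAULT_FDR,
) -> list[EnrichmentResult]:
    """Enriched terms at the given FDR, sorted by (qvalue, pvalue, term_id)."""
    if not (0 < fdr_threshold <= 1):
        raise ValueError(f"fdr_threshold must be in (0, 1], got {fdr_threshold}")
    tested = score_terms(target, background, ann, dag)
    kept = [r for r in tested if r.qvalue <= fdr_threshold]
    kept.sort(key=lambda r: (r.qvalue, r.pvalue, r.term_id))
    return kept
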