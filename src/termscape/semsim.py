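"""Information content and pairwise semantic similarity of GO terms.

Information content (IC) of a term is the negative natural log of its
annotation probability, IC(t) = -ln(|genes(t)| / |universe|), where genes(t)
is the descendant-propagated gene set: a gene annotated anywhere below t is
annotated to t. IC is therefore anti-monotone along edges and the namespace
root, which covers the whole universe, has IC 0. Natural log throughout; the
Lin index is invariant to the log base, the aggregate index below is not.

Two similarity measures over a pair of terms:

* **Lin**: 2*IC(c) / (IC(t1) + IC(t2)) where c is the common ancestor
  (self included) with maximal IC. Ranges from 0 (only the root in common)
  to 1 (identical terms).

* **Aggregate information content (AIC)**, the default measure. Each term
  carries a semantic weight derived from its IC through a logistic curve,

      SW(t) = 1 / (1 + exp(-1 / IC(t))),   SW = 1 at IC = 0 (the limit),

  a term's semantic value is the weight summed over its ancestors-or-self,
  SV(t) = sum SW, and

      sim(t1, t2) = sum_{c in common ancestors-or-self} 2*SW(c)
                    / (SV(t1) + SV(t2)).

  This is the aggregate-IC index of Song et al. (2014), pinned here exactly
  as implemented: logistic weight with unit numerator in the exponent,
  natural-log IC, the root's weight taken as the IC->0 limit. Unlike Lin it
  credits every shared ancestor, so two terms with a deep shared lineage
  score higher than two sharing only generic ancestry.

Both measures satisfy sim(t, t) = 1 (for IC > 0), symmetry, and range [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .annotations import AnnotationSet
from .ontology import OntologyDAG

__all__ = [
    "TermStats",
    "SimilarityMatrix",
    "information_content",
    "term_stats",
    "lin_similarity",
    "aic_similarity",
    "similarity_matrix",
    "semantic_weight",
    "semantic_value",
    "MEASURES",
]

MEASURES = ("lin", "aic")


@dataclass(frozen=True)
class TermStats:
    """Annotation probability and information content of one term."""

    term_id: str
    p: float  # in (0, 1]
    ic: float  # -ln(p), nats


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric pairwise similarity over an ordered term list."""

    terms: tuple[str, ...]
    values: np.ndarray  # square, symmetric, entries in [0, 1]
    index: str  # "lin" | "aic"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.terms), len(self.terms)):
            raise ValueError("matrix shape does not match term list")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")
        object.__setattr__(self, "values", v)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.terms, columns=self.terms)

    def to_csv(self, path) -> None:
        """Dump for debugging/inspection."""
        self.to_frame().to_csv(path)


def information_content(
    term_id: str, ann: AnnotationSet, dag: OntologyDAG
) -> TermStats:
    """IC from the propagated annotation count relative to the universe."""
    tid = dag.resolve(term_id)
    count = len(ann.propagated.get(tid, ()))
    if count == 0:
        raise ValueError(f"term {tid} has no propagated annotation")
    p = count / len(ann.universe)
    return TermStats(term_id=tid, p=p, ic=-math.log(p))


def term_stats(
    ann: AnnotationSet, dag: OntologyDAG
) -> dict[str, TermStats]:
    """IC for every annotated term (the ancestors needed by both measures
    are annotated whenever their descendants are, by propagation)."""
    return {
        tid: information_content(tid, ann, dag) for tid in ann.propagated
    }


def _common_ancestors(
    t1: str, t2: str, dag: OntologyDAG
) -> frozenset[str]:
    return dag.ancestors_or_self(t1) & dag.ancestors_or_self(t2)


def lin_similarity(
    t1: str,
    t2: str,
    stats: Mapping[str, TermStats],
    dag: OntologyDAG,
) -> float:
    """Lin index: twice the max-IC common ancestor over the IC sum.

    The max-IC member of the common-ancestor set is necessarily a lowest
    common ancestor (IC is anti-monotone along edges), so scanning the full
    intersection is equivalent to restricting to LCAs. Conventions: 1.0 for
    a term with itself (IC > 0); 0.0 when both ICs are 0 or the best shared
    ancestor is the root.
    """
    ic1, ic2 = stats[t1].ic, stats[t2].ic
    denom = ic1 + ic2
    if denom == 0.0:
        return 0.0
    if t1 == t2:
        return 1.0
    common = _common_ancestors(t1, t2, dag)
    best = max((stats[c].ic for c in common if c in stats), default=0.0)
    return min(1.0, 2.0 * best / denom)


def semantic_weight(ic: float) -> float:
    """Logistic IC weight; continuous limit 1 at ic = 0."""
    if ic <= 0.0:
        return 1.0
    return 1.0 / (1.0 + math.exp(-1.0 / ic))


def semantic_value(t: str, stats: Mapping[str, TermStats], dag: OntologyDAG) -> float:
    return sum(
        semantic_weight(stats[a].ic)
        for a in dag.ancestors_or_self(t)
        if a in stats
    )


def aic_similarity(
    t1: str,
    t2: str,
    stats: Mapping[str, TermStats],
    dag: OntologyDAG,
) -> float:
    """Aggregate-IC similarity (see module docstring for the pinned form)."""
    sv1 = semantic_value(t1, stats, dag)
    sv2 = semantic_value(t2, stats, dag)
    if sv1 + sv2 == 0.0:
        return 0.0
    common = _common_ancestors(t1, t2, dag)
    shared = sum(
        2.0 * semantic_weight(stats[c].ic) for c in common if c in stats
    )
    return min(1.0, shared / (sv1 + sv2))


_MEASURE_FN = {"lin": lin_similarity, "aic": aic_similarity}


def similarity_matrix(
    terms: Iterable[str],
    measure: str,
    stats: Mapping[str, TermStats],
    dag: OntologyDAG,
) -> SimilarityMatrix:
    """Pairwise similarity over ``terms`` with the chosen measure.

    Symmetry holds by construction (each pair computed once). Requires at
    least two terms; a singleton run is the caller's special case.
    """
    terms = tuple(terms)
    if len(terms) < 2:
        raise ValueError("similarity matrix needs at least 2 terms")
    if measure not in _MEASURE_FN:
        raise ValueError(f"measure must be one of {MEASURES}, got {measure!r}")
    fn = _MEASURE_FN[measure]
    n = len(terms)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            s = fn(terms[i], terms[j], stats, dag)
            values[i, j] = values[j, i] = s
    return SimilarityMatrix(terms=terms, values=values, index=measure)
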