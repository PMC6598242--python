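"""Synthetic ontology/annotation fixtures with planted structure.

Emits small OBO + GAF text pairs, a target gene list, and a ground-truth
record, so that the whole pipeline — parsing, propagation, enrichment,
similarity, clustering — can be exercised end to end without downloading
real GO releases. Two kinds of structure can be planted:

* an *enriched term*: most of the target set is drawn from the genes below
  one chosen term, so the enrichment test has a known positive;
* *separated subtrees*: the DAG is built as disjoint subtrees under the
  root and genes are annotated within a single subtree, so the semantic
  similarity matrix has a known block structure and the clustering stage
  has a known cluster count and partition.

The generated DAG mimics the shape of real GO at toy scale (a rooted
multi-parent hierarchy with sparse gene annotation); it makes no attempt
to match real term-size distributions. All randomness flows through one
seeded generator, so identical specs give byte-identical files.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .annotations import AnnotationSet, parse_gaf
from .ontology import OntologyDAG, parse_obo

__all__ = ["SyntheticSpec", "SyntheticData", "generate", "InfeasibleSpecError"]

_ASPECT = {
    "biological_process": "P",
    "molecular_function": "F",
    "cellular_component": "C",
}


class InfeasibleSpecError(ValueError):
    """The requested planted structure cannot be realized."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Knobs of the generator; defaults give a small but statistically
    comfortable fixture (30 terms, 200 genes, a 20-gene target with 80%
    of it drawn from below one planted term)."""

    seed: int = 0
    n_terms: int = 30
    branching: int = 3  # informs how bushy levels are
    depth: int = 4
    n_genes: int = 200
    annotation_rate: float = 3.0  # mean direct annotations per gene
    planted_terms: tuple[str, ...] | None = None  # None -> auto-pick one
    target_size: int = 20
    planted_fraction: float = 0.8  # share of target drawn from the plant
    planted_cluster_count: int = 1
    namespace: str = "biological_process"

    def __post_init__(self) -> None:
        if self.target_size > self.n_genes:
            raise InfeasibleSpecError("target_size exceeds n_genes")
        if self.n_terms < 2 + self.planted_cluster_count:
            raise InfeasibleSpecError("too few terms for the requested layout")


@dataclass
class SyntheticData:
    """Generated fixture plus its ground truth."""

    spec: SyntheticSpec
    obo_text: str
    gaf_text: str
    target: tuple[str, ...]
    truth: dict = field(default_factory=dict)

    def parse(self) -> tuple[OntologyDAG, AnnotationSet]:
        """Round-trip the generated text through the real parsers."""
        dag = parse_obo(io.StringIO(self.obo_text), self.spec.namespace)
        ann = parse_gaf(io.StringIO(self.gaf_text), dag)
        return dag, ann

    def target_text(self) -> str:
        return "\n".join(self.target) + "\n"

    def write_files(self, directory) -> dict[str, str]:
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        paths = {
            "obo": d / "synthetic.obo",
            "gaf": d / "synthetic.gaf",
            "target": d / "target.txt",
        }
        paths["obo"].write_text(self.obo_text, encoding="utf-8")
        paths["gaf"].write_text(self.gaf_text, encoding="utf-8")
        paths["target"].write_text(self.target_text(), encoding="utf-8")
        return {k: str(v) for k, v in paths.items()}


def _tid(i: int) -> str:
    return f"GO:{i:07d}"


def generate(spec: SyntheticSpec) -> SyntheticData:
    """Build one fixture from ``spec`` (deterministic in ``spec.seed``)."""
    rng = np.random.default_rng(spec.seed)
    n_sub = max(1, spec.planted_cluster_count)

    root = _tid(1)
    level: dict[str, int] = {root: 0}
    parents: dict[str, list[str]] = {root: []}
    subtree_of: dict[str, int] = {}

    next_id = 2
    subtree_roots: list[str] = []
    if n_sub >= 2:
        for s in range(n_sub):
            t = _tid(next_id)
            next_id += 1
            subtree_roots.append(t)
            level[t] = 1
            parents[t] = [root]
            subtree_of[t] = s
    else:
        subtree_roots = [root]
        subtree_of[root] = 0

    # members[s] lists candidate parents per subtree, ordered by level
    members: list[list[str]] = [[r] for r in subtree_roots]
    min_level = 2 if n_sub >= 2 else 1

    for i in range(next_id, spec.n_terms + 1):
        t = _tid(i)
        s = (i - next_id) % n_sub  # balanced assignment across subtrees
        lev = int(rng.integers(min_level, spec.depth + 1))
        pool = [p for p in members[s] if level[p] < lev]
        if not pool:
            pool = [subtree_roots[s]]
            lev = level[pool[0]] + 1
        n_par = 2 if (len(pool) >= 2 and rng.random() < 0.3) else 1
        chosen = list(rng.choice(pool, size=n_par, replace=False))
        parents[t] = sorted(chosen)
        level[t] = lev
        subtree_of[t] = s
        members[s].append(t)

    all_terms = sorted(parents)

    # ancestors-or-self closure, for internal propagation
    anc: dict[str, frozenset[str]] = {}

    def closure(t: str) -> frozenset[str]:
        if t not in anc:
            out: set[str] = {t}
            for p in parents[t]:
                out |= closure(p)
            anc[t] = frozenset(out)
        return anc[t]

    for t in all_terms:
        closure(t)

    # gene annotations: each gene annotates terms of one subtree
    annotatable: list[list[str]] = [
        [t for t in m if t not in subtree_roots or n_sub == 1]
        or m  # degenerate: a subtree with only its root
        for m in members
    ]
    if n_sub == 1:
        annotatable = [[t for t in members[0] if t != root] or [root]]

    genes = [f"g{i + 1:04d}" for i in range(spec.n_genes)]
    direct: dict[str, list[str]] = {}
    gene_subtree: dict[str, int] = {}
    for g in genes:
        s = int(rng.integers(0, n_sub))
        gene_subtree[g] = s
        k = 1 + int(rng.poisson(max(0.0, spec.annotation_rate - 1.0)))
        k = min(k, len(annotatable[s]))
        direct[g] = sorted(
            str(t) for t in rng.choice(annotatable[s], size=k, replace=False)
        )

    propagated: dict[str, set[str]] = {t: set() for t in all_terms}
    for g, tids in direct.items():
        reached: set[str] = set()
        for t in tids:
            reached |= anc[t]
        for t in reached:
            propagated[t].add(g)

    # choose / validate the planted terms and draw the target
    draw = int(round(spec.planted_fraction * spec.target_size))
    if spec.planted_terms is not None:
        planted = tuple(spec.planted_terms)
        for t in planted:
            if t not in propagated:
                raise InfeasibleSpecError(f"planted term {t} not generated")
    elif spec.target_size > 0:
        cap = max(draw + 2, spec.n_genes // 4)
        candidates = [
            t
            for t in all_terms
            if t != root
            and t not in subtree_roots
            and draw <= len(propagated[t]) <= cap
        ]
        if not candidates:
            raise InfeasibleSpecError(
                "no term has a propagated gene set compatible with the "
                f"requested draw of {draw}"
            )
        planted = (str(rng.choice(candidates)),)
    else:
        planted = ()

    target: tuple[str, ...] = ()
    if spec.target_size > 0:
        pool_in = sorted(set().union(*(propagated[t] for t in planted)))
        if len(pool_in) < draw:
            raise InfeasibleSpecError(
                f"planted subtree holds {len(pool_in)} genes < draw {draw}"
            )
        pool_out = sorted(set(genes) - set(pool_in))
        n_out = spec.target_size - draw
        if len(pool_out) < n_out:
            raise InfeasibleSpecError("not enough genes outside the plant")
        inside = [str(g) for g in rng.choice(pool_in, size=draw, replace=False)]
        outside = [str(g) for g in rng.choice(pool_out, size=n_out, replace=False)]
        target = tuple(sorted(inside + outside))

    obo_text = _render_obo(all_terms, parents, spec.namespace)
    gaf_text = _render_gaf(direct, spec.namespace)
    truth = {
        "seed": spec.seed,
        "planted_terms": list(planted),
        "n_from_planted": draw if target else 0,
        "target": list(target),
        "subtree_of_term": dict(sorted(subtree_of.items())),
        "subtree_of_gene": dict(sorted(gene_subtree.items())),
        "subtree_roots": list(subtree_roots),
        "root": root,
        "term_level": dict(sorted(level.items())),
    }
    return SyntheticData(
        spec=spec,
        obo_text=obo_text,
        gaf_text=gaf_text,
        target=target,
        truth=truth,
    )


def _render_obo(
    terms: list[str], parents: dict[str, list[str]], namespace: str
) -> str:
    chunks = ["format-version: 1.2\nontology: synthetic\n"]
    for t in terms:
        lines = [
            "[Term]",
            f"id: {t}",
            f"name: synthetic term {int(t.split(':')[1])}",
            f"namespace: {namespace}",
        ]
        lines += [f"is_a: {p} ! parent" for p in parents[t]]
        chunks.append("\n".join(lines) + "\n")
    return "\n".join(chunks)


def _render_gaf(direct: dict[str, list[str]], namespace: str) -> str:
    aspect = _ASPECT[namespace]
    rows = ["!gaf-version: 2.1"]
    for g in sorted(direct):
        for t in direct[g]:
            rows.append(
                "\t".join(
                    [
                        "SYN",  # DB
                        g,  # DB Object ID
                        g,  # DB Object Symbol
                        "",  # Qualifier
                        t,  # GO ID
                        "SYN_REF:0000001",  # DB:Reference
                        "IEA",  # Evidence
                        "",  # With/From
                        aspect,  # Aspect
                        f"synthetic gene {g}",  # DB Object Name
                        "",  # Synonym
                        "protein",  # DB Object Type
                        "taxon:32644",  # Taxon
                        "20200101",  # Date
                        "SYN",  # Assigned By
                        "",  # Annotation Extension
                        "",  # Gene Product Form ID
                    ]
                )
            )
    return "\n".join(rows) + "\n"
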