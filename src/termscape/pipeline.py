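"""End-to-end analysis: parse -> resolve -> enrich -> cluster -> embed.

:func:`run_analysis` glues the stages together and returns a
:class:`~termscape.export.RunResult` ready for JSON/CSV export. Stage
counts (genes recognized/dropped, terms tested/enriched, chosen k) are
logged through the ``termscape`` logger.

Small-result edge cases: with no enriched term the result is empty (k=0);
a single enriched term forms cluster 0 with itself as medoid at the center
of the unit square; two enriched terms are embedded but kept in one
cluster, since a 2-point spectrum carries no usable eigengap.
"""

from __future__ import annotations

import datetime as _dt
import logging

from . import annotations as _ann
from . import clustering as _clu
from . import enrichment as _enr
from . import layout as _lay
from . import semsim as _sem
from .export import RunResult, TermRecord
from .ontology import parse_obo

__all__ = ["run_analysis", "AUTO_CLUSTERS"]

logger = logging.getLogger("termscape")

#: sentinel for "choose k with the eigengap heuristic"
AUTO_CLUSTERS = -1


def run_analysis(
    obo_path,
    gaf_path,
    target: str,
    background: str | None = None,
    namespace: str = "biological_process",
    fdr_threshold: float = _enr.DEFAULT_FDR,
    n_clusters: int = AUTO_CLUSTERS,
    similarity: str = "aic",
    seed: int = 0,
    exclude_evidence=None,
    case_insensitive: bool = False,
    jitter: bool = False,
    organism: str = "",
    timestamp: bool = False,
) -> RunResult:
    """Run the full enrichment/clustering/embedding pipeline.

    ``target`` and ``background`` are raw comma- or newline-separated
    symbol strings (read files before calling). ``n_clusters`` of -1 means
    automatic eigengap selection. ``timestamp=False`` leaves the ``created``
    field empty so identical inputs give byte-identical exports.
    """
    if similarity not in _sem.MEASURES:
        raise ValueError(f"similarity must be one of {_sem.MEASURES}")
    if not (0 < fdr_threshold <= 1):
        raise ValueError(f"fdr threshold must be in (0, 1], got {fdr_threshold}")

    dag = parse_obo(obo_path, namespace)
    logger.info("ontology: %d terms in %s", len(dag), namespace)

    ann = _ann.parse_gaf(gaf_path, dag, exclude_evidence=exclude_evidence)
    logger.info(
        "annotations: %d genes, %d annotated terms",
        len(ann.universe),
        len(ann.propagated),
    )

    tgt_res = _ann.resolve_gene_set(
        target, ann, source="target", case_insensitive=case_insensitive
    )
    logger.info(
        "target: %d recognized, %d unrecognized",
        len(tgt_res.recognized),
        len(tgt_res.unrecognized),
    )
    if background is not None:
        bg_res = _ann.resolve_gene_set(
            background, ann, source="background",
            case_insensitive=case_insensitive,
        )
        bg = set(bg_res.recognized)
        logger.info(
            "background: %d recognized, %d unrecognized",
            len(bg_res.recognized),
            len(bg_res.unrecognized),
        )
    else:
        bg = set(_ann.default_background(ann))
        logger.info("background: default (all %d annotated genes)", len(bg))

    tgt = _ann.restrict_target(tgt_res.recognized, bg)

    tested = _enr.score_terms(tgt, bg, ann, dag)
    enriched = [r for r in tested if r.qvalue <= fdr_threshold]
    enriched.sort(key=lambda r: (r.qvalue, r.pvalue, r.term_id))
    logger.info(
        "enrichment: %d terms tested, %d below FDR %g",
        len(tested),
        len(enriched),
        fdr_threshold,
    )

    created = (
        _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds")
        if timestamp
        else ""
    )
    run = RunResult(
        created=created,
        namespace=namespace,
        fdr_threshold=fdr_threshold,
        similarity=similarity,
        seed=int(seed),
        n_terms_tested=len(tested),
        k=0,
        organism=organism,
    )
    if not enriched:
        return run

    terms = tuple(r.term_id for r in enriched)
    n = len(terms)

    if n == 1:
        labels: tuple[int, ...] = (0,)
        k = 1
        medoid_flags = (True,)
        coords = [(0.5, 0.5)]
    else:
        stats = _sem.term_stats(ann, dag)
        sim = _sem.similarity_matrix(terms, similarity, stats, dag)
        if n < 3:
            k = 1
            labels = tuple([0] * n)
            meds = _clu.medoids(sim, labels)
            medoid_flags = tuple(t in set(meds) for t in terms)
        else:
            if n_clusters == AUTO_CLUSTERS:
                k = _clu.eigengap_k(sim)
                logger.info("eigengap: k = %d", k)
            else:
                k = int(n_clusters)
            assign = _clu.spectral_cluster(sim, k, seed=seed)
            labels = assign.labels
            medoid_flags = assign.medoid_flags()
        emb = _lay.mds_embed(sim, seed=seed)
        if jitter:
            emb = _lay.jitter_coincident(emb, seed=seed)
        coords = [tuple(xy) for xy in emb.coords]

    run.k = k
    name_of = {t: dag.terms[t].name for t in terms}
    run.enrichments = [
        TermRecord(
            termid=r.term_id,
            name=name_of[r.term_id],
            pvalue=r.qvalue,
            pvalue_raw=r.pvalue,
            level=r.enrichment_size,
            semanticdissimilarityx=float(coords[i][0]),
            semanticdissimilarityy=float(coords[i][1]),
            cluster=int(labels[i]),
            medoid=bool(medoid_flags[i]),
            genes=r.genes,
        )
        for i, r in enumerate(enriched)
    ]
    return run
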