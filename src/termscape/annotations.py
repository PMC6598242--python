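"""GAF parsing, annotation propagation, and gene-set resolution.

Annotations read from a GAF 2.1/2.2 file are propagated up the ontology
("true-path rule"): a gene directly annotated to a term counts as annotated
to every ancestor of that term. The propagated map drives both the
contingency counts of the enrichment test and the term probabilities behind
information content.

Gene identity is the GAF object symbol (column 3), matching the
HGNC/VGNC/MOD symbol convention of typical input gene lists. Matching is
case-sensitive by default with an optional case-insensitive fallback.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio.UniProt import GOA

from .ontology import ObsoleteTermError, OntologyDAG, UnknownTermError

__all__ = [
    "AnnotationSet",
    "GeneSetResolution",
    "AnnotationError",
    "MalformedGafError",
    "EmptyAnnotationError",
    "EmptyGeneSetError",
    "parse_gaf",
    "resolve_gene_set",
    "default_background",
]

_GAF_COLUMNS = 17


class AnnotationError(Exception):
    """Base class for annotation-layer failures."""


class MalformedGafError(AnnotationError):
    """A GAF data row does not have the expected column count."""


class EmptyAnnotationError(AnnotationError):
    """No usable annotation rows remain after filtering."""


class EmptyGeneSetError(AnnotationError):
    """A required gene set resolved to zero recognized symbols."""


@dataclass
class AnnotationSet:
    """Direct and DAG-propagated gene annotations for one namespace.

    Attributes
    ----------
    direct
        gene symbol -> set of directly annotated term ids.
    propagated
        term id -> set of gene symbols annotated to the term or to any of
        its descendants.
    universe
        all annotated gene symbols (union of every propagated set).
    """

    direct: dict[str, set[str]]
    propagated: dict[str, set[str]]
    universe: frozenset[str]
    namespace: str = ""
    _folded: dict[str, str] = field(default_factory=dict, repr=False)

    def casefold_lookup(self, symbol: str) -> str | None:
        """Return the universe symbol matching ``symbol`` case-insensitively,
        or None. Ambiguous folds (two universe symbols differing only by
        case) resolve to neither."""
        if not self._folded:
            counts: dict[str, int] = {}
            for g in self.universe:
                counts[g.casefold()] = counts.get(g.casefold(), 0) + 1
            self._folded = {
                g.casefold(): g for g in self.universe if counts[g.casefold()] == 1
            }
        return self._folded.get(symbol.casefold())


@dataclass(frozen=True)
class GeneSetResolution:
    """Outcome of matching raw gene symbols against the annotated universe."""

    recognized: tuple[str, ...]
    unrecognized: tuple[str, ...]
    source: str  # "target" | "background"


def _validated_lines(handle) -> io.StringIO:
    """Check column counts of GAF data rows, returning a re-readable buffer."""
    out = []
    for lineno, line in enumerate(handle, start=1):
        stripped = line.rstrip("\n")
        if not stripped or stripped.startswith("!"):
            out.append(line)
            continue
        ncols = stripped.count("\t") + 1
        if ncols != _GAF_COLUMNS:
            raise MalformedGafError(
                f"line {lineno}: expected {_GAF_COLUMNS} tab-separated "
                f"columns, found {ncols}"
            )
        out.append(line)
    return io.StringIO("".join(out))


def parse_gaf(
    path,
    dag: OntologyDAG,
    exclude_evidence: Iterable[str] | None = None,
) -> AnnotationSet:
    """Read a GAF 2.1/2.2 file and propagate annotations up ``dag``.

    Rows are skipped when the qualifier contains ``NOT`` (alone or piped),
    when the GO term is not in ``dag``'s namespace (including obsolete
    terms), or when the evidence code is in ``exclude_evidence``.

    Raises :class:`MalformedGafError` on a bad column count and
    :class:`EmptyAnnotationError` when nothing usable remains.
    """
    excluded = frozenset(exclude_evidence or ())

    if hasattr(path, "read"):
        buf = _validated_lines(path)
    else:
        with open(Path(path), encoding="utf-8") as fh:
            buf = _validated_lines(fh)

    direct: dict[str, set[str]] = {}
    for rec in GOA.gafiterator(buf):
        qualifiers = rec.get("Qualifier", [])
        if any("NOT" in q.split("|") or q == "NOT" for q in qualifiers):
            continue
        if rec.get("Evidence", "") in excluded:
            continue
        try:
            tid = dag.resolve(rec["GO_ID"])
        except (UnknownTermError, ObsoleteTermError):
            continue  # outside this namespace (or obsolete): skip row
        gene = rec["DB_Object_Symbol"]
        direct.setdefault(gene, set()).add(tid)

    if not direct:
        raise EmptyAnnotationError(
            "no annotation rows usable in namespace " + dag.namespace
        )

    propagated: dict[str, set[str]] = {}
    for gene, tids in direct.items():
        reached: set[str] = set()
        for tid in tids:
            reached |= dag.ancestors_or_self(tid)
        for t in reached:
            propagated.setdefault(t, set()).add(gene)

    return AnnotationSet(
        direct=direct,
        propagated=propagated,
        universe=frozenset(direct),
        namespace=dag.namespace,
    )


def _split_symbols(raw: str) -> list[str]:
    parts: list[str] = []
    for chunk in raw.replace(",", "\n").splitlines():
        sym = chunk.strip()
        if sym:
            parts.append(sym)
    # de-duplicate preserving first occurrence, case preserved
    seen: set[str] = set()
    uniq = []
    for s in parts:
        if s not in seen:
            seen.add(s)
            uniq.append(s)
    return uniq


def resolve_gene_set(
    raw: str,
    ann: AnnotationSet,
    source: str = "target",
    case_insensitive: bool = False,
) -> GeneSetResolution:
    """Split a comma- or newline-separated symbol list and match it against
    the annotated universe.

    An empty or fully unrecognized *target* set is a hard error
    (:class:`EmptyGeneSetError`); a background set may legally resolve empty
    only in the sense that the caller falls back to the default background.
    """
    symbols = _split_symbols(raw)
    recognized: list[str] = []
    unrecognized: list[str] = []
    for s in symbols:
        if s in ann.universe:
            recognized.append(s)
        elif case_insensitive and (hit := ann.casefold_lookup(s)) is not None:
            recognized.append(hit)
        else:
            unrecognized.append(s)
    if source == "target" and not recognized:
        shown = ", ".join(unrecognized[:5]) or "<empty input>"
        raise EmptyGeneSetError(
            f"no target gene matched the annotated universe "
            f"(first unmatched: {shown})"
        )
    return GeneSetResolution(
        recognized=tuple(recognized),
        unrecognized=tuple(unrecognized),
        source=source,
    )


def default_background(ann: AnnotationSet) -> frozenset[str]:
    """All annotated genes — the background used when none is supplied."""
    return ann.universe


def restrict_target(
    target: Iterable[str], background: Iterable[str]
) -> tuple[str, ...]:
    """Drop target genes outside the background (with a warning)."""
    bg = set(background)
    kept = tuple(g for g in target if g in bg)
    dropped = [g for g in target if g not in bg]
    if dropped:
        warnings.warn(
            f"{len(dropped)} target gene(s) outside the background were "
            f"dropped: {', '.join(dropped[:5])}",
            stacklevel=2,
        )
    return kept
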