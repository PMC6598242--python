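"""Serialization of a complete run to JSON and CSV.

The per-term record follows the Run/Enrichment field names used by the
original web service schema: ``termid``, ``name``, ``pvalue`` (the
BH-adjusted value actually used for filtering), ``level`` (enrichment
size), ``semanticdissimilarityx`` / ``semanticdissimilarityy`` (unit-square
coordinates), ``cluster``, ``medoid`` and ``genes``. Because a single
"pvalue" field is ambiguous, the raw per-term p-value is additionally
emitted as ``pvalue_raw``.

Floats are written with %.6g formatting and fixed key order, so that
export -> load -> export is byte-identical.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "TermRecord",
    "RunResult",
    "export_json",
    "export_csv",
    "load_json",
    "CSV_HEADER",
]

CSV_HEADER = [
    "termid",
    "name",
    "pvalue",
    "pvalue_raw",
    "level",
    "semanticdissimilarityx",
    "semanticdissimilarityy",
    "cluster",
    "medoid",
    "genes",
]


def _q(v: float) -> float:
    """Quantize to 6 significant digits (idempotent)."""
    return float(f"{float(v):.6g}")


@dataclass(frozen=True)
class TermRecord:
    """Export-ready record for one enriched term."""

    termid: str
    name: str
    pvalue: float  # BH-adjusted; the filtering value
    pvalue_raw: float
    level: float  # enrichment size (observed / expected)
    semanticdissimilarityx: float
    semanticdissimilarityy: float
    cluster: int
    medoid: bool
    genes: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "termid": self.termid,
            "name": self.name,
            "pvalue": _q(self.pvalue),
            "pvalue_raw": _q(self.pvalue_raw),
            "level": _q(self.level),
            "semanticdissimilarityx": _q(self.semanticdissimilarityx),
            "semanticdissimilarityy": _q(self.semanticdissimilarityy),
            "cluster": int(self.cluster),
            "medoid": bool(self.medoid),
            "genes": list(self.genes),
        }


@dataclass
class RunResult:
    """Everything a consumer needs to render or re-analyse one run."""

    created: str  # ISO timestamp, or "" for reproducible output
    namespace: str
    fdr_threshold: float
    similarity: str  # "lin" | "aic"
    seed: int
    n_terms_tested: int
    k: int  # number of clusters (0 when nothing was enriched)
    enrichments: list[TermRecord] = field(default_factory=list)
    organism: str = ""

    def to_dict(self) -> dict:
        return {
            "created": self.created,
            "namespace": self.namespace,
            "fdr_threshold": _q(self.fdr_threshold),
            "similarity": self.similarity,
            "seed": int(self.seed),
            "n_terms_tested": int(self.n_terms_tested),
            "n_terms_enriched": len(self.enrichments),
            "k": int(self.k),
            "organism": self.organism,
            "enrichments": [r.to_dict() for r in self.enrichments],
        }

    def summary(self) -> str:
        """Human-readable recap of the run."""
        lines = [
            f"namespace        : {self.namespace}",
            f"fdr threshold    : {self.fdr_threshold:g}",
            f"similarity index : {self.similarity}",
            f"terms tested     : {self.n_terms_tested}",
            f"terms enriched   : {len(self.enrichments)}",
            f"clusters (k)     : {self.k}",
        ]
        for c in range(self.k):
            members = [r for r in self.enrichments if r.cluster == c]
            med = next(r for r in members if r.medoid)
            lines.append(
                f"  cluster {c}: {len(members)} terms; "
                f"medoid {med.termid} ({med.name})"
            )
        return "\n".join(lines)


def export_json(run: RunResult, path) -> None:
    Path(path).write_text(
        json.dumps(run.to_dict(), indent=2, ensure_ascii=False) + "\n",
        encoding="utf-8",
    )


def load_json(path) -> RunResult:
    obj = json.loads(Path(path).read_text(encoding="utf-8"))
    records = [
        TermRecord(
            termid=r["termid"],
            name=r["name"],
            pvalue=r["pvalue"],
            pvalue_raw=r["pvalue_raw"],
            level=r["level"],
            semanticdissimilarityx=r["semanticdissimilarityx"],
            semanticdissimilarityy=r["semanticdissimilarityy"],
            cluster=r["cluster"],
            medoid=r["medoid"],
            genes=tuple(r["genes"]),
        )
        for r in obj["enrichments"]
    ]
    return RunResult(
        created=obj["created"],
        namespace=obj["namespace"],
        fdr_threshold=obj["fdr_threshold"],
        similarity=obj["similarity"],
        seed=obj["seed"],
        n_terms_tested=obj["n_terms_tested"],
        k=obj["k"],
        enrichments=records,
        organism=obj.get("organism", ""),
    )


def export_csv(run: RunResult, path) -> None:
    """One RFC-4180 row per enriched term; genes joined with ';'."""
    with open(Path(path), "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_HEADER)
        for r in run.enrichments:
            d = r.to_dict()
            writer.writerow(
                [
                    d["termid"],
                    d["name"],
                    f"{d['pvalue']:.6g}",
                    f"{d['pvalue_raw']:.6g}",
                    f"{d['level']:.6g}",
                    f"{d['semanticdissimilarityx']:.6g}",
                    f"{d['semanticdissimilarityy']:.6g}",
                    d["cluster"],
                    "true" if d["medoid"] else "false",
                    ";".join(d["genes"]),
                ]
            )
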