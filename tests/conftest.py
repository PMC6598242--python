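"""Shared fixture builders: tiny hand-written OBO/GAF pairs.

The canonical hand fixture ("rcab") is the four-level family

    R <- C <- {A, B}      plus   D <- R   (D attached directly to the root)

annotated over an 8-gene universe so that |A| = |B| = |D| = 2 and |C| = 4
after propagation. Its information contents are known in closed form
(IC(C) = ln 2, IC(A) = IC(B) = 2 ln 2), giving Lin(A, B) = 0.5 exactly.
"""

from __future__ import annotations

import io

import pytest

from termscape.annotations import parse_gaf
from termscape.ontology import parse_obo

BP = "biological_process"


def mk_obo(parents: dict[str, list[str]], namespace: str = BP) -> str:
    """OBO text from a term -> parent-list mapping (is_a edges)."""
    chunks = ["format-version: 1.2\nontology: test-fixture\n"]
    for tid in sorted(parents):
        lines = [
            "[Term]",
            f"id: {tid}",
            f"name: name of {tid}",
            f"namespace: {namespace}",
        ]
        lines += [f"is_a: {p} ! parent" for p in parents[tid]]
        chunks.append("\n".join(lines) + "\n")
    return "\n".join(chunks)


def mk_gaf(direct: dict[str, list[str]], qualifier: str = "",
           evidence: str = "IEA") -> str:
    """GAF 2.1 text from a gene -> direct-term mapping."""
    rows = ["!gaf-version: 2.1"]
    for gene in sorted(direct):
        for tid in direct[gene]:
            rows.append("\t".join([
                "TST", gene, gene, qualifier, tid, "TST:1", evidence, "",
                "P", "", "", "protein", "taxon:32644", "20200101", "TST",
                "", "",
            ]))
    return "\n".join(rows) + "\n"


def load(obo_text: str, gaf_text: str, namespace: str = BP):
    dag = parse_obo(io.StringIO(obo_text), namespace)
    ann = parse_gaf(io.StringIO(gaf_text), dag)
    return dag, ann


R, C, A, B, D = (f"GO:000000{i}" for i in "12345")

RCAB_PARENTS = {R: [], C: [R], A: [C], B: [C], D: [R]}
RCAB_DIRECT = {
    "g1": [A], "g2": [A],
    "g3": [B], "g4": [B],
    "g5": [D], "g6": [D],
    "g7": [R], "g8": [R],
}


@pytest.fixture(scope="session")
def rcab():
    """(dag, ann) for the canonical hand fixture; universe of 8 genes."""
    return load(mk_obo(RCAB_PARENTS), mk_gaf(RCAB_DIRECT))


@pytest.fixture(scope="session")
def chain():
    """R <- C <- A chain with one gene on the leaf."""
    return load(
        mk_obo({R: [], C: [R], A: [C]}),
        mk_gaf({"g1": [A]}),
    )


@pytest.fixture(scope="session")
def diamond():
    """R <- {P1, P2} <- A diamond (A has two parents)."""
    p1, p2, a = "GO:0000010", "GO:0000011", "GO:0000012"
    dag = parse_obo(
        io.StringIO(mk_obo({R: [], p1: [R], p2: [R], a: [p1, p2]})), BP
    )
    return dag, (R, p1, p2, a)
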