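"""Compose head + assertion + provenance + publication-info graphs into
nanopublications, validate their structure, and read/write them as TriG or
N-Quads documents.

A nanopublication is one IRI naming four named graphs: the head (which ties
the nanopublication to its three content graphs), the assertion (the claim),
the provenance (how the claim was produced) and the publication info (who
published it, when, under what license).  Graph IRIs are the nanopublication
IRI plus fixed fragments (``#head``, ``#assertion``, ``#provenance``,
``#pubinfo``), so a whole corpus can live in one TriG file and be recovered
from its head graphs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .config import (
    NP_HAS_ASSERTION,
    NP_HAS_PROVENANCE,
    NP_HAS_PUBINFO,
    NP_NANOPUBLICATION,
    RDF_TYPE,
)
from .context_graphs import (
    ProvenanceContext,
    PublicationMeta,
    build_provenance_graph,
    build_pubinfo_graph,
)
from .errors import AssemblyError, StructureError
from .rdf_core import (
    Dialect,
    GraphBundle,
    Iri,
    Quad,
    UriPolicy,
    mint_iri,
    read_quads,
    write_quads,
)
from .templates import (
    DEGeneRecord,
    OverlapRecord,
    VocabularyConfig,
    build_de_assertion,
    build_overlap_assertion,
    nanopub_key,
)

__all__ = [
    "Nanopublication",
    "ValidationReport",
    "assemble",
    "validate",
    "build_nanopub",
    "build_corpus",
    "write_nanopub",
    "read_nanopub",
    "write_corpus",
    "read_corpus",
]


@dataclass(frozen=True)
class Nanopublication:
    nanopub_iri: Iri
    head: GraphBundle
    assertion: GraphBundle
    provenance: GraphBundle
    pubinfo: GraphBundle

    @property
    def graph_iris(self) -> dict[str, Iri]:
        """The graph IRI of each part — taken from the part's own quads when
        present, else the conventional ``#fragment`` name."""
        out: dict[str, Iri] = {}
        for part, bundle in (
            ("head", self.head),
            ("assertion", self.assertion),
            ("provenance", self.provenance),
            ("pubinfo", self.pubinfo),
        ):
            graphs = sorted(bundle.graph_iris(), key=lambda g: g.value)
            out[part] = graphs[0] if graphs else Iri(f"{self.nanopub_iri.value}#{part}")
        return out

    def bundle(self) -> GraphBundle:
        """All four graphs as one quad set."""
        return self.head.union(self.assertion, self.provenance, self.pubinfo)


@dataclass(frozen=True)
class ValidationReport:
    """Structural violations found in a nanopublication; empty means valid."""

    violations: tuple[tuple[str, str, str], ...] = ()

    @property
    def ok(self) -> bool:
        return not self.violations


def _single_graph_iri(bundle: GraphBundle, part: str) -> Iri:
    graphs = bundle.graph_iris()
    if len(graphs) != 1:
        raise AssemblyError(
            f"{part} bundle must hold exactly one named graph, found {len(graphs)}"
        )
    return next(iter(graphs))


def _head_graph(np_iri: Iri, parts: dict[str, Iri]) -> GraphBundle:
    g = parts["head"]
    return GraphBundle(
        [
            Quad(np_iri, RDF_TYPE, NP_NANOPUBLICATION, g),
            Quad(np_iri, NP_HAS_ASSERTION, parts["assertion"], g),
            Quad(np_iri, NP_HAS_PROVENANCE, parts["provenance"], g),
            Quad(np_iri, NP_HAS_PUBINFO, parts["pubinfo"], g),
        ]
    )


def assemble(
    assertion: GraphBundle,
    provenance: GraphBundle,
    pubinfo: GraphBundle,
    policy: UriPolicy,
    key: str,
) -> Nanopublication:
    """Re-home three single-graph bundles under a freshly minted
    nanopublication IRI and build the head graph.

    Graph contexts are renamed to the nanopublication's fragment scheme, and
    references to the old graph IRIs (e.g. the provenance statements about
    the assertion graph) are rewritten along with them.  If the pubinfo
    graph is about a single placeholder subject, that subject is rewritten
    to the nanopublication IRI.
    """
    if len(assertion) == 0:
        raise AssemblyError("assertion graph must be non-empty")
    if len(provenance) == 0 or len(pubinfo) == 0:
        raise AssemblyError("provenance and pubinfo graphs must be non-empty")
    np_iri = mint_iri(policy, "nanopub", key)
    parts = {p: mint_iri(policy, p, key) for p in ("head", "assertion", "provenance", "pubinfo")}
    remap = {
        _single_graph_iri(assertion, "assertion"): parts["assertion"],
        _single_graph_iri(provenance, "provenance"): parts["provenance"],
        _single_graph_iri(pubinfo, "pubinfo"): parts["pubinfo"],
    }
    pub_subjects = {q.subject for q in pubinfo.quads}
    if len(pub_subjects) == 1 and (subj := next(iter(pub_subjects))) != np_iri:
        remap[subj] = np_iri
    return Nanopublication(
        nanopub_iri=np_iri,
        head=_head_graph(np_iri, parts),
        assertion=assertion.with_graph_iri(remap),
        provenance=provenance.with_graph_iri(remap),
        pubinfo=pubinfo.with_graph_iri(remap),
    )


def validate(np: Nanopublication) -> ValidationReport:
    """Check the structural invariants; returns a report, never raises."""
    v: list[tuple[str, str, str]] = []
    parts = np.graph_iris
    iris = set(parts.values())
    if len(iris) != 4:
        v.append(("GRAPH_IRIS_NOT_DISTINCT", "the four graph IRIs must be distinct", np.nanopub_iri.value))
    for part, bundle in (
        ("head", np.head),
        ("assertion", np.assertion),
        ("provenance", np.provenance),
        ("pubinfo", np.pubinfo),
    ):
        wrong = {q.graph for q in bundle.quads} - {parts[part]}
        for g in sorted(w.value for w in wrong):
            v.append(("GRAPH_CONTEXT_MISMATCH", f"{part} quad in foreign graph", g))
    expected_head = _head_graph(np.nanopub_iri, parts)
    if np.head != expected_head:
        missing = expected_head.quads - np.head.quads
        extra = np.head.quads - expected_head.quads
        for q in missing:
            v.append(("HEAD_MISSING_STATEMENT", f"head lacks {q.predicate.value}", np.nanopub_iri.value))
        for q in extra:
            v.append(("HEAD_EXTRA_STATEMENT", f"unexpected head statement {q.predicate.value}", q.subject.value))
    if len(np.assertion) == 0:
        v.append(("ASSERTION_EMPTY", "assertion graph is empty", parts["assertion"].value))
    prov_nodes = {q.subject for q in np.provenance.quads} | {
        q.object for q in np.provenance.quads if isinstance(q.object, Iri)
    }
    if parts["assertion"] not in prov_nodes:
        v.append(
            ("PROV_NO_ASSERTION_LINK", "provenance never mentions the assertion graph", parts["provenance"].value)
        )
    pub_nodes = {q.subject for q in np.pubinfo.quads} | {
        q.object for q in np.pubinfo.quads if isinstance(q.object, Iri)
    }
    if np.nanopub_iri not in pub_nodes:
        v.append(
            ("PUBINFO_NO_NANOPUB_REF", "pubinfo never mentions the nanopublication", parts["pubinfo"].value)
        )
    return ValidationReport(tuple(v))


def build_nanopub(
    rec: DEGeneRecord | OverlapRecord,
    vocab: VocabularyConfig,
    policy: UriPolicy,
    ctx: ProvenanceContext,
    meta: PublicationMeta,
) -> Nanopublication:
    """One-call pipeline: record → assertion + contexts → nanopublication."""
    key = nanopub_key(rec)
    np_iri = mint_iri(policy, "nanopub", key)
    parts = {p: mint_iri(policy, p, key) for p in ("head", "assertion", "provenance", "pubinfo")}
    if isinstance(rec, DEGeneRecord):
        assertion = build_de_assertion(rec, vocab, policy, graph_iri=parts["assertion"])
    else:
        assertion = build_overlap_assertion(rec, vocab, policy, graph_iri=parts["assertion"])
    provenance = build_provenance_graph(
        parts["assertion"], ctx, policy, graph_iri=parts["provenance"]
    )
    pubinfo = build_pubinfo_graph(np_iri, meta, graph_iri=parts["pubinfo"])
    return Nanopublication(
        nanopub_iri=np_iri,
        head=_head_graph(np_iri, parts),
        assertion=assertion,
        provenance=provenance,
        pubinfo=pubinfo,
    )


def build_corpus(
    de_records: Sequence[DEGeneRecord],
    overlap_records: Sequence[OverlapRecord],
    vocab: VocabularyConfig,
    policy: UriPolicy,
    ctx: ProvenanceContext,
    meta: PublicationMeta,
) -> list[Nanopublication]:
    """One nanopublication per result-table row (N de rows + M overlap rows)."""
    return [
        build_nanopub(rec, vocab, policy, ctx, meta)
        for rec in (*de_records, *overlap_records)
    ]


# ---------------------------------------------------------------------------
# serialization


def write_nanopub(np: Nanopublication, path: str | Path, dialect: Dialect = "trig") -> None:
    Path(path).write_text(write_quads(np.bundle(), dialect), encoding="utf-8")


def write_corpus(
    nps: Iterable[Nanopublication], path: str | Path, dialect: Dialect = "trig"
) -> None:
    bundle = GraphBundle()
    bundle = bundle.union(*(np.bundle() for np in nps))
    Path(path).write_text(write_quads(bundle, dialect), encoding="utf-8")


def nanopubs_from_bundle(bundle: GraphBundle, strict: bool = False) -> list[Nanopublication]:
    """Recover nanopublications from a mixed quad set via their head graphs.

    With ``strict`` set, quads outside any recovered nanopublication raise a
    :class:`StructureError`; otherwise they are ignored (a corpus file may
    cohabit with fixture graphs).
    """
    heads = [
        q for q in bundle.quads if q.predicate == RDF_TYPE and q.object == NP_NANOPUBLICATION
    ]
    nps: list[Nanopublication] = []
    claimed: set[Iri] = set()
    for head_q in sorted(heads, key=lambda q: q.subject.value):
        np_iri = head_q.subject
        head_graph = bundle.graph(head_q.graph)
        links = {}
        for pred, part in (
            (NP_HAS_ASSERTION, "assertion"),
            (NP_HAS_PROVENANCE, "provenance"),
            (NP_HAS_PUBINFO, "pubinfo"),
        ):
            objs = [
                q.object
                for q in head_graph.quads
                if q.subject == np_iri and q.predicate == pred and isinstance(q.object, Iri)
            ]
            if len(objs) != 1:
                raise StructureError(
                    f"head of {np_iri.value} must link exactly one {part} graph"
                )
            links[part] = objs[0]
        nps.append(
            Nanopublication(
                nanopub_iri=np_iri,
                head=head_graph,
                assertion=bundle.graph(links["assertion"]),
                provenance=bundle.graph(links["provenance"]),
                pubinfo=bundle.graph(links["pubinfo"]),
            )
        )
        claimed.add(head_q.graph)
        claimed.update(links.values())
    if strict:
        stray = bundle.graph_iris() - claimed
        if stray:
            raise StructureError(
                f"{len(stray)} graph(s) do not belong to any nanopublication: "
                + ", ".join(sorted(g.value for g in stray)[:3])
            )
    return nps


def read_corpus(path: str | Path, dialect: Dialect = "trig") -> list[Nanopublication]:
    bundle = read_quads(Path(path).read_text(encoding="utf-8"), dialect)
    return nanopubs_from_bundle(bundle)


def read_nanopub(path: str | Path, dialect: Dialect = "trig") -> Nanopublication:
    """Read a file holding exactly one nanopublication (four named graphs)."""
    bundle = read_quads(Path(path).read_text(encoding="utf-8"), dialect)
    n_graphs = len(bundle.graph_iris())
    if n_graphs != 4:
        raise StructureError(f"expected exactly 4 named graphs, found {n_graphs}")
    nps = nanopubs_from_bundle(bundle, strict=True)
    if len(nps) != 1:
        raise StructureError(f"expected exactly 1 nanopublication, found {len(nps)}")
    return nps[0]
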