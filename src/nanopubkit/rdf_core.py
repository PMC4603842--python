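"""Minimal RDF quad model with deterministic IRI minting.

The package represents every graph as an immutable set of quads whose nodes
are IRIs or literals — blank nodes are deliberately banned.  Every node that
a nanopublication itself introduces (association hubs, promoters, regions,
the named graphs) is minted a stable skolem IRI from a ``(kind, key)`` pair,
so that two runs over the same input produce byte-identical documents and
graph equality is plain set equality.

Serialization goes through :mod:`rdflib`; N-Quads output is line-sorted so
that documents diff stably.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Literal as TLiteral, Mapping
from urllib.parse import quote

import rdflib
from rdflib import Dataset, URIRef
from rdflib.term import BNode, Literal as RdfLiteral

from .errors import InvalidArgumentError, ParseError, ResolutionError

__all__ = [
    "Iri",
    "LiteralValue",
    "Quad",
    "GraphBundle",
    "UriPolicy",
    "MINT_KINDS",
    "GRAPH_PART_KINDS",
    "mint_iri",
    "resolve_curie",
    "write_quads",
    "read_quads",
    "XSD_STRING",
]

# An absolute IRI: a scheme followed by a non-empty remainder, no whitespace
# or angle brackets anywhere.
_ABSOLUTE_IRI = re.compile(r"^[A-Za-z][A-Za-z0-9+.\-]*:[^\s<>\"{}|\\^`]+$")

XSD_STRING = "http://www.w3.org/2001/XMLSchema#string"


@dataclass(frozen=True, slots=True)
class Iri:
    """An absolute IRI (e.g. ``http://bio2rdf.org/geneid:25``)."""

    value: str

    def __post_init__(self) -> None:
        if not _ABSOLUTE_IRI.match(self.value):
            raise InvalidArgumentError(f"not an absolute IRI: {self.value!r}")

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True, slots=True)
class LiteralValue:
    """An RDF literal: lexical form plus an optional datatype or language tag.

    A datatype of ``xsd:string`` is normalized away, matching RDF 1.1 where a
    simple literal and an ``xsd:string`` literal are the same term.
    """

    lexical: str
    datatype: Iri | None = None
    language: str | None = None

    def __post_init__(self) -> None:
        if self.datatype is not None and self.language is not None:
            raise InvalidArgumentError("literal cannot carry both datatype and language")
        if self.language is not None and not re.match(
            r"^[A-Za-z]{1,8}(-[A-Za-z0-9]{1,8})*$", self.language
        ):
            raise InvalidArgumentError(f"bad language tag: {self.language!r}")
        if self.datatype is not None and self.datatype.value == XSD_STRING:
            object.__setattr__(self, "datatype", None)


Node = Iri | LiteralValue


@dataclass(frozen=True, slots=True)
class Quad:
    """One RDF statement within a named graph.  No blank nodes anywhere."""

    subject: Iri
    predicate: Iri
    object: Node
    graph: Iri


class GraphBundle:
    """An immutable keyed collection of named graphs (a set of quads).

    Equality is set equality of the quads; the prefix map only affects how
    TriG output abbreviates IRIs.
    """

    __slots__ = ("quads", "prefix_map")

    def __init__(
        self,
        quads: Iterable[Quad] = (),
        prefix_map: Mapping[str, Iri] | None = None,
    ):
        self.quads: frozenset[Quad] = frozenset(quads)
        self.prefix_map: dict[str, Iri] = dict(prefix_map or {})

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GraphBundle):
            return NotImplemented
        return self.quads == other.quads

    def __hash__(self) -> int:
        return hash(self.quads)

    def __len__(self) -> int:
        return len(self.quads)

    def __iter__(self) -> Iterator[Quad]:
        return iter(self.quads)

    def __repr__(self) -> str:
        return f"GraphBundle({len(self.quads)} quads, {len(self.graph_iris())} graphs)"

    def graph_iris(self) -> set[Iri]:
        return {q.graph for q in self.quads}

    def graph(self, graph_iri: Iri) -> "GraphBundle":
        """The sub-bundle holding only the quads of one named graph."""
        return GraphBundle(
            (q for q in self.quads if q.graph == graph_iri), self.prefix_map
        )

    def union(self, *others: "GraphBundle") -> "GraphBundle":
        quads = set(self.quads)
        prefixes = dict(self.prefix_map)
        for other in others:
            quads.update(other.quads)
            prefixes.update(other.prefix_map)
        return GraphBundle(quads, prefixes)

    def with_graph_iri(self, mapping: Mapping[Iri, Iri]) -> "GraphBundle":
        """Rename graph contexts and rewrite node occurrences of the old IRIs.

        Used by the assembler to re-home independently built graphs under a
        nanopublication's own graph names while keeping cross-graph references
        (e.g. provenance statements about the assertion graph) intact.
        """

        def node(n: Node) -> Node:
            return mapping.get(n, n) if isinstance(n, Iri) else n

        return GraphBundle(
            (
                Quad(
                    mapping.get(q.subject, q.subject),
                    mapping.get(q.predicate, q.predicate),
                    node(q.object),
                    mapping.get(q.graph, q.graph),
                )
                for q in self.quads
            ),
            self.prefix_map,
        )


MINT_KINDS = {
    "nanopub",
    "head",
    "assertion",
    "provenance",
    "pubinfo",
    "association",
    "promoter",
    "region",
    "entity",
}

#: Kinds minted as fragments of the owning nanopublication IRI.
GRAPH_PART_KINDS = ("head", "assertion", "provenance", "pubinfo")

_DEFAULT_FRAGMENTS = {k: k for k in GRAPH_PART_KINDS}


@dataclass(frozen=True)
class UriPolicy:
    """Deterministic IRI minting policy.

    ``slug`` minting appends the percent-encoded key (under a ``kind/``
    segment for non-nanopub kinds); ``content-hash`` minting appends the
    SHA-256 hex digest of the key instead, for opaque stable identifiers.
    Graph-part kinds (head/assertion/provenance/pubinfo) are fragments of the
    nanopublication IRI minted from the same key.
    """

    base_namespace: Iri
    strategy: TLiteral["slug", "content-hash"] = "slug"
    fragment_labels: Mapping[str, str] = field(
        default_factory=lambda: dict(_DEFAULT_FRAGMENTS)
    )

    def mint(self, kind: str, key: str) -> Iri:
        return mint_iri(self, kind, key)


def _encode_key(policy: UriPolicy, key: str) -> str:
    if policy.strategy == "content-hash":
        return hashlib.sha256(key.encode("utf-8")).hexdigest()
    return quote(key, safe="-._~")


def mint_iri(policy: UriPolicy, kind: str, key: str) -> Iri:
    """Mint a stable IRI for a node of the given kind.

    Injective over distinct ``(kind, key)`` pairs under both strategies and
    idempotent: the same call always returns the same IRI.
    """
    if not key:
        raise InvalidArgumentError("mint_iri: key must be non-empty")
    if kind not in MINT_KINDS:
        raise InvalidArgumentError(f"mint_iri: unknown kind {kind!r}")
    base = policy.base_namespace.value
    if kind in GRAPH_PART_KINDS:
        fragment = policy.fragment_labels.get(kind, kind)
        return Iri(f"{base}{_encode_key(policy, key)}#{fragment}")
    if kind == "nanopub":
        return Iri(f"{base}{_encode_key(policy, key)}")
    return Iri(f"{base}{kind}/{_encode_key(policy, key)}")


def resolve_curie(curie: str, prefix_map: Mapping[str, Iri]) -> Iri:
    """Expand a compact IRI like ``so:SO_0001411`` against a prefix map."""
    prefix, sep, local = curie.partition(":")
    if not sep:
        raise ResolutionError(f"not a CURIE (no colon): {curie!r}")
    if prefix not in prefix_map:
        raise ResolutionError(f"unknown CURIE prefix: {prefix!r}")
    return Iri(prefix_map[prefix].value + local)


# ---------------------------------------------------------------------------
# rdflib bridge and serialization


def _to_rdflib_node(n: Node):
    if isinstance(n, Iri):
        return URIRef(n.value)
    if n.language is not None:
        return RdfLiteral(n.lexical, lang=n.language)
    if n.datatype is not None:
        return RdfLiteral(n.lexical, datatype=URIRef(n.datatype.value))
    return RdfLiteral(n.lexical)


def _from_rdflib_node(n) -> Node:
    if isinstance(n, BNode):
        raise ParseError(f"blank node {n!r} encountered; blank nodes are not supported")
    if isinstance(n, URIRef):
        return Iri(str(n))
    lit: RdfLiteral = n
    if lit.language:
        return LiteralValue(str(lit), language=lit.language)
    if lit.datatype:
        return LiteralValue(str(lit), datatype=Iri(str(lit.datatype)))
    return LiteralValue(str(lit))


def to_dataset(bundle: GraphBundle) -> Dataset:
    """Materialize a bundle as an rdflib :class:`~rdflib.Dataset`."""
    ds = Dataset(default_union=True)
    for prefix, ns in bundle.prefix_map.items():
        ds.bind(prefix, ns.value, override=True)
    for q in bundle.quads:
        ds.graph(URIRef(q.graph.value)).add(
            (
                URIRef(q.subject.value),
                URIRef(q.predicate.value),
                _to_rdflib_node(q.object),
            )
        )
    return ds


def from_dataset(ds: Dataset, prefix_map: Mapping[str, Iri] | None = None) -> GraphBundle:
    quads = []
    for s, p, o, g in ds.quads((None, None, None, None)):
        if g is None or isinstance(g, BNode):
            raise ParseError("quad without a named graph context")
        subj = _from_rdflib_node(s)
        pred = _from_rdflib_node(p)
        if not isinstance(subj, Iri) or not isinstance(pred, Iri):
            raise ParseError("subject/predicate must be IRIs")
        quads.append(Quad(subj, pred, _from_rdflib_node(o), Iri(str(g))))
    prefixes = dict(prefix_map or {})
    for prefix, ns in ds.namespaces():
        prefixes.setdefault(prefix, Iri(str(ns)))
    return GraphBundle(quads, prefixes)


def _error_line(exc: Exception, text: str) -> int | None:
    """Best-effort line number for a parser exception: an explicit attribute
    or message field when present, else locating the quoted offending line."""
    line = getattr(exc, "lines", None)
    if isinstance(line, int):
        return line
    m = re.search(r"line[:\s]+(\d+)", str(exc), re.IGNORECASE)
    if m:
        return int(m.group(1))
    m = re.search(r"'([^']+)'", str(exc))
    if m:
        for i, content in enumerate(text.splitlines(), start=1):
            if m.group(1).strip() and m.group(1).strip() in content:
                return i
    return None


Dialect = TLiteral["trig", "nquads", "turtle"]

_FORMATS = {"trig": "trig", "nquads": "nquads", "turtle": "turtle"}

#: Graph IRI assigned to triples read from context-free Turtle documents.
TURTLE_GRAPH = Iri("urn:x-nanopubkit:default-graph")


def write_quads(bundle: GraphBundle, dialect: Dialect = "trig") -> str:
    """Serialize a bundle; ``nquads`` output is line-sorted for stable diffs."""
    if dialect not in _FORMATS:
        raise InvalidArgumentError(f"unknown dialect: {dialect!r}")
    ds = to_dataset(bundle)
    if dialect == "turtle":
        graphs = bundle.graph_iris()
        if len(graphs) > 1:
            raise InvalidArgumentError("turtle cannot carry more than one graph")
        text = ds.serialize(format="turtle")
        return text
    text = ds.serialize(format=_FORMATS[dialect])
    if dialect == "nquads":
        lines = sorted(line for line in text.splitlines() if line.strip())
        return "\n".join(lines) + ("\n" if lines else "")
    return text


def read_quads(
    text: str,
    dialect: Dialect = "trig",
    prefix_map: Mapping[str, Iri] | None = None,
    graph_iri: Iri = TURTLE_GRAPH,
) -> GraphBundle:
    """Parse a TriG/N-Quads document (or Turtle, homed into ``graph_iri``)."""
    if dialect not in _FORMATS:
        raise InvalidArgumentError(f"unknown dialect: {dialect!r}")
    ds = Dataset(default_union=True)
    try:
        if dialect == "turtle":
            ds.graph(URIRef(graph_iri.value)).parse(data=text, format="turtle")
        else:
            ds.parse(data=text, format=_FORMATS[dialect])
    except Exception as exc:  # rdflib raises several parser exception types
        raise ParseError(
            f"cannot parse {dialect}: {exc}", line=_error_line(exc, text)
        ) from exc
    return from_dataset(ds, prefix_map)
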