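"""Provenance and publication-info graphs.

The provenance graph records, in PROV-O, how the assertion came to be: the
workflow activity that generated it, the input entities the activity used,
the output entities it produced, and the agent responsible.  Each local
entity can additionally be linked to its counterpart inside a Research
Object — the aggregation bundling the workflow, its data and its execution
traces — so the nanopublication's provenance acts as a lightweight proxy for
the full Research Object and many nanopublications can point at one RO.

The publication-info graph carries the citation metadata of the
nanopublication itself: authors (as researcher-id IRIs), contributors,
creation time, version and license.  Every triple in it is about the
nanopublication IRI.

PROV-O prints no predicate for the nanopub→RO cross-links, so the defaults
(``prov:alternateOf`` for entity↔RO-entity, ``ore:isAggregatedBy`` for
activity→RO) are package conventions and both are configurable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path

from .config import (
    DCT_CONTRIBUTOR,
    DCT_CREATED,
    DCT_CREATOR,
    DCT_HAS_VERSION,
    DCT_LICENSE,
    ORE_AGGREGATES,
    ORE_IS_AGGREGATED_BY,
    PROV_ACTIVITY,
    PROV_AGENT,
    PROV_ALTERNATE_OF,
    PROV_ENDED_AT_TIME,
    PROV_ENTITY,
    PROV_USED,
    PROV_WAS_ASSOCIATED_WITH,
    PROV_WAS_DERIVED_FROM,
    PROV_WAS_GENERATED_BY,
    RDF_TYPE,
    XSD_DATETIME,
)
from .errors import ParseError, ValidationError
from .rdf_core import GraphBundle, Iri, LiteralValue, Quad, UriPolicy, mint_iri

__all__ = [
    "EntityLink",
    "ProvenanceContext",
    "PublicationMeta",
    "build_provenance_graph",
    "build_pubinfo_graph",
    "read_ro_manifest",
    "write_ro_manifest",
    "load_publication_meta",
]


@dataclass(frozen=True)
class EntityLink:
    """A workflow input or output, optionally mapped to its RO counterpart."""

    local_iri: Iri
    ro_iri: Iri | None = None
    role: str | None = None
    type_iri: Iri | None = None  # optional domain process-ontology class


def _check_timestamp(value: str) -> str:
    try:
        datetime.fromisoformat(value.replace("Z", "+00:00"))
    except ValueError:
        raise ValidationError(f"not an ISO-8601 timestamp: {value!r}") from None
    return value


@dataclass(frozen=True)
class ProvenanceContext:
    """The workflow-run description shared by a batch of nanopublications."""

    workflow_activity_iri: Iri
    research_object_iri: Iri | None = None
    inputs: tuple[EntityLink, ...] = ()
    outputs: tuple[EntityLink, ...] = ()
    agent_iri: Iri | None = None
    execution_time: str | None = None
    ro_link_predicate: Iri = PROV_ALTERNATE_OF
    activity_ro_predicate: Iri = ORE_IS_AGGREGATED_BY

    def __post_init__(self) -> None:
        if self.execution_time is not None:
            _check_timestamp(self.execution_time)
        for ent in (*self.inputs, *self.outputs):
            if not isinstance(ent, EntityLink):
                raise ValidationError("inputs/outputs must be EntityLink instances")


@dataclass(frozen=True)
class PublicationMeta:
    authors: tuple[Iri, ...]
    created: str
    license_iri: Iri
    contributors: tuple[Iri, ...] = ()
    version: str = "1.0"

    def __post_init__(self) -> None:
        if not self.authors:
            raise ValidationError("publication metadata needs at least one author")
        _check_timestamp(self.created)


def build_provenance_graph(
    assertion_graph_iri: Iri,
    ctx: ProvenanceContext,
    policy: UriPolicy,
    graph_iri: Iri | None = None,
    key: str | None = None,
) -> GraphBundle:
    """The PROV-O provenance graph for one assertion graph.

    States that the assertion graph was generated by the workflow activity,
    which used the inputs and generated the outputs the assertion derives
    from; attaches agent, timestamp and Research-Object cross-links.
    Provenance is always about the assertion *graph*, never about individual
    assertion triples.
    """
    if not isinstance(ctx.workflow_activity_iri, Iri):
        raise ValidationError("ProvenanceContext needs a workflow activity IRI")
    g = graph_iri or mint_iri(policy, "provenance", key or assertion_graph_iri.value)
    act = ctx.workflow_activity_iri
    quads: list[Quad] = [
        Quad(assertion_graph_iri, PROV_WAS_GENERATED_BY, act, g),
        Quad(act, RDF_TYPE, PROV_ACTIVITY, g),
    ]
    for ent in ctx.inputs:
        quads.append(Quad(act, PROV_USED, ent.local_iri, g))
    for ent in ctx.outputs:
        quads.append(Quad(ent.local_iri, PROV_WAS_GENERATED_BY, act, g))
        quads.append(Quad(assertion_graph_iri, PROV_WAS_DERIVED_FROM, ent.local_iri, g))
    for ent in (*ctx.inputs, *ctx.outputs):
        quads.append(Quad(ent.local_iri, RDF_TYPE, PROV_ENTITY, g))
        if ent.type_iri is not None:
            quads.append(Quad(ent.local_iri, RDF_TYPE, ent.type_iri, g))
        if ent.ro_iri is not None:
            quads.append(Quad(ent.local_iri, ctx.ro_link_predicate, ent.ro_iri, g))
    if ctx.research_object_iri is not None:
        quads.append(Quad(act, ctx.activity_ro_predicate, ctx.research_object_iri, g))
    if ctx.agent_iri is not None:
        quads.append(Quad(act, PROV_WAS_ASSOCIATED_WITH, ctx.agent_iri, g))
        quads.append(Quad(ctx.agent_iri, RDF_TYPE, PROV_AGENT, g))
    if ctx.execution_time is not None:
        quads.append(
            Quad(
                act,
                PROV_ENDED_AT_TIME,
                LiteralValue(ctx.execution_time, datatype=XSD_DATETIME),
                g,
            )
        )
    return GraphBundle(quads)


def build_pubinfo_graph(
    nanopub_iri: Iri,
    meta: PublicationMeta,
    graph_iri: Iri | None = None,
    policy: UriPolicy | None = None,
) -> GraphBundle:
    """Citation metadata; every triple's subject is the nanopublication IRI."""
    if graph_iri is None:
        if policy is None:
            raise ValidationError("build_pubinfo_graph needs graph_iri or policy")
        graph_iri = mint_iri(policy, "pubinfo", nanopub_iri.value)
    g = graph_iri
    quads: list[Quad] = [
        Quad(nanopub_iri, DCT_CREATED, LiteralValue(meta.created, datatype=XSD_DATETIME), g),
        Quad(nanopub_iri, DCT_HAS_VERSION, LiteralValue(meta.version), g),
        Quad(nanopub_iri, DCT_LICENSE, meta.license_iri, g),
    ]
    for author in meta.authors:
        quads.append(Quad(nanopub_iri, DCT_CREATOR, author, g))
    for contributor in meta.contributors:
        quads.append(Quad(nanopub_iri, DCT_CONTRIBUTOR, contributor, g))
    return GraphBundle(quads)


def read_ro_manifest(path: str | Path) -> ProvenanceContext:
    """Read a minimal Research-Object manifest.

    JSON form: ``{"ro_iri": ..., "activity_iri": ..., "aggregates": [...]}``.
    An RDF (Turtle) manifest with ``ore:aggregates`` statements is also
    accepted.  Aggregated resources become candidate input entities with
    both local and RO IRIs equal (callers refine the split and roles).
    """
    path = Path(path)
    if path.suffix in (".ttl", ".rdf", ".nt"):
        from .rdf_core import read_quads

        bundle = read_quads(path.read_text(encoding="utf-8"), "turtle")
        ro_iris = {q.subject for q in bundle.quads if q.predicate == ORE_AGGREGATES}
        if len(ro_iris) != 1:
            raise ParseError(f"{path}: expected exactly one aggregating RO resource")
        ro = next(iter(ro_iris))
        entities = tuple(
            EntityLink(local_iri=q.object, ro_iri=q.object)
            for q in sorted(
                (q for q in bundle.quads if q.predicate == ORE_AGGREGATES),
                key=lambda q: q.object.value if isinstance(q.object, Iri) else "",
            )
            if isinstance(q.object, Iri)
        )
        return ProvenanceContext(
            workflow_activity_iri=Iri(ro.value.rstrip("/") + "#activity"),
            research_object_iri=ro,
            inputs=entities,
        )
    try:
        data = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: malformed manifest: {exc}", line=exc.lineno) from exc
    if not isinstance(data, dict) or "ro_iri" not in data:
        raise ParseError(f"{path}: manifest must be an object with an 'ro_iri' key")
    ro = Iri(data["ro_iri"])
    activity = Iri(data.get("activity_iri", ro.value.rstrip("/") + "#activity"))
    entities = tuple(
        EntityLink(local_iri=Iri(iri), ro_iri=Iri(iri))
        for iri in data.get("aggregates", [])
    )
    return ProvenanceContext(
        workflow_activity_iri=activity,
        research_object_iri=ro,
        inputs=entities,
        agent_iri=Iri(data["agent_iri"]) if data.get("agent_iri") else None,
        execution_time=data.get("execution_time"),
    )


def load_publication_meta(path: str | Path) -> PublicationMeta:
    """Load author metadata from a YAML file with keys ``authors``,
    ``contributors``, ``created``, ``version`` and ``license``."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(raw, dict):
        raise ParseError(f"{path}: metadata file must hold a mapping")
    return PublicationMeta(
        authors=tuple(Iri(a) for a in raw.get("authors", [])),
        contributors=tuple(Iri(c) for c in raw.get("contributors", [])),
        created=raw["created"],
        version=str(raw.get("version", "1.0")),
        license_iri=Iri(raw["license"]),
    )


def write_ro_manifest(ctx: ProvenanceContext, path: str | Path) -> None:
    """Write the JSON manifest form of a provenance context (round-trips with
    :func:`read_ro_manifest` for the RO IRI and aggregated entity set)."""
    data: dict = {
        "ro_iri": ctx.research_object_iri.value if ctx.research_object_iri else None,
        "activity_iri": ctx.workflow_activity_iri.value,
        "aggregates": [e.local_iri.value for e in (*ctx.inputs, *ctx.outputs)],
    }
    if ctx.agent_iri:
        data["agent_iri"] = ctx.agent_iri.value
    if ctx.execution_time:
        data["execution_time"] = ctx.execution_time
    Path(path).write_text(json.dumps(data, indent=2) + "\n", encoding="utf-8")
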