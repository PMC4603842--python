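"""Sequence Ontology extension for chromatin regions and chromatin states.

Chromatin-state calls (active/weak/poised promoter, heterochromatic — the
histone-mark-derived segmentations of the human genome) have no classes in
the public ontologies, so the package ships a small extension: a
``chromatin_region`` class under SO ``biological_region`` (SO_0001411), a
``chromatin_state`` class under SO ``feature_attribute`` (SO_0000733), the
four state classes under ``chromatin_state``, and a ``has_state`` object
property linking a chromatin region to its state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

from .config import (
    OBO,
    OWL_CLASS,
    OWL_OBJECT_PROPERTY,
    RDFS_DOMAIN,
    RDFS_LABEL,
    RDFS_RANGE,
    RDFS_SUBCLASSOF,
    RDF_TYPE,
    SKOS_DEFINITION,
    RunConfig,
)
from .rdf_core import GraphBundle, Iri, LiteralValue, Quad

__all__ = [
    "ChromatinStateKind",
    "ClassDef",
    "EXTENSION_CLASSES",
    "build_extension_ontology",
    "subclass_descendants",
    "extension_graph_iri",
]


class ChromatinStateKind(str, Enum):
    """The four chromatin states a promoter region can be annotated with."""

    ACTIVE_PROMOTER = "active_promoter"
    WEAK_PROMOTER = "weak_promoter"
    POISED_PROMOTER = "poised_promoter"
    HETEROCHROMATIC = "heterochromatic"


@dataclass(frozen=True)
class ClassDef:
    curie: str
    label: str
    definition: str
    parent_curie: str


SO_BIOLOGICAL_REGION = Iri(OBO + "SO_0001411")
SO_FEATURE_ATTRIBUTE = Iri(OBO + "SO_0000733")

# The six extension classes with their textual definitions.  (The source
# table's URI column contains a one-off "chromantin_state" misspelling; the
# consistent "chromatin_state" spelling is used throughout.)
EXTENSION_CLASSES: tuple[ClassDef, ...] = (
    ClassDef(
        "biosemantics:chromatin_region",
        "chromatin_region",
        "A region of chromatin, likely to be involved in a biological process",
        "so:SO_0001411",
    ),
    ClassDef(
        "biosemantics:chromatin_state",
        "chromatin_state",
        "Annotation of chromatin states, defined by combinations of chromatin "
        "modification patterns (described in publication by Ernst et al. "
        "Nature, 2011)",
        "so:SO_0000733",
    ),
    ClassDef(
        "biosemantics:active_promoter",
        "active_promoter",
        "Open chromatin region, associated with promoters, transcriptionally "
        "active, defined by the most highly observed chromatin marks : "
        "H3K4me2, H3K4me3, H3K27ac, H3K9ac",
        "biosemantics:chromatin_state",
    ),
    ClassDef(
        "biosemantics:weak_promoter",
        "weak_promoter",
        "Open chromatin region, associated with promoters, weak transcription "
        "activity, defined by the most highly observed chromatin marks : "
        "H3K4me1, H3K4me2, H3K4me3, H3K9ac",
        "biosemantics:chromatin_state",
    ),
    ClassDef(
        "biosemantics:poised_promoter",
        "poised_promoter",
        "Open chromatin region, associated with promoters, described as a "
        "bivalent domain that has strong signals of both active and inactive "
        "histone marks. Most highly observed histone marks: H3K27me3, "
        "H3K4me2, H3K4me3",
        "biosemantics:chromatin_state",
    ),
    ClassDef(
        "biosemantics:heterochromatic",
        "heterochromatic",
        "Closed chromatin formation, transcriptionally inactive. It is "
        "associated with none histone marks",
        "biosemantics:chromatin_state",
    ),
)


def extension_graph_iri(config: RunConfig) -> Iri:
    return Iri(config.biosemantics_namespace.value + "ontology")


def chromatin_region_class(config: RunConfig) -> Iri:
    return Iri(config.biosemantics_namespace.value + "chromatin_region")


def chromatin_state_class(config: RunConfig, kind: ChromatinStateKind | None = None) -> Iri:
    local = kind.value if kind is not None else "chromatin_state"
    return Iri(config.biosemantics_namespace.value + local)


def has_state_property(config: RunConfig) -> Iri:
    return Iri(config.biosemantics_namespace.value + "has_state")


def build_extension_ontology(config: RunConfig) -> GraphBundle:
    """Emit the extension as one named graph: 6 classes + ``has_state``.

    Each class is declared ``owl:Class`` with a label, a ``skos:definition``
    annotation and its single superclass link.  ``has_state`` is declared
    with domain ``chromatin_region`` (the only chromatin-typed class in the
    extension) and range ``chromatin_state``.
    """
    g = extension_graph_iri(config)
    ns = config.biosemantics_namespace.value
    quads: list[Quad] = []

    def expand(curie: str) -> Iri:
        prefix, _, local = curie.partition(":")
        if prefix == "biosemantics":
            return Iri(ns + local)
        return Iri(OBO + local)

    for cdef in EXTENSION_CLASSES:
        cls = expand(cdef.curie)
        quads.append(Quad(cls, RDF_TYPE, OWL_CLASS, g))
        quads.append(Quad(cls, RDFS_LABEL, LiteralValue(cdef.label, language="en"), g))
        quads.append(Quad(cls, SKOS_DEFINITION, LiteralValue(cdef.definition, language="en"), g))
        quads.append(Quad(cls, RDFS_SUBCLASSOF, expand(cdef.parent_curie), g))

    prop = has_state_property(config)
    quads.append(Quad(prop, RDF_TYPE, OWL_OBJECT_PROPERTY, g))
    quads.append(Quad(prop, RDFS_LABEL, LiteralValue("has_state", language="en"), g))
    quads.append(Quad(prop, RDFS_DOMAIN, chromatin_region_class(config), g))
    quads.append(Quad(prop, RDFS_RANGE, chromatin_state_class(config), g))

    return GraphBundle(quads, dict(config.prefix_map))


def subclass_descendants(bundle: GraphBundle, root: Iri) -> set[Iri]:
    """Reflexive-transitive ``subClassOf`` closure beneath ``root``.

    Returns the empty set (with a warning) when ``root`` never occurs in the
    bundle; a class with no subclasses yields just itself.
    """
    children: dict[Iri, set[Iri]] = {}
    mentioned: set[Iri] = set()
    for q in bundle.quads:
        mentioned.add(q.subject)
        if isinstance(q.object, Iri):
            mentioned.add(q.object)
        if q.predicate == RDFS_SUBCLASSOF and isinstance(q.object, Iri):
            children.setdefault(q.object, set()).add(q.subject)
    if root not in mentioned:
        warnings.warn(f"subclass_descendants: root {root.value} not present in bundle")
        return set()
    seen = {root}
    stack = [root]
    while stack:
        node = stack.pop()
        for child in children.get(node, ()):
            if child not in seen:
                seen.add(child)
                stack.append(child)
    return seen
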