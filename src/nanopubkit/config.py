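"""Namespace defaults, well-known term IRIs and config-file loading.

Several vocabularies used by the assertion templates are referenced by label
in the underlying study without a printed namespace IRI (the ``biosemantics:``
prefix, the NIFSTD disease/promoter classes, the exact SIO association id).
The defaults below are therefore best-effort mappings, clearly overridable
through a YAML/JSON config file; they are artifact conventions, not citations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import InvalidArgumentError
from .rdf_core import Iri, UriPolicy

# --- core W3C vocabularies -------------------------------------------------

RDF_TYPE = Iri("http://www.w3.org/1999/02/22-rdf-syntax-ns#type")
RDFS_SUBCLASSOF = Iri("http://www.w3.org/2000/01/rdf-schema#subClassOf")
RDFS_LABEL = Iri("http://www.w3.org/2000/01/rdf-schema#label")
RDFS_DOMAIN = Iri("http://www.w3.org/2000/01/rdf-schema#domain")
RDFS_RANGE = Iri("http://www.w3.org/2000/01/rdf-schema#range")
OWL_CLASS = Iri("http://www.w3.org/2002/07/owl#Class")
OWL_OBJECT_PROPERTY = Iri("http://www.w3.org/2002/07/owl#ObjectProperty")
XSD_DATETIME = Iri("http://www.w3.org/2001/XMLSchema#dateTime")
XSD_DOUBLE = Iri("http://www.w3.org/2001/XMLSchema#double")
XSD_INTEGER = Iri("http://www.w3.org/2001/XMLSchema#integer")

# --- nanopublication schema ------------------------------------------------

NP = "http://www.nanopub.org/nschema#"
NP_NANOPUBLICATION = Iri(NP + "Nanopublication")
NP_HAS_ASSERTION = Iri(NP + "hasAssertion")
NP_HAS_PROVENANCE = Iri(NP + "hasProvenance")
NP_HAS_PUBINFO = Iri(NP + "hasPublicationInfo")

# --- PROV-O (allow-listed subset) -----------------------------------------

PROV = "http://www.w3.org/ns/prov#"
PROV_ACTIVITY = Iri(PROV + "Activity")
PROV_ENTITY = Iri(PROV + "Entity")
PROV_AGENT = Iri(PROV + "Agent")
PROV_USED = Iri(PROV + "used")
PROV_WAS_GENERATED_BY = Iri(PROV + "wasGeneratedBy")
PROV_WAS_DERIVED_FROM = Iri(PROV + "wasDerivedFrom")
PROV_WAS_ASSOCIATED_WITH = Iri(PROV + "wasAssociatedWith")
PROV_ENDED_AT_TIME = Iri(PROV + "endedAtTime")
PROV_ALTERNATE_OF = Iri(PROV + "alternateOf")

#: The only PROV terms the provenance builder may emit.
PROV_ALLOWED_TERMS = frozenset(
    t.value
    for t in (
        PROV_ACTIVITY,
        PROV_ENTITY,
        PROV_AGENT,
        PROV_USED,
        PROV_WAS_GENERATED_BY,
        PROV_WAS_DERIVED_FROM,
        PROV_WAS_ASSOCIATED_WITH,
        PROV_ENDED_AT_TIME,
        PROV_ALTERNATE_OF,
    )
)

# --- ORE / Research Object -------------------------------------------------

ORE = "http://www.openarchives.org/ore/terms/"
ORE_AGGREGATES = Iri(ORE + "aggregates")
ORE_IS_AGGREGATED_BY = Iri(ORE + "isAggregatedBy")
ORE_AGGREGATION = Iri(ORE + "Aggregation")

# --- Dublin Core -----------------------------------------------------------

DCTERMS = "http://purl.org/dc/terms/"
DCT_CREATED = Iri(DCTERMS + "created")
DCT_CREATOR = Iri(DCTERMS + "creator")
DCT_CONTRIBUTOR = Iri(DCTERMS + "contributor")
DCT_HAS_VERSION = Iri(DCTERMS + "hasVersion")
DCT_LICENSE = Iri(DCTERMS + "license")
DCT_DESCRIPTION = Iri(DCTERMS + "description")

#: Annotation property carrying the textual definition of an ontology class.
SKOS_DEFINITION = Iri("http://www.w3.org/2004/02/skos/core#definition")

# --- domain namespaces -----------------------------------------------------

OBO = "http://purl.obolibrary.org/obo/"
SIO = "http://semanticscience.org/resource/"
NIFSTD = "http://uri.neuinfo.org/nif/nifstd/"
BIO2RDF = "http://bio2rdf.org/"

#: Placeholder for the chromatin-extension namespace: the source study names
#: a ``biosemantics:`` prefix but never prints its IRI, so this is a config
#: value with an overridable default.
BIOSEMANTICS_DEFAULT = "http://purl.example.org/biosemantics/"

DEFAULT_PREFIXES: dict[str, Iri] = {
    "rdf": Iri("http://www.w3.org/1999/02/22-rdf-syntax-ns#"),
    "rdfs": Iri("http://www.w3.org/2000/01/rdf-schema#"),
    "owl": Iri("http://www.w3.org/2002/07/owl#"),
    "xsd": Iri("http://www.w3.org/2001/XMLSchema#"),
    "skos": Iri("http://www.w3.org/2004/02/skos/core#"),
    "np": Iri(NP),
    "prov": Iri(PROV),
    "ore": Iri(ORE),
    "dcterms": Iri(DCTERMS),
    "sio": Iri(SIO),
    "so": Iri(OBO),
    "obo": Iri(OBO),
    "nifstd": Iri(NIFSTD),
    "biosemantics": Iri(BIOSEMANTICS_DEFAULT),
    "geneid": Iri(BIO2RDF + "geneid:"),
    "go": Iri(BIO2RDF + "go:"),
    "taxonomy": Iri(BIO2RDF + "taxonomy:"),
    "drugbank": Iri(BIO2RDF + "drugbank:"),
    "drugbank_target": Iri(BIO2RDF + "drugbank_target:"),
    "geneid_vocabulary": Iri(BIO2RDF + "geneid_vocabulary:"),
    "goa_vocabulary": Iri(BIO2RDF + "goa_vocabulary:"),
    "drugbank_vocabulary": Iri(BIO2RDF + "drugbank_vocabulary:"),
}

DEFAULT_BASE_NAMESPACE = Iri("https://example.org/np/")


def default_policy() -> UriPolicy:
    return UriPolicy(base_namespace=DEFAULT_BASE_NAMESPACE, strategy="slug")


# --- run configuration -----------------------------------------------------


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to run the pipeline end-to-end without edits."""

    prefix_map: Mapping[str, Iri] = field(default_factory=lambda: dict(DEFAULT_PREFIXES))
    policy: UriPolicy = field(default_factory=default_policy)
    biosemantics_namespace: Iri = Iri(BIOSEMANTICS_DEFAULT)
    seed: int = 0

    def with_overrides(self, **kwargs: Any) -> "RunConfig":
        return replace(self, **kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML or JSON config file.

    Recognized keys: ``base_namespace``, ``strategy``, ``biosemantics_namespace``,
    ``prefixes`` (mapping prefix -> namespace IRI), ``seed``.
    """
    path = Path(path)
    raw = path.read_text(encoding="utf-8")
    data = json.loads(raw) if path.suffix == ".json" else yaml.safe_load(raw)
    if not isinstance(data, dict):
        raise InvalidArgumentError(f"config file {path} must hold a mapping")
    prefixes = dict(DEFAULT_PREFIXES)
    for prefix, ns in (data.get("prefixes") or {}).items():
        prefixes[prefix] = Iri(ns)
    biosem = Iri(data.get("biosemantics_namespace", BIOSEMANTICS_DEFAULT))
    prefixes["biosemantics"] = biosem
    policy = UriPolicy(
        base_namespace=Iri(data.get("base_namespace", DEFAULT_BASE_NAMESPACE.value)),
        strategy=data.get("strategy", "slug"),
    )
    if policy.strategy not in ("slug", "content-hash"):
        raise InvalidArgumentError(f"unknown minting strategy: {policy.strategy!r}")
    return RunConfig(
        prefix_map=prefixes,
        policy=policy,
        biosemantics_namespace=biosem,
        seed=int(data.get("seed", 0)),
    )
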