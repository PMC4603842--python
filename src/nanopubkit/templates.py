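"""Assertion templates for the two result types.

Two kinds of scientific claims are minted into assertion graphs:

1. *Differential expression*: a gene–disease association node, typed with
   the SIO class for a gene-disease association linked with altered gene
   expression, pointing via ``refers_to`` at both the bio2rdf gene and the
   Huntington's disease class.  Three triples, no more.

2. *Genomic overlap*: the gene is ``associated_with`` a promoter, and the
   promoter ``overlaps_with`` a biological region — a CpG island, or a
   chromatin region carrying one of the four chromatin states via
   ``has_state``.  Four or five triples respectively, giving five
   structurally distinct overlap variants.

Assertions are deliberately minimal: coordinates, scores and experimental
context belong in the provenance graph, not here.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

from .config import NIFSTD, RDF_TYPE, SIO, RunConfig
from .errors import SchemaError, ValidationError
from .ontology_ext import ChromatinStateKind
from .rdf_core import GraphBundle, Iri, Quad, UriPolicy, mint_iri

__all__ = [
    "DEGeneRecord",
    "OverlapRecord",
    "VocabularyConfig",
    "REGION_KINDS",
    "CPG_ISLAND",
    "default_vocabulary",
    "build_de_assertion",
    "build_overlap_assertion",
    "records_from_tsv",
    "nanopub_key",
]

CPG_ISLAND = "cpg_island"

#: The five admissible region kinds for an overlap assertion.
REGION_KINDS: frozenset[str] = frozenset(
    {CPG_ISLAND} | {k.value for k in ChromatinStateKind}
)


@dataclass(frozen=True)
class DEGeneRecord:
    """One row of the differential-expression result table."""

    gene_id: int
    symbol: str | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.gene_id, int) or self.gene_id <= 0:
            raise ValidationError(f"gene_id must be a positive integer, got {self.gene_id!r}")


@dataclass(frozen=True)
class OverlapRecord:
    """One row of the gene→promoter→region overlap table."""

    gene_id: int
    promoter_key: str
    region_kind: str

    def __post_init__(self) -> None:
        if not isinstance(self.gene_id, int) or self.gene_id <= 0:
            raise ValidationError(f"gene_id must be a positive integer, got {self.gene_id!r}")
        if not self.promoter_key:
            raise ValidationError("promoter_key must be non-empty")
        if self.region_kind not in REGION_KINDS:
            raise ValidationError(
                f"unknown region_kind {self.region_kind!r}; "
                f"expected one of {sorted(REGION_KINDS)}"
            )


@dataclass(frozen=True)
class VocabularyConfig:
    """The class and predicate IRIs the templates instantiate.

    The study behind these templates names its vocabularies (NIFSTD, SIO,
    SO, bio2rdf) but does not print every numeric term id; defaults below
    are best-effort mappings (``refers to`` is SIO_000628; the altered-
    expression association class follows the DisGeNET convention of
    SIO_001123; NIFSTD disease/promoter/CpG-island ids are readable
    placeholders).  All are overridable.
    """

    hd_disease: Iri = Iri(NIFSTD + "HuntingtonsDisease")
    de_association_class: Iri = Iri(SIO + "SIO_001123")
    refers_to: Iri = Iri(SIO + "SIO_000628")
    associated_with: Iri = Iri("http://purl.obolibrary.org/obo/so#associated_with")
    overlaps_with: Iri = Iri("http://purl.obolibrary.org/obo/so#overlaps")
    promoter_class: Iri = Iri(NIFSTD + "Promoter")
    cpg_island_class: Iri = Iri(NIFSTD + "CpGIsland")
    gene_iri_pattern: str = "http://bio2rdf.org/geneid:{gene_id}"
    chromatin_region_class: Iri = Iri("http://purl.example.org/biosemantics/chromatin_region")
    has_state: Iri = Iri("http://purl.example.org/biosemantics/has_state")
    chromatin_states: Mapping[str, Iri] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "{gene_id}" not in self.gene_iri_pattern:
            raise ValidationError("gene_iri_pattern must contain a {gene_id} slot")

    def gene_iri(self, gene_id: int) -> Iri:
        return Iri(self.gene_iri_pattern.format(gene_id=gene_id))

    def state_iri(self, kind: str) -> Iri:
        states = self.chromatin_states or _default_states(
            self.chromatin_region_class.value.rsplit("/", 1)[0] + "/"
        )
        return states[kind]


def _default_states(ns: str) -> dict[str, Iri]:
    return {k.value: Iri(ns + k.value) for k in ChromatinStateKind}


def default_vocabulary(config: RunConfig) -> VocabularyConfig:
    """Vocabulary with the chromatin extension rooted at the configured namespace."""
    ns = config.biosemantics_namespace.value
    return VocabularyConfig(
        chromatin_region_class=Iri(ns + "chromatin_region"),
        has_state=Iri(ns + "has_state"),
        chromatin_states=_default_states(ns),
    )


def nanopub_key(rec: DEGeneRecord | OverlapRecord) -> str:
    """The deterministic minting key of the nanopublication for a record."""
    if isinstance(rec, DEGeneRecord):
        return f"degene-{rec.gene_id}"
    return f"overlap-{rec.gene_id}-{rec.promoter_key}-{rec.region_kind}"


def build_de_assertion(
    rec: DEGeneRecord,
    vocab: VocabularyConfig,
    policy: UriPolicy,
    graph_iri: Iri | None = None,
) -> GraphBundle:
    """The 3-triple differential-expression assertion graph for one gene."""
    key = nanopub_key(rec)
    g = graph_iri or mint_iri(policy, "assertion", key)
    assoc = mint_iri(policy, "association", key)
    gene = vocab.gene_iri(rec.gene_id)
    return GraphBundle(
        [
            Quad(assoc, RDF_TYPE, vocab.de_association_class, g),
            Quad(assoc, vocab.refers_to, gene, g),
            Quad(assoc, vocab.refers_to, vocab.hd_disease, g),
        ]
    )


def build_overlap_assertion(
    rec: OverlapRecord,
    vocab: VocabularyConfig,
    policy: UriPolicy,
    graph_iri: Iri | None = None,
) -> GraphBundle:
    """The gene→promoter→region overlap assertion graph for one record.

    CpG-island records yield 4 triples (the region is typed directly);
    chromatin-state records yield 5 (the region is a ``chromatin_region``
    linked to its state class via ``has_state``).
    """
    key = nanopub_key(rec)
    g = graph_iri or mint_iri(policy, "assertion", key)
    gene = vocab.gene_iri(rec.gene_id)
    promoter = mint_iri(policy, "promoter", f"{rec.gene_id}-{rec.promoter_key}")
    region = mint_iri(
        policy, "region", f"{rec.gene_id}-{rec.promoter_key}-{rec.region_kind}"
    )
    quads = [
        Quad(gene, vocab.associated_with, promoter, g),
        Quad(promoter, RDF_TYPE, vocab.promoter_class, g),
        Quad(promoter, vocab.overlaps_with, region, g),
    ]
    if rec.region_kind == CPG_ISLAND:
        quads.append(Quad(region, RDF_TYPE, vocab.cpg_island_class, g))
    else:
        quads.append(Quad(region, RDF_TYPE, vocab.chromatin_region_class, g))
        quads.append(Quad(region, vocab.has_state, vocab.state_iri(rec.region_kind), g))
    return GraphBundle(quads)


_SCHEMAS: dict[str, tuple[str, ...]] = {
    "de": ("gene_id",),
    "overlap": ("gene_id", "promoter_key", "region_kind"),
}


def records_from_tsv(
    path: str | Path, schema: Literal["de", "overlap"]
) -> list[DEGeneRecord] | list[OverlapRecord]:
    """Read a result table (tab-separated, UTF-8, header row required).

    DE tables need a ``gene_id`` column (``symbol`` is optional, carried for
    provenance only); overlap tables need ``gene_id``, ``promoter_key`` and
    ``region_kind``.  Errors name the offending column or row.
    """
    if schema not in _SCHEMAS:
        raise ValidationError(f"unknown schema {schema!r}")
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, header row required")
        for col in _SCHEMAS[schema]:
            if col not in reader.fieldnames:
                raise SchemaError(f"{path}: missing required column {col!r}")
        records: list = []
        for row_num, row in enumerate(reader, start=2):
            try:
                gene_id = int(row["gene_id"])
            except (TypeError, ValueError):
                raise ValidationError(
                    f"{path}: bad gene_id {row.get('gene_id')!r}", row=row_num
                ) from None
            try:
                if schema == "de":
                    records.append(DEGeneRecord(gene_id, row.get("symbol") or None))
                else:
                    records.append(
                        OverlapRecord(gene_id, row["promoter_key"], row["region_kind"])
                    )
            except ValidationError as exc:
                raise ValidationError(f"{path}: {exc}", row=row_num) from None
    return records


def records_to_tsv(records: Iterable[DEGeneRecord | OverlapRecord], path: str | Path) -> None:
    """Write records back out in the canonical column order."""
    records = list(records)
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        if records and isinstance(records[0], OverlapRecord):
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["gene_id", "promoter_key", "region_kind"])
            for r in records:
                writer.writerow([r.gene_id, r.promoter_key, r.region_kind])
        else:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["gene_id", "symbol"])
            for r in records:
                writer.writerow([r.gene_id, r.symbol or ""])
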