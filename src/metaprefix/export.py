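"""Interchange exports: TSV/YAML, SSSOM mappings, JSON-LD contexts, RDF.

The canonical registry file (JSON, prefix → record) is the single source of
truth; everything here is a derived artifact for downstream integration:

* :func:`export_tsv` / :func:`export_yaml` — flat reusable tables;
* :func:`export_context` — Semantic Web prefix maps (JSON-LD ``@context``)
  mapping a prefix (``chebi``) to its URI prefix
  (``http://purl.obolibrary.org/obo/CHEBI_``), in three profiles: ``full``
  (everything, canonical lowercase), ``obo`` (ontology records, preferred
  casing), ``semweb`` (a curated collection);
* :func:`export_sssom` — cross-registry equivalence mappings in the Simple
  Standard for Sharing Ontological Mappings TSV (``# ``-prefixed YAML
  header, one row per mapping, ``skos:exactMatch`` predicate);
* :func:`export_rdf` — the registry, metaregistry, and collections as one
  RDF graph serialized to N-Triples, Turtle, or JSON-LD, reusing DCTERMS /
  FOAF / RDFS / SKOS terms plus a small package-local schema vocabulary.

All exporters are deterministic: sorted keys and fixed column orders make
output byte-identical across runs on identical input.
"""

from __future__ import annotations

import datetime
import io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from rdflib import Graph, Literal, Namespace, URIRef
from rdflib.namespace import DCTERMS, FOAF, RDF, RDFS, SKOS

from .records import PLACEHOLDER, Registry, ResourceRecord

__all__ = [
    "ExportError",
    "PrefixMap",
    "SssomDoc",
    "export_context",
    "export_rdf",
    "export_sssom",
    "export_tsv",
    "export_yaml",
    "read_tsv",
]

logger = logging.getLogger(__name__)

#: Fixed column order of the TSV export; list-valued fields are joined with |.
TSV_COLUMNS = (
    "prefix",
    "preferred_prefix",
    "name",
    "homepage",
    "description",
    "pattern",
    "example",
    "uri_format",
    "synonyms",
    "deprecated",
    "proprietary",
    "replaced_by",
    "depends_on",
    "license",
    "version",
    "contact",
)

#: Package-local RDF schema vocabulary, complementing DCTERMS/FOAF/RDFS/SKOS.
SCHEMA = Namespace("https://w3id.org/metaprefix/schema#")
RESOURCE_NS = Namespace("https://w3id.org/metaprefix/registry/")
METAREGISTRY_NS = Namespace("https://w3id.org/metaprefix/metaregistry/")
COLLECTION_NS = Namespace("https://w3id.org/metaprefix/collection/")

_RDF_SYNTAXES = {"ntriples": "nt", "turtle": "turtle", "jsonld": "json-ld"}

#: SSSOM vocabulary bindings: equivalences are skos:exactMatch; provenance
#: distinguishes manually curated from lexically matched (automated) edges.
SSSOM_PREDICATE = "skos:exactMatch"
SSSOM_JUSTIFICATIONS = {
    "curated": "semapv:ManualMappingCuration",
    "automated": "semapv:LexicalMatching",
}


class ExportError(RuntimeError):
    """Export configuration or collision failure."""


# ---------------------------------------------------------------------------
# TSV / YAML
# ---------------------------------------------------------------------------

def export_tsv(registry: Registry) -> pd.DataFrame:
    """One row per record, fixed column order, lists joined with ``|``."""
    rows = []
    for prefix in sorted(registry.records):
        record = registry.records[prefix]
        rows.append(
            {
                "prefix": record.prefix,
                "preferred_prefix": record.preferred_prefix or "",
                "name": record.name or "",
                "homepage": record.homepage or "",
                "description": record.description or "",
                "pattern": record.pattern or "",
                "example": record.example or "",
                "uri_format": record.uri_format or "",
                "synonyms": "|".join(record.synonyms),
                "deprecated": str(record.deprecated).lower(),
                "proprietary": str(record.proprietary).lower(),
                "replaced_by": record.replaced_by or "",
                "depends_on": "|".join(record.depends_on),
                "license": record.license or "",
                "version": record.version or "",
                "contact": record.contact or "",
            }
        )
    return pd.DataFrame(rows, columns=list(TSV_COLUMNS))


def write_tsv(registry: Registry, path: str | Path) -> None:
    export_tsv(registry).to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_tsv(path: str | Path) -> Registry:
    """Inverse of :func:`write_tsv` for the scalar and list fields it carries."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records = []
    for row in frame.to_dict(orient="records"):
        records.append(
            ResourceRecord(
                prefix=row["prefix"],
                preferred_prefix=row["preferred_prefix"] or None,
                name=row["name"] or None,
                homepage=row["homepage"] or None,
                description=row["description"] or None,
                pattern=row["pattern"] or None,
                example=row["example"] or None,
                uri_format=row["uri_format"] or None,
                synonyms=row["synonyms"].split("|") if row["synonyms"] else [],
                deprecated=row["deprecated"] == "true",
                proprietary=row["proprietary"] == "true",
                replaced_by=row["replaced_by"] or None,
                depends_on=row["depends_on"].split("|") if row["depends_on"] else [],
                license=row["license"] or None,
                version=row["version"] or None,
                contact=row["contact"] or None,
            )
        )
    return Registry(records)


def export_yaml(registry: Registry) -> str:
    """The canonical registry content as YAML (keys sorted)."""
    return yaml.safe_dump(registry.to_dict(), sort_keys=True, allow_unicode=True)


# ---------------------------------------------------------------------------
# Prefix-map contexts
# ---------------------------------------------------------------------------

@dataclass
class PrefixMap:
    """An ordered prefix → URI-prefix map for Semantic Web use."""

    entries: dict[str, str] = field(default_factory=dict)

    def to_jsonld(self) -> str:
        return json.dumps({"@context": dict(self.entries)}, indent=2, sort_keys=True) + "\n"


def _uri_prefix(record: ResourceRecord) -> Optional[str]:
    """URI prefix of a record: its format string minus the trailing
    placeholder.  Only formats *ending* in the placeholder are eligible —
    an internal placeholder has no constant prefix to contract against."""
    if record.uri_format is None or record.uri_format.count(PLACEHOLDER) != 1:
        return None
    if not record.uri_format.endswith(PLACEHOLDER):
        return None
    return record.uri_format[: -len(PLACEHOLDER)]


def export_context(
    registry: Registry,
    profile: str = "full",
    collection: Optional[str] = None,
    strict: bool = False,
) -> PrefixMap:
    """Derive a prefix-map context from the registry.

    Membership and casing follow the profile: ``full`` includes every
    eligible record under its canonical lowercase prefix; ``obo`` restricts
    to records mapped to the OBO Foundry registry and uses the preferred
    (stylized) prefix; ``semweb`` restricts to the members of a named
    collection.  Deprecated records and records whose URI format does not
    end in the placeholder are excluded (the latter with a logged warning).

    URI-prefix collisions are resolved by keeping the first record in
    sorted-prefix order and logging the drop; ``strict=True`` raises
    instead, listing the colliding prefixes.
    """
    if profile not in ("full", "obo", "semweb"):
        raise ExportError(f"unknown context profile {profile!r}")
    members: Optional[set[str]] = None
    if profile == "semweb" or collection is not None:
        if collection is None:
            raise ExportError("the semweb profile requires a collection identifier")
        if collection not in registry.collections:
            raise ExportError(f"unknown collection {collection!r}")
        members = set(registry.collections[collection].members)

    entries: dict[str, str] = {}
    value_owner: dict[str, str] = {}
    for prefix in sorted(registry.records):
        record = registry.records[prefix]
        if record.deprecated:
            continue
        if members is not None and prefix not in members:
            continue
        if profile == "obo" and "obofoundry" not in record.mappings:
            continue
        uri_prefix = _uri_prefix(record)
        if uri_prefix is None:
            if record.uri_format is not None:
                logger.warning(
                    "record %r excluded from context: uri_format %r does not end "
                    "in the placeholder",
                    prefix,
                    record.uri_format,
                )
            continue
        key = (
            record.preferred_prefix
            if profile == "obo" and record.preferred_prefix
            else prefix
        )
        if uri_prefix in value_owner:
            message = (
                f"URI prefix {uri_prefix!r} claimed by both "
                f"{value_owner[uri_prefix]!r} and {key!r}"
            )
            if strict:
                raise ExportError(message)
            logger.warning("%s; dropping %r", message, key)
            continue
        entries[key] = uri_prefix
        value_owner[uri_prefix] = key
    return PrefixMap(entries)


# ---------------------------------------------------------------------------
# SSSOM
# ---------------------------------------------------------------------------

@dataclass
class SssomDoc:
    """A mapping set: YAML header metadata plus one row per equivalence."""

    metadata: dict
    rows: list[dict[str, str]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        columns = ["subject_id", "predicate_id", "object_id", "mapping_justification"]
        return pd.DataFrame(self.rows, columns=columns)

    def to_tsv(self) -> str:
        """Serialize with the conventional ``# ``-prefixed YAML header block."""
        buffer = io.StringIO()
        header = yaml.safe_dump(self.metadata, sort_keys=True, allow_unicode=True)
        for line in header.rstrip("\n").split("\n"):
            buffer.write(f"# {line}\n")
        self.to_frame().to_csv(buffer, sep="\t", index=False, lineterminator="\n")
        return buffer.getvalue()


def export_sssom(registry: Registry, mapping_date: Optional[str] = None) -> SssomDoc:
    """Export the metaregistry's cross-registry equivalences as SSSOM.

    One row per mapping: the subject is the registry-side CURIE of the
    record, the object the registry-scoped CURIE of the external prefix,
    the predicate a constant exact-match term.  The justification encodes
    provenance (manual curation vs lexical matching).
    """
    curie_map = {
        "metaprefix": str(RESOURCE_NS),
        "skos": str(SKOS),
        "semapv": "https://w3id.org/semapv/vocab/",
    }
    for key in sorted(registry.metas):
        curie_map[key] = f"{METAREGISTRY_NS}{key}/"
    metadata = {
        "mapping_set_id": f"{METAREGISTRY_NS}mappings.sssom.tsv",
        "license": "https://creativecommons.org/publicdomain/zero/1.0/",
        "mapping_date": mapping_date or datetime.date.today().isoformat(),
        "curie_map": curie_map,
    }
    rows = [
        {
            "subject_id": f"metaprefix:{m.prefix}",
            "predicate_id": SSSOM_PREDICATE,
            "object_id": f"{m.registry_key}:{m.external_prefix}",
            "mapping_justification": SSSOM_JUSTIFICATIONS.get(
                m.provenance, SSSOM_JUSTIFICATIONS["curated"]
            ),
        }
        for m in registry.mappings()
    ]
    return SssomDoc(metadata=metadata, rows=rows)


# ---------------------------------------------------------------------------
# RDF
# ---------------------------------------------------------------------------

def _registry_graph(registry: Registry) -> Graph:
    graph = Graph()
    graph.bind("schema", SCHEMA)
    graph.bind("dcterms", DCTERMS)
    graph.bind("foaf", FOAF)
    graph.bind("skos", SKOS)
    graph.add((SCHEMA.Resource, RDF.type, RDFS.Class))
    graph.add((SCHEMA.Collection, RDF.type, RDFS.Class))
    for prefix in sorted(registry.records):
        record = registry.records[prefix]
        node = RESOURCE_NS[prefix]
        graph.add((node, RDF.type, SCHEMA.Resource))
        graph.add((node, RDFS.label, Literal(record.name or prefix)))
        graph.add((node, DCTERMS.description, Literal(record.description or "")))
        if record.homepage:
            graph.add((node, FOAF.homepage, URIRef(record.homepage)))
        if record.preferred_prefix:
            graph.add((node, SCHEMA.preferredPrefix, Literal(record.preferred_prefix)))
        for synonym in record.synonyms:
            graph.add((node, SKOS.altLabel, Literal(synonym)))
        if record.pattern:
            graph.add((node, SCHEMA.pattern, Literal(record.pattern)))
        if record.example:
            graph.add((node, SCHEMA.example, Literal(record.example)))
        if record.uri_format:
            graph.add((node, SCHEMA.uriFormat, Literal(record.uri_format)))
        if record.deprecated:
            graph.add((node, SCHEMA.deprecated, Literal(True)))
        if record.replaced_by:
            graph.add((node, DCTERMS.isReplacedBy, RESOURCE_NS[record.replaced_by]))
        for dep in record.depends_on:
            graph.add((node, SCHEMA.dependsOn, RESOURCE_NS[dep]))
        for registry_key in sorted(record.mappings):
            external = URIRef(
                f"{METAREGISTRY_NS}{registry_key}/{record.mappings[registry_key]}"
            )
            graph.add((node, SKOS.exactMatch, external))
    for identifier in sorted(registry.collections):
        collection = registry.collections[identifier]
        node = COLLECTION_NS[identifier]
        graph.add((node, RDF.type, SCHEMA.Collection))
        graph.add((node, RDFS.label, Literal(collection.name or identifier)))
        for member in collection.members:
            graph.add((node, SCHEMA.hasMember, RESOURCE_NS[member]))
    return graph


def export_rdf(registry: Registry, syntax: str = "turtle") -> str:
    """Serialize registry + metaregistry + collections as one RDF graph.

    The triple multiset is identical across the supported syntaxes
    (``ntriples``, ``turtle``, ``jsonld``); every record yields at least
    type, label, and description triples.

    Raises
    ------
    ExportError
        On an unsupported syntax name.
    """
    if syntax not in _RDF_SYNTAXES:
        raise ExportError(
            f"unsupported RDF syntax {syntax!r}; choose from {sorted(_RDF_SYNTAXES)}"
        )
    graph = _registry_graph(registry)
    return graph.serialize(format=_RDF_SYNTAXES[syntax])
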