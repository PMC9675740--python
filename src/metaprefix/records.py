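"""Domain model for a metaregistry of biomedical identifier resources.

An *identifier resource* (an ontology or database such as ChEBI, UniProt, or
PubMed) assigns each of its entities a *local unique identifier* (LUI, an
accession such as ``P0DP23``).  A *registry* catalogs identifier resources:
for each it records a canonical prefix, a human-readable name, a homepage, a
description, an optional regular-expression pattern for LUIs, and URI format
strings for turning a LUI into a resolvable URI.  A *metaregistry*
additionally maintains equivalence mappings from its own records to the
records of external registries, acting as an interoperability layer between
otherwise conflicting prefix standards.

This module defines the record types (:class:`ResourceRecord`,
:class:`Provider`, :class:`RegistryMeta`, :class:`ExternalRecord`,
:class:`CrossRegistryMapping`, :class:`Collection`, :class:`Attribution`),
the :class:`Registry` container with JSON persistence, record-level
validation (:func:`validate_record`), registry-level quality assurance
(:func:`registry_violations`), and the curated-over-imported merge policy
(:func:`merge_external_metadata`).

Validation is *reporting*, not *gating*: malformed content produces
:class:`Violation` values rather than exceptions, so that partially curated
records can be loaded, inspected, and repaired.  Violations carry a level:
``error`` marks a broken structural invariant (e.g. an example LUI that does
not match the declared pattern) while ``warning`` marks incomplete metadata
(e.g. a missing homepage), mirroring the heterogeneous capability profiles
of real external registries.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional

from pydantic import BaseModel, Field

__all__ = [
    "PLACEHOLDER",
    "Attribution",
    "Collection",
    "ConsistencyError",
    "CrossRegistryMapping",
    "ExternalRecord",
    "Provider",
    "Registry",
    "RegistryMeta",
    "ResourceRecord",
    "Violation",
    "load_registry",
    "merge_external_metadata",
    "norm_key",
    "registry_json_schema",
    "registry_violations",
    "save_registry",
    "validate_record",
]

#: Placeholder token in URI format strings; exactly one occurrence is
#: substituted by the local unique identifier.  A single fixed token keeps
#: format strings bit-exact across exporters.
PLACEHOLDER = "$1"

#: Canonical prefixes are lowercase alphanumeric with internal ``._-``.
PREFIX_RE = re.compile(r"^[a-z0-9][a-z0-9._-]*$")

#: ORCID identifiers: four dash-separated groups, final character may be X.
ORCID_RE = re.compile(r"^\d{4}-\d{4}-\d{4}-\d{3}[\dX]$")

#: Characters removed by :func:`norm_key`.
_NORM_STRIP = {"-", "_", ".", " ", "/"}

#: Provider categories, in default resolution priority order.
PROVIDER_CATEGORIES = ("first-party", "third-party", "resolver")


def norm_key(s: str) -> str:
    """Normalize a prefix-like string to its lookup key.

    Casefolds and removes dashes, underscores, dots, spaces, and slashes so
    that capitalization variants (``go`` vs ``GO``) and punctuation variants
    (``ec-code`` vs ``eccode``) collapse to the same key.

    >>> norm_key("NCBI_taxid")
    'ncbitaxid'

    Raises
    ------
    ValueError
        If ``s`` is empty or normalizes to the empty string.
    """
    if not s:
        raise ValueError("cannot normalize an empty prefix string")
    key = "".join(c for c in s.casefold() if c not in _NORM_STRIP)
    if not key:
        raise ValueError(f"prefix string {s!r} normalizes to the empty string")
    return key


class ConsistencyError(ValueError):
    """A cross-object consistency precondition was breached."""


class Attribution(BaseModel):
    """Who contributed or reviewed a record: a name and an ORCID."""

    name: str
    orcid: Optional[str] = None


class Provider(BaseModel):
    """One source of URIs for a resource's entities.

    Providers are *first-party* (the resource itself), *third-party*
    (e.g. an ontology browser such as OntoBee or OLS), or a *resolver*
    (a redirection service).
    """

    code: str
    name: Optional[str] = None
    uri_format: str
    category: str = "first-party"


class ResourceRecord(BaseModel):
    """One identifier resource in the registry.

    Only ``prefix`` is structurally mandatory; all metadata is optional at
    the model level and completeness is assessed by :func:`validate_record`.
    """

    prefix: str
    preferred_prefix: Optional[str] = None
    name: Optional[str] = None
    homepage: Optional[str] = None
    description: Optional[str] = None
    synonyms: list[str] = Field(default_factory=list)
    pattern: Optional[str] = None
    example: Optional[str] = None
    uri_format: Optional[str] = None
    providers: list[Provider] = Field(default_factory=list)
    deprecated: bool = False
    proprietary: bool = False
    replaced_by: Optional[str] = None
    depends_on: list[str] = Field(default_factory=list)
    mappings: dict[str, str] = Field(default_factory=dict)
    contributor: Optional[Attribution] = None
    reviewer: Optional[Attribution] = None
    download_obo: Optional[str] = None
    download_owl: Optional[str] = None
    download_json: Optional[str] = None
    license: Optional[str] = None
    version: Optional[str] = None
    contact: Optional[str] = None

    def compiled_pattern(self) -> Optional[re.Pattern[str]]:
        """Compile the LUI pattern, or ``None`` if absent or malformed."""
        if self.pattern is None:
            return None
        try:
            return re.compile(self.pattern)
        except re.error:
            return None

    def is_valid_identifier(self, luid: str) -> bool:
        """Whether ``luid`` fully matches the pattern (vacuously true if none).

        Full-match semantics: a pattern stored without surrounding anchors is
        implicitly anchored, so ``^\\d{7}$`` and ``\\d{7}`` behave alike and
        partial matches are rejected.
        """
        compiled = self.compiled_pattern()
        if compiled is None:
            return True
        return compiled.fullmatch(luid) is not None


class RegistryMeta(BaseModel):
    """Descriptor of an external registry.

    ``capabilities`` mirrors the external registry's metadata model: which
    fields its schema carries (name, homepage, description, example LUI,
    pattern, provider, license, version, ...).  ``policy_group`` is the
    import policy stratum:

    1. rich metadata, biomedical scope, assigns global prefixes —
       unmatched prefixes become new registry records;
    2. partially relevant or under-specified — unmatched prefixes go to a
       curation sheet for manual review;
    3. minimal metadata or no biomedical focus — unmatched prefixes are
       dropped without report.

    Group assignment is editorial configuration, not inferred from data.
    """

    key: str
    name: Optional[str] = None
    homepage: Optional[str] = None
    capabilities: dict[str, bool] = Field(default_factory=dict)
    policy_group: int = 2
    import_order: int = 0


class ExternalRecord(BaseModel):
    """A normalized row from an external registry dump.

    Ingestion reduces each external registry's native schema to this flat
    form in which exactly one field is annotated as the external prefix;
    all other metadata is optional.
    """

    registry_key: str
    external_prefix: str
    name: Optional[str] = None
    homepage: Optional[str] = None
    example: Optional[str] = None
    pattern: Optional[str] = None
    uri_format: Optional[str] = None


class CrossRegistryMapping(BaseModel):
    """An equivalence edge of the metaregistry.

    Asserts that the registry record ``prefix`` and the external registry
    ``registry_key``'s record ``external_prefix`` describe the same
    identifier resource.
    """

    prefix: str
    registry_key: str
    external_prefix: str
    provenance: str = "curated"  # or "automated"


class Collection(BaseModel):
    """A curated grouping of prefixes (e.g. Semantic Web vocabularies)."""

    identifier: str
    name: Optional[str] = None
    description: Optional[str] = None
    members: list[str] = Field(default_factory=list)


@dataclass(frozen=True)
class Violation:
    """One broken invariant on a record or registry.

    ``level`` is ``"error"`` for structural invariants and ``"warning"``
    for incomplete metadata; quality-assurance gates fail on errors only.
    """

    prefix: str
    field: str
    code: str
    message: str
    level: str = "error"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.level}] {self.prefix}.{self.field}: {self.message} ({self.code})"


def _placeholder_count(uri_format: str) -> int:
    return uri_format.count(PLACEHOLDER)


def validate_record(record: ResourceRecord) -> list[Violation]:
    """Check one record against the data-model invariants.

    Returns one :class:`Violation` per broken invariant; the empty list iff
    the record is fully valid.  Never raises on malformed content — a
    non-compiling pattern, a bad ORCID, and a placeholder-less URI format
    are all reported as data.
    """
    v: list[Violation] = []
    p = record.prefix

    def err(field: str, code: str, message: str) -> None:
        v.append(Violation(p, field, code, message, "error"))

    def warn(field: str, code: str, message: str) -> None:
        v.append(Violation(p, field, code, message, "warning"))

    if not PREFIX_RE.match(record.prefix or ""):
        err("prefix", "prefix-shape", f"prefix {record.prefix!r} is not lowercase canonical form")

    # Completeness: prefix, name, and description are expected on every
    # record; a homepage on every non-deprecated one.
    if not record.name:
        warn("name", "missing-name", "record has no human-readable name")
    if not record.description:
        warn("description", "missing-description", "record has no description")
    if not record.homepage and not record.deprecated:
        warn("homepage", "missing-homepage", "active record has no homepage")

    if record.prefix in record.synonyms:
        err("synonyms", "prefix-in-synonyms", "canonical prefix repeated in synonyms")
    seen_keys: dict[str, str] = {}
    for syn in record.synonyms:
        try:
            key = norm_key(syn)
        except ValueError:
            err("synonyms", "empty-synonym", f"synonym {syn!r} normalizes to nothing")
            continue
        if key in seen_keys:
            err(
                "synonyms",
                "duplicate-synonym",
                f"synonyms {seen_keys[key]!r} and {syn!r} collide after key-normalization",
            )
        else:
            seen_keys[key] = syn

    if record.pattern is not None and record.compiled_pattern() is None:
        err("pattern", "pattern-invalid", f"pattern {record.pattern!r} does not compile")
    elif record.pattern is not None and record.example is not None:
        if not record.is_valid_identifier(record.example):
            err(
                "example",
                "pattern-mismatch",
                f"example {record.example!r} does not fully match pattern {record.pattern!r}",
            )

    if record.uri_format is not None and _placeholder_count(record.uri_format) != 1:
        err(
            "uri_format",
            "placeholder-count",
            f"uri_format {record.uri_format!r} must contain exactly one {PLACEHOLDER!r}",
        )
    for provider in record.providers:
        if _placeholder_count(provider.uri_format) != 1:
            err(
                "providers",
                "placeholder-count",
                f"provider {provider.code!r} uri_format must contain exactly one {PLACEHOLDER!r}",
            )
        if provider.category not in PROVIDER_CATEGORIES:
            err(
                "providers",
                "provider-category",
                f"provider {provider.code!r} has unknown category {provider.category!r}",
            )

    if record.replaced_by is not None and not record.deprecated:
        err("replaced_by", "replaced-not-deprecated", "replaced_by is set but deprecated is false")

    for role, attribution in (("contributor", record.contributor), ("reviewer", record.reviewer)):
        if attribution is not None and attribution.orcid is not None:
            if not ORCID_RE.match(attribution.orcid):
                err(role, "orcid-shape", f"{attribution.orcid!r} is not a valid ORCID")

    return v


def merge_external_metadata(record: ResourceRecord, ext: ExternalRecord) -> ResourceRecord:
    """Merge metadata imported from an external registry into a record.

    Curated content always wins over imported content, field-wise: only
    fields that are empty on ``record`` are filled from ``ext``.  The merge
    is idempotent and returns a new record (the input is not mutated).

    Raises
    ------
    ConsistencyError
        If ``ext.registry_key`` is not mapped on the record, or is mapped to
        a different external prefix.
    """
    mapped = record.mappings.get(ext.registry_key)
    if mapped is None:
        raise ConsistencyError(
            f"record {record.prefix!r} has no mapping to registry {ext.registry_key!r}"
        )
    if mapped != ext.external_prefix:
        raise ConsistencyError(
            f"record {record.prefix!r} maps {ext.registry_key!r} to {mapped!r}, "
            f"not {ext.external_prefix!r}"
        )
    updates: dict[str, str] = {}
    for field in ("name", "homepage", "example", "pattern", "uri_format"):
        if getattr(record, field) is None and getattr(ext, field) is not None:
            updates[field] = getattr(ext, field)
    if not updates:
        return record.model_copy()
    return record.model_copy(update=updates)


class Registry:
    """The metaregistry: records, external-registry descriptors, collections.

    Records are keyed by canonical prefix.  Cross-registry mappings are
    stored on each record (``record.mappings``: registry key → external
    prefix) and enumerated via :meth:`mappings`; mapping provenance
    (curated vs automated) is tracked per edge.
    """

    def __init__(
        self,
        records: Iterable[ResourceRecord] = (),
        metas: Iterable[RegistryMeta] = (),
        collections: Iterable[Collection] = (),
    ) -> None:
        self.records: dict[str, ResourceRecord] = {}
        self.metas: dict[str, RegistryMeta] = {}
        self.collections: dict[str, Collection] = {}
        self._provenance: dict[tuple[str, str], str] = {}
        for record in records:
            self.add_record(record)
        for meta in metas:
            self.add_meta(meta)
        for collection in collections:
            self.collections[collection.identifier] = collection

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ResourceRecord]:
        return iter(self.records.values())

    def __contains__(self, prefix: str) -> bool:
        return prefix in self.records

    def __getitem__(self, prefix: str) -> ResourceRecord:
        return self.records[prefix]

    def get(self, prefix: str) -> Optional[ResourceRecord]:
        return self.records.get(prefix)

    # -- mutation -----------------------------------------------------------
    def add_record(self, record: ResourceRecord) -> None:
        if record.prefix in self.records:
            raise ConsistencyError(f"duplicate record prefix {record.prefix!r}")
        self.records[record.prefix] = record

    def add_meta(self, meta: RegistryMeta) -> None:
        if meta.key in self.metas:
            raise ConsistencyError(f"duplicate registry key {meta.key!r}")
        for other in self.metas.values():
            if other.import_order == meta.import_order:
                raise ConsistencyError(
                    f"registries {other.key!r} and {meta.key!r} share import_order "
                    f"{meta.import_order}"
                )
        self.metas[meta.key] = meta

    def set_mapping(
        self, prefix: str, registry_key: str, external_prefix: str, provenance: str = "curated"
    ) -> None:
        record = self.records[prefix]
        existing = record.mappings.get(registry_key)
        if existing is not None and existing != external_prefix:
            raise ConsistencyError(
                f"record {prefix!r} already maps {registry_key!r} to {existing!r}"
            )
        record.mappings[registry_key] = external_prefix
        self._provenance[(prefix, registry_key)] = provenance

    # -- views --------------------------------------------------------------
    def mappings(self) -> list[CrossRegistryMapping]:
        """Enumerate all cross-registry mappings, sorted for determinism."""
        out = []
        for prefix in sorted(self.records):
            record = self.records[prefix]
            for registry_key in sorted(record.mappings):
                out.append(
                    CrossRegistryMapping(
                        prefix=prefix,
                        registry_key=registry_key,
                        external_prefix=record.mappings[registry_key],
                        provenance=self._provenance.get((prefix, registry_key), "curated"),
                    )
                )
        return out

    def mapped_external_prefixes(self, registry_key: str) -> set[str]:
        """External prefixes of ``registry_key`` already mapped to some record."""
        return {
            record.mappings[registry_key]
            for record in self.records.values()
            if registry_key in record.mappings
        }

    def copy(self) -> "Registry":
        clone = Registry(
            (record.model_copy(deep=True) for record in self.records.values()),
            (meta.model_copy(deep=True) for meta in self.metas.values()),
            (collection.model_copy(deep=True) for collection in self.collections.values()),
        )
        clone._provenance = dict(self._provenance)
        return clone

    # -- persistence --------------------------------------------------------
    def to_dict(self) -> dict[str, dict]:
        """The canonical registry file content: prefix → record, keys sorted."""
        return {
            prefix: self.records[prefix].model_dump(exclude_defaults=True, exclude={"prefix"})
            for prefix in sorted(self.records)
        }

    @classmethod
    def from_dict(
        cls,
        data: dict[str, dict],
        metas: Iterable[RegistryMeta] = (),
        collections: Iterable[Collection] = (),
    ) -> "Registry":
        records = [
            ResourceRecord(prefix=prefix, **fields) for prefix, fields in data.items()
        ]
        return cls(records, metas, collections)


def registry_violations(registry: Registry) -> list[Violation]:
    """Registry-level quality assurance.

    Runs :func:`validate_record` on every record and adds the global
    checks: the key-normalized lookup over canonical prefixes, preferred
    prefixes, and synonyms must be collision-free across records (keys of
    one record may coincide — ``eccode`` and its synonym ``ec-code`` share
    a key harmlessly — but no key may point at two records); mapping edges
    must be unique per (registry, external prefix); collection members and
    ``replaced_by``/``depends_on`` targets must exist.
    """
    violations: list[Violation] = []
    for record in registry:
        violations.extend(validate_record(record))

    claimed: dict[str, str] = {}
    for prefix in sorted(registry.records):
        record = registry.records[prefix]
        candidates = [record.prefix] + record.synonyms
        if record.preferred_prefix:
            candidates.append(record.preferred_prefix)
        local: set[str] = set()
        for candidate in candidates:
            try:
                key = norm_key(candidate)
            except ValueError:
                continue
            if key in local:
                continue
            local.add(key)
            owner = claimed.get(key)
            if owner is not None and owner != prefix:
                violations.append(
                    Violation(
                        prefix,
                        "synonyms",
                        "lookup-collision",
                        f"key {key!r} (from {candidate!r}) collides with record {owner!r}",
                    )
                )
            else:
                claimed.setdefault(key, prefix)

    edge_owner: dict[tuple[str, str], str] = {}
    for record in registry:
        for registry_key, external_prefix in record.mappings.items():
            edge = (registry_key, external_prefix)
            owner = edge_owner.get(edge)
            if owner is not None:
                violations.append(
                    Violation(
                        record.prefix,
                        "mappings",
                        "duplicate-mapping",
                        f"external prefix {external_prefix!r} of {registry_key!r} is also "
                        f"mapped by record {owner!r}",
                    )
                )
            else:
                edge_owner[edge] = record.prefix

    for record in registry:
        if record.replaced_by is not None and record.replaced_by not in registry:
            violations.append(
                Violation(
                    record.prefix,
                    "replaced_by",
                    "dangling-reference",
                    f"replaced_by target {record.replaced_by!r} is not in the registry",
                )
            )
        for dep in record.depends_on:
            if dep not in registry:
                violations.append(
                    Violation(
                        record.prefix,
                        "depends_on",
                        "dangling-reference",
                        f"depends_on target {dep!r} is not in the registry",
                    )
                )
    for collection in registry.collections.values():
        for member in collection.members:
            if member not in registry:
                violations.append(
                    Violation(
                        collection.identifier,
                        "members",
                        "dangling-reference",
                        f"collection member {member!r} is not in the registry",
                    )
                )
    return violations


def qa_errors(registry: Registry) -> list[Violation]:
    """Error-level violations only: the gate used by alignment and exports."""
    return [v for v in registry_violations(registry) if v.level == "error"]


def save_registry(registry: Registry, path: str | Path) -> None:
    """Write the canonical registry file: one JSON object, prefix → record,
    UTF-8, keys sorted."""
    Path(path).write_text(
        json.dumps(registry.to_dict(), indent=2, sort_keys=True, ensure_ascii=False) + "\n",
        encoding="utf-8",
    )


def load_registry(path: str | Path) -> Registry:
    """Load a canonical registry file written by :func:`save_registry`."""
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    return Registry.from_dict(data)


def registry_json_schema() -> dict:
    """JSON Schema for one record, published alongside the registry file so
    third parties can validate without importing this package."""
    return ResourceRecord.model_json_schema()
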