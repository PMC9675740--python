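"""Multi-registry alignment: mapping external registry dumps onto the registry.

External registries describe overlapping sets of identifier resources under
inconsistent prefixes — differing in capitalization (``go`` vs ``GO``),
punctuation (``ec-code`` vs ``eccode``), abbreviation (``flybase`` vs
``fb``), and vocabulary (``intenz`` vs ``eccode``).  Alignment finds the
equivalences and records them as cross-registry mappings, turning the
registry into a metaregistry.

The procedure, per external registry, is:

1. build a lookup table over the normalized canonical prefix, preferred
   prefix, and synonyms of every record, *excluding* records already mapped
   to this registry (:func:`build_lookup`);
2. for each dump row: skip external prefixes that already have a mapping;
   look up the normalized external prefix; on a hit not suppressed by the
   blocklist, emit an automated mapping (:func:`align`);
3. on a miss, dispatch by the registry's import policy group: group 1 —
   synthesize a new registry record from the row's metadata; group 2 —
   emit a curation-sheet row for manual review; group 3 — skip silently;
4. merge mappings and new records back into the registry atomically,
   re-running quality assurance (:func:`apply_result`).

A manually curated blocklist of known-incorrect candidate mappings
post-processes the automated matches: it suppresses false positives on
lookup hits but never creates mappings.

Registries are processed sequentially in ``import_order``; the whole run is
idempotent — re-aligning an already-applied dump yields no new mappings or
records.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from .records import (
    CrossRegistryMapping,
    ExternalRecord,
    Registry,
    RegistryMeta,
    ResourceRecord,
    norm_key,
    qa_errors,
)
from .standardize import PrefixIndex

__all__ = [
    "AlignmentError",
    "AlignmentResult",
    "Blocklist",
    "SkippedRecord",
    "align",
    "align_all",
    "apply_result",
    "build_lookup",
    "write_curation_sheet",
]

#: Column order of the curation sheet emitted for group-2 misses.
CURATION_COLUMNS = ("registry_key", "external_prefix", "name", "homepage", "example", "uri_format")


class AlignmentError(RuntimeError):
    """Alignment configuration or application failure."""


@dataclass(frozen=True)
class Blocklist:
    """Manually curated known-incorrect candidate mappings.

    Each entry is a (registry key, external prefix, registry prefix) triple
    naming a lookup hit that must *not* become a mapping.  Consulted only on
    hits: it suppresses false positives, it never creates mappings.
    """

    entries: frozenset[tuple[str, str, str]] = frozenset()

    def is_blocked(self, registry_key: str, external_prefix: str, prefix: str) -> bool:
        return (registry_key, external_prefix, prefix) in self.entries

    @classmethod
    def from_triples(cls, triples: Iterable[tuple[str, str, str]]) -> "Blocklist":
        return cls(frozenset(tuple(t) for t in triples))

    @classmethod
    def load(cls, path: str | Path) -> "Blocklist":
        """Load from a JSON list of [registry_key, external_prefix, prefix]."""
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls.from_triples(tuple(row) for row in data)


@dataclass(frozen=True)
class SkippedRecord:
    """A dump row not acted upon, with the reason why."""

    record: ExternalRecord
    reason: str  # already-mapped | blocklisted | group-3-unmatched


@dataclass
class AlignmentResult:
    """Outcome of aligning one external registry dump.

    The four lists partition the input dump: every row lands in exactly one
    of ``new_mappings`` (lookup hits), ``new_records`` (group-1 misses),
    ``curation_rows`` (group-2 misses), or ``skipped``.
    """

    registry_key: str
    new_mappings: list[CrossRegistryMapping] = field(default_factory=list)
    new_records: list[ResourceRecord] = field(default_factory=list)
    curation_rows: list[ExternalRecord] = field(default_factory=list)
    skipped: list[SkippedRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return (
            len(self.new_mappings)
            + len(self.new_records)
            + len(self.curation_rows)
            + len(self.skipped)
        )


def build_lookup(registry: Registry, exclude_registry: Optional[str] = None) -> PrefixIndex:
    """Build the alignment lookup table.

    Covers the canonical prefix, preferred prefix, and synonyms of every
    record — except records that already carry a mapping to
    ``exclude_registry``, which are removed so their keys cannot re-match
    (each record takes at most one external prefix per registry).

    Raises
    ------
    PrefixCollisionError
        On a key collision, naming both offending records.
    """
    records = [
        record
        for record in registry
        if exclude_registry is None or exclude_registry not in record.mappings
    ]
    return PrefixIndex.from_records(records)


def _synthesize_prefix(row: ExternalRecord, registry: Registry, index: PrefixIndex) -> str:
    """Canonical prefix for a new record from a group-1 miss.

    The normalized external prefix; suffixed with ``.<registry_key>`` if
    that key is taken, keeping synthesis deterministic and auditable.
    """
    base = norm_key(row.external_prefix)
    if base not in index and base not in registry:
        return base
    return f"{base}.{row.registry_key}"


def _synthesize_record(row: ExternalRecord, prefix: str) -> ResourceRecord:
    return ResourceRecord(
        prefix=prefix,
        name=row.name or row.external_prefix,
        homepage=row.homepage,
        description=row.name or f"Identifier resource imported from the "
        f"{row.registry_key} registry as {row.external_prefix!r}.",
        example=row.example,
        pattern=row.pattern,
        uri_format=row.uri_format,
        mappings={row.registry_key: row.external_prefix},
    )


def align(
    registry: Registry,
    meta: RegistryMeta,
    dump: list[ExternalRecord],
    blocklist: Optional[Blocklist] = None,
) -> AlignmentResult:
    """Align one external registry dump against the registry.

    Pure with respect to ``registry``: the result describes what *would*
    change; :func:`apply_result` commits it.

    Raises
    ------
    AlignmentError
        On rows not carrying ``meta.key`` or an unknown policy group.
    """
    if meta.policy_group not in (1, 2, 3):
        raise AlignmentError(
            f"registry {meta.key!r} has unknown policy group {meta.policy_group!r}"
        )
    blocklist = blocklist or Blocklist()
    index = build_lookup(registry, exclude_registry=meta.key)
    already_mapped = registry.mapped_external_prefixes(meta.key)
    result = AlignmentResult(registry_key=meta.key)
    claimed_prefixes: set[str] = set()  # registry records claimed this run
    claimed_external: set[str] = set()  # external prefixes seen this run
    synthesized: set[str] = set()

    for row in dump:
        if row.registry_key != meta.key:
            raise AlignmentError(
                f"dump row {row.external_prefix!r} carries registry key "
                f"{row.registry_key!r}, expected {meta.key!r}"
            )
        if row.external_prefix in already_mapped or row.external_prefix in claimed_external:
            result.skipped.append(SkippedRecord(row, "already-mapped"))
            continue
        try:
            key = norm_key(row.external_prefix)
        except ValueError:
            result.skipped.append(SkippedRecord(row, "group-3-unmatched"))
            continue
        hit = index.lookup.get(key)
        if hit is not None and blocklist.is_blocked(meta.key, row.external_prefix, hit):
            result.skipped.append(SkippedRecord(row, "blocklisted"))
            continue
        if hit is not None and hit in claimed_prefixes:
            # another row of this dump already claimed the record
            result.skipped.append(SkippedRecord(row, "already-mapped"))
            continue
        if hit is not None:
            result.new_mappings.append(
                CrossRegistryMapping(
                    prefix=hit,
                    registry_key=meta.key,
                    external_prefix=row.external_prefix,
                    provenance="automated",
                )
            )
            claimed_prefixes.add(hit)
            claimed_external.add(row.external_prefix)
            continue
        # miss: dispatch on the import policy group
        if meta.policy_group == 1:
            prefix = _synthesize_prefix(row, registry, index)
            if prefix in synthesized or prefix in registry:
                result.skipped.append(SkippedRecord(row, "already-mapped"))
                continue
            result.new_records.append(_synthesize_record(row, prefix))
            synthesized.add(prefix)
            claimed_external.add(row.external_prefix)
        elif meta.policy_group == 2:
            result.curation_rows.append(row)
        else:
            result.skipped.append(SkippedRecord(row, "group-3-unmatched"))

    assert len(result) == len(dump), "alignment result must partition the dump"
    return result


def write_curation_sheet(rows: Iterable[ExternalRecord], path: str | Path) -> None:
    """Write group-2 misses as a TSV curation sheet for manual review."""
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(CURATION_COLUMNS)
        for row in rows:
            writer.writerow(
                ["" if getattr(row, column) is None else getattr(row, column)
                 for column in CURATION_COLUMNS]
            )


def apply_result(
    registry: Registry,
    result: AlignmentResult,
    curation_sheet: Optional[str | Path] = None,
) -> Registry:
    """Merge an alignment result into the registry, all-or-nothing.

    Returns a new registry with the mappings and new records merged; the
    input registry is never mutated.  Quality assurance (including
    collision-free lookup construction) is re-run on the merged registry;
    any failure aborts with no partial state.  Group-2 curation rows are
    written to a TSV sidecar when ``curation_sheet`` is given.

    Raises
    ------
    AlignmentError
        If the merged registry fails quality assurance or the result is
        inconsistent with the current registry state.
    """
    merged = registry.copy()
    for record in result.new_records:
        if record.prefix in merged:
            existing = merged[record.prefix]
            if existing.mappings.get(result.registry_key) == record.mappings.get(
                result.registry_key
            ):
                continue  # re-application of the same result: no-op
            raise AlignmentError(
                f"new record {record.prefix!r} collides with an existing record"
            )
        merged.add_record(record.model_copy(deep=True))
        merged._provenance[(record.prefix, result.registry_key)] = "automated"
    for mapping in result.new_mappings:
        if mapping.prefix not in merged:
            raise AlignmentError(
                f"mapping target {mapping.prefix!r} is not in the registry"
            )
        existing = merged[mapping.prefix].mappings.get(mapping.registry_key)
        if existing == mapping.external_prefix:
            continue  # idempotent re-application
        if existing is not None:
            raise AlignmentError(
                f"record {mapping.prefix!r} already maps {mapping.registry_key!r} "
                f"to {existing!r}"
            )
        merged.set_mapping(
            mapping.prefix, mapping.registry_key, mapping.external_prefix, "automated"
        )
    errors = qa_errors(merged)
    if errors:
        raise AlignmentError(
            "merged registry fails quality assurance; aborting with no partial "
            "write: " + "; ".join(str(e) for e in errors[:5])
        )
    # the lookup must also still build collision-free
    build_lookup(merged)
    if curation_sheet is not None:
        write_curation_sheet(result.curation_rows, curation_sheet)
    return merged


def align_all(
    registry: Registry,
    dumps: dict[str, list[ExternalRecord]],
    blocklist: Optional[Blocklist] = None,
) -> tuple[Registry, list[AlignmentResult]]:
    """Sequentially align several registries in ``import_order``.

    Earlier registries win naming conflicts for synthesized records, since
    later synthesis sees the records they introduced.
    """
    results: list[AlignmentResult] = []
    metas = sorted(
        (registry.metas[key] for key in dumps), key=lambda m: m.import_order
    )
    current = registry
    for meta in metas:
        result = align(current, meta, dumps[meta.key], blocklist)
        current = apply_result(current, result)
        results.append(result)
    return current, results
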