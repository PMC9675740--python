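"""CURIE/URI standardization against the registry.

The same entity is referred to in the wild by many surface forms: the
Calmodulin-1 protein's UniProt entry appears under several distinct URIs
(first-party pages, PURLs, resolver redirects) and several CURIE spellings
(canonical ``uniprot:P0DP23``, cased variants, external-registry prefixes).
This module collapses that multiplicity onto canonical forms:

* :func:`norm_key` — casefold and strip punctuation so that ``go``/``GO``
  and ``ec-code``/``eccode`` share a lookup key (re-exported from
  :mod:`metaprefix.records`);
* :class:`PrefixIndex` — the injective lookup table from normalized keys to
  canonical prefixes, built from every record's canonical prefix, preferred
  prefix, and synonyms; construction fails loudly on collision;
* :func:`standardize_prefix` / :func:`standardize_curie` — map arbitrary
  prefixes and CURIEs to canonical form, including stripping redundantly
  embedded namespaces ("bananas", e.g. ``GO:GO:0006915``);
* :func:`validate_identifier` — full-match LUI pattern validation;
* :func:`curie_to_uri` / :func:`list_provider_uris` / :func:`parse_uri` —
  bit-exact URI construction from format strings, provider enumeration,
  and longest-prefix URI contraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

from .records import (
    PLACEHOLDER,
    Registry,
    ResourceRecord,
    norm_key,
)

__all__ = [
    "Curie",
    "CurieParseError",
    "PrefixCollisionError",
    "PrefixIndex",
    "UnresolvableError",
    "curie_forms",
    "curie_to_uri",
    "list_provider_uris",
    "norm_key",
    "parse_uri",
    "standardize_curie",
    "standardize_prefix",
    "validate_identifier",
]


class PrefixCollisionError(ValueError):
    """Two records claim the same normalized lookup key."""


class CurieParseError(ValueError):
    """Input string is not CURIE-shaped (no colon); distinct from an
    unknown prefix, which yields ``None``."""


class UnresolvableError(ValueError):
    """No URI format string is available to expand a CURIE."""


@dataclass(frozen=True)
class Curie:
    """A compact URI: canonical prefix plus local unique identifier."""

    prefix: str
    luid: str

    def __str__(self) -> str:
        return f"{self.prefix}:{self.luid}"

    def render(self, registry: Optional[Registry] = None, preferred: bool = False) -> str:
        """Render as a string; with ``preferred=True`` use the record's
        stylized prefix casing (e.g. ``GO:0006915``) when available.

        Canonical lowercase is the default output form; preferred-casing
        rendering is opt-in.
        """
        if preferred and registry is not None:
            record = registry.get(self.prefix)
            if record is not None and record.preferred_prefix:
                return f"{record.preferred_prefix}:{self.luid}"
        return str(self)


class PrefixIndex:
    """Injective lookup table: normalized key → canonical prefix.

    Built from the canonical prefix, preferred prefix, and all prefix
    synonyms of every record.  Keys of a single record may coincide after
    normalization (``eccode`` and its synonym ``ec-code``); a key claimed
    by two different records is a collision and construction fails,
    naming both offending records.
    """

    def __init__(self, lookup: Optional[dict[str, str]] = None) -> None:
        self.lookup: dict[str, str] = lookup or {}

    @classmethod
    def from_records(cls, records: Iterable[ResourceRecord]) -> "PrefixIndex":
        lookup: dict[str, str] = {}
        for record in records:
            candidates = [record.prefix] + record.synonyms
            if record.preferred_prefix:
                candidates.append(record.preferred_prefix)
            for candidate in candidates:
                try:
                    key = norm_key(candidate)
                except ValueError:
                    continue
                owner = lookup.get(key)
                if owner is not None and owner != record.prefix:
                    raise PrefixCollisionError(
                        f"lookup key {key!r} (from {candidate!r}) is claimed by both "
                        f"records {owner!r} and {record.prefix!r}"
                    )
                lookup[key] = record.prefix
        return cls(lookup)

    @classmethod
    def from_registry(cls, registry: Registry) -> "PrefixIndex":
        return cls.from_records(registry)

    def __len__(self) -> int:
        return len(self.lookup)

    def __contains__(self, key: str) -> bool:
        return key in self.lookup


def standardize_prefix(index: PrefixIndex, s: str) -> Optional[str]:
    """Map any prefix variant to its canonical prefix, or ``None``.

    Total: never raises; empty and unknown inputs return ``None``.
    """
    try:
        key = norm_key(s)
    except ValueError:
        return None
    return index.lookup.get(key)


def standardize_curie(index: PrefixIndex, registry: Registry, s: str) -> Optional[Curie]:
    """Standardize a CURIE string to canonical prefix + LUI.

    Splits on the *first* colon (LUIs may themselves contain colons).  If
    the LUI redundantly embeds the record's own namespace — a "banana" such
    as ``GO:GO:0006915`` — the embedded token is stripped exactly once, and
    only when it equals the canonical or preferred prefix case-insensitively,
    so LUIs that legitimately start with letters are never mangled.

    Returns ``None`` for an unrecognized prefix.

    Raises
    ------
    CurieParseError
        If ``s`` contains no colon at all.
    """
    if ":" not in s:
        raise CurieParseError(f"{s!r} is not a CURIE: missing ':' separator")
    raw_prefix, luid = s.split(":", 1)
    prefix = standardize_prefix(index, raw_prefix)
    if prefix is None:
        return None
    record = registry.get(prefix)
    if record is not None:
        bananas = {prefix.casefold()}
        if record.preferred_prefix:
            bananas.add(record.preferred_prefix.casefold())
        head, sep, tail = luid.partition(":")
        if sep and head.casefold() in bananas:
            luid = tail
    return Curie(prefix, luid)


def validate_identifier(registry: Registry, prefix: str, luid: str) -> bool:
    """Whether ``luid`` is a valid local identifier for ``prefix``.

    Full-match against the record's pattern; records lacking a pattern
    validate vacuously (see :func:`identifier_is_vacuous` to flag those).

    Raises
    ------
    KeyError
        If ``prefix`` is not a canonical prefix in the registry.
    """
    record = registry[prefix]
    return record.is_valid_identifier(luid)


def identifier_is_vacuous(registry: Registry, prefix: str) -> bool:
    """True when validation for ``prefix`` passes only because no pattern is
    curated — partial metadata, not positive evidence."""
    return registry[prefix].compiled_pattern() is None


def _expand(uri_format: str, luid: str) -> str:
    return uri_format.replace(PLACEHOLDER, luid, 1)


def curie_to_uri(
    registry: Registry, curie: Curie, provider: Optional[str] = None
) -> str:
    """Substitute the LUI into a URI format string (bit-exact).

    Uses the record's primary ``uri_format`` by default; ``provider``
    selects a specific provider by code.

    Raises
    ------
    UnresolvableError
        If no URI format string is available for the choice made.
    KeyError
        If the prefix is not in the registry.
    """
    record = registry[curie.prefix]
    if provider is not None:
        for p in record.providers:
            if p.code == provider:
                return _expand(p.uri_format, curie.luid)
        raise UnresolvableError(
            f"record {curie.prefix!r} has no provider with code {provider!r}"
        )
    if record.uri_format is not None:
        return _expand(record.uri_format, curie.luid)
    if record.providers:
        return _expand(record.providers[0].uri_format, curie.luid)
    raise UnresolvableError(f"record {curie.prefix!r} has no URI format string")


def list_provider_uris(registry: Registry, curie: Curie) -> list[tuple[str, str]]:
    """Construct one URI per provider, in the record's provider order.

    Duplicate URIs (two providers sharing one format string) are
    deduplicated with a warning; the first provider keeps the URI.
    """
    record = registry[curie.prefix]
    out: list[tuple[str, str]] = []
    seen: dict[str, str] = {}
    for provider in record.providers:
        uri = _expand(provider.uri_format, curie.luid)
        if uri in seen:
            warnings.warn(
                f"providers {seen[uri]!r} and {provider.code!r} of {curie.prefix!r} "
                f"construct the same URI {uri!r}; keeping the first",
                stacklevel=2,
            )
            continue
        seen[uri] = provider.code
        out.append((provider.code, uri))
    return out


def curie_forms(registry: Registry, curie: Curie) -> list[str]:
    """All distinct CURIE spellings for one entity known to the registry:
    the canonical form, the preferred-cased form, and one form per mapped
    external registry prefix.  Sorted, duplicates removed."""
    record = registry[curie.prefix]
    forms = {str(curie)}
    if record.preferred_prefix:
        forms.add(f"{record.preferred_prefix}:{curie.luid}")
    for external_prefix in record.mappings.values():
        forms.add(f"{external_prefix}:{curie.luid}")
    return sorted(forms)


def _uri_patterns(registry: Registry) -> list[tuple[str, str, str]]:
    """All (head, tail, prefix) URI templates over records and providers.

    Each URI format splits at the placeholder into a constant head and tail;
    a URI matches if it starts with head and ends with tail, the LUI being
    the remainder.
    """
    patterns: list[tuple[str, str, str]] = []
    for prefix in sorted(registry.records):
        record = registry.records[prefix]
        formats = []
        if record.uri_format is not None:
            formats.append(record.uri_format)
        formats.extend(p.uri_format for p in record.providers)
        for fmt in formats:
            if fmt.count(PLACEHOLDER) != 1:
                continue
            head, _, tail = fmt.partition(PLACEHOLDER)
            patterns.append((head, tail, prefix))
    return patterns


def parse_uri(registry: Registry, uri: str) -> Optional[Curie]:
    """Contract a URI to a CURIE by matching all known URI prefixes.

    Every record's primary URI format and every provider format is a
    candidate.  On multiple matches the longest URI prefix (head) wins;
    remaining ties break lexicographically by canonical prefix, for
    determinism.  Returns ``None`` when no template matches.
    """
    best: Optional[tuple[int, str, str]] = None  # (-len(head), prefix, luid)
    for head, tail, prefix in _uri_patterns(registry):
        if not uri.startswith(head) or not uri.endswith(tail):
            continue
        luid = uri[len(head) : len(uri) - len(tail) if tail else len(uri)]
        if not luid:
            continue
        candidate = (-len(head), prefix, luid)
        if best is None or candidate < best:
            best = candidate
    if best is None:
        return None
    return Curie(best[1], best[2])
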