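"""CURIE resolution and the registry health report.

:func:`resolve` computes the redirect target a resolver service would send a
CURIE to: it standardizes the input, validates the local identifier against
the record's pattern (a failure warns but does not block — resolution is URL
computation, not gatekeeping), and picks the highest-ranked available
provider, first-party before third-party before resolver by default.

:func:`health_check` produces the periodic report on which records'
homepages are still reachable and which URI format strings still resolve for
the record's example identifier.  The HTTP fetch function is injected by the
caller, so the report is computable from replayed or stubbed statuses and
the test suite never touches the network.  Redirects (3xx) count as
accessible; 4xx/5xx and raised connection errors do not.
"""

from __future__ import annotations

import datetime
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

from .records import Registry
from .standardize import (
    Curie,
    PrefixIndex,
    UnresolvableError,
    curie_to_uri,
    standardize_curie,
)

__all__ = [
    "HealthReport",
    "RecordHealth",
    "ResolutionError",
    "health_check",
    "resolve",
]

#: Default provider preference for resolution.
DEFAULT_PROVIDER_RANK = ("first-party", "third-party", "resolver")


class ResolutionError(ValueError):
    """The CURIE could not be standardized against the registry."""


def resolve(
    registry: Registry,
    curie_string: str,
    provider_rank: Sequence[str] = DEFAULT_PROVIDER_RANK,
    index: Optional[PrefixIndex] = None,
) -> str:
    """Compute the URL a resolver would redirect ``curie_string`` to.

    The record's primary ``uri_format`` counts as its leading first-party
    provider.  An identifier failing the record's pattern still resolves,
    with a warning attached.

    Raises
    ------
    ResolutionError
        If the prefix cannot be standardized.
    UnresolvableError
        If no provider in any ranked category has a URI format.
    """
    if index is None:
        index = PrefixIndex.from_registry(registry)
    curie = standardize_curie(index, registry, curie_string)
    if curie is None:
        raise ResolutionError(f"cannot standardize the prefix of {curie_string!r}")
    record = registry[curie.prefix]
    if not record.is_valid_identifier(curie.luid):
        warnings.warn(
            f"identifier {curie.luid!r} does not match the pattern "
            f"{record.pattern!r} of {curie.prefix!r}",
            stacklevel=2,
        )
    candidates: dict[str, list[str]] = {category: [] for category in provider_rank}
    if record.uri_format is not None and "first-party" in candidates:
        candidates["first-party"].append(record.uri_format)
    for provider in record.providers:
        if provider.category in candidates:
            candidates[provider.category].append(provider.uri_format)
    for category in provider_rank:
        if candidates[category]:
            return candidates[category][0].replace("$1", curie.luid, 1)
    raise UnresolvableError(
        f"record {curie.prefix!r} has no provider in categories {list(provider_rank)}"
    )


@dataclass(frozen=True)
class RecordHealth:
    """Health status of one record at one check time."""

    prefix: str
    homepage_ok: Optional[bool]  # None: no homepage to check
    uri_ok: Optional[bool]  # None: no example URI to check
    checked_at: str


@dataclass
class HealthReport:
    """Per-record statuses plus summary counts (a pure function of the
    per-record flags)."""

    statuses: list[RecordHealth] = field(default_factory=list)

    @property
    def summary(self) -> dict[str, int]:
        counts = {
            "records": len(self.statuses),
            "homepage_ok": 0,
            "homepage_failed": 0,
            "homepage_unchecked": 0,
            "uri_ok": 0,
            "uri_failed": 0,
            "uri_unchecked": 0,
        }
        for status in self.statuses:
            if status.homepage_ok is None:
                counts["homepage_unchecked"] += 1
            elif status.homepage_ok:
                counts["homepage_ok"] += 1
            else:
                counts["homepage_failed"] += 1
            if status.uri_ok is None:
                counts["uri_unchecked"] += 1
            elif status.uri_ok:
                counts["uri_ok"] += 1
            else:
                counts["uri_failed"] += 1
        return counts

    def to_markdown(self) -> str:
        """The detailed table: one color-coded row per record."""
        symbol = {True: "🟢", False: "🔴", None: "⚪"}
        lines = [
            "| prefix | homepage | example URI |",
            "| --- | --- | --- |",
        ]
        for status in self.statuses:
            lines.append(
                f"| {status.prefix} | {symbol[status.homepage_ok]} | "
                f"{symbol[status.uri_ok]} |"
            )
        return "\n".join(lines) + "\n"

    def to_dict(self) -> dict:
        return {
            "summary": self.summary,
            "records": [
                {
                    "prefix": s.prefix,
                    "homepage_ok": s.homepage_ok,
                    "uri_ok": s.uri_ok,
                    "checked_at": s.checked_at,
                }
                for s in self.statuses
            ],
        }


def _probe(fetch: Callable[[str], int], url: str) -> bool:
    """Accessible iff the fetch neither raises nor returns a 4xx/5xx status.

    3xx redirects count as accessible.
    """
    try:
        status = fetch(url)
    except Exception:
        return False
    return status < 400


def health_check(registry: Registry, fetch: Callable[[str], int]) -> HealthReport:
    """Run the health report with an injected ``fetch(url) -> status`` function.

    Failures are data, never exceptions: a raising fetch marks the URL as
    inaccessible (connection error).  The example-URI check uses the
    record's example identifier expanded through its primary URI format.
    """
    checked_at = datetime.datetime.now(datetime.timezone.utc).isoformat(timespec="seconds")
    report = HealthReport()
    for prefix in sorted(registry.records):
        record = registry.records[prefix]
        homepage_ok = _probe(fetch, record.homepage) if record.homepage else None
        uri_ok: Optional[bool] = None
        if record.example is not None:
            try:
                uri = curie_to_uri(registry, Curie(prefix, record.example))
            except UnresolvableError:
                uri = None
            if uri is not None:
                uri_ok = _probe(fetch, uri)
        report.statuses.append(RecordHealth(prefix, homepage_ok, uri_ok, checked_at))
    return report
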