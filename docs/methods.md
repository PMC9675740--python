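# Methods

## The standardization model

The toolkit treats prefix heterogeneity as a normalization problem. The
normalization key of a prefix-like string is its casefolded form with the
characters `-`, `_`, `.`, space, and `/` removed; this identifies exactly the
capitalization variants (`go` / `GO`) and punctuation variants (`ec-code` /
`eccode`) observed across registries, while leaving genuinely different
vocabulary (`intenz` vs `eccode`) and abbreviations (`fb` vs `flybase`) to
explicit curated synonyms. The prefix index is the map from normalization
keys of every record's canonical prefix, preferred prefix, and synonyms to
the canonical prefix. Its injectivity is the load-bearing invariant: quality
assurance rejects any registry state in which one key would point at two
records, and index construction fails loudly with both offending records
named. Keys of a *single* record may coincide (the synonym `ec-code`
normalizes to the record's own prefix `eccode`); that collapses harmlessly.

CURIE standardization splits on the first colon, because LUIs may themselves
contain colons. A redundant embedded namespace (a "banana", e.g.
`GO:GO:0006915`, a construction prescribed by some resolvers) is stripped at
most once and only when the embedded token equals the record's canonical or
preferred prefix case-insensitively — so `flybase:FBgn0011293` is never
mangled, and the doubly redundant `GO:GO:GO:0006915` standardizes to the LUI
`GO:0006915`, which pattern validation then correctly rejects.

LUI validation is anchored full-match: a pattern stored without `^`/`$` is
implicitly anchored, so partial matches never validate. Records without a
curated pattern validate vacuously but are flaggable
(`identifier_is_vacuous`), reflecting that many external registries carry
patterns only on some entries. Variant LUI spellings *within* a resource
(Enzyme Commission `1.4` vs `1.4.-.-` vs `1.4.*`) are deliberately not
repaired — they surface as pattern failures, nothing more.

URI handling is string-exact. Expansion substitutes the LUI for the single
`$1` placeholder. Contraction matches a URI against every record's primary
format and every provider format, split at the placeholder into a constant
head and tail; the longest head wins, with remaining ties broken
lexicographically by canonical prefix (records carry no import rank, so the
alphabetical rule is the deterministic tie-break at record level). Formats
whose placeholder is internal still contract (head + tail match) but are
ineligible for prefix-map contexts, where only a trailing placeholder yields
a usable URI prefix.

## Alignment

External registries are stratified into three import policy groups as
*configuration*, not inference — the criteria (metadata richness, biomedical
scope, focus on assigning global prefixes, governance) are editorial.
Alignment of one dump proceeds row by row: external prefixes already mapped
for that registry are skipped; otherwise the normalized external prefix is
looked up in an index built *excluding* records already mapped to that
registry (each record takes at most one external prefix per registry). Hits
become automated mappings unless suppressed by the blocklist of curated
known-incorrect matches; the blocklist only suppresses, it never creates.
Misses dispatch by group: 1 → a new record synthesized from the row's
metadata, 2 → a curation-sheet row, 3 → silent skip. The result partitions
the dump exactly (asserted at run time).

New-record prefixes are the normalized external prefix, suffixed with
`.<registry_key>` on collision — a deterministic, auditable rule.
Synthesized records fall back to the external prefix as name and an
"imported from" description so they carry the minimum identifying metadata;
a missing homepage is a warning, not an error, mirroring the capability
gaps of real registries. Application is all-or-nothing: mappings and records
are merged into a copy, quality assurance (including collision-free index
construction) re-runs, and any failure aborts with the original registry
untouched. Registries are processed sequentially in `import_order`, so
earlier registries win naming conflicts for synthesized records. Overriding
an automated mapping requires blocklisting it and re-running; alignment
never silently replaces an existing mapping.

Validation severity is two-level by design: structural invariants (prefix
shape, synonym collisions, pattern/example mismatch, placeholder counts,
`replaced_by` without deprecation, malformed ORCIDs) are errors and gate
alignment and export; incomplete metadata (missing name, description, or
homepage) is reported as warnings, because externally imported content is
incomplete by nature and blocking on it would make group-1 import unusable.

## Exports

All exporters are deterministic: sorted record and mapping order, fixed
column order, and fixed vocabulary bindings make repeated exports
byte-identical (the SSSOM `mapping_date` must be pinned by the caller for
byte-identity across days). SSSOM rows use `skos:exactMatch` as the
equivalence predicate with `semapv:ManualMappingCuration` /
`semapv:LexicalMatching` justifications for curated vs automated provenance
— the mapping-format standard names no bindings, so these are package
choices. The RDF schema is deliberately minimal: records are typed
`schema:Resource` with `rdfs:label`, `dcterms:description`,
`foaf:homepage`, pattern/example/URI-format literals, `skos:altLabel`
synonyms, `dcterms:isReplacedBy`, `schema:dependsOn`, and `skos:exactMatch`
edges into per-registry namespaces; collections are `schema:Collection`
with `schema:hasMember`. Context profiles: `full` emits every eligible
record under its canonical lowercase prefix; `obo` restricts to records
mapped to the OBO Foundry and uses preferred (stylized) casing; `semweb`
follows a curated collection. Deprecated records and non-terminal
placeholders are excluded; URI-prefix value collisions keep the first
record in sorted order with a logged drop (or raise in strict mode).

## Resolution and health

Resolution is URL computation, not serving: the default provider ranking is
first-party > third-party > resolver, with the record's primary URI format
acting as the leading first-party provider. A pattern-invalid LUI still
resolves, with a warning — resolvers in practice must handle sloppy input.
The health check takes an injected `fetch(url) -> status` callable; 2xx and
3xx count as accessible, 4xx/5xx and raised connection errors do not, and
failures are data, never exceptions. Timeouts and retries are the injected
fetcher's concern; the test suite only ever uses stubs.

## The synthetic-fixture generator

The generator emulates the heterogeneity the alignment algorithm must
invert, not the statistics of real registry growth. Ground-truth registries
are built from biologically flavored syllable compounds, rejection-sampled
so that every prefix and synonym is globally unique under the normalization
key — collision-free by construction. Each record carries a numeric LUI
pattern of width 4–8 with a matching example and a record-unique URI format,
so URI round-trips are exact.

Dumps are derived per registry: each truth record is emitted with
probability `1 − novel_rate` under a prefix perturbed by, in order, curated
synonym swap, punctuation insertion (1–2 characters from `-_.` at interior
positions), and case mangling (upper/capitalize/swapcase, falling back to
upper-case so the surface form always changes). Punctuation and casing
preserve the normalization key by construction, and synonym swaps stay in
the lookup table, so alignment must recover the planted map with precision
and recall exactly 1.0 — this is a designed invariant, not a tuned outcome.
`⌈novel_rate · n⌉` out-of-vocabulary rows (rejection-sampled disjoint from
all truth keys) are appended with no planted counterpart; per-field dropout
probabilities emulate registries whose schemas carry a field only on some
entries. A single integer seed drives one `random.Random` stream with a
documented draw order (records in sorted prefix order: inclusion, synonym,
punctuation, casing, then field dropout in fixed field order; novel rows
last), so all counts are reproducible.

What passing these tests does *not* show: real registries contain records
that are not identifier resources at all, semantic near-misses (two distinct
resources with plausibly swappable names), and vocabulary variants absent
from any curated synonym list. Those require human curation; on such inputs
the algorithm's guarantee degrades from "perfect recovery" to "no wrong
mappings beyond lookup-table semantics, everything else channelled to
curation".

## Problem sizes and defaults

The demonstration registry holds 10 records, 7 registry descriptors, and 12
cross-registry mappings — large enough to exercise every code path
(deprecation, bananas, synonym fans, provider categories, collections).
Synthetic checks use 200-record registries with 2 synonyms each for
alignment recovery (10 seeds), 1,000 records for URI round-tripping, and
perturbation rates of 0.5–0.7 for casing/punctuation with a 20% novel-row
rate — rates high enough that essentially every dump row is perturbed while
keeping rejection sampling far from the ~28,000-compound name space. The
UniProt provider fixture in the demonstration registry is a synthetic
reconstruction of that resource's publicly known URL schemes, used as demo
and test data only.

## Known limitations

* Alignment matches on normalized-key equality only; no fuzzy or semantic
  matching, by design — ambiguity belongs in the curation sheet.
* The `proprietary` flag is stored but does not affect export filtering;
  its downstream semantics are unspecified.
* Deprecated records are required to carry only prefix, name, and
  description; their homepages are not demanded.
* RDF export uses a minimal term set; consumers needing richer provenance
  should join against the JSON root data.
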