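# metaprefix

A metaregistry toolkit for biomedical identifier resources.

Life-science entities — chemicals, proteins, taxa, publications — are curated
in identifier resources (ChEBI, UniProt, NCBI Taxonomy, PubMed, ...), each of
which assigns a *local unique identifier* (LUI) such as `P0DP23`. In the wild
the same entity is written as many different URIs and CURIEs: the prefix for
the NCBI Taxonomy alone appears as `taxonomy`, `NCBITAXON`, `NCBITaxon`,
`NCBI_taxid`, ... across registries and ontology cross-references, and a single
UniProt entry is reachable through first-party pages, PURLs, and several
resolver URL schemes. `metaprefix` is a toolkit for collapsing that
multiplicity onto canonical forms and for maintaining the registry that makes
it possible. It is aimed at curators of prefix registries and at developers of
knowledge-graph, ontology, and text-mining pipelines who need deterministic
CURIE/URI handling.

## What it does

* **Registry data model** — validated records for identifier resources
  (canonical prefix, synonyms, LUI regular-expression `pattern`, example LUI,
  URI format strings with a `$1` placeholder, providers, deprecation,
  attribution), with record-level validation and registry-level quality
  assurance. Curated metadata always wins over imported metadata, field-wise.
* **Standardization engine** — every prefix variant is reduced by the
  normalization key `norm_key(s)` (casefold, strip `-_. /`), and an injective
  lookup table maps keys to canonical prefixes; construction fails loudly on
  collision. CURIEs split on the first colon and redundant embedded namespaces
  (`GO:GO:0006915`) are stripped exactly once. URIs are built by bit-exact
  substitution of the LUI into a format string and contracted back by
  longest-URI-prefix matching.
* **Alignment** — external-registry dumps are matched against the lookup
  table; hits become automated cross-registry equivalence mappings, misses are
  dispatched by the registry's import policy group (1: synthesize a new
  record, 2: emit a curation sheet, 3: drop silently), and a curated blocklist
  suppresses known-incorrect matches. The run partitions the dump exactly and
  is idempotent.
* **Exports** — deterministic TSV/YAML tables, SSSOM mapping sets
  (`skos:exactMatch` rows with a `# `-prefixed YAML header), JSON-LD
  prefix-map contexts (`full`/`obo`/`semweb` profiles), and RDF
  (N-Triples/Turtle/JSON-LD with identical triple sets).
* **Resolution & health** — CURIE-to-URL resolution ranked first-party >
  third-party > resolver, and a health report over homepages and example URIs
  driven by an injected fetch function (no live network required).
* **Synthetic fixtures** — seeded generators for ground-truth registries and
  perturbed dumps with planted equivalences, so alignment precision/recall is
  measurable without downloading anything.

## Worked example

```python
from metaprefix import (
    Curie, PrefixIndex, example_registry,
    standardize_curie, standardize_prefix,
    list_provider_uris, curie_forms, curie_to_uri, parse_uri,
)

registry = example_registry()
index = PrefixIndex.from_registry(registry)

print(standardize_curie(index, registry, "GO:GO:0006915"))
# go:0006915            <- redundant namespace stripped, prefix canonicalized
print(standardize_prefix(index, "NCBI_taxid"))
# ncbitaxon             <- synonym resolved via the normalized lookup table

entry = Curie("uniprot", "P0DP23")
for code, uri in list_provider_uris(registry, entry):
    print(code, uri)
# uniprot https://www.uniprot.org/uniprot/P0DP23
# purl https://purl.uniprot.org/uniprot/P0DP23
# legacy http://www.uniprot.org/uniprot/P0DP23
# alphafold https://www.alphafold.ebi.ac.uk/entry/P0DP23
# miriam https://identifiers.org/uniprot:P0DP23
# miriam.legacy https://identifiers.org/uniprot/P0DP23
# n2t https://n2t.net/uniprot:P0DP23
print(curie_forms(registry, entry))
# ['UniProt:P0DP23', 'uniprot:P0DP23', 'uniprotkb:P0DP23']

print(parse_uri(registry, curie_to_uri(registry, entry)))
# uniprot:P0DP23        <- contraction inverts expansion exactly
```

Seven distinct URIs and three distinct CURIE spellings for one protein entry
is precisely the interoperability problem the lookup table solves: all of them
standardize back to `uniprot:P0DP23`.

The same functionality is available from the shell:

```bash
metaprefix standardize GO:GO:0006915          # -> go:0006915
metaprefix expand uniprot:P0DP23              # -> https://www.uniprot.org/uniprot/P0DP23
metaprefix contract https://identifiers.org/uniprot:P0DP23
metaprefix export context --out context.jsonld
metaprefix fixtures generate --n 50 --seed 1 --out scratch/fixtures
```

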