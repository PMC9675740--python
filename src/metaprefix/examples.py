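"""A small curated demonstration registry.

Covers well-known identifier resources whose prefix heterogeneity motivates
standardization: UniProt (whose entry P0DP23 is reachable through many
distinct provider URIs and CURIE spellings), the Gene Ontology (redundant
``GO:GO:...`` CURIEs), ChEBI (OBO PURLs), the NCBI Taxonomy (ten-plus
prefix variants across registries: ``taxonomy``, ``NCBITAXON``,
``NCBI_taxid``, ...), the Enzyme Commission resource (``ec-code`` vs ``EC``
vs ``intenz``), FlyBase (abbreviated ``fb``), PubMed, and the deprecated
HGNC gene-family resource replaced by hgnc.genegroup.

The UniProt provider list is a synthetic reconstruction of the publicly
known URL schemes for that entry (first-party site and PURL, a third-party
structure browser, and the identifiers.org/N2T/metaregistry resolver
styles); it is test/demo data, not a redistribution of any registry.

Registry descriptors model a representative slice of external registries
with their import policy groups: group 1 (rich metadata, global-prefix
focus: identifiers.org-like ``miriam``, ``obofoundry``, ``ols``, ``n2t``),
group 2 (partially relevant or under-specified: ``bioportal``, ``go``,
``ncbi``, ``uniprot``), and group 3 (minimal metadata: ``prefixcc``).
"""

from __future__ import annotations

from .records import (
    Attribution,
    Collection,
    Provider,
    Registry,
    RegistryMeta,
    ResourceRecord,
)

__all__ = ["example_registry"]


def _uniprot() -> ResourceRecord:
    return ResourceRecord(
        prefix="uniprot",
        preferred_prefix="UniProt",
        name="UniProt Knowledgebase",
        homepage="https://www.uniprot.org",
        description="Comprehensive resource of protein sequence and functional information.",
        synonyms=["uniprotkb", "SwissProt", "UP"],
        pattern=r"^[A-Z][0-9][A-Z0-9]{3}[0-9]$",
        example="P0DP23",
        uri_format="https://www.uniprot.org/uniprot/$1",
        providers=[
            Provider(
                code="uniprot",
                name="UniProt website",
                uri_format="https://www.uniprot.org/uniprot/$1",
                category="first-party",
            ),
            Provider(
                code="purl",
                name="UniProt PURL",
                uri_format="https://purl.uniprot.org/uniprot/$1",
                category="first-party",
            ),
            Provider(
                code="legacy",
                name="UniProt legacy entry page",
                uri_format="http://www.uniprot.org/uniprot/$1",
                category="first-party",
            ),
            Provider(
                code="alphafold",
                name="AlphaFold structure browser",
                uri_format="https://www.alphafold.ebi.ac.uk/entry/$1",
                category="third-party",
            ),
            Provider(
                code="miriam",
                name="identifiers.org (CURIE style)",
                uri_format="https://identifiers.org/uniprot:$1",
                category="resolver",
            ),
            Provider(
                code="miriam.legacy",
                name="identifiers.org (path style)",
                uri_format="https://identifiers.org/uniprot/$1",
                category="resolver",
            ),
            Provider(
                code="n2t",
                name="Name-to-Thing",
                uri_format="https://n2t.net/uniprot:$1",
                category="resolver",
            ),
        ],
        mappings={"miriam": "uniprot", "n2t": "uniprot", "prefixcommons": "uniprotkb"},
        contributor=Attribution(name="Example Curator", orcid="0000-0002-1825-0097"),
        license="CC BY 4.0",
    )


def example_registry() -> Registry:
    """Build the demonstration registry (records, registry descriptors,
    and one Semantic Web collection)."""
    records = [
        _uniprot(),
        ResourceRecord(
            prefix="go",
            preferred_prefix="GO",
            name="Gene Ontology",
            homepage="http://geneontology.org",
            description="Structured vocabulary of gene and gene-product attributes.",
            synonyms=["gocc", "gobp", "gomf"],
            pattern=r"^\d{7}$",
            example="0006915",
            uri_format="http://purl.obolibrary.org/obo/GO_$1",
            providers=[
                Provider(
                    code="obo",
                    uri_format="http://purl.obolibrary.org/obo/GO_$1",
                    category="first-party",
                ),
                Provider(
                    code="amigo",
                    uri_format="http://amigo.geneontology.org/amigo/term/GO:$1",
                    category="first-party",
                ),
            ],
            depends_on=["chebi"],
            mappings={"obofoundry": "GO", "miriam": "go", "bioportal": "GO"},
        ),
        ResourceRecord(
            prefix="chebi",
            preferred_prefix="CHEBI",
            name="Chemical Entities of Biological Interest",
            homepage="https://www.ebi.ac.uk/chebi",
            description="Dictionary of molecular entities focused on small chemical compounds.",
            pattern=r"^\d+$",
            example="15377",
            uri_format="http://purl.obolibrary.org/obo/CHEBI_$1",
            mappings={"obofoundry": "CHEBI", "miriam": "chebi"},
        ),
        ResourceRecord(
            prefix="ncbitaxon",
            preferred_prefix="NCBITaxon",
            name="NCBI Taxonomy",
            homepage="https://www.ncbi.nlm.nih.gov/taxonomy",
            description="Curated classification and nomenclature for all organisms.",
            synonyms=[
                "taxonomy",
                "taxon",
                "NCBI_taxid",
                "NCBI_Taxon_id",
                "uniprot.taxonomy",
                "taxid",
            ],
            pattern=r"^\d+$",
            example="9606",
            uri_format="https://www.ncbi.nlm.nih.gov/Taxonomy/Browser/wwwtax.cgi?id=$1",
            providers=[
                Provider(
                    code="ncbi",
                    uri_format="https://www.ncbi.nlm.nih.gov/Taxonomy/Browser/wwwtax.cgi?id=$1",
                    category="first-party",
                ),
                Provider(
                    code="obo",
                    uri_format="http://purl.obolibrary.org/obo/NCBITaxon_$1",
                    category="third-party",
                ),
                Provider(
                    code="resolver",
                    uri_format="https://resolver.example.org/ncbitaxon:$1",
                    category="resolver",
                ),
            ],
            mappings={"miriam": "taxonomy", "obofoundry": "NCBITaxon", "bioportal": "NCBITAXON"},
        ),
        ResourceRecord(
            prefix="eccode",
            preferred_prefix="EC",
            name="Enzyme Commission Classification",
            homepage="https://www.enzyme-database.org",
            description="Numerical classification scheme for enzyme-catalysed reactions.",
            synonyms=["ec-code", "ec", "intenz", "enzyme"],
            example="1.1.1.1",
            pattern=r"^\d+(\.\d+){0,3}(\.(-|\d+|n\d+)){0,3}$",
            uri_format="https://www.enzyme-database.org/query.php?ec=$1",
            mappings={"miriam": "ec-code"},
        ),
        ResourceRecord(
            prefix="flybase",
            preferred_prefix="FlyBase",
            name="FlyBase",
            homepage="https://flybase.org",
            description="Database of Drosophila genes and genomes.",
            synonyms=["fb"],
            pattern=r"^FBgn\d{7}$",
            example="FBgn0011293",
            uri_format="https://flybase.org/reports/$1",
        ),
        ResourceRecord(
            prefix="pubmed",
            name="PubMed",
            homepage="https://pubmed.ncbi.nlm.nih.gov",
            description="Citations for biomedical literature.",
            synonyms=["PMID"],
            pattern=r"^\d+$",
            example="29175850",
            uri_format="https://pubmed.ncbi.nlm.nih.gov/$1",
        ),
        ResourceRecord(
            prefix="hgnc.genegroup",
            name="HGNC Gene Groups",
            homepage="https://www.genenames.org",
            description="Gene group resource of the HUGO Gene Nomenclature Committee.",
            pattern=r"^\d+$",
            example="423",
            uri_format="https://www.genenames.org/data/genegroup/#!/group/$1",
        ),
        ResourceRecord(
            prefix="hgnc.genefamily",
            name="HGNC Gene Families",
            description="Predecessor of the HGNC gene-group resource; never archived.",
            deprecated=True,
            replaced_by="hgnc.genegroup",
            pattern=r"^\d+$",
            example="423",
            uri_format="https://www.genenames.org/cgi-bin/genefamilies/set/$1",
        ),
        ResourceRecord(
            prefix="foaf",
            preferred_prefix="FOAF",
            name="Friend of a Friend",
            homepage="http://xmlns.com/foaf/spec/",
            description="Vocabulary for describing people and social networks.",
            example="Person",
            uri_format="http://xmlns.com/foaf/0.1/$1",
        ),
    ]
    metas = [
        RegistryMeta(
            key="miriam",
            name="Identifiers.org",
            homepage="https://identifiers.org",
            capabilities={
                "has_name": True,
                "has_homepage": True,
                "has_description": True,
                "has_example": True,
                "has_pattern": True,
                "has_provider": True,
                "has_license": False,
                "has_version": False,
            },
            policy_group=1,
            import_order=0,
        ),
        RegistryMeta(
            key="obofoundry",
            name="OBO Foundry",
            homepage="https://obofoundry.org",
            capabilities={
                "has_name": True,
                "has_homepage": True,
                "has_description": True,
                "has_example": False,
                "has_pattern": False,
                "has_provider": True,
                "has_license": True,
                "has_version": False,
            },
            policy_group=1,
            import_order=1,
        ),
        RegistryMeta(
            key="ols",
            name="Ontology Lookup Service",
            homepage="https://www.ebi.ac.uk/ols",
            capabilities={"has_name": True, "has_homepage": False, "has_description": True},
            policy_group=1,
            import_order=2,
        ),
        RegistryMeta(
            key="n2t",
            name="Name-to-Thing",
            homepage="https://n2t.net",
            capabilities={"has_name": True, "has_homepage": True, "has_provider": True},
            policy_group=1,
            import_order=3,
        ),
        RegistryMeta(
            key="bioportal",
            name="BioPortal",
            homepage="https://bioportal.bioontology.org",
            capabilities={"has_name": True, "has_homepage": False, "has_description": True},
            policy_group=2,
            import_order=4,
        ),
        RegistryMeta(
            key="prefixcommons",
            name="Prefix Commons",
            homepage="https://prefixcommons.org",
            capabilities={"has_name": True, "has_homepage": True},
            policy_group=2,
            import_order=5,
        ),
        RegistryMeta(
            key="prefixcc",
            name="prefix.cc",
            homepage="https://prefix.cc",
            capabilities={"has_name": False, "has_homepage": False},
            policy_group=3,
            import_order=6,
        ),
    ]
    collections = [
        Collection(
            identifier="0000002",
            name="Semantic Web prefixes",
            description="Prefixes useful for general Semantic Web resources.",
            members=["foaf"],
        )
    ]
    return Registry(records, metas, collections)
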