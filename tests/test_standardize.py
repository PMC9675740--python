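"""Prefix/CURIE normalization, URI expansion and contraction."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from metaprefix import (
    Curie,
    CurieParseError,
    PrefixCollisionError,
    PrefixIndex,
    Provider,
    Registry,
    ResourceRecord,
    UnresolvableError,
    curie_to_uri,
    list_provider_uris,
    norm_key,
    parse_uri,
    standardize_curie,
    standardize_prefix,
    validate_identifier,
)


class TestNormKey:
    @pytest.mark.parametrize(
        "raw, key",
        [
            ("ec-code", "eccode"),
            ("GO", "go"),
            ("NCBITaxon", "ncbitaxon"),
            ("NCBI_Taxon_id", "ncbitaxonid"),
            ("uniprot.taxonomy", "uniprottaxonomy"),
            ("hgnc genefamily", "hgncgenefamily"),
        ],
    )
    def test_casing_and_punctuation_collapse(self, raw, key):
        assert norm_key(raw) == key

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            norm_key("")
        with pytest.raises(ValueError):
            norm_key("-_.")

    @given(st.text(alphabet="abcdefgh-_. /XYZ", min_size=1).filter(
        lambda s: any(c.isalnum() for c in s)))
    def test_idempotent_and_invariant_under_its_own_transformations(self, s):
        key = norm_key(s)
        assert norm_key(key) == key
        assert norm_key(s.upper()) == key
        assert norm_key(s.replace("a", "a-")) == key


class TestPrefixIndex:
    def test_collision_fails_loudly_naming_both_records(self):
        records = [
            ResourceRecord(prefix="one", synonyms=["taxon"]),
            ResourceRecord(prefix="two", synonyms=["TAX-ON"]),
        ]
        with pytest.raises(PrefixCollisionError) as excinfo:
            PrefixIndex.from_records(records)
        assert "one" in str(excinfo.value) and "two" in str(excinfo.value)

    def test_own_key_coincidence_is_not_a_collision(self):
        records = [ResourceRecord(prefix="eccode", preferred_prefix="EC-code")]
        index = PrefixIndex.from_records(records)
        assert index.lookup["eccode"] == "eccode"


class TestStandardizePrefix:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("taxonomy", "ncbitaxon"),
            ("NCBITAXON", "ncbitaxon"),
            ("NCBI_taxid", "ncbitaxon"),
            ("ncbitaxon", "ncbitaxon"),
            ("ec-code", "eccode"),
            ("EC", "eccode"),
            ("intenz", "eccode"),
            ("fb", "flybase"),
            ("zz-unknown", None),
            ("", None),
        ],
    )
    def test_variants_map_to_canonical(self, index, raw, expected):
        assert standardize_prefix(index, raw) == expected

    def test_agrees_with_its_own_normalization(self, index):
        for raw in ("GO", "Ec-Code", "TAXONOMY", "FlyBase"):
            assert standardize_prefix(index, raw) == standardize_prefix(index, norm_key(raw))


class TestStandardizeCurie:
    @pytest.mark.parametrize(
        "raw, prefix, luid",
        [
            ("GO:GO:0006915", "go", "0006915"),  # redundant namespace stripped once
            ("uniprot:P0DP23", "uniprot", "P0DP23"),
            ("TAXONOMY:12345", "ncbitaxon", "12345"),
            ("go:0006915", "go", "0006915"),
            ("EC:1.1.1.1", "eccode", "1.1.1.1"),
        ],
    )
    def test_examples(self, index, registry, raw, prefix, luid):
        assert standardize_curie(index, registry, raw) == Curie(prefix, luid)

    def test_unknown_prefix_yields_none(self, index, registry):
        assert standardize_curie(index, registry, "zz-unknown:123") is None

    def test_missing_colon_is_a_parse_error(self, index, registry):
        with pytest.raises(CurieParseError):
            standardize_curie(index, registry, "not a curie")

    def test_banana_stripped_at_most_once(self, index, registry):
        curie = standardize_curie(index, registry, "GO:GO:GO:0006915")
        assert curie == Curie("go", "GO:0006915")

    def test_luid_starting_with_letters_is_not_mangled(self, index, registry):
        curie = standardize_curie(index, registry, "flybase:FBgn0011293")
        assert curie == Curie("flybase", "FBgn0011293")

    def test_idempotent_on_rendered_output(self, index, registry):
        for raw in ("GO:GO:0006915", "TAXONOMY:12345", "uniprot:P0DP23"):
            once = standardize_curie(index, registry, raw)
            again = standardize_curie(index, registry, str(once))
            assert again == once


class TestValidateIdentifier:
    @pytest.mark.parametrize(
        "prefix, luid, ok",
        [
            ("pubmed", "29175850", True),
            ("go", "0006915", True),
            ("go", "GO:0006915", False),  # unstandardized form fails full match
            ("uniprot", "P0DP23", True),
            ("uniprot", "not an id", False),
        ],
    )
    def test_full_match_against_pattern(self, registry, prefix, luid, ok):
        assert validate_identifier(registry, prefix, luid) is ok

    def test_patternless_record_passes_vacuously(self, registry):
        from metaprefix.standardize import identifier_is_vacuous

        assert validate_identifier(registry, "foaf", "anything") is True
        assert identifier_is_vacuous(registry, "foaf") is True
        assert identifier_is_vacuous(registry, "go") is False

    def test_unknown_prefix_is_a_key_error(self, registry):
        with pytest.raises(KeyError):
            validate_identifier(registry, "zz-unknown", "1")


class TestCurieToUri:
    def test_primary_format(self, registry):
        assert (
            curie_to_uri(registry, Curie("uniprot", "P0DP23"))
            == "https://www.uniprot.org/uniprot/P0DP23"
        )

    def test_obo_purl_substitution_is_bit_exact(self, registry):
        assert (
            curie_to_uri(registry, Curie("chebi", "1234"))
            == "http://purl.obolibrary.org/obo/CHEBI_1234"
        )

    def test_resolver_provider_selected_by_code(self, registry):
        assert (
            curie_to_uri(registry, Curie("ncbitaxon", "9606"), provider="resolver")
            == "https://resolver.example.org/ncbitaxon:9606"
        )

    def test_no_format_is_unresolvable(self):
        registry = Registry([ResourceRecord(prefix="bare")])
        with pytest.raises(UnresolvableError):
            curie_to_uri(registry, Curie("bare", "1"))


class TestListProviderUris:
    def test_uniprot_entry_has_at_least_seven_distinct_uris(self, registry):
        uris = list_provider_uris(registry, Curie("uniprot", "P0DP23"))
        values = [uri for _, uri in uris]
        assert len(values) == len(set(values)) >= 7

    def test_zero_providers_gives_empty_list(self, registry):
        assert list_provider_uris(registry, Curie("chebi", "1234")) == []

    def test_shared_format_deduplicated_with_warning(self):
        record = ResourceRecord(
            prefix="dup",
            providers=[
                Provider(code="a", uri_format="https://e.org/$1"),
                Provider(code="b", uri_format="https://e.org/$1"),
            ],
        )
        registry = Registry([record])
        with pytest.warns(UserWarning):
            uris = list_provider_uris(registry, Curie("dup", "1"))
        assert uris == [("a", "https://e.org/1")]


class TestParseUri:
    @pytest.mark.parametrize(
        "uri, prefix, luid",
        [
            ("https://www.uniprot.org/uniprot/P0DP23", "uniprot", "P0DP23"),
            ("http://purl.obolibrary.org/obo/CHEBI_1234", "chebi", "1234"),
            ("http://purl.obolibrary.org/obo/NCBITaxon_9606", "ncbitaxon", "9606"),
            ("https://pubmed.ncbi.nlm.nih.gov/29175850", "pubmed", "29175850"),
        ],
    )
    def test_contraction(self, registry, uri, prefix, luid):
        assert parse_uri(registry, uri) == Curie(prefix, luid)

    def test_no_match_yields_none(self, registry):
        assert parse_uri(registry, "https://nothing.example.net/1") is None

    def test_longest_uri_prefix_wins(self):
        registry = Registry(
            [
                ResourceRecord(prefix="outer", uri_format="https://e.org/$1"),
                ResourceRecord(prefix="inner", uri_format="https://e.org/sub/$1"),
            ]
        )
        assert parse_uri(registry, "https://e.org/sub/42") == Curie("inner", "42")
        assert parse_uri(registry, "https://e.org/other/42") == Curie("outer", "other/42")

    def test_equal_length_tie_breaks_lexicographically(self):
        registry = Registry(
            [
                ResourceRecord(prefix="beta", uri_format="https://tie.org/$1"),
                ResourceRecord(prefix="alpha", uri_format="https://tie.org/$1"),
            ]
        )
        assert parse_uri(registry, "https://tie.org/7") == Curie("alpha", "7")

    def test_round_trip_with_expansion(self, index, registry):
        for raw in ("uniprot:P0DP23", "chebi:15377", "pubmed:29175850"):
            curie = standardize_curie(index, registry, raw)
            assert parse_uri(registry, curie_to_uri(registry, curie)) == curie
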