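"""The registry alignment algorithm: lookup, dispatch, application."""

import pytest

from metaprefix import (
    AlignmentError,
    Blocklist,
    ExternalRecord,
    PrefixCollisionError,
    Registry,
    RegistryMeta,
    ResourceRecord,
    align,
    align_all,
    apply_result,
    build_lookup,
)


def _row(key: str, ext: str, **kwargs) -> ExternalRecord:
    return ExternalRecord(registry_key=key, external_prefix=ext, **kwargs)


@pytest.fixture
def meta1():
    return RegistryMeta(key="extreg", policy_group=1, import_order=10)


@pytest.fixture
def meta2():
    return RegistryMeta(key="extreg", policy_group=2, import_order=10)


class TestBuildLookup:
    def test_records_mapped_to_excluded_registry_are_removed(self):
        registry = Registry(
            [
                ResourceRecord(prefix="a", mappings={"olsx": "A"}),
                ResourceRecord(prefix="b"),
                ResourceRecord(prefix="c"),
            ]
        )
        index = build_lookup(registry, exclude_registry="olsx")
        assert "a" not in index and "b" in index and "c" in index

    def test_planted_collision_raises(self):
        registry = Registry(
            [
                ResourceRecord(prefix="x", synonyms=["taxon"]),
                ResourceRecord(prefix="y", synonyms=["TAXON"]),
            ]
        )
        with pytest.raises(PrefixCollisionError):
            build_lookup(registry)

    def test_empty_registry_gives_empty_index(self):
        assert len(build_lookup(Registry())) == 0


class TestAlign:
    def test_synonym_abbreviation_and_vocabulary_variants_map(self, registry, meta1):
        dump = [
            _row("extreg", "FlyBase"),
            _row("extreg", "intenz"),
            _row("extreg", "NCBI-Taxon"),
        ]
        result = align(registry, meta1, dump)
        assert {(m.prefix, m.external_prefix) for m in result.new_mappings} == {
            ("flybase", "FlyBase"),
            ("eccode", "intenz"),
            ("ncbitaxon", "NCBI-Taxon"),
        }
        assert all(m.provenance == "automated" for m in result.new_mappings)

    def test_already_mapped_external_prefix_is_skipped(self, registry, meta1):
        # uniprot already maps miriam->uniprot; a miriam dump must not remap it
        meta = RegistryMeta(key="miriam", policy_group=1, import_order=99)
        result = align(registry, meta, [_row("miriam", "uniprot")])
        assert result.new_mappings == [] and result.new_records == []
        assert result.skipped[0].reason == "already-mapped"

    def test_group1_miss_synthesizes_a_new_record(self, registry, meta1):
        row = _row("extreg", "NovelDB", name="Novel Database", homepage="https://nov.el")
        result = align(registry, meta1, [row])
        assert len(result.new_records) == 1
        record = result.new_records[0]
        assert record.prefix == "noveldb"
        assert record.mappings == {"extreg": "NovelDB"}
        assert record.name == "Novel Database"

    def test_group2_miss_lands_on_the_curation_sheet(self, registry, meta2):
        before = len(registry)
        result = align(registry, meta2, [_row("extreg", "randomont")])
        assert len(result.curation_rows) == 1
        assert len(registry) == before  # align never mutates the registry

    def test_group3_miss_is_silently_skipped(self, registry):
        meta = RegistryMeta(key="extreg", policy_group=3, import_order=10)
        result = align(registry, meta, [_row("extreg", "randomont")])
        assert result.skipped[0].reason == "group-3-unmatched"
        assert not result.curation_rows and not result.new_records

    def test_blocklisted_hit_is_suppressed(self, registry, meta1):
        blocklist = Blocklist.from_triples([("extreg", "FB", "flybase")])
        result = align(registry, meta1, [_row("extreg", "FB")], blocklist)
        assert result.new_mappings == []
        assert result.skipped[0].reason == "blocklisted"

    def test_blocklist_never_creates_mappings(self, registry, meta1):
        blocklist = Blocklist.from_triples([("extreg", "ghost", "flybase")])
        result = align(registry, meta1, [_row("extreg", "ghost")], blocklist)
        assert result.new_mappings == []  # a miss stays a miss

    def test_unknown_policy_group_is_a_configuration_error(self, registry):
        meta = RegistryMeta(key="extreg", policy_group=2, import_order=10)
        meta.policy_group = 7
        with pytest.raises(AlignmentError):
            align(registry, meta, [])

    def test_foreign_registry_key_rows_are_rejected(self, registry, meta1):
        with pytest.raises(AlignmentError):
            align(registry, meta1, [_row("otherreg", "x")])

    def test_partition_property(self, registry, meta1):
        dump = [
            _row("extreg", "FlyBase"),
            _row("extreg", "newthing"),
            _row("extreg", "newthing"),  # duplicate in dump
            _row("extreg", "fb"),  # second hit on flybase
        ]
        result = align(registry, meta1, dump)
        assert len(result) == len(dump)

    def test_permuting_the_dump_preserves_the_mapping_set(self, registry, meta1):
        dump = [
            _row("extreg", "FlyBase"),
            _row("extreg", "intenz"),
            _row("extreg", "GO"),
            _row("extreg", "brandnew"),
        ]
        forward = align(registry, meta1, dump)
        backward = align(registry, meta1, list(reversed(dump)))
        key = lambda r: {(m.prefix, m.external_prefix) for m in r.new_mappings}
        assert key(forward) == key(backward)
        assert {r.prefix for r in forward.new_records} == {
            r.prefix for r in backward.new_records
        }


class TestApplyResult:
    def test_counts_add_up(self, registry, meta1):
        dump = [_row("extreg", "FlyBase"), _row("extreg", "GO"), _row("extreg", "newdb")]
        result = align(registry, meta1, dump)
        merged = apply_result(registry, result)
        assert len(merged) == len(registry) + 1
        assert len(merged.mappings()) == len(registry.mappings()) + 3  # 2 hits + 1 new record

    def test_input_registry_untouched(self, registry, meta1):
        result = align(registry, meta1, [_row("extreg", "newdb")])
        apply_result(registry, result)
        assert "newdb" not in registry

    def test_rerunning_align_after_apply_is_idempotent(self, registry, meta1):
        dump = [_row("extreg", "FlyBase"), _row("extreg", "newdb"), _row("extreg", "GO")]
        merged = apply_result(registry, align(registry, meta1, dump))
        rerun = align(merged, meta1, dump)
        assert rerun.new_mappings == [] and rerun.new_records == []
        assert len(rerun) == len(dump)

    def test_reapplying_the_same_result_is_a_no_op(self, registry, meta1):
        dump = [_row("extreg", "FlyBase"), _row("extreg", "newdb")]
        result = align(registry, meta1, dump)
        once = apply_result(registry, result)
        twice = apply_result(once, result)
        assert len(twice) == len(once)
        assert twice.mappings() == once.mappings()

    def test_colliding_new_record_aborts_without_partial_write(self, registry, meta1):
        result = align(registry, meta1, [_row("extreg", "GOCC")])
        # sabotage: pretend the hit was a miss synthesizing a colliding record
        bad = ResourceRecord(prefix="newdb", synonyms=["taxonomy"], name="x", description="x")
        result.new_records.append(bad)
        with pytest.raises(AlignmentError):
            apply_result(registry, result)
        assert "newdb" not in registry

    def test_curation_sheet_sidecar(self, registry, meta2, tmp_path):
        sheet = tmp_path / "curation.tsv"
        result = align(registry, meta2, [_row("extreg", "randomont", name="Random Ont")])
        apply_result(registry, result, curation_sheet=sheet)
        lines = sheet.read_text(encoding="utf-8").splitlines()
        assert lines[0].split("\t") == [
            "registry_key", "external_prefix", "name", "homepage", "example", "uri_format",
        ]
        assert lines[1].startswith("extreg\trandomont\tRandom Ont")


class TestAlignAll:
    def test_sequential_import_in_import_order(self, registry):
        registry.add_meta(RegistryMeta(key="first", policy_group=1, import_order=50))
        registry.add_meta(RegistryMeta(key="second", policy_group=1, import_order=60))
        dumps = {
            "second": [_row("second", "shinynew")],
            "first": [_row("first", "shinynew")],
        }
        merged, results = align_all(registry, dumps)
        # the earlier registry synthesizes the record; the later one maps to it
        assert [r.registry_key for r in results] == ["first", "second"]
        assert len(results[0].new_records) == 1
        assert len(results[1].new_mappings) == 1
        assert merged["shinynew"].mappings == {"first": "shinynew", "second": "shinynew"}
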