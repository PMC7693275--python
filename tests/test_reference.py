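import dataclasses

import pytest

from taxonym.errors import ReferenceFormatError, StatusMappingError, SynonymCycleError
from taxonym.fixtures import FixtureSpec, generate_reference
from taxonym.reference import (
    DEFAULT_DIALECT,
    Dialect,
    DiffOptions,
    diff_backbones,
    flatten_synonym_chains,
    load_reference,
    summarize,
    validate_reference,
    write_reference,
)

from helpers import mk_table, oracle_flatten_target


def _write_tsv(path, header, rows):
    lines = ["\t".join(header)] + ["\t".join(r) for r in rows]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


class TestLoadReference:
    def test_minimal_file(self, tmp_path):
        f = tmp_path / "ref.tsv"
        _write_tsv(
            f,
            ["Input_Taxon", "Status", "Output_Taxon"],
            [
                ["Draba alba L.", "accepted", "Draba alba L."],
                ["Draba nigra Sm.", "synonym", "Draba alba L."],
                ["Draba dubia", "unresolved", ""],
            ],
        )
        table = load_reference(f)
        assert len(table) == 3
        assert [r.status for r in table] == ["accepted", "synonym", "unresolved"]
        assert table.records[1].accepted_name == "Draba alba L."

    def test_status_vocabulary_mapped_by_dialect(self, tmp_path):
        f = tmp_path / "ref.tsv"
        _write_tsv(
            f,
            ["Input_Taxon", "Status", "Output_Taxon"],
            [["Draba alba L.", "Accepted", "Draba alba L."]],
        )
        # default dialect maps case-insensitively
        assert load_reference(f).records[0].status == "accepted"
        strict = Dialect(status_map={"ok": "accepted"})
        with pytest.raises(StatusMappingError) as exc:
            load_reference(f, strict)
        assert "Accepted" in str(exc.value)

    def test_missing_column_named_in_error(self, tmp_path):
        f = tmp_path / "ref.tsv"
        _write_tsv(f, ["Input_Taxon", "Status"], [["Draba alba L.", "accepted"]])
        with pytest.raises(ReferenceFormatError) as exc:
            load_reference(f)
        assert "Output_Taxon" in str(exc.value)

    def test_unmapped_columns_kept_as_extras(self, tmp_path):
        f = tmp_path / "ref.tsv"
        _write_tsv(
            f,
            ["Input_Taxon", "Status", "Output_Taxon", "Remarks"],
            [["Draba alba L.", "accepted", "Draba alba L.", "note"]],
        )
        assert load_reference(f).records[0].extras == {"Remarks": "note"}

    def test_generated_fixture_loads_with_counts(self, tmp_path):
        spec = FixtureSpec(n_genera=25, species_per_genus=(40, 40), seed=9)
        table, truth = generate_reference(spec)
        assert len(table) == truth.expected_summary.total_names == 1000
        f = tmp_path / "gen.tsv"
        write_reference(table, f)
        loaded = load_reference(f)
        assert len(loaded) == 1000
        assert set(loaded.genus_index) == {r.parsed.genus for r in table}

    def test_row_order_preserved(self, tmp_path):
        table, _ = generate_reference(FixtureSpec(n_genera=5, seed=1))
        f = tmp_path / "gen.tsv"
        write_reference(table, f)
        assert [r.input_name for r in load_reference(f)] == [
            r.input_name for r in table
        ]

    def test_names_canonicalized_on_load(self, tmp_path):
        f = tmp_path / "ref.tsv"
        _write_tsv(
            f,
            ["Input_Taxon", "Status", "Output_Taxon"],
            [["Isoëtes   alba C. F. W. Meissn.", "accepted", ""]],
        )
        rec = load_reference(f).records[0]
        assert rec.input_name == "Isoetes alba C.F.W.Meissn."

    def test_dialect_config_round_trip(self, tmp_path):
        conf = tmp_path / "d.conf"
        conf.write_text(
            "column.input_name = Name\n"
            "column.status = State\n"
            "column.accepted_name = Target\n"
            "status.ok = accepted\n"
            "status.syn = synonym\n"
            "status.nn = unresolved\n",
            encoding="utf-8",
        )
        dialect = Dialect.from_config(conf)
        f = tmp_path / "ref.tsv"
        _write_tsv(f, ["Name", "State", "Target"], [["Poa annua L.", "ok", ""]])
        assert load_reference(f, dialect).records[0].status == "accepted"

    def test_genus_index_consistent_with_records(self, rich_table):
        rebuilt = {}
        for rec in rich_table:
            rebuilt.setdefault(rec.parsed.genus, []).append(rec)
        assert {g: [r.input_name for r in rs] for g, rs in rebuilt.items()} == {
            g: [r.input_name for r in rs] for g, rs in rich_table.genus_index.items()
        }


class TestValidateReference:
    def test_valid_table(self):
        table = mk_table(
            [("Poa alba L.", "accepted"), ("Poa nigra Sm.", "synonym", "Poa alba L.")]
        )
        report = validate_reference(table)
        assert report.is_valid
        assert report.n_records == 2

    def test_chain_detected(self):
        table = mk_table(
            [
                ("Poa alpha L.", "synonym", "Poa beta Sm."),
                ("Poa beta Sm.", "synonym", "Poa gamma Hook."),
                ("Poa gamma Hook.", "accepted"),
            ]
        )
        report = validate_reference(table)
        assert report.chained_synonyms == [
            ["Poa alpha L.", "Poa beta Sm.", "Poa gamma Hook."]
        ]
        assert not report.cycles

    def test_two_node_cycle_detected(self):
        table = mk_table(
            [
                ("Poa alpha L.", "synonym", "Poa beta Sm."),
                ("Poa beta Sm.", "synonym", "Poa alpha L."),
            ]
        )
        report = validate_reference(table)
        assert report.cycles == [["Poa alpha L.", "Poa beta Sm."]]

    def test_dangling_and_duplicates(self):
        table = mk_table(
            [
                ("Poa alba L.", "accepted"),
                ("Poa alba L.", "accepted"),
                ("Poa lost Sm.", "synonym", "Poa missing Hook."),
                ("Poa void Sm.", "synonym", ""),
            ]
        )
        report = validate_reference(table)
        assert report.duplicate_names == ["Poa alba L."]
        assert sorted(report.dangling_synonyms) == ["Poa lost Sm.", "Poa void Sm."]

    def test_pure_function(self, rich_table):
        before = [dataclasses.replace(r) for r in rich_table]
        validate_reference(rich_table)
        assert list(rich_table) == before

    def test_finds_exactly_injected_defects(self):
        spec = FixtureSpec(
            n_genera=8,
            synonym_fraction=0.3,
            chain_fraction=0.2,
            n_dangling=3,
            n_cycles=2,
            n_duplicates=2,
            seed=21,
        )
        table, truth = generate_reference(spec)
        report = validate_reference(table)
        assert sorted(report.dangling_synonyms) == sorted(truth.dangling_names)
        assert len(report.cycles) == 2
        assert {frozenset(c) for c in report.cycles} == {
            frozenset(p) for p in truth.cycle_pairs
        }
        assert sorted(report.duplicate_names) == sorted(truth.duplicate_names)
        assert len(report.chained_synonyms) == truth.n_chained

    def test_clean_fixture_is_valid(self):
        table, _ = generate_reference(FixtureSpec(n_genera=6, synonym_fraction=0.3, seed=2))
        assert validate_reference(table).is_valid


class TestFlatten:
    def test_chain_rewired_to_terminal(self):
        table = mk_table(
            [
                ("Poa alpha L.", "synonym", "Poa beta Sm."),
                ("Poa beta Sm.", "synonym", "Poa gamma Hook."),
                ("Poa gamma Hook.", "accepted"),
            ]
        )
        flat = flatten_synonym_chains(table)
        assert flat.lookup("Poa alpha L.").accepted_name == "Poa gamma Hook."
        assert flat.lookup("Poa beta Sm.").accepted_name == "Poa gamma Hook."

    def test_idempotent_and_count_preserving(self, rich_table):
        flat1 = flatten_synonym_chains(rich_table)
        flat2 = flatten_synonym_chains(flat1)
        assert len(flat1) == len(rich_table)
        assert flat1.records == flat2.records

    def test_idempotent_byte_identical(self, tmp_path, rich_table):
        flat1 = flatten_synonym_chains(rich_table)
        flat2 = flatten_synonym_chains(flat1)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_reference(flat1, p1)
        write_reference(flat2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_every_synonym_targets_accepted(self, flat_table):
        for rec in flat_table:
            if rec.status == "synonym":
                target = flat_table.lookup(rec.accepted_name)
                assert target is not None and target.status == "accepted"

    def test_long_chain_against_pointer_oracle(self):
        spec = FixtureSpec(
            n_genera=6, synonym_fraction=0.2, chain_lengths=(5,), seed=13
        )
        table, truth = generate_reference(spec)
        (chain,) = truth.chain_paths
        assert len(chain) == 6  # five synonyms plus the accepted terminal
        flat = flatten_synonym_chains(table)
        for name in chain[:-1]:
            assert flat.lookup(name).accepted_name == oracle_flatten_target(name, table)
            assert flat.lookup(name).accepted_name == chain[-1]

    def test_cycle_raises_naming_members(self):
        table = mk_table(
            [
                ("Poa alpha L.", "synonym", "Poa beta Sm."),
                ("Poa beta Sm.", "synonym", "Poa alpha L."),
            ]
        )
        with pytest.raises(SynonymCycleError) as exc:
            flatten_synonym_chains(table)
        assert "Poa alpha L." in str(exc.value)

    def test_dangling_demoted_to_unresolved(self, caplog):
        table = mk_table(
            [
                ("Poa alba L.", "accepted"),
                ("Poa lost Sm.", "synonym", "Poa missing Hook."),
            ]
        )
        import logging

        with caplog.at_level(logging.WARNING, logger="taxonym.reference"):
            flat = flatten_synonym_chains(table)
        rec = flat.lookup("Poa lost Sm.")
        assert rec.status == "unresolved"
        assert rec.accepted_name == ""
        assert any("demoted" in m for m in caplog.messages)

    def test_non_synonyms_untouched(self, rich_table):
        flat = flatten_synonym_chains(rich_table)
        for before, after in zip(rich_table, flat):
            if before.status != "synonym":
                assert before == after


class TestSummarize:
    def test_empty_table(self):
        stats = summarize(mk_table([]))
        assert stats.total_names == 0
        assert stats.accepted_species == 0
        assert stats.genera_all == 0

    def test_hand_counted_fixture(self):
        rows = [(f"Genus{'abcdefghij'[i]} alba L.", "accepted") for i in range(10)]
        rows += [
            ("Genusa hybrida_x L.", "accepted"),
            ("Genusb_x mixta L.", "accepted"),
        ]
        rows += [
            (f"Genusa syn{'abcde'[i]}ua Sm.", "synonym", "Genusa alba L.")
            for i in range(5)
        ]
        rows += [("Genusc dubia", "unresolved")]
        stats = summarize(mk_table(rows))
        assert stats.accepted_species == 10
        assert stats.natural_hybrids == 2
        assert stats.synonyms == 5
        assert stats.unresolved == 1
        assert stats.total_names == 18
        assert (
            stats.accepted_incl_infraspecific
            + stats.natural_hybrids
            + stats.synonyms
            + stats.unresolved
            == stats.total_names
        )

    def test_generator_truth_for_seed_grid(self):
        for seed in range(6):
            spec = FixtureSpec(
                n_genera=7,
                species_per_genus=(2, 5),
                synonym_fraction=0.3,
                chain_fraction=0.2,
                infraspecific_fraction=0.25,
                hybrid_fraction=0.1,
                unresolved_fraction=0.12,
                homonym_pairs=1,
                seed=seed,
            )
            table, truth = generate_reference(spec)
            stats = summarize(table)
            expected = truth.expected_summary
            for name in (
                "total_names",
                "accepted_species",
                "accepted_incl_infraspecific",
                "accepted_infraspecific",
                "natural_hybrids",
                "synonyms",
                "unresolved",
                "genera_accepted",
                "genera_all",
                "families",
                "orders",
            ):
                assert getattr(stats, name) == getattr(expected, name), (seed, name)

    def test_unresolved_by_genus(self):
        table = mk_table(
            [
                ("Poa alba L.", "accepted"),
                ("Poa dubia", "unresolved"),
                ("Poa incerta", "unresolved"),
                ("Briza media L.", "accepted"),
            ]
        )
        stats = summarize(table)
        assert stats.unresolved_by_genus == {"Poa": (2, 3)}

    def test_round_trip_stability(self, tmp_path, rich_table):
        f = tmp_path / "rt.tsv"
        write_reference(rich_table, f)
        assert summarize(load_reference(f)) == summarize(rich_table)


class TestDiff:
    def test_self_diff_identical(self, rich_table):
        report = diff_backbones(rich_table, rich_table)
        assert report.identical == len(rich_table)
        for fieldname in (
            "only_in_a",
            "only_in_b",
            "different_author",
            "different_synonym",
            "different_orthography",
            "other_difference",
            "resolved_in_a_unresolved_in_b",
            "accepted_in_a_synonym_in_b",
            "synonym_in_a_accepted_in_b",
        ):
            assert getattr(report, fieldname) == 0, fieldname

    def test_only_in_a(self):
        a = mk_table([("Poa alba L.", "accepted")])
        b = mk_table([])
        report = diff_backbones(a, b)
        assert report.only_in_a == 1
        assert report.identical == 0

    def test_different_author(self):
        a = mk_table([("Genus alba Sm.", "accepted")])
        b = mk_table([("Genus alba L.", "accepted")])
        report = diff_backbones(a, b)
        assert report.different_author == 1
        assert report.identical == 0
        assert report.only_in_a == report.only_in_b == 0

    def test_different_synonym_target(self):
        a = mk_table(
            [("Poa x L.", "accepted"), ("Poa s Sm.", "synonym", "Poa x L.")]
        )
        b = mk_table(
            [("Poa y L.", "accepted"), ("Poa s Sm.", "synonym", "Poa y L.")]
        )
        report = diff_backbones(a, b)
        assert report.different_synonym == 1

    def test_status_contrasts(self):
        a = mk_table(
            [
                ("Poa alba L.", "accepted"),
                ("Poa beta Sm.", "synonym", "Poa alba L."),
                ("Poa ceta Hook.", "accepted"),
            ]
        )
        b = mk_table(
            [
                ("Poa alba L.", "synonym", "Poa ceta Hook."),
                ("Poa beta Sm.", "accepted"),
                ("Poa ceta Hook.", "unresolved"),
            ]
        )
        report = diff_backbones(a, b)
        assert report.accepted_in_a_synonym_in_b == 1
        assert report.synonym_in_a_accepted_in_b == 1
        assert report.resolved_in_a_unresolved_in_b == 1

    def test_orthographic_variant_paired(self):
        a = mk_table([("Genus warscewiczii L.", "accepted")])
        b = mk_table([("Genus warszewiczii L.", "accepted")])
        report = diff_backbones(a, b)
        assert report.different_orthography == 1
        # presence partition still counts both sides
        assert report.only_in_a == 1 and report.only_in_b == 1

    def test_orthography_requires_same_authority(self):
        a = mk_table([("Genus warscewiczii L.", "accepted")])
        b = mk_table([("Genus warszewiczii Sm.", "accepted")])
        assert diff_backbones(a, b).different_orthography == 0

    def test_orthography_threshold_configurable(self):
        a = mk_table([("Genus aaaa L.", "accepted")])
        b = mk_table([("Genus bbbb L.", "accepted")])
        assert diff_backbones(a, b).different_orthography == 0
        wide = DiffOptions(max_orthography_distance=4)
        assert diff_backbones(a, b, wide).different_orthography == 1

    def test_presence_partition(self, rich_table):
        other, _ = generate_reference(
            FixtureSpec(n_genera=10, synonym_fraction=0.2, seed=77)
        )
        report = diff_backbones(rich_table, other)
        paired = (
            report.identical
            + report.different_author
            + report.different_synonym
            + report.other_difference
        )
        assert 2 * paired + report.only_in_a + report.only_in_b == len(
            rich_table
        ) + len(other)
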