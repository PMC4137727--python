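"""Ingest, deduplication and the whitelist/derived-list/stoplist filter chain."""

from __future__ import annotations

import numpy as np
import pytest

from hetmotif.associations import (
    MalformedRowError,
    deduplicate,
    filter_by_drug_whitelist,
    parse_predications,
    read_table,
    remove_stoplist_terms,
    restrict_to_derived_lists,
    table_stats,
    write_table,
    export_ntriples,
)
from hetmotif.types import AssociationRecord


def rec(s, st, o, ot, pmid="1", pred="ASSOCIATED_WITH"):
    return AssociationRecord(
        subject_id=s, subject_type=st, predicate=pred, object_id=o, object_type=ot, pmid=pmid
    )


class TestParse:
    def test_row_maps_to_record(self, tmp_path):
        p = tmp_path / "x.tsv"
        p.write_text("d001\tdisease\tASSOCIATED_WITH\tg007\tgene\t12345\n")
        (r,) = list(parse_predications(p))
        assert (r.subject_id, r.subject_type) == ("d001", "disease")
        assert (r.object_id, r.object_type) == ("g007", "gene")
        assert r.pmid == "12345" and r.layer == "disease-gene"

    def test_empty_file_gives_empty_stream(self, tmp_path):
        p = tmp_path / "x.tsv"
        p.write_text("")
        assert list(parse_predications(p)) == []

    def test_header_skipped_and_malformed_rows_counted(self, tmp_path, caplog):
        rng = np.random.default_rng(7)
        p = tmp_path / "x.tsv"
        lines = ["subject_id\tsubject_type\tpredicate\tobject_id\tobject_type\tpmid"]
        bad_at = {100, 500, 900}
        n_good = 0
        for i in range(1000):
            if i in bad_at:
                lines.append("broken row")
            else:
                a, b = f"d{rng.integers(50):03d}", f"g{rng.integers(50):03d}"
                lines.append(f"{a}\tdisease\tTREATS\t{b}\tgene\t{i}")
                n_good += 1
        p.write_text("\n".join(lines) + "\n")
        with caplog.at_level("WARNING"):
            records = list(parse_predications(p))
        assert len(records) == n_good == 997
        assert sum("malformed" in m for m in caplog.messages) == 3

    def test_strict_mode_aborts_on_malformed(self, tmp_path):
        p = tmp_path / "x.tsv"
        p.write_text("only three\tfields\there\n")
        with pytest.raises(MalformedRowError):
            list(parse_predications(p, strict=True))

    def test_unknown_entity_type_names_token(self, tmp_path):
        p = tmp_path / "x.tsv"
        p.write_text("a\tprotein_kind\tX\tb\tgene\t1\n")
        with pytest.raises(ValueError, match="protein_kind"):
            list(parse_predications(p))

    def test_entity_tokens_are_casefolded_and_trimmed(self, tmp_path):
        p = tmp_path / "x.tsv"
        p.write_text(" Aspirin \tdrug\tTREATS\tHeadache\tdisease\t1\n")
        (r,) = list(parse_predications(p))
        assert r.subject_id == "aspirin" and r.object_id == "headache"


class TestDeduplicate:
    def test_symmetric_records_collapse(self):
        t = deduplicate([rec("a", "disease", "b", "gene", "p1"),
                         rec("b", "gene", "a", "disease", "p2")])
        (ua,) = list(t)
        assert (ua.entity_a, ua.entity_b) == ("a", "b")
        assert ua.support == 2 and ua.pmids == {"p1", "p2"}

    def test_self_association_dropped_and_counted(self):
        t = deduplicate([rec("a", "gene", "a", "gene", "p1")])
        assert len(t) == 0 and t.dropped_self == 1

    def test_support_conservation_on_random_stream(self, rng):
        # 500 records over a limited pair pool; supports must sum to inputs minus self-drops
        records = []
        for i in range(500):
            a = f"e{rng.integers(16):02d}"
            b = f"e{rng.integers(16):02d}"
            records.append(rec(a, "disease", b, "disease", pmid=str(i)))
        t = deduplicate(records)
        n_self = sum(1 for r in records if r.subject_id == r.object_id)
        assert sum(a.support for a in t) == 500 - n_self
        assert t.dropped_self == n_self
        # independent pair-count oracle
        pairs = {
            tuple(sorted((r.subject_id, r.object_id)))
            for r in records
            if r.subject_id != r.object_id
        }
        assert len(t) == len(pairs)

    def test_order_invariance(self, rng):
        records = [
            rec(f"d{rng.integers(10)}", "disease", f"g{rng.integers(10)}", "gene", str(i))
            for i in range(200)
        ]
        t1 = deduplicate(records)
        shuffled = list(records)
        rng.shuffle(shuffled)
        t2 = deduplicate(shuffled)
        assert {a.key: (a.support, frozenset(a.pmids)) for a in t1} == {
            a.key: (a.support, frozenset(a.pmids)) for a in t2
        }


class TestFilters:
    def test_whitelist_keeps_member_drug(self):
        t = deduplicate([rec("aspirin", "drug", "g1", "gene")])
        out = filter_by_drug_whitelist(t, {"aspirin"})
        assert len(out) == 1

    def test_whitelist_requires_both_drug_endpoints(self):
        t = deduplicate([rec("aspirin", "drug", "warfarin", "drug")])
        assert len(filter_by_drug_whitelist(t, {"aspirin"})) == 0
        assert len(filter_by_drug_whitelist(t, {"aspirin", "warfarin"})) == 1

    def test_whitelist_leaves_drugfree_layers_untouched(self):
        t = deduplicate([rec("d1", "disease", "g1", "gene")])
        assert len(filter_by_drug_whitelist(t, {"whatever"})) == 1

    def test_empty_whitelist_rejected(self):
        t = deduplicate([rec("x", "drug", "g1", "gene")])
        with pytest.raises(ValueError):
            filter_by_drug_whitelist(t, set())

    def test_whitelist_against_membership_oracle(self, rng):
        records = []
        for i in range(200):
            records.append(rec(f"drug{rng.integers(40):02d}", "drug",
                               f"g{rng.integers(40):02d}", "gene", str(i)))
        t = deduplicate(records)
        wl = {f"drug{i:02d}" for i in range(16)}  # 40% of the drug tokens
        out = filter_by_drug_whitelist(t, wl)
        expected = sum(1 for a in t if (a.entity_a if a.type_a == "drug" else a.entity_b) in wl)
        assert len(out) == expected

    def test_derived_lists_drop_outsiders(self):
        t = deduplicate([
            rec("x", "drug", "g1", "gene"),
            rec("x", "drug", "g2", "gene"),
            rec("g1", "gene", "g3", "gene"),   # g3 not drug-connected
            rec("g1", "gene", "g2", "gene"),
            rec("x", "drug", "d1", "disease"),
            rec("d1", "disease", "g1", "gene"),
            rec("d2", "disease", "g1", "gene"),  # d2 not drug-connected
        ])
        t = filter_by_drug_whitelist(t, {"x"})
        out = restrict_to_derived_lists(t)
        layers = {(a.layer, a.entity_a, a.entity_b) for a in out}
        assert ("gene-gene", "g1", "g3") not in layers
        assert ("gene-gene", "g1", "g2") in layers
        assert ("disease-gene", "d1", "g1") in layers
        assert ("disease-gene", "d2", "g1") not in layers

    def test_derived_lists_against_two_pass_oracle(self, rng):
        records = []
        for i in range(300):
            kind = rng.integers(4)
            if kind == 0:
                records.append(rec(f"x{rng.integers(10)}", "drug", f"g{rng.integers(30)}", "gene", str(i)))
            elif kind == 1:
                records.append(rec(f"x{rng.integers(10)}", "drug", f"d{rng.integers(30)}", "disease", str(i)))
            elif kind == 2:
                records.append(rec(f"g{rng.integers(30)}", "gene", f"g{rng.integers(30)}", "gene", str(i)))
            else:
                records.append(rec(f"d{rng.integers(30)}", "disease", f"g{rng.integers(30)}", "gene", str(i)))
        t = filter_by_drug_whitelist(deduplicate(records), {f"x{i}" for i in range(5)})
        out = restrict_to_derived_lists(t)
        genes = {e for a in t if a.layer == "drug-gene"
                 for e, ty in ((a.entity_a, a.type_a), (a.entity_b, a.type_b)) if ty == "gene"}
        diseases = {e for a in t if a.layer == "disease-drug"
                    for e, ty in ((a.entity_a, a.type_a), (a.entity_b, a.type_b)) if ty == "disease"}
        ok = {"gene": genes, "disease": diseases}
        for a in t:
            kept = a.key in out
            if a.layer in ("gene-gene", "disease-disease", "disease-gene"):
                expect = all(e in ok[ty] for e, ty in ((a.entity_a, a.type_a), (a.entity_b, a.type_b)))
            else:
                expect = True
            assert kept == expect, a.key

    def test_stoplist_removes_touching_associations(self):
        t = deduplicate([rec("protein", "gene", "g1", "gene"),
                         rec("g1", "gene", "g2", "gene")])
        out = remove_stoplist_terms(t, {"Protein"})
        assert [a.entity_a for a in out] == ["g1"]

    def test_stoplist_is_exact_token_not_substring(self):
        t = deduplicate([rec("proteinase", "gene", "g1", "gene")])
        assert len(remove_stoplist_terms(t, {"protein"})) == 1

    def test_empty_stoplist_is_identity(self):
        t = deduplicate([rec("a", "gene", "b", "gene")])
        assert len(remove_stoplist_terms(t, set())) == 1

    def test_filters_are_monotone(self, rng):
        records = [rec(f"x{rng.integers(8)}", "drug", f"g{rng.integers(20)}", "gene", str(i))
                   for i in range(100)]
        t = deduplicate(records)
        wl_out = filter_by_drug_whitelist(t, {"x0", "x1", "x2"})
        dl_out = restrict_to_derived_lists(wl_out)
        sl_out = remove_stoplist_terms(dl_out, {"g0"})
        keys = lambda tab: {a.key for a in tab}
        assert keys(sl_out) <= keys(dl_out) <= keys(wl_out) <= keys(t)


class TestStatsAndIO:
    def test_stats_direct_count(self):
        t = deduplicate([rec("d1", "disease", "g1", "gene"),
                         rec("d1", "disease", "g2", "gene")])
        s = table_stats(t)
        assert s["per_layer"]["disease-gene"]["unique_associations"] == 2
        assert s["per_layer"]["disease-gene"]["unique_entities"] == 3
        assert s["total_unique_entities"] == 3

    def test_stats_empty_table(self):
        s = table_stats(deduplicate([]))
        assert s["total_unique_associations"] == 0
        assert all(v["unique_associations"] == 0 for v in s["per_layer"].values())

    def test_entities_shared_between_layers_counted_once(self):
        t = deduplicate([rec("d1", "disease", "g1", "gene"),
                         rec("g1", "gene", "g2", "gene")])
        assert table_stats(t)["total_unique_entities"] == 3

    def test_table_roundtrip(self, tmp_path, rng):
        records = [rec(f"d{rng.integers(10)}", "disease", f"g{rng.integers(10)}", "gene", str(i))
                   for i in range(50)]
        t = deduplicate(records)
        p = tmp_path / "t.tsv"
        write_table(t, p)
        t2 = read_table(p)
        assert {a.key: (a.support, frozenset(a.pmids)) for a in t} == {
            a.key: (a.support, frozenset(a.pmids)) for a in t2
        }

    def test_ntriples_export_one_triple_per_association(self, tmp_path):
        t = deduplicate([rec("d1", "disease", "g1", "gene"),
                         rec("d2", "disease", "g1", "gene")])
        p = tmp_path / "t.nt"
        export_ntriples(t, p)
        lines = [l for l in p.read_text().splitlines() if l.strip()]
        assert len(lines) == 2
        assert all("layer/disease-gene" in l for l in lines)
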