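"""Repertoire data model, I/O round-trips, lemmatization, descriptors."""

import math

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from surnamebias import (
    LemmaRule,
    Repertoire,
    aggregate_repertoires,
    apply_lemmatization,
    canonical_surname,
    growth_rate,
    load_study_communities,
    read_repertoire,
    s_over_n,
    write_repertoire,
)
from surnamebias.exceptions import FormatError, RuleError, ValidationError
from surnamebias.repertoire import read_community_metadata, read_lemma_rules


class TestCanonicalization:
    def test_trim_collapse_upper(self):
        assert canonical_surname("  de   rossi ") == "DE ROSSI"

    def test_idempotent(self):
        once = canonical_surname(" Albertini  Marchesani ")
        assert canonical_surname(once) == once

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            canonical_surname("   ")


class TestRepertoire:
    def test_direct_construction(self):
        rep = Repertoire("C", 1993, "phonebook", {"ROSSI": 3, "VERDI": 1})
        assert (rep.n, rep.s) == (4, 2)

    def test_duplicate_forms_summed(self):
        rep = Repertoire("C", 1993, "phonebook", {"ROSSI": 2, " rossi ": 1})
        assert rep.counts == {"ROSSI": 3}
        assert (rep.n, rep.s) == (3, 1)

    @pytest.mark.parametrize("bad", [0, -1, 1.5])
    def test_invalid_count_rejected(self, bad):
        with pytest.raises(ValidationError):
            Repertoire("C", 1993, "phonebook", {"ROSSI": bad})

    def test_unknown_source_kind_rejected(self):
        with pytest.raises(ValidationError):
            Repertoire("C", 1993, "tax-roll", {"ROSSI": 1})


class TestIO:
    @pytest.mark.parametrize("suffix", [".csv", ".tsv", ".xlsx"])
    def test_round_trip(self, tmp_path, suffix):
        rep = Repertoire("C", 1993, "phonebook", {"ROSSI": 3, "VERDI": 1, "DE LUCA": 2})
        path = tmp_path / f"rep{suffix}"
        write_repertoire(rep, path)
        back = read_repertoire(path, "C", 1993, "phonebook")
        assert back.counts == rep.counts

    def test_missing_count_column_means_one_bearer_per_row(self, tmp_path):
        path = tmp_path / "acts.csv"
        path.write_text("surname\nROSSI\nROSSI\nVERDI\n")
        rep = read_repertoire(path)
        assert rep.counts == {"ROSSI": 2, "VERDI": 1}

    def test_missing_surname_column_is_format_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("name,count\nROSSI,2\n")
        with pytest.raises(FormatError):
            read_repertoire(path)

    def test_zero_count_row_is_validation_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("surname,count\nROSSI,0\n")
        with pytest.raises(ValidationError, match="row 0"):
            read_repertoire(path)


class TestLemmatization:
    def test_edit_correction(self):
        rep = Repertoire("C", 1700, "marriage", {"BEVLACQUA": 2})
        rule = LemmaRule("edit_correction", "BEVLACQUA", "BEVILACQUA")
        merged, report = apply_lemmatization(rep, [rule])
        assert merged.counts == {"BEVILACQUA": 2}
        assert report.bearers_moved.tolist() == [2]

    def test_compound_reduction(self):
        rep = Repertoire("C", 1700, "marriage", {"ALBERTINI MARCHESANI": 1, "ROSSI": 1})
        rule = LemmaRule("compound_reduction", "ALBERTINI MARCHESANI", "ALBERTINI")
        merged, _ = apply_lemmatization(rep, [rule])
        assert merged.counts == {"ALBERTINI": 1, "ROSSI": 1}

    def test_empty_rule_list_is_identity(self):
        rep = Repertoire("C", 1700, "marriage", {"ROSSI": 2, "ROSSO": 1})
        merged, report = apply_lemmatization(rep, [])
        assert merged.counts == rep.counts
        assert report.empty

    def test_unmatched_forms_pass_through(self):
        # The conservative contract: Rosso and Rossi stay distinct absent a rule.
        rep = Repertoire("C", 1700, "marriage", {"ROSSO": 1, "ROSSI": 2})
        rule = LemmaRule("variant_merge", "MARINO", "MARINI")
        merged, report = apply_lemmatization(rep, [rule])
        assert merged.counts == rep.counts
        assert report.empty

    def test_rules_apply_once_non_recursively(self):
        rep = Repertoire("C", 1700, "marriage", {"A B": 1})
        rules = [
            LemmaRule("compound_reduction", "A B", "B"),
            LemmaRule("variant_merge", "B", "C"),
        ]
        merged, _ = apply_lemmatization(rep, rules)
        assert merged.counts == {"B": 1}  # not cascaded to C

    def test_empty_canonical_is_rule_error(self):
        with pytest.raises(RuleError):
            LemmaRule("variant_merge", "ROSSI", "  ")

    def test_rule_file_round_trip(self, tmp_path):
        path = tmp_path / "rules.csv"
        path.write_text("kind,pattern,canonical\nedit_correction,Bevlacqua,Bevilacqua\n")
        rules = read_lemma_rules(path)
        assert rules == [LemmaRule("edit_correction", "BEVLACQUA", "BEVILACQUA")]

    @given(
        counts=st.dictionaries(
            st.text(alphabet="ABCDE", min_size=1, max_size=3),
            st.integers(min_value=1, max_value=20),
            min_size=1,
            max_size=8,
        ),
        rules=st.lists(
            st.tuples(
                st.text(alphabet="ABCDE", min_size=1, max_size=3),
                st.text(alphabet="ABCDE", min_size=1, max_size=3),
            ),
            max_size=5,
        ),
    )
    @settings(max_examples=50, derandomize=True)
    def test_conserves_bearers_never_increases_types(self, counts, rules):
        rep = Repertoire("C", 1700, "marriage", counts)
        rule_objs = [LemmaRule("variant_merge", p, c) for p, c in rules]
        merged, _ = apply_lemmatization(rep, rule_objs)
        assert merged.n == rep.n
        assert merged.s <= rep.s


class TestDescriptors:
    def test_s_over_n_careggine(self):
        # present-day list of the smallest alpine community: S=70, N=206
        rep_meta = load_study_communities().set_index("community_id")
        row = rep_meta.loc["Careggine"]
        assert round(row.st / row.nt, 4) == 0.3398

    def test_s_over_n_degenerate(self):
        singles = Repertoire("C", 1993, "phonebook", {"A": 1, "B": 1})
        assert s_over_n(singles) == 1.0
        mono = Repertoire("C", 1993, "phonebook", {"A": 5})
        assert s_over_n(mono) == 0.2

    @pytest.mark.parametrize(
        "n0,nt,expected",
        [(297, 350, 0.15), (895, 423, -1.12), (100, 100, 0.0)],
    )
    def test_growth_rate(self, n0, nt, expected):
        assert round(growth_rate(n0, nt), 2) == expected

    def test_growth_rate_montecarlo_printed_value_mismatch(self):
        # Documented discrepancy: the printed rate (-2.09) does not equal the
        # formula applied to the printed counts (-2.19); kept verbatim, flagged.
        meta = load_study_communities().set_index("community_id")
        row = meta.loc["Montecarlo"]
        assert round(growth_rate(row.n0, row.nt), 2) == -2.19
        assert row.printed_growth_rate == -2.09


class TestAggregation:
    def test_self_aggregation_doubles_n(self):
        rep = Repertoire("C", 1993, "phonebook", {"A": 2, "B": 1})
        agg = aggregate_repertoires([rep, rep], "region")
        assert agg.s == rep.s and agg.n == 2 * rep.n

    def test_disjoint_union(self):
        a = Repertoire("A", 1993, "phonebook", {"A": 1})
        b = Repertoire("B", 1993, "phonebook", {"B": 1})
        agg = aggregate_repertoires([a, b], "region")
        assert agg.counts == {"A": 1, "B": 1}

    def test_shared_surname_summed_three_ways(self):
        reps = [
            Repertoire(f"C{i}", 1993, "phonebook", {"SHARED": i + 1, f"U{i}": 1})
            for i in range(3)
        ]
        agg = aggregate_repertoires(reps, "region")
        assert agg.counts["SHARED"] == 1 + 2 + 3
        assert agg.n == sum(r.n for r in reps)
        assert agg.s <= sum(r.s for r in reps)

    def test_empty_list_rejected(self):
        with pytest.raises(ValidationError):
            aggregate_repertoires([], "region")


class TestStudyMetadata:
    def test_table_shape_and_validation(self, tmp_path):
        meta = load_study_communities()
        assert len(meta) == 26
        assert meta.province.nunique() == 11
        assert meta.region.nunique() == 8
        # the same table passes the generic metadata reader's validation
        path = tmp_path / "meta.csv"
        meta.to_csv(path, index=False)
        frame = read_community_metadata(path)
        assert len(frame) == 26
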