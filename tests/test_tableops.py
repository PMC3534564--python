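import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirkit.datastore import NA
from mirkit.tableops import (
    ExperimentTable,
    ID_PATTERNS,
    MergePlan,
    MergeRelation,
    dedupe_rows,
    extract_ids,
    merge_columns,
    merge_datasets,
    split_column,
)


def table(rows, columns):
    return ExperimentTable(pd.DataFrame(rows, columns=columns))


LEFT = table([("TP53", "7157", "1.2"), (NA, "999", "0.5")], ["sym", "entrez", "val"])
RIGHT = table([("TP53", "10", "0.01"), ("BRCA2", "20", "0.2")], ["sym", "entrez", "p"])


class TestMergeDatasets:
    def test_self_merge_on_unique_key_preserves_rows(self):
        t = table([("a", "1"), ("b", "2"), ("c", "3")], ["key", "v"])
        plan = MergePlan((MergeRelation("key", "key"),), mode="intersection")
        merged, report = merge_datasets(t, t, plan)
        assert len(merged) == 3
        assert report.matched_by_level == [3]
        assert report.left_unmatched == report.right_unmatched == 0

    def test_hand_enumerated_intersection_and_union(self):
        plan_i = MergePlan((MergeRelation("sym", "sym"),), mode="intersection")
        merged, report = merge_datasets(LEFT, RIGHT, plan_i)
        assert len(merged) == 1
        assert merged.df.iloc[0]["sym_left"] == "TP53"
        assert report.matched_total == 1 and report.left_unmatched == 1
        assert report.right_unmatched == 1

        plan_u = MergePlan((MergeRelation("sym", "sym"),), mode="union")
        merged_u, report_u = merge_datasets(LEFT, RIGHT, plan_u)
        assert len(merged_u) == 3  # 1 matched + 1 left NA-filled + 1 right NA-filled
        assert report_u.matched_pairs + report_u.left_unmatched + report_u.right_unmatched == 3

    def test_two_level_merge_assigns_levels_by_order(self):
        right2 = table([("TP53", "10", "0.01"), (NA, "999", "0.2")], ["sym", "entrez", "p"])
        plan = MergePlan(
            (MergeRelation("sym", "sym"), MergeRelation("entrez", "entrez")),
            mode="intersection",
        )
        merged, report = merge_datasets(LEFT, right2, plan)
        assert report.matched_by_level == [1, 1]
        assert report.left_unmatched == 0
        assert len(merged) == 2

    def test_row_matchable_at_both_levels_counts_at_first(self):
        left = table([("A", "1")], ["sym", "entrez"])
        right = table([("A", "1", "x")], ["sym", "entrez", "v"])
        plan = MergePlan((MergeRelation("sym", "sym"), MergeRelation("entrez", "entrez")))
        _, report = merge_datasets(left, right, plan)
        assert report.matched_by_level == [1, 0]

    def test_na_keys_never_match(self):
        left = table([(NA, "1")], ["sym", "v"])
        right = table([(NA, "2")], ["sym", "w"])
        plan = MergePlan((MergeRelation("sym", "sym"),), mode="union")
        merged, report = merge_datasets(left, right, plan)
        assert report.matched_total == 0
        assert len(merged) == 2

    def test_symbol_namespace_folds_case(self):
        left = table([("tp53", "1")], ["sym", "v"])
        right = table([("TP53", "2")], ["sym", "w"])
        exact = MergePlan((MergeRelation("sym", "sym"),))
        folded = MergePlan((MergeRelation("sym", "sym", namespace="gene_symbol"),))
        assert merge_datasets(left, right, exact)[1].matched_total == 0
        assert merge_datasets(left, right, folded)[1].matched_total == 1

    def test_one_to_many_expands_cartesian(self):
        left = table([("A", "x")], ["k", "v"])
        right = table([("A", "1"), ("A", "2")], ["k", "w"])
        merged, report = merge_datasets(left, right, MergePlan((MergeRelation("k", "k"),)))
        assert len(merged) == 2
        assert report.matched_total == 1 and report.matched_pairs == 2

    def test_translated_relation_bridges_namespaces(self, snapshot):
        # left carries dre Entrez ids, right carries dre symbols
        left = table([("100007", "a"), ("100008", "b")], ["entrez", "v"])
        right = table([("g000007", "x"), ("g000009", "y")], ["sym", "w"])
        plan = MergePlan(
            (MergeRelation("entrez", "sym", translation=("entrez", "gene_symbol", "dre")),),
            mode="intersection",
        )
        merged, report = merge_datasets(left, right, plan, snapshot)
        assert report.matched_total == 1
        assert merged.df.iloc[0]["sym"] == "g000007"

    def test_translation_without_snapshot_is_fatal(self):
        plan = MergePlan(
            (MergeRelation("entrez", "sym", translation=("entrez", "gene_symbol", "dre")),)
        )
        with pytest.raises(ValueError, match="snapshot"):
            merge_datasets(LEFT, RIGHT, plan)

    def test_missing_relation_column_is_fatal(self):
        plan = MergePlan((MergeRelation("nope", "sym"),))
        with pytest.raises(ValueError, match="nope"):
            merge_datasets(LEFT, RIGHT, plan)

    def _random_table(self, rng, n_rows, prefix):
        keys1 = [rng.choice(["a", "b", "c", "d", NA]) for _ in range(n_rows)]
        keys2 = [str(rng.integers(0, 5)) for _ in range(n_rows)]
        vals = [f"{prefix}{i}" for i in range(n_rows)]
        return table(list(zip(keys1, keys2, vals)), ["k1", "k2", "v"])

    @pytest.mark.parametrize("seed", range(12))
    def test_union_conservation_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        left = self._random_table(rng, int(rng.integers(0, 12)), "L")
        right = self._random_table(rng, int(rng.integers(0, 12)), "R")
        relations = (MergeRelation("k1", "k1"), MergeRelation("k2", "k2"))
        union, report = merge_datasets(left, right, MergePlan(relations, mode="union"))
        inter, report_i = merge_datasets(left, right, MergePlan(relations, mode="intersection"))
        assert len(union) == report.matched_pairs + report.left_unmatched + report.right_unmatched
        assert sum(report.matched_by_level) == report.matched_total
        assert report.matched_total + report.left_unmatched == len(left)
        # intersection rows are a subset of union rows
        union_rows = {tuple(r) for r in union.df.itertuples(index=False)}
        inter_rows = {tuple(r) for r in inter.df.itertuples(index=False)}
        assert inter_rows <= union_rows
        assert report_i.matched_total == report.matched_total

    @pytest.mark.parametrize("seed", range(6))
    def test_right_row_order_never_changes_report(self, seed):
        rng = np.random.default_rng(100 + seed)
        left = self._random_table(rng, 10, "L")
        right = self._random_table(rng, 10, "R")
        plan = MergePlan((MergeRelation("k1", "k1"), MergeRelation("k2", "k2")))
        _, report = merge_datasets(left, right, plan)
        shuffled = ExperimentTable(right.df.sample(frac=1, random_state=7).reset_index(drop=True))
        _, report_s = merge_datasets(left, shuffled, plan)
        assert report.matched_by_level == report_s.matched_by_level
        assert report.right_unmatched == report_s.right_unmatched

    def test_reversing_independent_relations_preserves_matched_total(self):
        left = table([("A", "1"), ("B", "2"), (NA, "3")], ["sym", "entrez"])
        right = table([("A", "9"), (NA, "2"), (NA, "3")], ["sym", "entrez"])
        fwd = MergePlan((MergeRelation("sym", "sym"), MergeRelation("entrez", "entrez")))
        rev = MergePlan((MergeRelation("entrez", "entrez"), MergeRelation("sym", "sym")))
        _, r1 = merge_datasets(left, right, fwd)
        _, r2 = merge_datasets(left, right, rev)
        assert r1.matched_total == r2.matched_total
        assert r1.matched_by_level != r2.matched_by_level  # attribution may shift


class TestRowOps:
    def test_dedupe_noop_without_duplicates(self):
        t = table([("a", "1"), ("b", "2")], ["k", "v"])
        out = dedupe_rows(t, ["k"])
        assert len(out) == 2

    def test_dedupe_keeps_earliest_row_id(self):
        t = table([("a", "first"), ("a", "second")], ["k", "v"])
        with pytest.warns(UserWarning):
            out = dedupe_rows(t, ["k"])
        assert len(out) == 1
        assert out.df.iloc[0]["v"] == "first"
        assert list(out.df.index) == [0]

    def test_dedupe_count_matches_bruteforce_grouping(self):
        rng = np.random.default_rng(5)
        keys = [str(rng.integers(0, 8)) for _ in range(50)]
        t = table([(k, str(i)) for i, k in enumerate(keys)], ["k", "v"])
        with pytest.warns(UserWarning):
            out = dedupe_rows(t, ["k"])
        expected_removed = len(keys) - len(set(keys))
        assert out.df.attrs["n_removed"] == expected_removed
        assert len(out) == len(set(keys))

    def test_dedupe_empty_keys_fatal(self):
        with pytest.raises(ValueError):
            dedupe_rows(LEFT, [])


class TestSplitMerge:
    def test_split_on_delimiter(self):
        t = table([("GO:1;GO:2",), ("GO:3",)], ["terms"])
        out = split_column(t, "terms", ";")
        assert out.df.iloc[0]["terms_1"] == "GO:1"
        assert out.df.iloc[0]["terms_2"] == "GO:2"
        assert out.df.iloc[1]["terms_2"] == NA  # padded

    def test_merge_skips_na(self):
        t = table([("a", NA, "c")], ["x", "y", "z"])
        out = merge_columns(t, ["x", "y", "z"], "_")
        assert out.df.iloc[0]["x_y_z"] == "a_c"

    def test_empty_delimiter_fatal(self):
        with pytest.raises(ValueError):
            split_column(LEFT, "sym", "")

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.lists(st.text(alphabet="abcXYZ09", min_size=1, max_size=4), min_size=1, max_size=4),
            min_size=1,
            max_size=6,
        )
    )
    def test_split_then_merge_round_trip(self, cell_parts):
        original = [";".join(parts) for parts in cell_parts]
        t = table([(v,) for v in original], ["c"])
        split = split_column(t, "c", ";")
        part_cols = [c for c in split.columns if c.startswith("c_")]
        merged = merge_columns(split, part_cols, ";", new_column="restored")
        assert list(merged.df["restored"]) == original


class TestExtractIds:
    def test_genbank_preset(self):
        t = table([("NM_001234 | tp53 | chr17",)], ["c"])
        out = extract_ids(t, "c", "genbank")
        assert out.df.iloc[0]["c_genbank"] == "NM_001234"

    def test_no_match_is_na(self):
        t = table([("nothing here",)], ["c"])
        out = extract_ids(t, "c", "go_term")
        assert out.df.iloc[0]["c_go_term"] == NA

    def test_invalid_custom_pattern_fatal(self):
        with pytest.raises(ValueError, match="invalid pattern"):
            extract_ids(LEFT, "sym", "([")

    def test_presets_match_scan_oracle_on_composite_cells(self):
        rng = np.random.default_rng(9)
        fragments = {
            "genbank": lambda: f"NM_{rng.integers(0, 999999):06d}",
            "ensembl_gene": lambda: f"ENSDARG{rng.integers(0, 10**11):011d}",
            "ensembl_transcript": lambda: f"ENST{rng.integers(0, 10**11):011d}",
            "go_term": lambda: f"GO:{rng.integers(0, 10**7):07d}",
        }
        noise = ["tp53", "chr17", "hello", "xyz"]
        cells = []
        for _ in range(100):
            parts = [fragments[k]() for k in fragments if rng.random() < 0.6]
            parts += [noise[rng.integers(0, len(noise))]]
            parts = [parts[i] for i in rng.permutation(len(parts))]
            cells.append(" | ".join(parts))
        t = table([(c,) for c in cells], ["c"])
        for preset, make in fragments.items():
            out = extract_ids(t, "c", preset)
            for cell, got in zip(cells, out.df[f"c_{preset}"]):
                expected = self._scan_oracle(cell, preset)
                assert got == expected, (preset, cell)

    @staticmethod
    def _scan_oracle(cell, preset):
        """Character-scan oracle: find the first identifier by prefix walk."""
        prefixes = {
            "genbank": "NM_",
            "ensembl_gene": "ENSDARG",
            "ensembl_transcript": "ENST",
            "go_term": "GO:",
        }
        prefix = prefixes[preset]
        for i in range(len(cell)):
            if cell[i : i + len(prefix)] == prefix:
                j = i + len(prefix)
                k = j
                while k < len(cell) and cell[k].isdigit():
                    k += 1
                if k > j:
                    return cell[i:k]
        return NA


def test_duplicate_column_names_rejected():
    df = pd.DataFrame([[1, 2]], columns=["a", "a"])
    with pytest.raises(ValueError, match="duplicate column"):
        ExperimentTable(df)
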