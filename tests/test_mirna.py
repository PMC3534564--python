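import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirkit import fixtures as fx, idmap, mirna
from mirkit.datastore import NA


def rec(seq, name="m", species="dre"):
    return mirna.MiRNARecord(species, name, "MIMAT0000001", seq)


def brute_force_mismatch(a, b):
    """Independent position-by-position recount of the homology metric."""
    n = 0
    for i in range(max(len(a), len(b))):
        if i >= len(a) or i >= len(b) or a[i] != b[i]:
            n += 1
    seed_ok = all(
        i < len(a) and i < len(b) and a[i] == b[i] for i in range(1, 8)
    )
    return n, seed_ok


class TestHomologyFilter:
    BASE = "UGAGGUAGUAGGUUGUAUAGUU"  # 22-mer

    def edited(self, pos_1based, new="C"):
        i = pos_1based - 1
        assert self.BASE[i] != new
        return self.BASE[:i] + new + self.BASE[i + 1 :]

    @pytest.mark.parametrize(
        "seq_b,n_mismatch,seed_identical,passes",
        [
            (BASE, 0, True, True),                      # identical 22-mers
            ("UGAGGUAGUCGGUUGUAUAGUU", 1, True, True),   # position 10 edit
            ("UGCGGUAGUAGGUUGUAUAGUU", 1, False, False),  # position 3 (seed) edit
            (BASE[:21], 1, True, True),                  # identical 21-mer prefix
        ],
    )
    def test_hand_counted_cases(self, seq_b, n_mismatch, seed_identical, passes):
        out = mirna.homology_filter([(rec(self.BASE), rec(seq_b, species="hsa"))], max_mismatch=1)
        row = out.iloc[0]
        assert row["n_mismatch"] == n_mismatch
        assert row["seed_identical"] == seed_identical
        assert row["pass"] == passes

    def test_seed_edit_fails_despite_budget(self):
        for pos in range(2, 9):
            seq_b = self.edited(pos, "C" if self.BASE[pos - 1] != "C" else "A")
            out = mirna.homology_filter([(rec(self.BASE), rec(seq_b))], max_mismatch=1)
            assert not out.iloc[0]["pass"], f"seed position {pos} must force failure"

    def test_zero_budget_passes_only_identical(self):
        pairs = [
            (rec(self.BASE), rec(self.BASE)),
            (rec(self.BASE), rec(self.edited(10))),
            (rec(self.BASE), rec(self.BASE[:21])),
        ]
        out = mirna.homology_filter(pairs, max_mismatch=0)
        assert list(out["pass"]) == [True, False, False]

    def test_dna_input_is_normalized(self):
        dna = self.BASE.replace("U", "t")
        out = mirna.homology_filter([(rec(dna), rec(self.BASE))], max_mismatch=0)
        assert out.iloc[0]["pass"]

    def test_invalid_character_is_fatal_and_names_the_record(self):
        with pytest.raises(ValueError, match="bad-mir"):
            mirna.homology_filter([(rec("ACGUNACGUACGUACGUACGUA", name="bad-mir"), rec(self.BASE))])

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        st.text(alphabet="ACGU", min_size=18, max_size=26),
        st.text(alphabet="ACGU", min_size=18, max_size=26),
        st.integers(min_value=0, max_value=3),
    )
    def test_matches_bruteforce_on_random_pairs(self, a, b, budget):
        out = mirna.homology_filter([(rec(a), rec(b, species="hsa"))], max_mismatch=budget)
        n, seed_ok = brute_force_mismatch(a, b)
        row = out.iloc[0]
        assert row["n_mismatch"] == n
        assert row["seed_identical"] == seed_ok
        assert row["pass"] == (n <= budget and seed_ok)


def all_hsa_mirnas(spec):
    return [fx.mirna_id(i, "hsa") for i in range(1, spec.n_mirnas + 1)]


def brute_force_pairs(snapshot_dir, species, source):
    from mirkit.datastore import read_table

    df = read_table(snapshot_dir / f"targets_{source}.tsv")
    df = df[df["species"] == species]
    return set(zip(df["mirna_id"], df["gene_symbol"]))


class TestPredictTargets:
    def test_empty_input_is_empty_table(self, snapshot):
        out = mirna.predict_targets([], "hsa", min_agreement=2, level="gene", s=snapshot)
        assert len(out) == 0

    def test_flags_reflect_source_membership(self, snapshot, snapshot_fixture, default_spec):
        out = mirna.predict_targets(
            all_hsa_mirnas(default_spec), "hsa", min_agreement=1, level="pair", s=snapshot
        )
        sets = {
            src: brute_force_pairs(snapshot_fixture.out_dir, "hsa", src)
            for src in ("targetscan", "microcosm", "mirnaorg")
        }
        for row in out.itertuples(index=False):
            pair = (row.mirna_id, row.gene_symbol)
            flags = (row.in_targetscan, row.in_microcosm, row.in_mirnaorg)
            expected = tuple(pair in sets[s] for s in ("targetscan", "microcosm", "mirnaorg"))
            assert flags == expected
            assert row.agreement_count == sum(expected)

    def test_planted_conserved_pairs_recovered_at_pair_level(
        self, snapshot, snapshot_fixture, default_spec
    ):
        out = mirna.predict_targets(
            all_hsa_mirnas(default_spec), "hsa", min_agreement=2, level="pair", s=snapshot
        )
        got = set(zip(out["mirna_id"], out["gene_symbol"]))
        planted = set(
            zip(snapshot_fixture.conserved["dst_mirna_id"], snapshot_fixture.conserved["dst_gene_symbol"])
        )
        assert got == planted

    def test_gene_level_union_matches_bruteforce(self, snapshot, snapshot_fixture, default_spec):
        out = mirna.predict_targets(
            all_hsa_mirnas(default_spec), "hsa", min_agreement=1, level="gene", s=snapshot
        )
        union = set()
        for src in ("targetscan", "microcosm", "mirnaorg"):
            union |= {g for _, g in brute_force_pairs(snapshot_fixture.out_dir, "hsa", src)}
        assert set(out["gene_symbol"]) == union
        assert len(out) == len(union)  # gene rows unique

    @pytest.mark.parametrize("level", ["pair", "gene"])
    def test_agreement_monotonicity(self, snapshot, default_spec, level):
        mirnas = all_hsa_mirnas(default_spec)
        key = ["mirna_id", "gene_symbol"] if level == "pair" else ["gene_symbol"]
        prev = None
        for k in (1, 2, 3):
            out = mirna.predict_targets(mirnas, "hsa", min_agreement=k, level=level, s=snapshot)
            keys = set(map(tuple, out[key].itertuples(index=False)))
            if prev is not None:
                assert keys <= prev
            prev = keys

    def test_min_agreement_above_sources_is_fatal(self, snapshot):
        with pytest.raises(ValueError, match="min_agreement"):
            mirna.predict_targets(["hsa-miR-1"], "hsa", ("microcosm",), 2, "gene", snapshot)

    def test_sorted_by_agreement_then_key(self, snapshot, default_spec):
        out = mirna.predict_targets(
            all_hsa_mirnas(default_spec), "hsa", min_agreement=1, level="gene", s=snapshot
        )
        rows = list(zip(-out["agreement_count"], out["gene_symbol"]))
        assert rows == sorted(rows)

    def test_absent_mirna_warns(self, snapshot):
        with pytest.warns(UserWarning, match="hsa-miR-9999"):
            mirna.predict_targets(["hsa-miR-9999"], "hsa", min_agreement=1, level="gene", s=snapshot)


class TestRegulatoryMirnas:
    def test_absent_gene_gets_na_row(self, snapshot):
        out = mirna.regulatory_mirnas(["gX"], "gene_symbol", "hsa", s=snapshot)
        assert out.iloc[0].tolist() == ["gX", NA, NA]

    def test_planted_single_source_regulator(self, snapshot, snapshot_fixture):
        bg = snapshot_fixture.background
        row = bg[bg["species"] == "dre"].iloc[0]
        out = mirna.regulatory_mirnas([row["gene_symbol"]], "gene_symbol", "dre", s=snapshot)
        hits = set(zip(out["mirna_id"], out["source"]))
        assert (row["mirna_id"], row["source"]) in hits

    def test_entrez_input_equals_symbol_query(self, snapshot, snapshot_fixture):
        gene = snapshot_fixture.conserved.iloc[0]
        gi = int(gene["gene_index"])
        by_symbol = mirna.regulatory_mirnas([fx.gene_symbol(gi, "hsa")], "gene_symbol", "hsa", s=snapshot)
        by_entrez = mirna.regulatory_mirnas([fx.entrez_id(gi, "hsa")], "entrez", "hsa", s=snapshot)
        assert set(zip(by_symbol["mirna_id"], by_symbol["source"])) == set(
            zip(by_entrez["mirna_id"], by_entrez["source"])
        )


class TestMetadata:
    def test_unknown_id_gets_na_fields(self, snapshot):
        out = mirna.get_metadata(["dre-miR-999"], "dre", snapshot)
        assert out.iloc[0].tolist() == ["dre", "dre-miR-999", NA, NA, False]

    def test_planted_record_returned_verbatim(self, snapshot):
        meta = snapshot.table("mirna_metadata")
        planted = meta[meta["species"] == "dre"].iloc[0]
        out = mirna.get_metadata([planted["mirna_id"]], "dre", snapshot)
        assert out.iloc[0]["mature_accession"] == planted["mature_accession"]
        assert out.iloc[0]["mature_sequence"] == planted["mature_sequence"]

    def test_duplicate_inputs_deduplicated(self, snapshot):
        out = mirna.get_metadata(["dre-miR-1", "dre-miR-1"], "dre", snapshot)
        assert len(out) == 1
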