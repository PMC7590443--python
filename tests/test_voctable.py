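"""Filtering, normalisation and class aggregation of volatile tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fruitscent.voctable import (
    CLASS_ORDER,
    ClassMap,
    ScentTable,
    SpeciesProfile,
    aggregate_classes,
    filter_compounds,
    read_class_map,
    read_scent_table,
    relative_amounts,
    species_means,
    write_class_map,
    write_scent_table,
)

from conftest import make_table


# ---------------------------------------------------------------------------
# brute-force oracle for the filtering rules
# ---------------------------------------------------------------------------

def removed_by_rules_oracle(table, controls, ubiq, rare, share):
    """Independent loop-based enumeration of the four removal rules."""
    fruit = [s for s in table.samples if s not in controls]
    removed = {}
    for c in table.compound_ids:
        rules = set()
        if controls:
            cmean = np.mean([table.amounts.loc[s, c] for s in sorted(controls)])
            fmean = np.mean([table.amounts.loc[s, c] for s in fruit])
            if cmean > 0 and cmean >= fmean:
                rules.add("control_contaminant")
        n_present = sum(table.amounts.loc[s, c] > 0 for s in fruit)
        if n_present / len(fruit) > ubiq:
            rules.add("ubiquity")
        sp_with = {table.species_of[s] for s in fruit if table.amounts.loc[s, c] > 0}
        if len(sp_with) == 1 and n_present / len(fruit) < rare:
            rules.add("rare_single_species")
        max_share = 0.0
        for sp in sorted({table.species_of[s] for s in fruit}):
            members = [s for s in fruit if table.species_of[s] == sp]
            mean_c = np.mean([table.amounts.loc[s, c] for s in members])
            total = sum(
                np.mean([table.amounts.loc[s, cc] for s in members])
                for cc in table.compound_ids
            )
            if total > 0:
                max_share = max(max_share, mean_c / total)
        if max_share <= share:
            rules.add("low_max_share")
        if rules:
            removed[c] = rules
    return removed


class TestFilterCompounds:
    def test_toy_table_rules(self, toy_table):
        filtered, log = filter_compounds(toy_table)
        by_rule = {r: set(g["compound"]) for r, g in log.groupby("rule")}
        # ubiquitous compound: present in 100% > 90%
        assert "everywhere" in by_rule["ubiquity"]
        # X: one species only, 1/10 = 10% < 25%
        assert "X" in by_rule["rare_single_species"]
        # Y: one species but 3/10 = 30% of samples -> retained by rarity rule
        assert "Y" not in by_rule.get("rare_single_species", set())
        assert "Y" in filtered.compound_ids
        # tiny: never above 1% of any species' emission
        assert "tiny" in by_rule["low_max_share"]
        assert set(filtered.compound_ids) == {"Y", "shared"}

    def test_matches_bruteforce_oracle(self, toy_table):
        _, log = filter_compounds(toy_table, ubiquity_threshold=0.8,
                                  rare_sample_fraction=0.35,
                                  max_share_threshold=0.05)
        oracle = removed_by_rules_oracle(toy_table, set(), 0.8, 0.35, 0.05)
        got = {c: set(g["rule"]) for c, g in log.groupby("compound")}
        assert got == oracle

    def test_control_contaminant_rule(self):
        table = make_table(
            {"s1": {"fruity": 3.0, "dirt": 0.5},
             "s2": {"fruity": 5.0, "dirt": 0.2},
             "blank": {"fruity": 0.1, "dirt": 1.0}},
            {"s1": "alpha", "s2": "beta", "blank": "control"},
        )
        filtered, log = filter_compounds(
            table, control_samples={"blank"}, ubiquity_threshold=None,
            rare_sample_fraction=None, max_share_threshold=None)
        assert set(log["compound"]) == {"dirt"}
        assert set(filtered.compound_ids) == {"fruity"}
        assert "blank" not in filtered.samples

    def test_idempotent(self, toy_table):
        once, _ = filter_compounds(toy_table)
        twice, log2 = filter_compounds(once)
        assert twice.amounts.equals(once.amounts)
        assert len(log2) == 0

    def test_bad_threshold_rejected(self, toy_table):
        with pytest.raises(ValueError, match="ubiquity_threshold"):
            filter_compounds(toy_table, ubiquity_threshold=1.5)
        with pytest.raises(ValueError, match="max_share_threshold"):
            filter_compounds(toy_table, max_share_threshold=0.0)

    def test_empty_table_rejected(self, toy_table):
        empty = ScentTable(toy_table.amounts.iloc[:, :0], toy_table.meta)
        with pytest.raises(ValueError, match="empty"):
            filter_compounds(empty)


class TestSpeciesMeans:
    def test_arithmetic_mean_and_zero_fill(self):
        table = make_table(
            {"s1": {"A": 1.0, "B": 3.0}, "s2": {"A": 3.0, "B": 1.0},
             "s3": {"A": 8.0}, "s4": {}, "s5": {}, "s6": {}},
            {"s1": "x", "s2": "x", "s3": "y", "s4": "y", "s5": "y", "s6": "y"},
        )
        means = species_means(table)
        assert means.loc["x", "A"] == 2.0 and means.loc["x", "B"] == 2.0
        # compound in 1 of 4 samples at amount 8 -> mean 2 (absences count)
        assert means.loc["y", "A"] == 2.0
        assert list(means.index) == ["x", "y"]  # sorted, sample-order free

    def test_single_sample_species_identity(self):
        table = make_table({"s1": {"A": 4.0, "B": 0.5}}, {"s1": "only"})
        means = species_means(table)
        assert means.loc["only"].tolist() == [4.0, 0.5]


class TestRelativeAmounts:
    def test_forced_values(self):
        m = pd.DataFrame([[2.0, 3.0, 5.0]], index=["sp"], columns=list("abc"))
        prof = relative_amounts(m)
        assert prof.values.loc["sp"].tolist() == [0.2, 0.3, 0.5]
        single = relative_amounts(pd.DataFrame([[7.0]], index=["sp"], columns=["a"]))
        assert single.values.iloc[0, 0] == 1.0

    def test_all_zero_row_warned_and_kept(self):
        m = pd.DataFrame([[1.0, 1.0], [0.0, 0.0]], index=["a", "b"],
                         columns=["c1", "c2"])
        with pytest.warns(UserWarning, match="all-zero"):
            prof = relative_amounts(m)
        assert prof.zero_rows == ["b"]
        assert prof.values.loc["b"].sum() == 0.0

    def test_negative_rejected(self):
        m = pd.DataFrame([[1.0, -0.1]], index=["a"], columns=["c1", "c2"])
        with pytest.raises(ValueError, match="negative"):
            relative_amounts(m)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(scale=st.floats(min_value=1e-6, max_value=1e6),
           row=st.lists(st.floats(min_value=0.0, max_value=100.0),
                        min_size=2, max_size=6).filter(lambda r: sum(r) > 0))
    def test_scale_invariance(self, scale, row):
        cols = [f"c{i}" for i in range(len(row))]
        base = pd.DataFrame([row], index=["sp"], columns=cols)
        scaled = base * scale
        a = relative_amounts(base).values.to_numpy()
        b = relative_amounts(scaled).values.to_numpy()
        np.testing.assert_allclose(a, b, atol=1e-12)


class TestAggregateClasses:
    def test_additivity(self):
        prof = SpeciesProfile(pd.DataFrame(
            [[0.3, 0.2, 0.5]], index=["sp"], columns=["a1", "a2", "t1"]))
        cm = ClassMap({"a1": "aliphatics", "a2": "aliphatics", "t1": "terpenoids"})
        agg = aggregate_classes(prof, cm)
        assert agg.values.loc["sp", "aliphatics"] == pytest.approx(0.5)
        assert agg.values.loc["sp", "terpenoids"] == pytest.approx(0.5)
        assert agg.level == "class"

    def test_single_class_everything(self):
        prof = SpeciesProfile(pd.DataFrame(
            [[0.4, 0.6]], index=["sp"], columns=["a1", "a2"]))
        cm = ClassMap({"a1": "aromatics", "a2": "aromatics"})
        agg = aggregate_classes(prof, cm)
        assert list(agg.values.columns) == ["aromatics"]
        assert agg.values.iloc[0, 0] == 1.0

    def test_groupby_oracle_and_row_sum_conservation(self):
        rng = np.random.default_rng(7)
        raw = rng.gamma(0.5, size=(8, 20)) * (rng.random((8, 20)) < 0.5)
        raw[raw.sum(axis=1) == 0, 0] = 1.0
        cols = [f"c{i}" for i in range(20)]
        prof = relative_amounts(pd.DataFrame(
            raw, index=[f"sp{i}" for i in range(8)], columns=cols))
        classes = [CLASS_ORDER[i % 7] for i in range(20)]
        cm = ClassMap(dict(zip(cols, classes)))
        agg = aggregate_classes(prof, cm)
        # independent group-by: explicit python accumulation
        for sp in prof.species:
            sums: dict[str, float] = {}
            for c, cls in zip(cols, classes):
                sums[cls] = sums.get(cls, 0.0) + prof.values.loc[sp, c]
            for cls, val in sums.items():
                assert agg.values.loc[sp, cls] == pytest.approx(val, abs=1e-15)
            assert abs(agg.values.loc[sp].sum() - prof.values.loc[sp].sum()) < 1e-12
        # canonical column order
        assert list(agg.values.columns) == [c for c in CLASS_ORDER
                                            if c in set(classes)]

    def test_unmapped_compound_named_in_error(self):
        prof = SpeciesProfile(pd.DataFrame(
            [[1.0, 0.0]], index=["sp"], columns=["known", "mystery"]))
        cm = ClassMap({"known": "aliphatics"})
        with pytest.raises(KeyError, match="mystery"):
            aggregate_classes(prof, cm)


class TestIO:
    def test_scent_table_roundtrip(self, toy_table, tmp_path):
        path = tmp_path / "scent.tsv"
        write_scent_table(toy_table, path)
        back = read_scent_table(path)
        pd.testing.assert_frame_equal(back.amounts, toy_table.amounts)
        assert back.species_of.to_dict() == toy_table.species_of.to_dict()

    def test_class_map_roundtrip(self, classmap7, tmp_path):
        path = tmp_path / "cm.csv"
        write_class_map(classmap7, path)
        assert read_class_map(path).class_of == classmap7.class_of

    def test_missing_cells_read_as_zero(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("sample,species,c1,c2\ns1,alpha,1.0,\ns2,beta,,2.0\n")
        table = read_scent_table(path)
        assert table.amounts.loc["s1", "c2"] == 0.0
        assert table.amounts.loc["s2", "c1"] == 0.0

    def test_invalid_tables_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            make_table({"s1": {"A": -1.0}}, {"s1": "x"})
        with pytest.raises(ValueError, match="ripeness"):
            make_table({"s1": {"A": 1.0}}, {"s1": "x"}, ripeness="overripe")
        with pytest.raises(ValueError, match="class labels"):
            ClassMap({"c": "esters"})
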