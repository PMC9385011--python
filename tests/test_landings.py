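"""Landings filter cascade: confidentiality cut, misc drop, group expansion,
top-90% retention, and revenue shares."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coastvuln import landings as ld


def receipts(rows):
    """rows: (community, species, year, weight, revenue, confidential, category)"""
    df = pd.DataFrame(rows, columns=["community", "species", "year", "weight",
                                     "revenue", "confidential", "category"])
    df["port_group"] = "PG1"
    return df


class TestAggregate:
    def test_single_receipt(self):
        totals = ld.aggregate_landings(receipts(
            [("C1", "a", 2010, 5.0, 10.0, False, "normal")]))
        assert totals["weight"].iloc[0] == 5.0

    def test_same_key_sums(self):
        totals = ld.aggregate_landings(receipts([
            ("C1", "a", 2010, 2.0, 1.0, False, "normal"),
            ("C1", "a", 2012, 3.0, 2.0, False, "normal")]))
        assert len(totals) == 1
        assert totals["weight"].iloc[0] == 5.0

    def test_year_span_inclusive_and_oracle(self):
        rng = np.random.default_rng(4)
        rows = [("C1", f"s{rng.integers(3)}", int(rng.integers(2009, 2019)),
                 float(rng.uniform(1, 10)), float(rng.uniform(1, 20)),
                 False, "normal") for _ in range(60)]
        df = receipts(rows)
        totals = ld.aggregate_landings(df, years=(2010, 2015))
        sub = df[(df["year"] >= 2010) & (df["year"] <= 2015)]
        expected = sub.groupby("species")["weight"].sum()
        got = totals.groupby("species")["weight"].sum()
        pd.testing.assert_series_equal(got, expected)

    def test_empty_span_warns(self):
        with pytest.warns(UserWarning, match="no receipts"):
            out = ld.aggregate_landings(
                receipts([("C1", "a", 2010, 1, 1, False, "normal")]),
                years=(1990, 1995))
        assert out.empty


class TestConfidentialFilter:
    def _totals(self, frac):
        return ld.aggregate_landings(receipts([
            ("C1", "a", 2010, 100 * (1 - frac), 1.0, False, "normal"),
            ("C1", "a", 2010, 100 * frac, 1.0, True, "normal")]))

    def test_quarter_confidential_removed(self):
        out, removed = ld.filter_confidential(self._totals(0.25))
        assert removed == ["C1"] and out.empty

    def test_zero_confidential_retained_unchanged(self):
        totals = self._totals(0.0)
        out, removed = ld.filter_confidential(totals)
        assert removed == []
        pd.testing.assert_frame_equal(out, totals[~totals["confidential"]]
                                      .reset_index(drop=True))

    def test_exactly_twenty_percent_retained(self):
        out, removed = ld.filter_confidential(self._totals(0.20))
        assert removed == []
        assert not out["confidential"].any()  # confidential rows still dropped

    def test_idempotent(self):
        once, _ = ld.filter_confidential(self._totals(0.25))
        twice, _ = ld.filter_confidential(once)
        pd.testing.assert_frame_equal(once, twice)


class TestDropMisc:
    def test_small_misc_removed(self):
        totals = ld.aggregate_landings(receipts([
            ("C1", "a", 2010, 97.0, 1.0, False, "normal"),
            ("C1", "misc", 2010, 3.0, 1.0, False, "other_misc")]))
        out, flagged = ld.drop_misc(totals)
        assert flagged == []
        assert not (out["category"] == "other_misc").any()

    def test_large_misc_retained_and_flagged(self):
        totals = ld.aggregate_landings(receipts([
            ("C1", "a", 2010, 93.0, 1.0, False, "normal"),
            ("C1", "misc", 2010, 7.0, 1.0, False, "other_misc")]))
        with pytest.warns(UserWarning, match="flagged"):
            out, flagged = ld.drop_misc(totals)
        assert flagged == ["C1"]
        assert (out["category"] == "other_misc").any()

    def test_no_misc_identity(self):
        totals = ld.aggregate_landings(receipts(
            [("C1", "a", 2010, 5.0, 1.0, False, "normal")]))
        out, flagged = ld.drop_misc(totals)
        pd.testing.assert_frame_equal(out, totals)


class TestExpandUnidentified:
    def test_split_conserves_and_distributes(self):
        totals = ld.aggregate_landings(receipts([
            ("C1", "grp", 2010, 10.0, 4.0, False, "unidentified_group")]))
        out = ld.expand_unidentified(totals, {"grp": {"A": 0.6, "B": 0.4}})
        by_sp = out.set_index("species")
        assert by_sp.loc["A", "weight"] == pytest.approx(6.0)
        assert by_sp.loc["B", "weight"] == pytest.approx(4.0)

    def test_empty_mapping_identity(self):
        totals = ld.aggregate_landings(receipts(
            [("C1", "a", 2010, 5.0, 1.0, False, "normal")]))
        pd.testing.assert_frame_equal(ld.expand_unidentified(totals, {}), totals)

    def test_unmapped_label_rejected_by_name(self):
        totals = ld.aggregate_landings(receipts(
            [("C1", "grp2", 2010, 5.0, 1.0, False, "unidentified_group")]))
        with pytest.raises(ValueError, match="grp2"):
            ld.expand_unidentified(totals, {"grp": {"A": 1.0}})

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=5))
    def test_conservation_property(self, raw):
        fracs = [f / sum(raw) for f in raw]
        group_map = {"grp": {f"m{i}": f for i, f in enumerate(fracs)}}
        totals = ld.aggregate_landings(receipts([
            ("C1", "grp", 2010, 13.7, 5.3, False, "unidentified_group"),
            ("C1", "a", 2010, 2.0, 1.0, False, "normal")]))
        out = ld.expand_unidentified(totals, group_map)
        assert out["weight"].sum() == pytest.approx(15.7, rel=1e-12)
        assert out["revenue"].sum() == pytest.approx(6.3, rel=1e-12)


class TestTop90:
    def _totals(self, shares):
        return ld.aggregate_landings(receipts([
            ("C1", f"s{i}", 2010, w, 1.0, False, "normal")
            for i, w in enumerate(shares)]))

    def test_toy_shares_retain_three(self):
        retained = ld.top90_by_weight(self._totals([50, 30, 15, 5]))
        assert sorted(retained["species"]) == ["s0", "s1", "s2"]

    def test_single_species(self):
        retained = ld.top90_by_weight(self._totals([100]))
        assert list(retained["species"]) == ["s0"]

    def test_boundary_share_alone(self):
        retained = ld.top90_by_weight(self._totals([90, 10]))
        assert list(retained["species"]) == ["s0"]

    def test_weight_ties_broken_by_identifier(self):
        retained = ld.top90_by_weight(self._totals([40, 40, 20]))
        # cumulative 40, 80, 100 -> all three retained; ordering deterministic
        assert sorted(retained["species"]) == ["s0", "s1", "s2"]


class TestRevenueShares:
    def test_single_retained_species(self):
        totals = ld.aggregate_landings(receipts(
            [("C1", "a", 2010, 5.0, 30.0, False, "normal")]))
        retained = pd.DataFrame({"community": ["C1"], "species": ["a"]})
        shares = ld.revenue_shares(totals, retained)
        assert shares["p"].iloc[0] == 1.0

    def test_thirty_seventy_split(self):
        totals = ld.aggregate_landings(receipts([
            ("C1", "a", 2010, 5.0, 30.0, False, "normal"),
            ("C1", "b", 2010, 5.0, 70.0, False, "normal")]))
        retained = pd.DataFrame({"community": ["C1", "C1"], "species": ["a", "b"]})
        shares = ld.revenue_shares(totals, retained).set_index("species")
        assert shares.loc["a", "p"] == pytest.approx(0.3)
        assert shares.loc["b", "p"] == pytest.approx(0.7)

    def test_shares_sum_to_one_per_community(self):
        rng = np.random.default_rng(8)
        rows = [(f"C{c}", f"s{s}", 2010, float(rng.uniform(1, 50)),
                 float(rng.uniform(1, 100)), False, "normal")
                for c in range(5) for s in range(6)]
        totals = ld.aggregate_landings(receipts(rows))
        retained = ld.top90_by_weight(totals)
        shares = ld.revenue_shares(totals, retained)
        sums = shares.groupby("community")["p"].sum()
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_unscored_species_dropped_and_renormalized(self):
        totals = ld.aggregate_landings(receipts([
            ("C1", "a", 2010, 5.0, 30.0, False, "normal"),
            ("C1", "b", 2010, 5.0, 70.0, False, "normal")]))
        retained = pd.DataFrame({"community": ["C1", "C1"], "species": ["a", "b"]})
        shares = ld.revenue_shares(totals, retained, scored_species={"b"})
        assert list(shares["species"]) == ["b"]
        assert shares["p"].iloc[0] == 1.0

    def test_weight_based_variant(self):
        totals = ld.aggregate_landings(receipts([
            ("C1", "a", 2010, 9.0, 30.0, False, "normal"),
            ("C1", "b", 2010, 1.0, 70.0, False, "normal")]))
        retained = pd.DataFrame({"community": ["C1", "C1"], "species": ["a", "b"]})
        shares = ld.revenue_shares(totals, retained,
                                   weighting="weight").set_index("species")
        assert shares.loc["a", "p"] == pytest.approx(0.9)


def test_misc_and_expand_commute_on_disjoint_labels():
    totals = ld.aggregate_landings(receipts([
        ("C1", "a", 2010, 90.0, 50.0, False, "normal"),
        ("C1", "misc", 2010, 3.0, 1.0, False, "other_misc"),
        ("C1", "grp", 2010, 7.0, 2.0, False, "unidentified_group")]))
    gm = {"grp": {"x": 0.5, "y": 0.5}}
    a, _ = ld.drop_misc(totals)
    a = ld.expand_unidentified(a, gm)
    b = ld.expand_unidentified(totals, gm)
    b, _ = ld.drop_misc(b)
    pd.testing.assert_frame_equal(
        a.reset_index(drop=True), b.reset_index(drop=True))


def test_full_cascade_bookkeeping():
    rows = []
    for comm, frac in [("C_clean", 0.0), ("C_edge", 0.20), ("C_drop", 0.25)]:
        rows.append((comm, "a", 2010, 100 * (1 - frac), 50.0, False, "normal"))
        if frac:
            rows.append((comm, "a", 2010, 100 * frac, 50.0, True, "normal"))
    shares, log = ld.prepare_revenue_shares(receipts(rows))
    assert log["removed_confidential"] == ["C_drop"]
    assert set(log["communities_with_shares"]) == {"C_clean", "C_edge"}
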