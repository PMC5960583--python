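"""Deterministic catch-processing rules and table I/O."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trammelnet import (
    CatchItem,
    CatchParseError,
    Fate,
    LengthWeightParams,
    NET_LEVEL,
    NetPoolRecord,
    PriceTable,
    assign_length_class,
    impute_length,
    item_revenue,
    length_to_weight,
    pool_discards_to_net,
    read_catch_tables,
    wall_totals,
    write_catch_tables,
)
from trammelnet.catch_data import read_lw_params, read_price_table


class TestLengthToWeight:
    @pytest.mark.parametrize("a,b,length,expected", [
        (0.01, 3.0, 10.0, 0.01),   # 0.01 * 10^3 g = 10 g
        (1.0, 1.0, 1.0, 0.001),
    ])
    def test_known_values(self, a, b, length, expected):
        params = LengthWeightParams("sp", a=a, b=b)
        assert length_to_weight(params, length) == pytest.approx(expected)

    def test_matches_direct_evaluation_on_grid(self, rng):
        """W = a L^b / 1000 against independent elementwise evaluation."""
        for _ in range(50):
            a = float(rng.uniform(0.001, 2.0))
            b = float(rng.uniform(1.0, 4.0))
            length = float(rng.uniform(0.5, 120.0))
            expected = a * length ** b / 1000.0
            got = length_to_weight(LengthWeightParams("sp", a=a, b=b), length)
            assert got == pytest.approx(expected, rel=1e-12)

    @given(a=st.floats(0.001, 5.0), b=st.floats(1.0, 4.0),
           length=st.floats(0.1, 200.0))
    @settings(max_examples=100, deadline=None)
    def test_monotone_and_homogeneous(self, a, b, length):
        p = LengthWeightParams("sp", a=a, b=b)
        p2 = LengthWeightParams("sp", a=2 * a, b=b)
        w = length_to_weight(p, length)
        assert length_to_weight(p, length * 1.01) > w
        assert length_to_weight(p2, length) == pytest.approx(2 * w, rel=1e-12)

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            length_to_weight(LengthWeightParams("sp", a=1.0, b=3.0), 0.0)


class TestAssignLengthClass:
    @pytest.mark.parametrize("length,width,expected", [
        (23.0, 10.0, 30.0),   # class maximum convention
        (20.0, 10.0, 20.0),   # boundary closes the lower class
        (7.1, 5.0, 10.0),     # 5-cm carapace classes for lobster
        (0.5, 10.0, 10.0),
    ])
    def test_examples(self, length, width, expected):
        assert assign_length_class(length, width) == expected

    @given(length=st.floats(0.01, 500.0), width=st.sampled_from([5.0, 10.0]))
    @settings(max_examples=200, deadline=None)
    def test_upper_bound_within_one_width(self, length, width):
        upper = assign_length_class(length, width)
        assert 0 <= upper - length < width or upper == pytest.approx(length)
        # the length lies in (upper - width, upper]
        assert upper - width < length <= upper + 1e-9

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            assign_length_class(-1.0, 10.0)
        with pytest.raises(ValueError):
            assign_length_class(10.0, 0.0)


class TestImputeLength:
    def _item(self, iid, species, length=None, upper=None):
        return CatchItem(iid, "w", species, Fate.DISCARD,
                         length_cm=length, length_class_upper_cm=upper)

    def test_mean_of_conspecifics(self):
        items = [self._item("a", "sp", 10.0), self._item("b", "sp", 20.0),
                 self._item("c", "other", 99.0)]
        assert impute_length(items, "sp") == 15.0

    def test_single_conspecific_identity(self):
        assert impute_length([self._item("a", "sp", 12.0)], "sp") == 12.0

    def test_pools_measured_and_class_upper(self):
        items = [self._item("a", "sp", length=11.0),
                 self._item("b", "sp", upper=30.0)]
        assert impute_length(items, "sp") == pytest.approx(20.5)

    def test_no_conspecific_length_is_an_error(self):
        with pytest.raises(ValueError, match="drop or flag"):
            impute_length([self._item("a", "other", 5.0)], "sp")


class TestItemRevenue:
    def test_mean_price_over_trips(self):
        prices = PriceTable([("cat", "t1", 40.0), ("cat", "t2", 44.0)])
        assert item_revenue(1.0, "cat", prices) == pytest.approx(42.0)

    def test_zero_weight(self):
        prices = PriceTable([("cat", "t1", 40.0)])
        assert item_revenue(0.0, "cat", prices) == 0.0

    def test_single_trip_price(self):
        prices = PriceTable([("Scorpaena scrofa", "t1", 17.68)])
        assert item_revenue(0.5, "Scorpaena scrofa", prices) == pytest.approx(8.84)

    def test_unknown_category(self):
        with pytest.raises(KeyError):
            item_revenue(1.0, "nope", PriceTable([("cat", "t", 1.0)]))


class TestPoolDiscards:
    def _discard(self, iid, species, wkg, wall="w1"):
        return CatchItem(iid, wall, species, Fate.DISCARD, weight_kg=wkg)

    def test_no_pool_identity(self):
        items = [self._discard("a", "sp", 1.5)]
        assert pool_discards_to_net(items, None) == {"sp": 1.5}

    def test_linear_subsample_scaling(self):
        pool = NetPoolRecord("n", total_volume_l=40.0, subsample_volume_l=20.0,
                             subsample_weights={"algae": 0.5})
        assert pool_discards_to_net([], pool)["algae"] == pytest.approx(1.0)

    def test_total_not_exceeding_subsample_is_unscaled(self):
        pool = NetPoolRecord("n", total_volume_l=15.0, subsample_volume_l=20.0,
                             subsample_weights={"algae": 0.5})
        assert pool_discards_to_net([], pool)["algae"] == pytest.approx(0.5)

    def test_mixed_wall_and_pool_matches_manual_sum(self, rng):
        species = ["a", "b"]
        items = [self._discard(f"i{k}", rng.choice(species), float(rng.uniform(0, 2)))
                 for k in range(20)]
        pool = NetPoolRecord("n", 50.0, 20.0, {"a": 0.3, "b": 0.1})
        expected = {}
        for it in items:
            expected[it.species] = expected.get(it.species, 0.0) + it.weight_kg
        for sp, w in pool.subsample_weights.items():
            expected[sp] = expected.get(sp, 0.0) + w * 50.0 / 20.0
        got = pool_discards_to_net(items, pool)
        assert got.keys() == expected.keys()
        for sp in expected:
            assert got[sp] == pytest.approx(expected[sp])

    def test_marketable_and_net_level_items_excluded_from_wall_sum(self):
        items = [
            self._discard("a", "sp", 1.0),
            CatchItem("b", NET_LEVEL, "sp", Fate.DISCARD, weight_kg=9.0),
            CatchItem("c", "w1", "sp", Fate.MARKETABLE, weight_kg=2.0,
                      commercial_category="cat"),
        ]
        assert pool_discards_to_net(items, None) == {"sp": 1.0}


class TestTables:
    def test_round_trip(self, tmp_path, toy_walls, toy_items):
        pools = [NetPoolRecord("N0", 42.5, 20.0, {"algae": 0.25, "star": 0.1})]
        paths = [tmp_path / n for n in ("walls.csv", "items.csv", "pools.csv")]
        write_catch_tables(toy_walls, toy_items, pools, *paths)
        walls2, items2, pools2 = read_catch_tables(*paths)
        assert walls2 == toy_walls
        assert items2 == toy_items
        assert pools2[0].net_id == "N0"
        assert pools2[0].total_volume_l == 42.5
        assert dict(pools2[0].subsample_weights) == {"algae": 0.25, "star": 0.1}

    def test_empty_items_file(self, tmp_path, toy_walls):
        paths = [tmp_path / n for n in ("walls.csv", "items.csv", "pools.csv")]
        write_catch_tables(toy_walls, [], [], *paths)
        walls2, items2, pools2 = read_catch_tables(paths[0], paths[1])
        assert len(walls2) == len(toy_walls)
        assert items2 == [] and pools2 == []

    def test_dangling_wall_id_names_the_row(self, tmp_path, toy_walls):
        bad = CatchItem("ix", "NOPE", "sp", Fate.DISCARD, weight_kg=1.0)
        paths = [tmp_path / n for n in ("walls.csv", "items.csv", "pools.csv")]
        write_catch_tables(toy_walls, [bad], [], *paths)
        with pytest.raises(CatchParseError, match="line 2.*ix.*NOPE"):
            read_catch_tables(paths[0], paths[1])

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "walls.csv"
        p.write_text("wall_id,trip_id\nw,t\n")
        with pytest.raises(CatchParseError, match="missing column"):
            read_catch_tables(p, p)

    def test_unknown_wall_type_rejected(self, tmp_path):
        p = tmp_path / "walls.csv"
        p.write_text("wall_id,trip_id,boat_id,net_id,wall_index,wall_type,"
                     "depth_m,soak_h\nw,t,b,n,1,NYLON,90,45\n")
        items = tmp_path / "items.csv"
        items.write_text(",".join(
            ["item_id", "wall_id", "species", "fate", "length_cm",
             "length_class_upper_cm", "weight_kg", "alive_on_arrival",
             "commercial_category"]) + "\n")
        with pytest.raises(CatchParseError, match="line 2"):
            read_catch_tables(p, items)

    def test_price_and_lw_readers(self, tmp_path):
        pp = tmp_path / "prices.csv"
        pp.write_text("commercial_category,trip_id,price_eur_per_kg\n"
                      "cat,t1,40\ncat,t2,44\n")
        assert read_price_table(pp).mean_price("cat") == 42.0
        lp = tmp_path / "lw.csv"
        lp.write_text("species,a,b,length_type,units\nsp,0.01,3,TOTAL_LENGTH,g_cm\n")
        assert read_lw_params(lp)["sp"].b == 3.0


class TestWallTotals:
    def test_revenue_and_discard_totals(self, toy_walls, toy_items, toy_prices):
        rev = wall_totals(toy_walls, toy_items, Fate.MARKETABLE, toy_prices)
        assert rev["N0W1"] == pytest.approx(0.5 * 17.68)
        assert rev["N1W1"] == 0.0
        dis = wall_totals(toy_walls, toy_items, Fate.DISCARD)
        assert dis["N0W2"] == pytest.approx(1.2)
        assert dis["N0W1"] == 0.0

    def test_invariants_of_records(self):
        with pytest.raises(ValueError):
            CatchItem("i", "w", "sp", Fate.MARKETABLE, weight_kg=1.0)  # no category
        with pytest.raises(ValueError):
            NetPoolRecord("n", -1.0, 20.0, {})
        with pytest.raises(ValueError):
            LengthWeightParams("sp", a=0.0, b=3.0)
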