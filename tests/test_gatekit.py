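"""Hierarchical gating, printed-cascade arithmetic, pick-list invariants."""

import numpy as np
import pandas as pd
import pytest

from conewell.gatekit import (
    GateNode,
    PredicateError,
    apply_gate_tree,
    build_picklist,
    evaluate_predicate,
    expected_library_hit_rate,
    gate_fraction,
)
from conewell.gridmap import MicrowellGrid


def random_feature_table(n=1000, n_t=3, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for mid in range(n):
        gfp0 = rng.uniform(0, 200)
        for t in range(n_t):
            rows.append(
                {
                    "well": "A1",
                    "microwell_id": mid,
                    "timepoint": t,
                    "time_hours": t * 4.0,
                    "count": int(rng.integers(0, 4)),
                    "GFP_mean": gfp0 + rng.uniform(-5, 60),
                    "r": rng.normal(0.4, 0.5),
                }
            )
    return pd.DataFrame(rows)


class TestGateTree:
    def test_root_holds_every_microwell(self):
        table = random_feature_table(50)
        tree = apply_gate_tree(table, GateNode("all"))
        assert tree.count == 50
        assert tree.fraction_of_parent == 100.0

    def test_tree_matches_brute_force_row_filtering(self):
        """3-level cascade vs literal pandas filtering on 1,000 microwells."""
        table = random_feature_table(1000, seed=3)
        tree = GateNode("all")
        singles = tree.add(GateNode("singles", "count@t0 == 1"))
        bright = singles.add(GateNode("bright", "GFP_mean@last >= 100"))
        bright.add(GateNode("growing", "r@t0 >= 0.25"))
        apply_gate_tree(table, tree)

        t0 = table[table.timepoint == 0]
        tl = table[table.timepoint == table.timepoint.max()]
        s1 = set(t0.loc[t0["count"] == 1, "microwell_id"])
        s2 = s1 & set(tl.loc[tl.GFP_mean >= 100, "microwell_id"])
        s3 = s2 & set(t0.loc[t0.r >= 0.25, "microwell_id"])
        assert {m for _, m in singles.members} == s1
        assert {m for _, m in bright.members} == s2
        assert {m for _, m in tree.find("growing").members} == s3

    def test_counts_never_increase_down_a_path(self):
        table = random_feature_table(400, seed=9)
        tree = GateNode("all")
        node = tree
        for k, pred in enumerate(
            ["count@t0 >= 1", "GFP_mean@t0 >= 50", "GFP_mean@any(t>=4) >= 120"]
        ):
            node = node.add(GateNode(f"g{k}", pred))
        apply_gate_tree(table, tree)
        counts = [n.count for n in tree.walk()]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_sibling_evaluation_is_order_independent(self):
        table = random_feature_table(200, seed=5)
        preds = ["count@t0 == 1", "r@t0 >= 0.5"]
        t1 = GateNode("all")
        for k, p in enumerate(preds):
            t1.add(GateNode(f"a{k}", p))
        t2 = GateNode("all")
        for k, p in enumerate(reversed(preds)):
            t2.add(GateNode(f"b{k}", p))
        apply_gate_tree(table, t1)
        apply_gate_tree(table, t2)
        assert t1.children[0].members == t2.children[1].members
        assert t1.children[1].members == t2.children[0].members

    def test_any_selector_uses_acquisition_hours(self):
        table = random_feature_table(100, n_t=4, seed=7)
        hits = evaluate_predicate(table, "GFP_mean@any(t>=8) >= 150")
        late = table[table.time_hours >= 8]
        expect = set(late.loc[late.GFP_mean >= 150, "microwell_id"])
        assert {m for _, m in hits} == expect

    def test_unknown_feature_or_timepoint_raise(self):
        table = random_feature_table(10)
        with pytest.raises(PredicateError, match="unknown feature"):
            evaluate_predicate(table, "CD8_mean@t0 >= 1")
        with pytest.raises(PredicateError, match="timepoint"):
            evaluate_predicate(table, "count@t9 >= 1")
        with pytest.raises(PredicateError, match="parse"):
            evaluate_predicate(table, "count == 1")


class TestGateFraction:
    @pytest.mark.parametrize(
        "count,parent,decimals,expected",
        [
            (47_597, 137_758, 0, 35.0),  # single-cell gate of the cascade
            (16_070, 47_597, 0, 34.0),  # 1:1 co-culture gate
            (107, 16_070, 1, 0.7),  # reporter-positive pairs
            (0, 50, 1, 0.0),
        ],
    )
    def test_printed_cascade_arithmetic(self, count, parent, decimals, expected):
        assert gate_fraction(count, parent, decimals) == expected

    def test_half_up_rounding_at_the_boundary(self):
        assert gate_fraction(5, 1000, 1) == 0.5
        assert gate_fraction(25, 1000, 0) == 3.0  # 2.5 rounds up, not to even

    def test_zero_parent_raises(self):
        with pytest.raises(ZeroDivisionError):
            gate_fraction(1, 0)

    @pytest.mark.parametrize(
        "lib,cognate,expected",
        [(100, 1, 1.0), (100, 100, 100.0), (50, 2, 4.0)],
    )
    def test_expected_library_hit_rate(self, lib, cognate, expected):
        assert expected_library_hit_rate(lib, cognate) == expected

    def test_hit_rate_domain_errors(self):
        with pytest.raises(ValueError):
            expected_library_hit_rate(100, 0)
        with pytest.raises(ValueError):
            expected_library_hit_rate(100, 101)


class TestPickList:
    def make_grid(self, n=25, accessible_all=True):
        side = int(np.sqrt(n))
        centers = np.array([(r * 65.0 + 65, c * 65.0 + 65)
                            for r in range(side) for c in range(side)])
        acc = np.ones(n, dtype=bool)
        if not accessible_all:
            acc[::5] = False
        return MicrowellGrid(
            ids=np.arange(n),
            centers_t0=centers,
            lattice_rows=np.repeat(np.arange(side), side),
            lattice_cols=np.tile(np.arange(side), side),
            shifts=np.array([[0.0, 0.0], [2.0, 3.0]]),
            pitch_px=65.0,
            pixel_size_um=2.0,
            accessible=acc,
        )

    def test_interleaved_alternating_order(self):
        grid = self.make_grid()
        pl = build_picklist(
            [1, 2, 3, 4], grid,
            interleave_by={1: "GFP", 2: "GFP", 3: "mCherry", 4: "mCherry"},
        )
        labels = [{1: "G", 2: "G", 3: "M", 4: "M"}[m]
                  for m in pl.entries.microwell_id]
        assert labels == ["G", "M", "G", "M"]

    def test_inaccessible_selection_rejected(self):
        grid = self.make_grid(accessible_all=False)
        with pytest.raises(ValueError, match="accessible"):
            build_picklist([0], grid)  # id 0 flagged inaccessible

    def test_blanks_are_empty_accessible_and_seed_deterministic(self):
        grid = self.make_grid()
        empty = [7, 8, 9, 11, 13]
        args = dict(n_blanks=2, seed=5, empty_ids=empty)
        p1 = build_picklist(list(range(1, 7)), grid, **args)
        p2 = build_picklist(list(range(1, 7)), grid, **args)
        pd.testing.assert_frame_equal(p1.entries, p2.entries)
        blanks = p1.entries[p1.entries.is_blank]
        assert len(blanks) == 2
        assert set(blanks.microwell_id) <= set(empty)
        assert (blanks.gate_path == "blank").all()

    def test_never_contains_inaccessible_microwells_adversarially(self):
        grid = self.make_grid(accessible_all=False)
        rng = np.random.default_rng(0)
        ok_ids = [int(i) for i in grid.ids if grid.accessible[grid.row_of(int(i))]]
        for trial in range(20):
            sel = list(rng.choice(ok_ids, size=5, replace=False))
            pl = build_picklist(
                sel, grid, n_blanks=2, seed=trial,
                empty_ids=[i for i in ok_ids if i not in sel],
            )
            assert all(
                grid.accessible[grid.row_of(m)] for m in pl.entries.microwell_id
            )
            assert pl.entries.deposition_well.is_unique

    def test_capacity_exceeded_raises(self):
        grid = self.make_grid()
        with pytest.raises(ValueError, match="capacity"):
            build_picklist(list(range(1, 10)), grid, deposition_layout=["A1", "A2"])

    def test_stage_coordinates_follow_last_shift_in_microns(self):
        grid = self.make_grid()
        pl = build_picklist([6], grid)
        row = pl.entries.iloc[0]
        cy, cx = grid.centers_t0[grid.row_of(6)] + np.array([2.0, 3.0])
        assert row.y_um == pytest.approx(cy * 2.0)
        assert row.x_um == pytest.approx(cx * 2.0)

    def test_round_trip_csv(self, tmp_path):
        from conewell.gatekit import PickList

        grid = self.make_grid()
        pl = build_picklist([1, 2], grid)
        pl.save(tmp_path / "picks.csv")
        back = PickList.load(tmp_path / "picks.csv")
        assert back.entries.microwell_id.tolist() == [1, 2]
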