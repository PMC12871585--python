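"""Hierarchical gating and pick-list generation.

Gates are nested predicates over the feature table, cytometry-style:
each node keeps exactly the parent members that satisfy its predicate,
so counts never increase down a path and every node reports its
fraction of the parent (half-up rounded percentages, matching how such
cascades are printed).

Predicate grammar — conjunctions of threshold comparisons on
(feature, timepoint) pairs::

    count@t0 == 1
    GFP_mean@t0 < 120 AND GFP_mean@any(t>=9) >= 120
    r@last >= 0.25 AND g@last >= 1.2

Selectors: ``@t<k>`` (timepoint index k), ``@first``, ``@last``,
``@any(t>=H)`` / ``@any(t>H)`` / ``@any(t<=H)`` / ``@any(t<H)`` (any
timepoint whose acquisition time in hours satisfies the bound).
Disjunctions are expressed as sibling nodes.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .gridmap import MicrowellGrid

_CLAUSE = re.compile(
    r"^\s*(?P<feature>[A-Za-z_]\w*)@(?P<selector>t\d+|first|last|any\(t\s*(?:>=|<=|>|<)\s*[\d.]+\))"
    r"\s*(?P<op>==|!=|<=|>=|<|>)\s*(?P<value>-?[\d.eE+]+|'[^']*'|\"[^\"]*\")\s*$"
)
_ANY = re.compile(r"any\(t\s*(?P<op>>=|<=|>|<)\s*(?P<hours>[\d.]+)\)")

_OPS = {
    "==": np.equal,
    "!=": np.not_equal,
    "<": np.less,
    "<=": np.less_equal,
    ">": np.greater,
    ">=": np.greater_equal,
}


class PredicateError(ValueError):
    """Unknown feature, timepoint or malformed predicate."""


@dataclass
class GateNode:
    """One gate in the hierarchy."""

    name: str
    predicate: Optional[str] = None  # None = root (all imaged microwells)
    children: list["GateNode"] = field(default_factory=list)
    members: frozenset = frozenset()
    count: int = 0
    fraction_of_parent: Optional[float] = None  # percent

    def add(self, child: "GateNode") -> "GateNode":
        self.children.append(child)
        return child

    def find(self, name: str) -> "GateNode":
        if self.name == name:
            return self
        for child in self.children:
            try:
                return child.find(name)
            except KeyError:
                pass
        raise KeyError(f"no gate named {name!r}")

    def walk(self):
        yield self
        for child in self.children:
            yield from child.walk()

    @classmethod
    def from_dict(cls, spec: dict) -> "GateNode":
        node = cls(name=spec["name"], predicate=spec.get("predicate"))
        for sub in spec.get("children", []):
            node.add(cls.from_dict(sub))
        return node

    def report(self) -> pd.DataFrame:
        rows = [
            {
                "gate": n.name,
                "predicate": n.predicate or "",
                "count": n.count,
                "fraction_of_parent_pct": n.fraction_of_parent,
            }
            for n in self.walk()
        ]
        return pd.DataFrame(rows)


def _clause_members(table: pd.DataFrame, clause: str) -> set:
    m = _CLAUSE.match(clause)
    if not m:
        raise PredicateError(f"cannot parse clause {clause!r}")
    feature, selector, op = m["feature"], m["selector"], m["op"]
    raw = m["value"]
    value = raw.strip("'\"") if raw[0] in "'\"" else float(raw)
    if feature not in table.columns:
        raise PredicateError(f"unknown feature {feature!r}")
    cmp = _OPS[op]

    key = ["well", "microwell_id"]
    if selector.startswith("any("):
        am = _ANY.match(selector)
        bound = float(am["hours"])
        tsel = _OPS[am["op"]](table["time_hours"].to_numpy(), bound)
        sub = table[tsel]
        hit = sub[cmp(sub[feature].to_numpy(), value)]
        return set(map(tuple, hit[key].itertuples(index=False)))
    if selector == "first":
        tp = table["timepoint"].min()
    elif selector == "last":
        tp = table["timepoint"].max()
    else:
        tp = int(selector[1:])
        if tp not in set(table["timepoint"].unique()):
            raise PredicateError(f"timepoint {tp} not present in the table")
    sub = table[table["timepoint"] == tp]
    hit = sub[cmp(sub[feature].to_numpy(), value)]
    return set(map(tuple, hit[key].itertuples(index=False)))


def evaluate_predicate(table: pd.DataFrame, predicate: str) -> frozenset:
    """Member set (well, microwell_id) satisfying a conjunctive predicate."""
    clauses = re.split(r"\s+AND\s+", predicate)
    members: Optional[set] = None
    for clause in clauses:
        hits = _clause_members(table, clause)
        members = hits if members is None else members & hits
    return frozenset(members or set())


def apply_gate_tree(feature_table: pd.DataFrame, tree: GateNode) -> GateNode:
    """Top-down evaluation: each node keeps parent members passing its gate.

    The root (predicate None) holds every imaged microwell.  Counts and
    half-up-rounded parent fractions are populated in place.
    """
    table = feature_table
    for col in ("well", "microwell_id", "timepoint"):
        if col not in table.columns:
            raise PredicateError(f"feature table lacks required column {col!r}")
    if "time_hours" not in table.columns:
        table = table.assign(time_hours=table["timepoint"].astype(float))

    everyone = frozenset(
        map(tuple, table[["well", "microwell_id"]].drop_duplicates().itertuples(index=False))
    )

    def descend(node: GateNode, parent_members: frozenset, parent_count: Optional[int]):
        if node.predicate is None:
            node.members = parent_members
        else:
            node.members = parent_members & evaluate_predicate(table, node.predicate)
        node.count = len(node.members)
        node.fraction_of_parent = (
            100.0 * node.count / parent_count if parent_count else None
        )
        for child in node.children:
            descend(child, node.members, node.count)

    descend(tree, everyone, None)
    tree.fraction_of_parent = 100.0
    return tree


def gate_fraction(count: int | GateNode, parent_count: int | None = None, decimals: int = 0) -> float:
    """Percentage of the parent gate, half-up rounded to ``decimals``.

    Accepts either a populated :class:`GateNode` or raw (count, parent)
    integers — the latter reproduces printed cascade arithmetic.
    """
    if isinstance(count, GateNode):
        node = count
        if node.fraction_of_parent is None:
            raise ValueError(f"gate {node.name!r}: fractions not populated")
        pct = Decimal(str(node.fraction_of_parent))
    else:
        if not parent_count:
            raise ZeroDivisionError("parent gate is empty")
        pct = Decimal(count) * 100 / Decimal(parent_count)
    q = Decimal(1).scaleb(-decimals)
    return float(pct.quantize(q, rounding=ROUND_HALF_UP))


def expected_library_hit_rate(library_size: int, cognate_count: int) -> float:
    """Expected percent of 1:1 co-cultures that activate, for an equally
    distributed presenting-cell library with ``cognate_count`` cognate
    members out of ``library_size``."""
    if not 0 < cognate_count <= library_size:
        raise ValueError("need 0 < cognate_count <= library_size")
    return 100.0 * cognate_count / library_size


# ---------------------------------------------------------------------------
# pick lists


@dataclass
class PickList:
    """Ordered retrieval worklist for the picker."""

    entries: pd.DataFrame  # well, microwell_id, x_um, y_um, deposition_well,
    #                        gate_path, is_blank

    COLUMNS = [
        "well",
        "microwell_id",
        "x_um",
        "y_um",
        "deposition_well",
        "gate_path",
        "is_blank",
    ]

    def __len__(self) -> int:
        return len(self.entries)

    def save(self, path) -> None:
        self.entries.to_csv(path, index=False)

    @classmethod
    def load(cls, path) -> "PickList":
        return cls(entries=pd.read_csv(path))


def deposition_wells(rows: int = 8, cols: int = 12) -> list[str]:
    """Standard plate well names, row-major: A1..A12, B1.."""
    return [f"{chr(ord('A') + r)}{c + 1}" for r in range(rows) for c in range(cols)]


def build_picklist(
    selected_ids: Sequence[int],
    grid: MicrowellGrid,
    deposition_layout: Sequence[str] | tuple[int, int] = (8, 12),
    n_blanks: int = 0,
    seed: int = 0,
    empty_ids: Sequence[int] = (),
    interleave_by: dict | None = None,
    gate_paths: dict | None = None,
    source_well: str = "A1",
) -> PickList:
    """Assemble the retrieval worklist.

    Every selected microwell must be accessible (hard invariant — the
    picker tip cannot reach the well perimeter).  ``interleave_by`` maps
    id -> label and alternates labels round-robin in the pick order
    (e.g. GFP+, mCherry+, GFP+, ...).  ``n_blanks`` empty accessible
    microwells are inserted at seeded-random positions as carry-over
    negative controls.  Stage coordinates are the t0 center plus the
    last registered shift, converted to microns.
    """
    rng = np.random.default_rng(seed)
    selected_ids = [int(i) for i in selected_ids]
    for mid in selected_ids:
        if not grid.accessible[grid.row_of(mid)]:
            raise ValueError(f"microwell {mid} is outside the accessible region")
    if isinstance(deposition_layout, tuple):
        dep_wells = deposition_wells(*deposition_layout)
    else:
        dep_wells = list(deposition_layout)
    if len(selected_ids) + n_blanks > len(dep_wells):
        raise ValueError(
            f"deposition capacity {len(dep_wells)} < "
            f"{len(selected_ids)} picks + {n_blanks} blanks"
        )

    if interleave_by:
        by_label: dict[str, list[int]] = {}
        for mid in selected_ids:
            by_label.setdefault(str(interleave_by.get(mid, "")), []).append(mid)
        order: list[int] = []
        buckets = [list(v) for _, v in sorted(by_label.items())]
        while any(buckets):
            for b in buckets:
                if b:
                    order.append(b.pop(0))
    else:
        order = list(selected_ids)

    blanks = []
    if n_blanks:
        candidates = [
            int(i)
            for i in empty_ids
            if grid.accessible[grid.row_of(int(i))] and int(i) not in set(selected_ids)
        ]
        if len(candidates) < n_blanks:
            raise ValueError(
                f"only {len(candidates)} accessible empty microwells for "
                f"{n_blanks} blanks"
            )
        blanks = list(rng.choice(candidates, size=n_blanks, replace=False))
        positions = sorted(rng.choice(len(order) + n_blanks, size=n_blanks, replace=False))
        for pos, mid in zip(positions, blanks):
            order.insert(pos, int(mid))

    blank_set = set(int(b) for b in blanks)
    last_shift = grid.shifts[-1]
    rows = []
    for k, mid in enumerate(order):
        cy, cx = grid.centers_t0[grid.row_of(mid)] + last_shift
        rows.append(
            {
                "well": source_well,
                "microwell_id": mid,
                "x_um": cx * grid.pixel_size_um,
                "y_um": cy * grid.pixel_size_um,
                "deposition_well": dep_wells[k],
                "gate_path": "blank" if mid in blank_set else (gate_paths or {}).get(mid, ""),
                "is_blank": mid in blank_set,
            }
        )
    entries = pd.DataFrame(rows, columns=PickList.COLUMNS)
    assert entries["deposition_well"].is_unique
    return PickList(entries=entries)
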