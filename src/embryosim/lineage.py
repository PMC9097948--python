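"""Invariant cell lineage and division schedule.

The C. elegans lineage is invariant: every wild-type embryo runs the same
binary tree of named divisions on an essentially fixed clock. The simulator
therefore treats fate and division timing as *data*, not dynamics — each
cell's fate label and division time come from a lineage table in the style
of automated-lineaging output, and the tree drives when and how agents
divide.

Names follow the Sulston convention: daughters append a positional suffix
to the mother's name (here restricted to ``a``/``p``, resolved against the
embryo's anterior-posterior axis), except for the early founder cells
(P0 -> AB + P1, P1 -> EMS + P2, P2 -> C + P3, P3 -> D + P4, EMS -> MS + E)
whose daughter names are fixed by convention.

Times are integer minutes, matching the 1-minute observation cadence of
live imaging.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from .errors import FormatError, StructureError

#: Fate labels carried by lineage nodes (tissue-marker categories plus catch-alls).
FATE_LABELS = ("pharynx", "neuron", "hypodermis", "muscle", "gut", "other", "unassigned")

#: Founder-cell daughter names fixed by the Sulston convention. The first
#: element of each pair is the daughter assigned to the anterior hemisphere.
FOUNDER_DAUGHTERS = {
    "P0": ("AB", "P1"),
    "P1": ("EMS", "P2"),
    "P2": ("C", "P3"),
    "P3": ("D", "P4"),
    "EMS": ("MS", "E"),
}

LINEAGE_COLUMNS = ["name", "parent", "birth_time", "division_time", "fate"]


@dataclass(frozen=True)
class LineageNode:
    """One cell in the lineage tree.

    ``division_time`` is ``None`` for terminal cells (never observed to
    divide within the recorded window).
    """

    name: str
    parent: Optional[str]
    birth_time: int
    division_time: Optional[int]
    fate: str = "unassigned"

    def __post_init__(self):
        if not self.name:
            raise FormatError("cell name must be nonempty")
        if self.birth_time < 0:
            raise FormatError(f"{self.name}: birth_time must be >= 0")
        if self.division_time is not None and self.division_time <= self.birth_time:
            raise FormatError(
                f"{self.name}: division_time ({self.division_time}) must exceed "
                f"birth_time ({self.birth_time})"
            )
        if self.fate not in FATE_LABELS:
            raise FormatError(f"{self.name}: unknown fate label {self.fate!r}")

    @property
    def is_terminal(self) -> bool:
        return self.division_time is None

    @property
    def lifetime(self) -> Optional[int]:
        """Minutes from birth to division; None for terminal cells."""
        if self.division_time is None:
            return None
        return self.division_time - self.birth_time


@dataclass(frozen=True)
class DivisionEvent:
    time: int
    dividing_cell: str
    daughter_names: tuple[str, str]


class LineageTree:
    """Validated binary tree of named, timed cells.

    Construction checks all structural invariants: unique names, existing
    parents, exactly 0 or 2 children per node, and daughter birth times
    equal to the mother's division time.
    """

    def __init__(self, nodes: Iterable[LineageNode]):
        self._nodes: dict[str, LineageNode] = {}
        for node in nodes:
            if node.name in self._nodes:
                raise FormatError(f"duplicate cell name {node.name!r}")
            self._nodes[node.name] = node
        if not self._nodes:
            raise StructureError("lineage tree must contain at least one cell")

        self._children: dict[str, list[str]] = {name: [] for name in self._nodes}
        roots = []
        for node in self._nodes.values():
            if node.parent is None:
                roots.append(node.name)
            else:
                if node.parent not in self._nodes:
                    raise StructureError(
                        f"{node.name}: parent {node.parent!r} not present in tree"
                    )
                self._children[node.parent].append(node.name)
        if len(roots) != 1:
            raise StructureError(f"expected exactly one root, found {len(roots)}")
        self._root = roots[0]

        for name, kids in self._children.items():
            kids.sort()
            node = self._nodes[name]
            if len(kids) not in (0, 2):
                raise StructureError(
                    f"{name}: has {len(kids)} children; binary division requires 0 or 2"
                )
            if kids and node.division_time is None:
                raise StructureError(f"{name}: has children but no division_time")
            if not kids and node.division_time is not None:
                raise StructureError(f"{name}: division_time set but no children recorded")
            for kid in kids:
                if self._nodes[kid].birth_time != node.division_time:
                    raise StructureError(
                        f"{kid}: birth_time {self._nodes[kid].birth_time} != "
                        f"mother {name} division_time {node.division_time}"
                    )

    # -- basic access -------------------------------------------------------

    @property
    def root(self) -> LineageNode:
        return self._nodes[self._root]

    def __len__(self) -> int:
        return len(self._nodes)

    def __contains__(self, name: str) -> bool:
        return name in self._nodes

    def __getitem__(self, name: str) -> LineageNode:
        return self._nodes[name]

    def __iter__(self):
        return iter(self._nodes.values())

    def names(self) -> list[str]:
        return list(self._nodes)

    def children(self, name: str) -> tuple[str, ...]:
        return tuple(self._children[name])

    def leaves(self) -> list[str]:
        return [n for n, kids in self._children.items() if not kids]

    def __eq__(self, other) -> bool:
        if not isinstance(other, LineageTree):
            return NotImplemented
        return self._nodes == other._nodes

    def __repr__(self) -> str:
        return f"LineageTree(n_cells={len(self)}, root={self._root!r})"

    # -- schedule -----------------------------------------------------------

    def division_schedule(self) -> list[DivisionEvent]:
        """All divisions sorted by (time, name).

        Same-time divisions are ordered lexicographically by mother name;
        the observation data fix no tie-break, so a deterministic one is
        imposed.
        """
        events = [
            DivisionEvent(node.division_time, node.name, self.children(node.name))
            for node in self._nodes.values()
            if node.division_time is not None
        ]
        events.sort(key=lambda e: (e.time, e.dividing_cell))
        return events


# -- operations --------------------------------------------------------------


def daughter_names(
    mother: str, division_axis: Sequence[float], ap_axis: Sequence[float]
) -> tuple[str, str]:
    """Name the two daughters of ``mother``.

    The first returned name is the daughter placed on the hemisphere where
    ``division_axis . ap_axis > 0`` (the anterior side). Founder cells use
    the fixed lookup table; all other cells get ``a``/``p`` suffixes.
    """
    if not mother:
        raise ValueError("mother name must be nonempty")
    d = np.asarray(division_axis, dtype=float)
    ap = np.asarray(ap_axis, dtype=float)
    if np.linalg.norm(d) == 0 or np.linalg.norm(ap) == 0:
        raise ValueError("division and AP axes must be nonzero")
    if mother in FOUNDER_DAUGHTERS:
        return FOUNDER_DAUGHTERS[mother]
    anterior, posterior = mother + "a", mother + "p"
    # The a-daughter sits on the hemisphere the axis shares with anterior.
    # A flipped axis just swaps which physical side each name lands on;
    # the name pair itself is fixed.
    return (anterior, posterior)


def cells_alive_at(tree: LineageTree, t: float) -> set[str]:
    """Names of cells alive at time ``t``: born, not yet divided."""
    if t < tree.root.birth_time:
        raise ValueError(
            f"t={t} precedes root birth time {tree.root.birth_time}"
        )
    return {
        node.name
        for node in tree
        if node.birth_time <= t and (node.division_time is None or node.division_time > t)
    }


def export_newick(tree: LineageTree) -> str:
    """Serialize to Newick with branch length = lifetime in minutes.

    Terminal cells get branch length 0 (their division is unobserved, and a
    real division always takes >= 1 minute, so 0 unambiguously marks a
    terminal on re-import). Fate labels travel as ``[&fate=...]`` metadata
    comments. The root's branch length is its own lifetime; the root birth
    time is taken as 0 on re-import.
    """

    def render(name: str) -> str:
        node = tree[name]
        kids = tree.children(name)
        lifetime = 0 if node.lifetime is None else node.lifetime
        label = f"{name}[&fate={node.fate}]:{lifetime}"
        if not kids:
            return label
        return "(" + ",".join(render(k) for k in kids) + ")" + label

    return render(tree.root.name) + ";"


def from_newick(text: str) -> LineageTree:
    """Parse a Newick string produced by :func:`export_newick`."""
    dtree = dendropy.Tree.get(
        data=text,
        schema="newick",
        suppress_internal_node_taxa=True,
        suppress_leaf_node_taxa=False,
        extract_comment_metadata=True,
    )
    nodes: list[LineageNode] = []

    def walk(dnode, parent_name: Optional[str], birth: int):
        name = dnode.label or (dnode.taxon.label if dnode.taxon else None)
        if not name:
            raise FormatError("newick node without a label")
        length = dnode.edge.length
        lifetime = 0 if length is None else int(round(length))
        meta = dnode.annotations.values_as_dict()
        fate = meta.get("fate", "unassigned")
        division = None if lifetime == 0 or not dnode.child_nodes() else birth + lifetime
        nodes.append(LineageNode(name, parent_name, birth, division, fate))
        for child in dnode.child_nodes():
            walk(child, name, birth + lifetime)

    walk(dtree.seed_node, None, 0)
    return LineageTree(nodes)


# -- tabular interface --------------------------------------------------------


def load_lineage(source) -> LineageTree:
    """Read a lineage table (path, file object, or string content).

    Expected header: ``name,parent,birth_time,division_time,fate`` with the
    empty string for absent parent / division_time.
    """
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    df = pd.read_csv(source, dtype={"name": str, "parent": str, "fate": str})
    missing = [c for c in LINEAGE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"lineage table missing columns: {missing}")

    nodes = []
    for row in df.itertuples(index=False):
        parent = None if pd.isna(row.parent) or row.parent == "" else str(row.parent)
        if pd.isna(row.division_time):
            division = None
        else:
            division = int(row.division_time)
        fate = "unassigned" if pd.isna(row.fate) or row.fate == "" else str(row.fate)
        try:
            birth = int(row.birth_time)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{row.name}: bad birth_time {row.birth_time!r}") from exc
        nodes.append(LineageNode(str(row.name), parent, birth, division, fate))
    return LineageTree(nodes)


def save_lineage(tree: LineageTree, path) -> None:
    """Write the lineage table format read by :func:`load_lineage`."""
    rows = [
        {
            "name": node.name,
            "parent": "" if node.parent is None else node.parent,
            "birth_time": node.birth_time,
            "division_time": "" if node.division_time is None else node.division_time,
            "fate": node.fate,
        }
        for node in tree
    ]
    pd.DataFrame(rows, columns=LINEAGE_COLUMNS).to_csv(path, index=False)
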