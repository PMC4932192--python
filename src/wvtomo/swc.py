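"""SWC neuron morphology container and text I/O.

The SWC format is the field's plain-text interchange for reconstructed
neurons: one node per line, seven whitespace-separated columns
``id type x y z radius parent``, 1-based ids, ``parent = -1`` for the root,
``#`` comments.  Type codes follow the common convention: 1 soma, 2 axon,
3 basal dendrite, 4 apical dendrite; anything else is carried through and
reported as "other" by the morphometry layer.

Positions are micrometres in (x, y, z).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Tuple

SOMA, AXON, BASAL, APICAL = 1, 2, 3, 4

TYPE_NAMES = {SOMA: "soma", AXON: "axon", BASAL: "basal", APICAL: "apical"}


@dataclass
class SWCNode:
    id: int
    type: int
    x: float
    y: float
    z: float
    radius: float
    parent: int  # -1 for root

    @property
    def position(self) -> Tuple[float, float, float]:
        return (self.x, self.y, self.z)


class SWCError(ValueError):
    """Malformed morphology (parse error or structural invariant violation)."""


@dataclass
class NeuronTree:
    """Rooted, acyclic neuron morphology.

    ``nodes`` maps node id to :class:`SWCNode`; exactly one node has
    ``parent == -1``.  Construction validates uniqueness of ids, existence of
    parents, acyclicity and finiteness of coordinates.
    """

    nodes: Dict[int, SWCNode] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------
    def validate(self) -> None:
        roots = [n.id for n in self.nodes.values() if n.parent == -1]
        if len(roots) != 1:
            raise SWCError(f"tree must have exactly one root, found {len(roots)}")
        for n in self.nodes.values():
            if n.parent != -1 and n.parent not in self.nodes:
                raise SWCError(f"node {n.id} references missing parent {n.parent}")
            if not all(math.isfinite(v) for v in (n.x, n.y, n.z, n.radius)):
                raise SWCError(f"node {n.id} has non-finite coordinates")
        # cycle check by walking to the root from every node
        for n in self.nodes.values():
            seen = set()
            cur = n
            while cur.parent != -1:
                if cur.id in seen:
                    raise SWCError(f"cycle detected through node {cur.id}")
                seen.add(cur.id)
                cur = self.nodes[cur.parent]

    @property
    def root(self) -> SWCNode:
        return next(n for n in self.nodes.values() if n.parent == -1)

    def children(self) -> Dict[int, List[int]]:
        ch: Dict[int, List[int]] = {i: [] for i in self.nodes}
        for n in self.nodes.values():
            if n.parent != -1:
                ch[n.parent].append(n.id)
        return ch

    def topological_order(self) -> List[int]:
        """Node ids with every parent preceding its children."""
        ch = self.children()
        order: List[int] = []
        stack = [self.root.id]
        while stack:
            i = stack.pop()
            order.append(i)
            stack.extend(reversed(ch[i]))
        return order

    # -- building ----------------------------------------------------------
    @classmethod
    def from_rows(cls, rows: Iterable[Tuple[int, int, float, float, float, float, int]]) -> "NeuronTree":
        nodes: Dict[int, SWCNode] = {}
        for (i, t, x, y, z, r, p) in rows:
            if i in nodes:
                raise SWCError(f"duplicate node id {i}")
            nodes[i] = SWCNode(int(i), int(t), float(x), float(y), float(z), float(r), int(p))
        return cls(nodes)


def read_swc(path: str | Path) -> NeuronTree:
    """Parse a standard 7-column SWC file; errors carry the offending line number."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise SWCError(f"{path}: line {lineno}: expected 7 columns, got {len(parts)}")
            try:
                rows.append(
                    (int(parts[0]), int(parts[1]), float(parts[2]), float(parts[3]),
                     float(parts[4]), float(parts[5]), int(parts[6]))
                )
            except ValueError as e:
                raise SWCError(f"{path}: line {lineno}: {e}") from None
    try:
        return NeuronTree.from_rows(rows)
    except SWCError as e:
        raise SWCError(f"{path}: {e}") from None


def write_swc(tree: NeuronTree, path: str | Path, comment: str = "") -> None:
    """Write nodes in topological order with 1-based consecutive ids."""
    order = tree.topological_order()
    remap = {old: new for new, old in enumerate(order, start=1)}
    with open(path, "w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("# id type x y z radius parent\n")
        for old in order:
            n = tree.nodes[old]
            parent = -1 if n.parent == -1 else remap[n.parent]
            fh.write(
                f"{remap[old]} {n.type} {n.x:.4f} {n.y:.4f} {n.z:.4f} {n.radius:.4f} {parent}\n"
            )
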