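"""Rooted skeleton trees of neuronal arbors, with SWC reading and writing.

A :class:`SkeletonTree` is the in-memory unit of arbor morphology: a rooted
tree of 3D nodes (positions in micrometres) with a local radius per node.
It corresponds one-to-one with the 7-column SWC format used for neuron
reconstructions (id, type, x, y, z, radius, parent).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = ["SkeletonNode", "SkeletonTree", "read_swc", "write_swc", "SwcFormatError"]

# SWC structure-type code for axonal compartments.
AXON_TYPE = 2


class SwcFormatError(ValueError):
    """Raised when an SWC file violates the 7-column tree dialect."""


@dataclass
class SkeletonNode:
    """One skeleton sample: position in μm, radius in μm, parent id (None at root)."""

    id: int
    position: np.ndarray
    radius: float
    parent: int | None = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError(f"node {self.id}: position must be a 3-vector")


class SkeletonTree:
    """A rooted tree of :class:`SkeletonNode`, the unit of arbor morphology.

    Invariants enforced at construction: node ids unique, exactly one root
    (parent is None), every parent id refers to an existing node, the parent
    relation is acyclic and connected, radii positive, coordinates finite.
    """

    def __init__(self, nodes: Iterable[SkeletonNode]):
        self._nodes: dict[int, SkeletonNode] = {}
        for node in nodes:
            if node.id in self._nodes:
                raise ValueError(f"duplicate node id {node.id}")
            self._nodes[node.id] = node
        self._validate()
        self._index_children()

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_arrays(
        cls,
        ids: Sequence[int],
        positions: np.ndarray,
        radii: Sequence[float],
        parents: Sequence[int | None],
    ) -> "SkeletonTree":
        positions = np.asarray(positions, dtype=float)
        return cls(
            SkeletonNode(int(i), positions[k], float(r), None if p is None else int(p))
            for k, (i, r, p) in enumerate(zip(ids, radii, parents))
        )

    def copy(self) -> "SkeletonTree":
        return SkeletonTree(
            SkeletonNode(n.id, n.position.copy(), n.radius, n.parent)
            for n in self._nodes.values()
        )

    # -- validation -----------------------------------------------------------

    def _validate(self) -> None:
        if not self._nodes:
            raise ValueError("a SkeletonTree must contain at least one node")
        roots = [n.id for n in self._nodes.values() if n.parent is None]
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root, found {len(roots)}")
        self._root_id = roots[0]
        for n in self._nodes.values():
            if n.parent is not None and n.parent not in self._nodes:
                raise ValueError(f"node {n.id} references missing parent {n.parent}")
            if not np.all(np.isfinite(n.position)):
                raise ValueError(f"node {n.id} has non-finite coordinates")
            if not (n.radius > 0):
                raise ValueError(f"node {n.id} has non-positive radius {n.radius}")
        # Acyclicity + connectivity: every node must reach the root.
        for n in self._nodes.values():
            seen = set()
            cur: int | None = n.id
            while cur is not None:
                if cur in seen:
                    raise ValueError(f"cycle in parent references at node {cur}")
                seen.add(cur)
                cur = self._nodes[cur].parent

    def _index_children(self) -> None:
        self._children: dict[int, list[int]] = {i: [] for i in self._nodes}
        for n in self._nodes.values():
            if n.parent is not None:
                self._children[n.parent].append(n.id)

    # -- basic accessors ------------------------------------------------------

    def __len__(self) -> int:
        return len(self._nodes)

    def __iter__(self) -> Iterator[SkeletonNode]:
        return iter(self._nodes.values())

    def __contains__(self, node_id: int) -> bool:
        return node_id in self._nodes

    def node(self, node_id: int) -> SkeletonNode:
        return self._nodes[node_id]

    @property
    def root_id(self) -> int:
        return self._root_id

    @property
    def root(self) -> SkeletonNode:
        return self._nodes[self._root_id]

    def children(self, node_id: int) -> list[int]:
        return list(self._children[node_id])

    def node_ids(self) -> list[int]:
        return list(self._nodes)

    def positions(self) -> np.ndarray:
        """All node positions as an (n, 3) array in μm (iteration order)."""
        return np.array([n.position for n in self._nodes.values()], dtype=float)

    def leaves(self) -> list[int]:
        """Ids of nodes with no children (tips)."""
        return [i for i, ch in self._children.items() if not ch]

    def branch_points(self) -> list[int]:
        """Ids of nodes with two or more children."""
        return [i for i, ch in self._children.items() if len(ch) >= 2]

    def edges(self) -> Iterator[tuple[SkeletonNode, SkeletonNode]]:
        """Yield (parent, child) node pairs."""
        for n in self._nodes.values():
            if n.parent is not None:
                yield self._nodes[n.parent], n

    def path_to_root(self, node_id: int) -> list[int]:
        """Node ids from ``node_id`` up to and including the root."""
        path = [node_id]
        while (p := self._nodes[path[-1]].parent) is not None:
            path.append(p)
        return path

    def cable_length(self) -> float:
        """Sum of Euclidean parent–child distances, in μm."""
        return float(
            sum(np.linalg.norm(p.position - c.position) for p, c in self.edges())
        )


# -- SWC I/O ------------------------------------------------------------------


def read_swc(path: str | Path) -> SkeletonTree:
    """Read a 7-column SWC file into a :class:`SkeletonTree`.

    Parent id -1 marks the root. Malformed rows, orphan parents and cyclic
    parent references raise :class:`SwcFormatError` naming the offending
    line or node.
    """
    path = Path(path)
    rows: list[tuple[int, int, float, float, float, float, int]] = []
    lines: dict[int, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise SwcFormatError(
                    f"{path.name}:{lineno}: expected 7 columns, got {len(parts)}"
                )
            try:
                nid, ntype = int(parts[0]), int(parts[1])
                x, y, z, r = (float(v) for v in parts[2:6])
                parent = int(parts[6])
            except ValueError as exc:
                raise SwcFormatError(f"{path.name}:{lineno}: {exc}") from exc
            if nid in lines:
                raise SwcFormatError(
                    f"{path.name}:{lineno}: duplicate node id {nid} "
                    f"(first seen on line {lines[nid]})"
                )
            lines[nid] = lineno
            rows.append((nid, ntype, x, y, z, r, parent))

    ids = {row[0] for row in rows}
    for nid, _, _, _, _, _, parent in rows:
        if parent != -1 and parent not in ids:
            raise SwcFormatError(
                f"{path.name}:{lines[nid]}: node {nid} references "
                f"missing parent {parent} (orphan node)"
            )
    try:
        return SkeletonTree(
            SkeletonNode(nid, np.array([x, y, z]), r, None if parent == -1 else parent)
            for nid, _, x, y, z, r, parent in rows
        )
    except ValueError as exc:
        raise SwcFormatError(f"{path.name}: {exc}") from exc


def write_swc(
    tree: SkeletonTree, path: str | Path, *, header: Sequence[str] = ()
) -> None:
    """Write a tree as 7-column SWC (type code 2 = axon), root first.

    ``header`` lines are emitted as ``#``-comments (used for seed/config
    provenance). Round-trip with :func:`read_swc` preserves topology and
    coordinates to float repr precision.
    """
    order: list[int] = []
    stack = [tree.root_id]
    while stack:
        nid = stack.pop()
        order.append(nid)
        stack.extend(sorted(tree.children(nid), reverse=True))
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        for nid in order:
            n = tree.node(nid)
            parent = -1 if n.parent is None else n.parent
            x, y, z = n.position
            fh.write(
                f"{n.id} {AXON_TYPE} {x:.6f} {y:.6f} {z:.6f} {n.radius:.6f} {parent}\n"
            )
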