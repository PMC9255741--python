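"""Rooted-tree-in-3-space model of a neuron.

A neuron is a collection of rooted binary trees (the *primary* trees or
stems) sharing a common root, the soma, which sits at the origin.  Every
non-soma branchpoint has exactly two children; SWC multifurcations are
binarized by inserting zero-length edges.  Node kinds:

- ``soma``: the root (any number of stems),
- ``bifurcation``: two children,
- ``continuation``: one child (a geometry sample along a branch),
- ``termination``: a leaf.

The *degree* of a tree is its number of leaves.  Per primary tree the
binary-tree identities hold: branches = 2*degree - 1, bifurcations =
degree - 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .swc import SOMA, BASAL_DENDRITE, SwcRecord

__all__ = [
    "NeuronNode",
    "Neuron",
    "NeuronModelError",
    "build_neuron",
    "node_distances",
    "restrict_to_ball",
]


class NeuronModelError(ValueError):
    """Input records cannot be assembled into a valid neuron model."""


@dataclass
class NeuronNode:
    id: int
    kind: str
    position: np.ndarray
    radius: float
    parent: int | None
    children: list[int] = field(default_factory=list)


class Neuron:
    """Immutable-by-convention tree model with cached geometry.

    Attributes
    ----------
    nodes : dict[int, NeuronNode]
    root : int
        Soma node id; its position is the origin.
    span_R : float
        Radius of the smallest soma-centered ball containing the neuron.
    longest_path_L : float
        Longest soma-to-tip path length.
    degree : int
        Number of terminations (leaves).
    n_bifurcations, n_branches : int
    """

    def __init__(self, nodes: dict[int, NeuronNode], root: int):
        self.nodes = nodes
        self.root = root
        self._assign_kinds()
        self._validate()
        self._compute_distances()

    # -- construction helpers -------------------------------------------------

    def _assign_kinds(self) -> None:
        for node in self.nodes.values():
            if node.id == self.root:
                node.kind = "soma"
            elif len(node.children) == 0:
                node.kind = "termination"
            elif len(node.children) == 1:
                node.kind = "continuation"
            elif len(node.children) == 2:
                node.kind = "bifurcation"
            else:
                raise NeuronModelError(
                    f"node {node.id} has {len(node.children)} children "
                    "after binarization"
                )

    def _validate(self) -> None:
        root = self.nodes[self.root]
        if root.parent is not None:
            raise NeuronModelError("root must have no parent")
        if not np.allclose(root.position, 0.0):
            raise NeuronModelError("soma must sit at the origin")
        reached = set(self.preorder())
        if reached != set(self.nodes):
            orphans = sorted(set(self.nodes) - reached)
            raise NeuronModelError(
                f"nodes {orphans} are not connected to the soma"
            )

    def _compute_distances(self) -> None:
        self.radial: dict[int, float] = {}
        self.path: dict[int, float] = {}
        for nid in self.preorder():
            node = self.nodes[nid]
            self.radial[nid] = float(np.linalg.norm(node.position))
            if node.parent is None:
                self.path[nid] = 0.0
            else:
                seg = node.position - self.nodes[node.parent].position
                self.path[nid] = self.path[node.parent] + float(np.linalg.norm(seg))
        self.span_R = max(self.radial.values())
        self.longest_path_L = max(self.path.values())
        self.degree = sum(1 for n in self.nodes.values() if n.kind == "termination")
        self.n_bifurcations = sum(
            1 for n in self.nodes.values() if n.kind == "bifurcation"
        )
        self.n_branches = self.n_bifurcations + self.degree

    # -- traversal ------------------------------------------------------------

    def preorder(self) -> Iterable[int]:
        """Node ids, parents before children (iterative DFS, cycle-safe)."""
        stack = [self.root]
        seen: set[int] = set()
        while stack:
            nid = stack.pop()
            if nid in seen:
                raise NeuronModelError(f"cycle through node {nid}")
            seen.add(nid)
            yield nid
            stack.extend(reversed(self.nodes[nid].children))

    def postorder(self) -> list[int]:
        order = list(self.preorder())
        order.reverse()
        return order

    def segments(self) -> Iterable[tuple[int, int]]:
        """(parent, child) id pairs for every edge."""
        for nid in self.preorder():
            for c in self.nodes[nid].children:
                yield nid, c

    def branches(self) -> list[list[int]]:
        """Maximal paths between structural nodes.

        Each branch runs from a soma/bifurcation node to the next
        bifurcation or termination, listing every node along the way
        (continuations included).  The first element is the branch's
        proximal structural node.
        """
        out: list[list[int]] = []
        structural = {"soma", "bifurcation"}
        for nid in self.preorder():
            node = self.nodes[nid]
            if node.kind not in structural:
                continue
            for child in node.children:
                path = [nid, child]
                cur = self.nodes[child]
                while cur.kind == "continuation":
                    nxt = cur.children[0]
                    path.append(nxt)
                    cur = self.nodes[nxt]
                out.append(path)
        return out

    # -- geometry -------------------------------------------------------------

    @property
    def total_length(self) -> float:
        return float(
            sum(
                np.linalg.norm(
                    self.nodes[c].position - self.nodes[p].position
                )
                for p, c in self.segments()
            )
        )

    def structural_nodes(self, kinds: Sequence[str]) -> list[NeuronNode]:
        want = set(kinds)
        return [n for n in self.nodes.values() if n.kind in want]

    def with_positions(self, positions: dict[int, np.ndarray]) -> "Neuron":
        """Copy of the neuron with some node positions replaced."""
        nodes = {
            nid: NeuronNode(
                id=n.id,
                kind=n.kind,
                position=np.asarray(positions.get(nid, n.position), dtype=float),
                radius=n.radius,
                parent=n.parent,
                children=list(n.children),
            )
            for nid, n in self.nodes.items()
        }
        return Neuron(nodes, self.root)

    def transformed(self, matrix: np.ndarray) -> "Neuron":
        """Apply an origin-fixing linear map (rotation/reflection)."""
        Q = np.asarray(matrix, dtype=float)
        return self.with_positions(
            {nid: Q @ n.position for nid, n in self.nodes.items()}
        )

    def to_records(self, structure_type: int = BASAL_DENDRITE) -> list[SwcRecord]:
        """Serialize to SWC records (ids renumbered 1..n in preorder)."""
        renum = {nid: i + 1 for i, nid in enumerate(self.preorder())}
        records = []
        for nid in self.preorder():
            n = self.nodes[nid]
            records.append(
                SwcRecord(
                    sample_id=renum[nid],
                    structure_type=SOMA if nid == self.root else structure_type,
                    x=float(n.position[0]),
                    y=float(n.position[1]),
                    z=float(n.position[2]),
                    radius=float(n.radius),
                    parent_id=-1 if n.parent is None else renum[n.parent],
                )
            )
        return records

    def to_dict(self) -> dict:
        return {
            "root": self.root,
            "nodes": {
                str(nid): {
                    "kind": n.kind,
                    "position": [float(v) for v in n.position],
                    "radius": float(n.radius),
                    "parent": n.parent,
                    "children": list(n.children),
                }
                for nid, n in self.nodes.items()
            },
        }

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<Neuron nodes={len(self.nodes)} degree={self.degree} "
            f"R={self.span_R:.3g} L={self.longest_path_L:.3g}>"
        )


def build_neuron(records: Sequence[SwcRecord]) -> Neuron:
    """Assemble SWC records into a :class:`Neuron`.

    All soma samples (1-point and 3-point conventions alike) collapse to
    a single root placed at the first soma sample's coordinates; the
    whole reconstruction is then translated so the root sits at the
    origin.  Nodes with more than two children (soma excepted) are
    binarized by inserting duplicate-position nodes joined by
    zero-length edges.
    """
    soma_ids = [r.sample_id for r in records if r.structure_type == SOMA]
    if not soma_ids:
        raise NeuronModelError("no soma record (structure type 1) in input")
    soma_set = set(soma_ids)
    first_soma = next(r for r in records if r.structure_type == SOMA)
    origin = np.array([first_soma.x, first_soma.y, first_soma.z], dtype=float)
    root_id = first_soma.sample_id

    nodes: dict[int, NeuronNode] = {
        root_id: NeuronNode(
            id=root_id,
            kind="soma",
            position=np.zeros(3),
            radius=first_soma.radius,
            parent=None,
        )
    }
    for rec in records:
        if rec.structure_type == SOMA:
            continue
        parent = rec.parent_id
        if parent in soma_set:
            parent = root_id
        if parent == -1:
            raise NeuronModelError(
                f"non-soma sample {rec.sample_id} is a root; "
                "disconnected from the soma"
            )
        nodes[rec.sample_id] = NeuronNode(
            id=rec.sample_id,
            kind="continuation",
            position=np.array([rec.x, rec.y, rec.z], dtype=float) - origin,
            radius=rec.radius,
            parent=parent,
        )
    for nid, node in nodes.items():
        if node.parent is not None:
            if node.parent not in nodes:
                raise NeuronModelError(
                    f"sample {nid} references missing parent {node.parent}"
                )
            nodes[node.parent].children.append(nid)

    _binarize(nodes, root_id)
    return Neuron(nodes, root_id)


def _binarize(nodes: dict[int, NeuronNode], root_id: int) -> None:
    """Insert duplicate-position nodes so non-soma branchpoints are binary."""
    next_id = max(nodes) + 1
    queue = [nid for nid in nodes if nid != root_id and len(nodes[nid].children) > 2]
    while queue:
        nid = queue.pop()
        node = nodes[nid]
        while len(node.children) > 2:
            twin = NeuronNode(
                id=next_id,
                kind="bifurcation",
                position=node.position.copy(),
                radius=node.radius,
                parent=nid,
                children=node.children[1:],
            )
            for c in twin.children:
                nodes[c].parent = twin.id
            node.children = [node.children[0], twin.id]
            nodes[twin.id] = twin
            next_id += 1
            node = twin


def node_distances(neuron: Neuron) -> dict[int, tuple[float, float]]:
    """Per-node (radial, path) distances from the soma, in file units.

    Radial distance is the Euclidean norm of the node position; path
    distance accumulates segment lengths along the dendrite, so
    path >= radial for every node.
    """
    return {nid: (neuron.radial[nid], neuron.path[nid]) for nid in neuron.nodes}


def restrict_to_ball(
    neuron: Neuron, r: float, *, keep_tangent_tips: bool = False
) -> Neuron:
    """Soma component of the neuron intersected with the closed ball B(0, r).

    Each segment is kept up to its first exit from the ball: because
    distance-to-origin is convex along a straight segment, the inside
    part reachable from the soma is a single interval starting at the
    proximal endpoint.  Clip points become terminations; subtrees beyond
    an exit are dropped.  Nodes at radial distance exactly ``r`` are
    inside (closed-ball convention).

    With ``keep_tangent_tips=True``, a segment leaving a node that sits
    exactly on the sphere keeps a zero-length termination at the node
    (the limit of the restriction as the radius shrinks to r from
    above); by default such grazing segments are dropped entirely.
    """
    if r < 0:
        raise ValueError(f"radius must be nonnegative, got {r}")
    next_id = max(neuron.nodes) + 1
    nodes: dict[int, NeuronNode] = {}
    root = neuron.nodes[neuron.root]
    nodes[neuron.root] = NeuronNode(
        id=neuron.root, kind="soma", position=root.position.copy(),
        radius=root.radius, parent=None,
    )
    stack = [(neuron.root, c) for c in root.children]
    while stack:
        pid, cid = stack.pop()
        p = neuron.nodes[pid].position
        child = neuron.nodes[cid]
        q = child.position
        if neuron.radial[cid] <= r:
            nodes[cid] = NeuronNode(
                id=cid, kind="continuation", position=q.copy(),
                radius=child.radius, parent=pid,
            )
            nodes[pid].children.append(cid)
            stack.extend((cid, g) for g in child.children)
            continue
        # child is outside: clip the segment at its first sphere exit
        d = q - p
        a = float(d @ d)
        if a == 0.0:
            continue  # zero-length edge to an outside duplicate: drop
        b = 2.0 * float(p @ d)
        c0 = float(p @ p) - r * r
        disc = b * b - 4.0 * a * c0
        u1 = (-b + np.sqrt(max(disc, 0.0))) / (2.0 * a)
        if u1 <= 0.0 and not keep_tangent_tips:
            continue  # parent sits on the sphere, segment points outward
        u1 = min(max(u1, 0.0), 1.0)
        clip = NeuronNode(
            id=next_id,
            kind="termination",
            position=p + u1 * d,
            radius=float(
                neuron.nodes[pid].radius
                + u1 * (child.radius - neuron.nodes[pid].radius)
            ),
            parent=pid,
        )
        nodes[next_id] = clip
        nodes[pid].children.append(next_id)
        next_id += 1
    return Neuron(nodes, neuron.root)
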