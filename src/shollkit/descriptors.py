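"""Sholl descriptor functions.

A *Sholl descriptor* maps a neuron to a compactly supported function of
normalized distance from the soma (radial or path, normalized by the
span R(N) or the longest path L(N) so the domain is [0, 1]), with values
in the reals or in the space of persistence diagrams.  Every descriptor
is invariant under origin-fixing isometries (rotations and reflections
through the soma) and, with the exception of tortuosity, stable under
small reconstruction jitter.

Real-valued descriptors
-----------------------
branching_pattern   leaves minus bifurcations within radius r
tortuosity          mean branch path-length / chord-length ratio
flux                summed crossing angles against the sphere normal
taper_rate          dendritic diameter at the last branchpoint (path domain)
leaf_index          leaves reachable from the last branchpoint within r
energy              norm of the inverse-square node field at the soma
wiring              total dendritic length inside the ball

Diagram-valued
--------------
tmd_classical       topological morphology descriptor (persistence barcode
                    of the radial-distance filtration; one bar per leaf)
sholl_tmd           r-varying TMD of the ball restriction
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .neuron import Neuron, restrict_to_ball

__all__ = [
    "ShollFunction",
    "PersistenceDiagram",
    "DiagramFunction",
    "EnergyPolarity",
    "branching_pattern",
    "tortuosity",
    "flux",
    "flux_at",
    "taper_rate",
    "leaf_index",
    "energy",
    "energy_polarity",
    "wiring",
    "wiring_at",
    "tmd_classical",
    "sholl_tmd",
    "REAL_DESCRIPTORS",
    "compute_descriptor",
]


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ShollFunction:
    """Right-continuous step function on the normalized domain [0, 1].

    ``values[i]`` holds on ``[breakpoints[i], breakpoints[i+1])``; the
    last value holds up to and including t = 1.  ``normalizer`` is the
    length (micrometres) that maps the native domain onto [0, 1]:
    R(N) for radial-domain descriptors, L(N) for path-domain ones.
    """

    descriptor_name: str
    domain_kind: str
    normalizer: float
    breakpoints: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        bp = np.asarray(self.breakpoints, dtype=float)
        va = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "breakpoints", bp)
        object.__setattr__(self, "values", va)
        if bp.ndim != 1 or va.shape != bp.shape or bp.size == 0:
            raise ValueError("breakpoints and values must be equal-length 1-D")
        if bp[0] != 0.0:
            raise ValueError("first breakpoint must be 0")
        if bp[-1] > 1.0 + 1e-12:
            raise ValueError("breakpoints must lie in [0, 1]")
        if np.any(np.diff(bp) <= 0):
            raise ValueError("breakpoints must be strictly ascending")

    def value_at(self, t: float) -> float:
        """Evaluate at t in [0, 1] (right-continuous; t=1 uses the last value)."""
        idx = int(np.searchsorted(self.breakpoints, t, side="right")) - 1
        return float(self.values[max(idx, 0)])

    def __call__(self, t: float) -> float:
        return self.value_at(t)

    def to_dict(self) -> dict:
        return {
            "name": self.descriptor_name,
            "domain_kind": self.domain_kind,
            "normalizer": float(self.normalizer),
            "breakpoints": self.breakpoints.tolist(),
            "values": self.values.tolist(),
        }


def _step_from_events(
    name: str,
    domain_kind: str,
    normalizer: float,
    events: list[tuple[float, float]],
    initial: float,
    dedupe: str = "last",
) -> ShollFunction:
    """Assemble a step function from (breakpoint, value) events.

    Events are sorted by breakpoint; duplicates collapse to the last
    (``dedupe='last'``) or largest (``'max'``) value at that breakpoint.
    ``initial`` is the value on [0, first event).
    """
    bps = [0.0]
    vals = [initial]
    for t, v in sorted(events, key=lambda e: e[0]):
        t = min(float(t), 1.0)
        if t == bps[-1]:
            if dedupe == "max":
                vals[-1] = max(vals[-1], v)
            else:
                vals[-1] = v
        else:
            bps.append(t)
            vals.append(v)
    return ShollFunction(name, domain_kind, normalizer, np.array(bps), np.array(vals))


@dataclass(frozen=True)
class PersistenceDiagram:
    """TMD barcode: one (start, end) bar per leaf, start >= end >= 0.

    ``start`` is the radial distance at which the leaf's path is born
    (the leaf itself), ``end`` the radial distance of the merge node
    where the path dies.  ``paths`` aligns with ``bars`` and lists the
    node ids of each leaf-to-merge path.
    """

    bars: np.ndarray
    paths: tuple[tuple[int, ...], ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        bars = np.asarray(self.bars, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "bars", bars)
        if bars.size and np.any(bars[:, 0] < bars[:, 1] - 1e-9):
            raise ValueError("bar start must be >= end")

    def __len__(self) -> int:
        return int(self.bars.shape[0])

    @property
    def total_persistence(self) -> float:
        return float(np.sum(self.bars[:, 0] - self.bars[:, 1])) if len(self) else 0.0

    def sorted_bars(self) -> np.ndarray:
        if not len(self):
            return self.bars
        order = np.lexsort((self.bars[:, 1], self.bars[:, 0]))
        return self.bars[order]


@dataclass(frozen=True)
class DiagramFunction:
    """Piecewise-constant persistence-diagram-valued function on [0, 1]."""

    breakpoints: np.ndarray
    diagrams: tuple[PersistenceDiagram, ...]
    normalizer: float
    descriptor_name: str = "sholl_tmd"
    domain_kind: str = "radial"

    def __post_init__(self) -> None:
        bp = np.asarray(self.breakpoints, dtype=float)
        object.__setattr__(self, "breakpoints", bp)
        if bp.size != len(self.diagrams) or bp.size == 0:
            raise ValueError("one diagram per breakpoint required")
        if bp[0] != 0.0 or np.any(np.diff(bp) <= 0):
            raise ValueError("breakpoints must start at 0 and be ascending")

    def value_at(self, t: float) -> PersistenceDiagram:
        idx = int(np.searchsorted(self.breakpoints, t, side="right")) - 1
        return self.diagrams[max(idx, 0)]

    def __call__(self, t: float) -> PersistenceDiagram:
        return self.value_at(t)


@dataclass(frozen=True)
class EnergyPolarity:
    """Two-way split of a neuron's node charges by field direction."""

    node_ids: tuple[int, ...]
    angle_matrix: np.ndarray
    cluster_labels: np.ndarray
    polarity: float  # angle (rad) between the two clusters' summed fields


# --------------------------------------------------------------------------
# helpers
# --------------------------------------------------------------------------


def _charge_nodes(neuron: Neuron) -> list[int]:
    """Nodes acting as charges: bifurcations and terminations (not soma,
    not continuation geometry samples), excluding any at the origin."""
    return [
        n.id
        for n in neuron.nodes.values()
        if n.kind in ("bifurcation", "termination") and neuron.radial[n.id] > 0
    ]


def _reach_radius(neuron: Neuron) -> dict[int, float]:
    """Max radial distance along the soma-to-node path (node resolution;
    exact because distance-to-origin is convex along straight segments)."""
    reach: dict[int, float] = {}
    for nid in neuron.preorder():
        parent = neuron.nodes[nid].parent
        r = neuron.radial[nid]
        reach[nid] = r if parent is None else max(reach[parent], r)
    return reach


def _degenerate(name: str, domain_kind: str, value: float) -> ShollFunction:
    return ShollFunction(name, domain_kind, 0.0, np.array([0.0]), np.array([value]))


# --------------------------------------------------------------------------
# real-valued descriptors
# --------------------------------------------------------------------------


def branching_pattern(
    neuron: Neuron, domain_kind: str = "radial", literal_sign: bool = False
) -> ShollFunction:
    """Leaves minus bifurcations within distance r (default sign).

    With the default sign the value at t = 1 equals the number of
    primary branches (stems), since every stem tree satisfies
    leaves - bifurcations = 1.  ``literal_sign=True`` flips the sign to
    bifurcations - leaves.  ``domain_kind`` selects radial distance
    (normalized by R(N)) or path distance (normalized by L(N)).
    """
    if domain_kind not in ("radial", "path"):
        raise ValueError(f"unknown domain_kind {domain_kind!r}")
    dist = neuron.radial if domain_kind == "radial" else neuron.path
    norm = neuron.span_R if domain_kind == "radial" else neuron.longest_path_L
    if norm == 0:
        return _degenerate("branching", domain_kind, 0.0)
    sign = -1.0 if literal_sign else 1.0
    deltas: dict[float, float] = {}
    for node in neuron.nodes.values():
        if node.kind == "termination":
            deltas[dist[node.id] / norm] = deltas.get(dist[node.id] / norm, 0.0) + sign
        elif node.kind == "bifurcation":
            deltas[dist[node.id] / norm] = deltas.get(dist[node.id] / norm, 0.0) - sign
    events = []
    running = 0.0
    for t in sorted(deltas):
        running += deltas[t]
        events.append((t, running))
    return _step_from_events("branching", domain_kind, norm, events, initial=0.0)


def tortuosity(neuron: Neuron) -> ShollFunction:
    """Mean tortuosity of branches completely inside the ball B(0, r).

    A branch's tortuosity is its path length divided by the Euclidean
    distance of its endpoints (>= 1; exactly 1 for straight branches).
    A branch counts once it is entirely contained in the ball *and*
    connected to the soma inside it; before any branch qualifies the
    value is 1.  Zero-length branches (binarization artifacts) and
    coincident-endpoint branches are excluded.
    """
    if neuron.span_R == 0:
        return _degenerate("tortuosity", "radial", 1.0)
    reach = _reach_radius(neuron)
    completed: list[tuple[float, float]] = []  # (completion radius, tortuosity)
    for branch in neuron.branches():
        pts = [neuron.nodes[nid].position for nid in branch]
        path_len = float(
            sum(np.linalg.norm(b - a) for a, b in zip(pts[:-1], pts[1:]))
        )
        chord = float(np.linalg.norm(pts[-1] - pts[0]))
        if path_len <= 0 or chord <= 0:
            continue
        completed.append((reach[branch[-1]] / neuron.span_R, path_len / chord))
    completed.sort(key=lambda e: e[0])
    events = []
    total = 0.0
    count = 0
    i = 0
    while i < len(completed):
        t = completed[i][0]
        while i < len(completed) and completed[i][0] == t:
            total += completed[i][1]
            count += 1
            i += 1
        events.append((t, total / count))
    return _step_from_events("tortuosity", "radial", neuron.span_R, events, initial=1.0)


def flux_at(neuron: Neuron, r: float) -> float:
    """Summed crossing angles (radians) of the arbor against the sphere |x| = r.

    For each straight segment, crossings of the sphere are the roots in
    [0, 1] of a quadratic (at most two, by convexity of the distance to
    the origin).  Each crossing contributes the unsigned angle between
    the parent-to-child segment direction and the outward radial normal,
    computed as atan2(||d x n||, d.n) for numerical robustness near
    parallel crossings.
    """
    if r <= 0:
        return 0.0
    total = 0.0
    for pid, cid in neuron.segments():
        p = neuron.nodes[pid].position
        q = neuron.nodes[cid].position
        d = q - p
        a = float(d @ d)
        if a == 0.0:
            continue
        b = 2.0 * float(p @ d)
        c0 = float(p @ p) - r * r
        disc = b * b - 4.0 * a * c0
        # clamp rounding-level negative discriminants: a sphere grazing a
        # node (e.g. the farthest tip at r = R) must register in every frame
        scale = b * b + 4.0 * abs(a * c0)
        if disc < -1e-12 * scale:
            continue
        sq = float(np.sqrt(max(disc, 0.0)))
        roots = [(-b - sq) / (2 * a)]
        if sq > 1e-7 * abs(a):
            roots.append((-b + sq) / (2 * a))  # distinct second crossing
        dhat = d / np.sqrt(a)
        for u in roots:
            if u < -1e-9 or u > 1.0 + 1e-9:
                continue
            u = min(max(u, 0.0), 1.0)
            x = p + u * d
            nx = float(np.linalg.norm(x))
            if nx == 0.0:
                continue
            n = x / nx
            total += float(np.arctan2(np.linalg.norm(np.cross(dhat, n)), dhat @ n))
    return total


def flux(neuron: Neuron, n_grid: int = 100) -> ShollFunction:
    """Flux descriptor sampled on an equispaced normalized grid.

    Flux is not piecewise constant in r, so the returned step function
    is a grid discretization: ``n_grid`` equispaced t values on [0, 1],
    each carrying the exact flux at radius t * R(N).
    """
    if neuron.span_R == 0:
        return _degenerate("flux", "radial", 0.0)
    ts = np.linspace(0.0, 1.0, n_grid)
    vals = np.array([flux_at(neuron, t * neuron.span_R) for t in ts])
    return ShollFunction("flux", "radial", neuron.span_R, ts, vals)


def taper_rate(neuron: Neuron) -> ShollFunction:
    """Dendritic diameter at the last branchpoint within path distance r.

    Path-domain descriptor (normalized by L(N)): branching nodes are
    ordered by path distance; the value at t is the diameter (twice the
    radius) of the branching node with the largest path distance not
    exceeding t * L(N).  Before the first branchpoint the value is the
    soma diameter.
    """
    if neuron.longest_path_L == 0:
        return _degenerate("taper", "path", 2.0 * neuron.nodes[neuron.root].radius)
    bifs = sorted(
        (n for n in neuron.nodes.values() if n.kind == "bifurcation"),
        key=lambda n: (neuron.path[n.id], n.id),
    )
    soma_diam = 2.0 * neuron.nodes[neuron.root].radius
    if all(n.radius == 0 for n in neuron.nodes.values()):
        warnings.warn("all radii are zero; taper rate is identically 0", stacklevel=2)
        return _degenerate("taper", "path", 0.0)
    events = [
        (neuron.path[n.id] / neuron.longest_path_L, 2.0 * n.radius) for n in bifs
    ]
    return _step_from_events(
        "taper", "path", neuron.longest_path_L, events, initial=soma_diam
    )


def leaf_index(neuron: Neuron) -> ShollFunction:
    """Leaves reachable (soma-fleeing) from the last branchpoint within r.

    At radius r the reference branchpoint b is the one with the largest
    radial distance <= r (the soma if none); the value is the number of
    terminations in b's subtree.  At t = 0 this is the total leaf count
    (the neuron's degree).  Ties between branchpoints at the same radial
    distance resolve to the larger reachable-leaf count.
    """
    if neuron.span_R == 0:
        return _degenerate("leaf_index", "radial", 0.0)
    leaves_below: dict[int, int] = {}
    for nid in neuron.postorder():
        node = neuron.nodes[nid]
        if node.kind == "termination":
            leaves_below[nid] = 1
        else:
            leaves_below[nid] = sum(leaves_below[c] for c in node.children)
    events = [
        (neuron.radial[n.id] / neuron.span_R, float(leaves_below[n.id]))
        for n in neuron.nodes.values()
        if n.kind == "bifurcation"
    ]
    return _step_from_events(
        "leaf_index",
        "radial",
        neuron.span_R,
        events,
        initial=float(neuron.degree),
        dedupe="max",
    )


def energy(neuron: Neuron, exponent: float = 2.0) -> ShollFunction:
    """Norm of the summed inverse-square node field at the soma.

    Bifurcation and termination nodes act as unit charges; a node at
    position v contributes v / |v|^(exponent+1) (Coulomb's law for the
    default exponent 2).  The value at t is the Euclidean norm of the
    summed contribution of charges within radius t * R(N) — an isometry
    invariant.  Under uniform spatial scaling by s the values scale by
    s^(-exponent).
    """
    if neuron.span_R == 0:
        return _degenerate("energy", "radial", 0.0)
    charges = sorted(_charge_nodes(neuron), key=lambda nid: neuron.radial[nid])
    events = []
    acc = np.zeros(3)
    i = 0
    while i < len(charges):
        t = neuron.radial[charges[i]] / neuron.span_R
        while i < len(charges) and neuron.radial[charges[i]] / neuron.span_R == t:
            nid = charges[i]
            v = neuron.nodes[nid].position
            acc = acc + v / neuron.radial[nid] ** (exponent + 1.0)
            i += 1
        events.append((t, float(np.linalg.norm(acc))))
    return _step_from_events("energy", "radial", neuron.span_R, events, initial=0.0)


def energy_polarity(neuron: Neuron, exponent: float = 2.0) -> EnergyPolarity:
    """Split node charges into two directional clusters.

    Builds the pairwise angle matrix between per-node field
    contributions v/|v|^(exponent+1), clusters it with average-linkage
    agglomeration cut at two clusters, and reports the angle between the
    two clusters' summed field vectors (the polarity score: near pi for
    bipolar neurons, small for unipolar ones).
    """
    ids = _charge_nodes(neuron)
    if len(ids) < 2:
        raise ValueError("energy polarity needs at least 2 non-soma charge nodes")
    vecs = np.array(
        [
            neuron.nodes[nid].position / neuron.radial[nid] ** (exponent + 1.0)
            for nid in ids
        ]
    )
    unit = vecs / np.linalg.norm(vecs, axis=1, keepdims=True)
    cos = np.clip(unit @ unit.T, -1.0, 1.0)
    angles = np.arccos(cos)
    np.fill_diagonal(angles, 0.0)
    angles = (angles + angles.T) / 2.0
    Z = linkage(squareform(angles, checks=False), method="average")
    labels = fcluster(Z, t=2, criterion="maxclust")
    s1 = vecs[labels == 1].sum(axis=0)
    s2 = vecs[labels == 2].sum(axis=0)
    n1, n2 = np.linalg.norm(s1), np.linalg.norm(s2)
    if n1 == 0 or n2 == 0:
        polarity = 0.0
    else:
        polarity = float(np.arccos(np.clip(s1 @ s2 / (n1 * n2), -1.0, 1.0)))
    return EnergyPolarity(tuple(ids), angles, labels, polarity)


def wiring_at(neuron: Neuron, r: float) -> float:
    """Total dendritic length of the soma component inside B(0, r)."""
    if r <= 0:
        return 0.0
    reach = _reach_radius(neuron)
    total = 0.0
    for pid, cid in neuron.segments():
        if reach[pid] > r:
            continue  # segment not reachable from the soma inside the ball
        p = neuron.nodes[pid].position
        q = neuron.nodes[cid].position
        d = q - p
        a = float(d @ d)
        if a == 0.0:
            continue
        if neuron.radial[cid] <= r:
            total += float(np.sqrt(a))
            continue
        b = 2.0 * float(p @ d)
        c0 = float(p @ p) - r * r
        disc = max(b * b - 4.0 * a * c0, 0.0)
        u1 = (-b + float(np.sqrt(disc))) / (2.0 * a)
        if u1 > 0:
            total += min(u1, 1.0) * float(np.sqrt(a))
    return total


def wiring(neuron: Neuron, n_grid: int = 100) -> ShollFunction:
    """Total wiring descriptor: length of the ball restriction vs radius.

    Wiring grows continuously in r; the step representation samples it
    on the union of an equispaced grid and the exact normalized node
    radii, so values at node radii (including t = 1, the total dendritic
    length) are exact.
    """
    if neuron.span_R == 0:
        return _degenerate("wiring", "radial", 0.0)
    # node breakpoints evaluate at the raw radius: renormalizing and
    # scaling back can land a hair below the node's own radius and flip
    # the closed-ball tie (breaking exact isometry invariance)
    radius_at = {float(t): t * neuron.span_R for t in np.linspace(0.0, 1.0, n_grid)}
    for nid in neuron.nodes:
        radius_at[neuron.radial[nid] / neuron.span_R] = neuron.radial[nid]
    ts = np.array(sorted(radius_at))
    vals = np.array([wiring_at(neuron, radius_at[t]) for t in ts])
    return ShollFunction("wiring", "radial", neuron.span_R, ts, vals)


# --------------------------------------------------------------------------
# diagram-valued descriptors
# --------------------------------------------------------------------------


def tmd_classical(neuron: Neuron) -> PersistenceDiagram:
    """Topological morphology descriptor of the radial-distance filtration.

    Each leaf is born at its radial distance; at every merge node the
    child carrying the larger value survives and the other emits the bar
    (its value, merge-node radial distance).  The final survivor emits
    (its value, 0) at the soma.  One bar per leaf.  Ties at a merge
    resolve to the smaller surviving leaf id.  The ``paths`` attribute
    holds the leaf-to-merge node sequences of the decomposition.
    """
    # state per resolved subtree: (value, leaf id, path so far)
    state: dict[int, tuple[float, int, list[int]]] = {}
    bars: list[tuple[float, float]] = []
    paths: list[tuple[int, ...]] = []
    for nid in neuron.postorder():
        node = neuron.nodes[nid]
        if node.kind == "termination":
            state[nid] = (neuron.radial[nid], nid, [nid])
        elif node.kind == "continuation":
            v, leaf, path = state.pop(node.children[0])
            state[nid] = (v, leaf, path + [nid])
        elif node.children:  # bifurcation or multi-stem soma
            entries = [state.pop(c) for c in node.children]
            entries.sort(key=lambda e: (-e[0], e[1]))
            survivor = entries[0]
            here = neuron.radial[nid]
            for v, _leaf, path in entries[1:]:
                bars.append((v, here))
                paths.append(tuple(path + [nid]))
            state[nid] = (survivor[0], survivor[1], survivor[2] + [nid])
    if neuron.root in state:
        # the global survivor dies at the soma (radial distance 0)
        v, _leaf, path = state.pop(neuron.root)
        bars.append((v, 0.0))
        paths.append(tuple(path))
    return PersistenceDiagram(np.array(bars).reshape(-1, 2), tuple(paths))


def sholl_tmd(neuron: Neuron) -> DiagramFunction:
    """r-varying TMD of the soma component restricted to a growing ball.

    Breakpoints are the sorted distinct normalized node radial
    distances; on each interval the diagram is the TMD of the
    restriction at the interval's left-endpoint radius, taken as the
    limit from the right (clip-point leaves carry start value exactly
    r, including zero-length grazing tips at nodes on the sphere).  At
    t = 1 the diagram equals the classical TMD of the whole neuron.
    """
    if neuron.span_R == 0:
        return DiagramFunction(
            np.array([0.0]),
            (PersistenceDiagram(np.empty((0, 2))),),
            0.0,
        )
    # restrict at the raw radii: renormalizing and scaling back can land a
    # hair below a node's own radius and flip the closed-ball tie
    radii = sorted({0.0} | {neuron.radial[nid] for nid in neuron.nodes})
    diagrams = tuple(
        tmd_classical(restrict_to_ball(neuron, r, keep_tangent_tips=True))
        for r in radii
    )
    bps = np.array([r / neuron.span_R for r in radii])
    return DiagramFunction(bps, diagrams, neuron.span_R)


# --------------------------------------------------------------------------
# registry
# --------------------------------------------------------------------------

#: Real-valued descriptors by canonical name.
REAL_DESCRIPTORS = {
    "branching": branching_pattern,
    "tortuosity": tortuosity,
    "flux": flux,
    "taper": taper_rate,
    "leaf_index": leaf_index,
    "energy": energy,
    "wiring": wiring,
}

#: All descriptor names accepted by :func:`compute_descriptor`.
ALL_DESCRIPTORS = tuple(REAL_DESCRIPTORS) + ("sholl_tmd",)


def compute_descriptor(neuron: Neuron, name: str, **params):
    """Compute a named descriptor (ShollFunction or DiagramFunction)."""
    if name == "sholl_tmd":
        return sholl_tmd(neuron)
    try:
        fn = REAL_DESCRIPTORS[name]
    except KeyError:
        raise ValueError(
            f"unknown descriptor {name!r}; choose from {ALL_DESCRIPTORS}"
        ) from None
    return fn(neuron, **params)
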