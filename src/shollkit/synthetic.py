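"""Synthetic neuron generation.

Labeled populations of rooted 3-D binary trees with controllable stem
count, branch-depth profile, tortuosity, polarity, and taper, written as
valid SWC, plus the small deterministic fixture trees used throughout
the test suite.  Coordinates are generated in micrometres at plausible
dendritic magnitudes (spans of tens to a few hundred micrometres);
domain normalization makes the absolute scale irrelevant to the
descriptors, but keeps taper and energy values well-conditioned.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .neuron import Neuron, NeuronModelError, build_neuron
from .swc import SwcRecord, write_swc

__all__ = [
    "ArchetypeParams",
    "GenerationError",
    "generate_neuron",
    "generate_population",
    "toy_fixtures",
]


class GenerationError(RuntimeError):
    """Synthetic growth failed after bounded retries."""


@dataclass(frozen=True)
class ArchetypeParams:
    """Growth parameters of a synthetic morphological class.

    Attributes
    ----------
    n_stems : stems (primary trees) leaving the soma.
    target_degree : leaves per stem; realized exactly by construction.
    segment_length : (mean, sd) of one growth step, micrometres.
    segments_per_branch : growth steps between structural nodes.
    branch_angle : half-angle (rad) between daughters at a bifurcation.
    tortuosity_factor : sd (rad) of the per-step direction jitter;
        0 gives perfectly straight branches.
    polarity : None for isotropic stems, or (axis, aperture) restricting
        stem directions to a cone of the given half-angle (rad).
    bipolar : alternate stems between the polarity axis and its
        opposite (two opposite cones).
    soma_radius : micrometres; node radii follow
        soma_radius * exp(-taper_decay * path distance).
    taper_decay : per-micrometre exponential taper rate.
    depth_profile : where bifurcations concentrate — 'burst-near-soma',
        'uniform', or 'distal-tuft'.
    seed : RNG seed; generation is deterministic given the params.
    """

    n_stems: int = 3
    target_degree: int = 8
    segment_length: tuple[float, float] = (7.0, 1.5)
    segments_per_branch: int = 8
    branch_angle: float = 0.5
    tortuosity_factor: float = 0.3
    polarity: tuple[tuple[float, float, float], float] | None = None
    bipolar: bool = False
    soma_radius: float = 5.0
    taper_decay: float = 0.004
    depth_profile: str = "uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_stems < 1:
            raise ValueError("n_stems must be >= 1")
        if self.target_degree < 1:
            raise ValueError("target_degree must be >= 1")
        if self.depth_profile not in ("burst-near-soma", "uniform", "distal-tuft"):
            raise ValueError(f"unknown depth_profile {self.depth_profile!r}")
        if self.bipolar and self.polarity is None:
            raise ValueError("bipolar growth needs a polarity axis")


def _rotate(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation of v around the unit axis."""
    c, s = np.cos(angle), np.sin(angle)
    return v * c + np.cross(axis, v) * s + axis * (axis @ v) * (1 - c)


def _perpendicular(v: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random unit vector perpendicular to v."""
    while True:
        w = rng.normal(size=3)
        w -= (w @ v) * v
        n = np.linalg.norm(w)
        if n > 1e-9:
            return w / n


def _cone_direction(
    axis: np.ndarray, aperture: float, rng: np.random.Generator
) -> np.ndarray:
    """Uniform direction within the cone of half-angle ``aperture``."""
    cos_t = rng.uniform(np.cos(aperture), 1.0)
    theta = np.arccos(np.clip(cos_t, -1.0, 1.0))
    perp = _perpendicular(axis, rng)
    return _rotate(axis, perp, theta)


def _stem_topology(
    degree: int, profile: str, rng: np.random.Generator
) -> list[tuple[int, int] | None]:
    """Random full binary tree with ``degree`` leaves.

    Nodes are indices into the returned list: ``None`` marks a leaf,
    otherwise (left, right) child indices.  The depth profile biases
    which leaf is split next: near-soma bursts split the shallowest
    leaf, distal tufts the deepest, uniform picks at random.
    """
    nodes: list[tuple[int, int] | None] = [None]
    depths = {0: 0}
    leaves = [0]
    for _ in range(degree - 1):
        if profile == "uniform":
            pick = int(rng.integers(len(leaves)))
        else:
            key = [depths[l] for l in leaves]
            extreme = min(key) if profile == "burst-near-soma" else max(key)
            candidates = [k for k, d in enumerate(key) if d == extreme]
            pick = candidates[int(rng.integers(len(candidates)))]
        node = leaves.pop(pick)
        li, ri = len(nodes), len(nodes) + 1
        nodes.extend([None, None])
        nodes[node] = (li, ri)
        depths[li] = depths[ri] = depths[node] + 1
        leaves.extend([li, ri])
    return nodes


def _grow(params: ArchetypeParams, rng: np.random.Generator) -> list[SwcRecord]:
    mean_len, sd_len = params.segment_length
    records = [SwcRecord(1, 1, 0.0, 0.0, 0.0, params.soma_radius, -1)]
    next_id = 2

    def step_length(factor: float = 1.0) -> float:
        return factor * max(float(rng.normal(mean_len, sd_len)), 0.1 * mean_len)

    def length_factor(is_leaf_branch: bool, depth: int) -> float:
        # depth profiles shape where branchpoints sit relative to the span:
        # near-soma bursts keep internal branches short and tips long;
        # distal tufts grow a long trunk before a short branching crown
        if params.depth_profile == "burst-near-soma":
            return 2.0 if is_leaf_branch else 0.4
        if params.depth_profile == "distal-tuft":
            return 2.5 if depth == 0 else 0.5
        return 1.0

    def node_radius(path: float) -> float:
        return max(params.soma_radius * np.exp(-params.taper_decay * path), 0.05)

    def grow_branch(
        topo: list, node: int, pos: np.ndarray, axis: np.ndarray,
        parent_id: int, path: float, depth: int = 0,
    ) -> None:
        # steps meander independently around the branch axis (ballistic
        # tropism): tortuosity scales every chord by the same expected
        # factor, leaving the normalized branching layout unchanged
        nonlocal next_id
        factor = length_factor(topo[node] is None, depth)
        for _ in range(params.segments_per_branch):
            d = axis
            if params.tortuosity_factor > 0:
                jitter = abs(float(rng.normal(0.0, params.tortuosity_factor)))
                d = _rotate(axis, _perpendicular(axis, rng), jitter)
            ln = step_length(factor)
            pos = pos + ln * d
            path += ln
            records.append(
                SwcRecord(next_id, 3, *map(float, pos), node_radius(path), parent_id)
            )
            parent_id = next_id
            next_id += 1
        if topo[node] is not None:
            li, ri = topo[node]
            azimuth = _perpendicular(axis, rng)
            grow_branch(topo, li, pos, _rotate(axis, azimuth, params.branch_angle),
                        parent_id, path, depth + 1)
            grow_branch(topo, ri, pos, _rotate(axis, azimuth, -params.branch_angle),
                        parent_id, path, depth + 1)

    for s in range(params.n_stems):
        if params.polarity is None:
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
        else:
            axis = np.asarray(params.polarity[0], dtype=float)
            axis /= np.linalg.norm(axis)
            if params.bipolar and s % 2 == 1:
                axis = -axis
            direction = _cone_direction(axis, params.polarity[1], rng)
        topo = _stem_topology(params.target_degree, params.depth_profile, rng)
        grow_branch(topo, 0, np.zeros(3), direction, 1, 0.0)
    return records


def generate_neuron(params: ArchetypeParams) -> Neuron:
    """Grow one synthetic neuron; deterministic given ``params.seed``.

    The realized degree equals ``n_stems * target_degree`` exactly (the
    stem topologies are planned before embedding).  Degenerate geometry
    triggers a retry on a fresh RNG substream, capped at 100 attempts.
    """
    ss = np.random.SeedSequence(params.seed)
    for attempt in range(100):
        rng = np.random.default_rng(ss.spawn(1)[0] if attempt else ss)
        try:
            return build_neuron(_grow(params, rng))
        except (NeuronModelError, ValueError):
            ss = np.random.SeedSequence([params.seed, attempt + 1])
            continue
    raise GenerationError(f"could not grow a valid neuron from {params}")


def generate_population(
    archetypes: dict[str, ArchetypeParams],
    n_per_class: int,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[dict[str, Neuron], dict[str, str]]:
    """Labeled synthetic population, optionally written as SWC + CSV.

    Per-neuron seeds derive deterministically from the master seed, so
    the same call produces byte-identical outputs.  When ``out_dir`` is
    given, one SWC file per neuron, a ``labels.csv`` (id,label) table,
    and a ``params.json`` record of the archetypes are written.

    Returns
    -------
    (neurons, labels) : dicts keyed by neuron id ``<label>_<index>``.
    """
    master = np.random.SeedSequence(seed)
    neurons: dict[str, Neuron] = {}
    labels: dict[str, str] = {}
    children = master.spawn(len(archetypes) * n_per_class)
    idx = 0
    for label, params in archetypes.items():
        for i in range(n_per_class):
            sub_seed = int(children[idx].generate_state(1)[0] % (2**31))
            idx += 1
            nid = f"{label}_{i:03d}"
            try:
                neurons[nid] = generate_neuron(replace(params, seed=sub_seed))
            except GenerationError as exc:
                raise GenerationError(f"class {label!r}, neuron {i}: {exc}") from exc
            labels[nid] = label
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for nid, neuron in neurons.items():
            (out / f"{nid}.swc").write_text(
                write_swc(neuron.to_records(), header=f"synthetic neuron {nid}")
            )
        pd.DataFrame(
            {"id": list(labels), "label": list(labels.values())}
        ).to_csv(out / "labels.csv", index=False)
        (out / "params.json").write_text(
            json.dumps(
                {label: asdict(p) for label, p in archetypes.items()},
                indent=2,
                default=list,
            )
        )
    return neurons, labels


# --------------------------------------------------------------------------
# deterministic toy fixtures
# --------------------------------------------------------------------------


def _neuron_from_rows(rows: list[tuple]) -> Neuron:
    return build_neuron([SwcRecord(*r) for r in rows])


def toy_fixtures() -> dict[str, Neuron]:
    """Small hand-constructed neurons with known closed-form descriptors.

    - ``t1``: Y-tree — soma at the origin, bifurcation A=(1,0,0), leaves
      B=(2,1,0) and C=(2,-1,0).  Span sqrt(5), longest path 1+sqrt(2),
      total wiring 1+2*sqrt(2).
    - ``s1``: the 8-node planar tree whose TMD path decomposition is
      {[5,4,2], [3,2,1], [8,6,1], [7,6]} under the radial ordering
      d(8) > d(3) > d(5) and d(8) > d(7).
    - ``zigzag``: a single 3-segment branch of path length 4 whose
      endpoints are distance 2 apart (tortuosity 2).
    - ``bipolar``: two opposite straight stems, each ending in a
      symmetric bifurcation (energy polarity ~ pi).
    """
    t1 = _neuron_from_rows([
        (1, 1, 0.0, 0.0, 0.0, 1.0, -1),
        (2, 3, 1.0, 0.0, 0.0, 0.5, 1),
        (3, 3, 2.0, 1.0, 0.0, 0.25, 2),
        (4, 3, 2.0, -1.0, 0.0, 0.25, 2),
    ])
    s1 = _neuron_from_rows([
        (1, 1, 0.0, 0.0, 0.0, 1.0, -1),
        (2, 3, 1.0, 0.0, 0.0, 0.5, 1),
        (3, 3, 2.0, 2.0, 0.0, 0.3, 2),
        (4, 3, 2.0, -1.0, 0.0, 0.3, 2),
        (5, 3, 2.5, -1.0, 0.0, 0.2, 4),
        (6, 3, -1.0, 0.0, 0.0, 0.5, 1),
        (7, 3, -2.0, 1.0, 0.0, 0.3, 6),
        (8, 3, -3.0, -1.0, 0.0, 0.3, 6),
    ])
    zigzag = _neuron_from_rows([
        (1, 1, 0.0, 0.0, 0.0, 1.0, -1),
        (2, 3, 0.5, float(np.sqrt(2.0)), 0.0, 0.5, 1),
        (3, 3, 1.5, float(np.sqrt(2.0)), 0.0, 0.4, 2),
        (4, 3, 2.0, 0.0, 0.0, 0.3, 3),
    ])
    bipolar = _neuron_from_rows([
        (1, 1, 0.0, 0.0, 0.0, 2.0, -1),
        (2, 3, 10.0, 0.0, 0.0, 1.0, 1),
        (3, 3, 20.0, 3.0, 0.0, 0.5, 2),
        (4, 3, 20.0, -3.0, 0.0, 0.5, 2),
        (5, 3, -10.0, 0.0, 0.0, 1.0, 1),
        (6, 3, -20.0, 3.0, 0.0, 0.5, 5),
        (7, 3, -20.0, -3.0, 0.0, 0.5, 5),
    ])
    return {"t1": t1, "s1": s1, "zigzag": zigzag, "bipolar": bipolar}
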