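"""Pseudo-metrics on neurons induced by Sholl descriptors.

Because descriptor functions are isometry invariant, the distance
between two neurons' descriptor functions is a *pseudo*-metric on
neuron sets: symmetric, satisfying the triangle inequality, but possibly
zero for distinct (e.g. isometric) neurons.

Real-valued descriptors are compared with exact Lp distances on the
merged breakpoint partition; diagram-valued ones with Wasserstein
distances between persistence diagrams, summed over the union of the
two functions' breakpoints for the Sholl-TMD.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .descriptors import (
    DiagramFunction,
    PersistenceDiagram,
    ShollFunction,
    compute_descriptor,
)
from .neuron import Neuron

__all__ = [
    "DistanceMatrix",
    "function_distance",
    "wasserstein",
    "sholl_tmd_distance",
    "distance_matrix",
]


def function_distance(
    f: ShollFunction, g: ShollFunction, p: float = 1.0
) -> float:
    """Lp distance between two step functions on [0, 1].

    Computed exactly on the merged breakpoint partition:
    (integral of |f - g|^p)^(1/p) for finite p >= 1, or the sup norm for
    p = inf.  Both functions must come from the same descriptor on the
    same domain kind.
    """
    if f.descriptor_name != g.descriptor_name or f.domain_kind != g.domain_kind:
        raise ValueError(
            f"descriptor mismatch: {f.descriptor_name}/{f.domain_kind} vs "
            f"{g.descriptor_name}/{g.domain_kind}"
        )
    if not (p >= 1.0):
        raise ValueError(f"order p must be >= 1, got {p}")
    grid = np.union1d(f.breakpoints, g.breakpoints)
    fv = np.array([f.value_at(t) for t in grid])
    gv = np.array([g.value_at(t) for t in grid])
    diff = np.abs(fv - gv)
    if math.isinf(p):
        return float(diff.max())
    widths = np.diff(np.append(grid, 1.0))
    return float((diff**p @ widths) ** (1.0 / p))


def _bar_distance(b1: np.ndarray, b2: np.ndarray, ground: str) -> float:
    d = np.abs(b1 - b2)
    return float(d.max()) if ground == "linf" else float(np.hypot(d[0], d[1]))


def _diag_cost(bar: np.ndarray, ground: str) -> float:
    pers = float(bar[0] - bar[1])
    return pers / 2.0 if ground == "linf" else pers / math.sqrt(2.0)


def wasserstein(
    d1: PersistenceDiagram,
    d2: PersistenceDiagram,
    p: float = 2.0,
    ground: str = "linf",
) -> float:
    """p-Wasserstein distance between persistence diagrams.

    Optimal partial matching: bars may match each other or project onto
    the diagonal.  The ground metric on the (start, end) plane is L-inf
    by default (diagonal cost |start - end| / 2) or L2 (``ground='l2'``).
    Solved exactly via the assignment algorithm on the standard
    diagonally-augmented cost matrix.
    """
    if not (p >= 1.0):
        raise ValueError(f"order p must be >= 1, got {p}")
    if ground not in ("linf", "l2"):
        raise ValueError(f"ground metric must be 'linf' or 'l2', got {ground!r}")
    n, m = len(d1), len(d2)
    if n == 0 and m == 0:
        return 0.0
    diag1 = np.array([_diag_cost(b, ground) ** p for b in d1.bars])
    diag2 = np.array([_diag_cost(b, ground) ** p for b in d2.bars])
    if n == 0:
        return float(diag2.sum() ** (1.0 / p))
    if m == 0:
        return float(diag1.sum() ** (1.0 / p))
    big = float(diag1.sum() + diag2.sum())
    for b1 in d1.bars:
        for b2 in d2.bars:
            big += _bar_distance(b1, b2, ground) ** p
    big += 1.0
    size = n + m
    cost = np.full((size, size), big)
    for i in range(n):
        for j in range(m):
            cost[i, j] = _bar_distance(d1.bars[i], d2.bars[j], ground) ** p
    for i in range(n):
        cost[i, m + i] = diag1[i]
    for j in range(m):
        cost[n + j, j] = diag2[j]
    cost[n:, m:] = 0.0
    rows, cols = linear_sum_assignment(cost)
    return float(cost[rows, cols].sum() ** (1.0 / p))


def sholl_tmd_distance(
    F1: DiagramFunction, F2: DiagramFunction, p: float = 2.0, *,
    ground: str = "linf", weighted: bool = False,
) -> float:
    """Distance between two Sholl-TMD diagram functions.

    Sum of p-Wasserstein distances between the diagrams evaluated (with
    right-continuity) at the union of both breakpoint sets.  With
    ``weighted=True`` each term is weighted by the length of its
    interval, turning the sum into an integral over [0, 1].

    Breakpoints closer than 1e-9 are merged (evaluating at the group
    maximum): rounding-level jitter of a breakpoint, e.g. from a rotated
    coordinate frame, must not spawn a spurious summand in which one
    function has switched diagrams and the other has not.
    """
    grid = np.union1d(F1.breakpoints, F2.breakpoints)
    if grid.size > 1:
        keep = np.append(np.diff(grid) > 1e-9, True)  # keep each group's max
        grid = grid[keep]
    terms = np.array(
        [wasserstein(F1.value_at(t), F2.value_at(t), p=p, ground=ground) for t in grid]
    )
    if weighted:
        widths = np.diff(np.append(grid, 1.0))
        return float(terms @ widths)
    return float(terms.sum())


@dataclass
class DistanceMatrix:
    """Symmetric pseudo-metric matrix over an ordered neuron set."""

    ids: tuple[str, ...]
    matrix: np.ndarray
    descriptor_name: str
    metric_params: dict = field(default_factory=dict)
    failures: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        self.matrix = m
        n = len(self.ids)
        if m.shape != (n, n):
            raise ValueError(f"matrix shape {m.shape} does not match {n} ids")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("distance matrix must have a zero diagonal")
        if np.any(m < 0):
            raise ValueError("distances must be nonnegative")

    def __len__(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.ids), columns=list(self.ids))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="id")

    @classmethod
    def from_csv(cls, path, descriptor_name: str = "unknown") -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return cls(tuple(df.index), df.to_numpy(dtype=float), descriptor_name)


def distance_matrix(
    neurons: Sequence[Neuron] | Mapping[str, Neuron],
    descriptor_name: str,
    p: float | None = None,
    ids: Sequence[str] | None = None,
    descriptor_params: dict | None = None,
    ground: str = "linf",
    weighted: bool = False,
) -> DistanceMatrix:
    """Pairwise descriptor pseudo-distance matrix over a neuron set.

    Each neuron's descriptor is computed once and cached.  Default order
    is p = 1 for real-valued descriptors and p = 2 (Wasserstein) for the
    Sholl-TMD.  Neurons whose descriptor computation fails are excluded
    from the matrix and reported in ``failures`` (with a warning), never
    silently dropped.
    """
    if isinstance(neurons, Mapping):
        items = [(str(k), v) for k, v in neurons.items()]
    else:
        if ids is None:
            ids = [f"n{i}" for i in range(len(neurons))]
        items = list(zip([str(i) for i in ids], neurons))
    if p is None:
        p = 2.0 if descriptor_name == "sholl_tmd" else 1.0
    params = descriptor_params or {}

    funcs: list[tuple[str, object]] = []
    failures: dict[str, str] = {}
    for nid, neuron in items:
        try:
            funcs.append((nid, compute_descriptor(neuron, descriptor_name, **params)))
        except Exception as exc:  # noqa: BLE001 - report, don't hide
            failures[nid] = f"{type(exc).__name__}: {exc}"
    if failures:
        warnings.warn(
            f"descriptor {descriptor_name!r} failed on {sorted(failures)}; "
            "excluded from the distance matrix",
            stacklevel=2,
        )

    if descriptor_name == "sholl_tmd":
        dist: Callable = lambda a, b: sholl_tmd_distance(
            a, b, p=p, ground=ground, weighted=weighted
        )
        metric_params = {"p": p, "ground": ground, "weighted": weighted}
    else:
        dist = lambda a, b: function_distance(a, b, p=p)
        metric_params = {"p": p}

    n = len(funcs)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = dist(funcs[i][1], funcs[j][1])
    return DistanceMatrix(
        ids=tuple(nid for nid, _ in funcs),
        matrix=mat,
        descriptor_name=descriptor_name,
        metric_params=metric_params,
        failures=failures,
    )
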