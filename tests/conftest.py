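"""Shared fixtures: toy trees, small random synthetic neurons, helpers."""

from __future__ import annotations

import itertools
import math
from dataclasses import replace

import numpy as np
import pytest

from shollkit import ArchetypeParams, generate_neuron, toy_fixtures
from shollkit.descriptors import DiagramFunction, ShollFunction


@pytest.fixture(scope="session")
def toys():
    return toy_fixtures()


def small_params(seed: int = 0, **kw) -> ArchetypeParams:
    """Small, fast-to-analyze archetype for property tests."""
    base = ArchetypeParams(
        n_stems=2,
        target_degree=4,
        segments_per_branch=3,
        segment_length=(15.0, 3.0),
        seed=seed,
    )
    return replace(base, **kw)


@pytest.fixture(scope="session")
def small_neurons():
    """20 small random synthetic neurons spanning the archetype knobs."""
    profiles = ("uniform", "burst-near-soma", "distal-tuft")
    out = []
    for i in range(20):
        out.append(
            generate_neuron(
                small_params(
                    seed=100 + i,
                    n_stems=1 + i % 3,
                    target_degree=3 + i % 4,
                    tortuosity_factor=(0.0, 0.2, 0.5)[i % 3],
                    depth_profile=profiles[i % 3],
                )
            )
        )
    return out


def random_orthogonal(rng: np.random.Generator, reflect: bool = False) -> np.ndarray:
    """Random 3x3 rotation (or reflection when requested)."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    if reflect:
        Q[:, 2] = -Q[:, 2]
    return Q


def assert_sholl_equal(f: ShollFunction, g: ShollFunction, tol: float = 1e-9):
    assert f.descriptor_name == g.descriptor_name
    assert f.domain_kind == g.domain_kind
    np.testing.assert_allclose(f.breakpoints, g.breakpoints, atol=tol, rtol=0)
    np.testing.assert_allclose(f.values, g.values, atol=tol, rtol=0)


def assert_diagram_multiset_equal(d1, d2, tol: float = 1e-9):
    """Diagrams are equal as bar multisets: an injective matching exists
    in which every matched pair agrees within ``tol`` (L-inf)."""
    from scipy.optimize import linear_sum_assignment

    assert len(d1) == len(d2)
    if len(d1) == 0:
        return
    cost = np.max(
        np.abs(d1.bars[:, None, :] - d2.bars[None, :, :]), axis=-1
    )
    rows, cols = linear_sum_assignment(cost)
    assert cost[rows, cols].max() <= tol


def assert_diagramfn_equal(F: DiagramFunction, G: DiagramFunction, tol: float = 1e-9):
    np.testing.assert_allclose(F.breakpoints, G.breakpoints, atol=tol, rtol=0)
    for d1, d2 in zip(F.diagrams, G.diagrams):
        assert_diagram_multiset_equal(d1, d2, tol)


def wasserstein_bruteforce(
    bars1: np.ndarray, bars2: np.ndarray, p: float, ground: str = "linf"
) -> float:
    """Exhaustive enumeration over all partial matchings with diagonal
    projections: the independent oracle for the assignment-based solver."""

    def bar_dist(a, b):
        d = np.abs(a - b)
        return float(d.max()) if ground == "linf" else float(np.hypot(*d))

    def diag(a):
        return (a[0] - a[1]) / 2.0 if ground == "linf" else (a[0] - a[1]) / math.sqrt(2)

    n, m = len(bars1), len(bars2)
    best = math.inf
    for k in range(min(n, m) + 1):
        for rows in itertools.combinations(range(n), k):
            for cols in itertools.permutations(range(m), k):
                cost = sum(
                    bar_dist(bars1[i], bars2[j]) ** p for i, j in zip(rows, cols)
                )
                cost += sum(diag(bars1[i]) ** p for i in range(n) if i not in rows)
                cost += sum(diag(bars2[j]) ** p for j in range(m) if j not in cols)
                best = min(best, cost)
    return best ** (1.0 / p)
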