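"""Closed-form and property checks for the eight Sholl descriptors."""

import numpy as np
import pytest

from shollkit import build_neuron
from shollkit.descriptors import (
    ShollFunction,
    branching_pattern,
    energy,
    energy_polarity,
    flux,
    flux_at,
    leaf_index,
    sholl_tmd,
    taper_rate,
    tmd_classical,
    tortuosity,
    wiring,
    wiring_at,
    compute_descriptor,
)
from shollkit.swc import SwcRecord
from shollkit.synthetic import generate_neuron

from .conftest import small_params

SQRT5 = np.sqrt(5.0)


def rows(*tuples):
    return [SwcRecord(*t) for t in tuples]


@pytest.fixture(scope="module")
def soma_only():
    return build_neuron(rows((1, 1, 0, 0, 0, 1, -1)))


class TestShollFunction:
    def test_right_continuous_evaluation(self):
        f = ShollFunction("x", "radial", 1.0, [0.0, 0.5], [1.0, 2.0])
        assert f.value_at(0.0) == 1.0
        assert f.value_at(0.499999) == 1.0
        assert f.value_at(0.5) == 2.0
        assert f.value_at(1.0) == 2.0

    @pytest.mark.parametrize(
        "bp, vals",
        [([0.1, 0.5], [1, 2]), ([0.0, 0.5, 0.4], [1, 2, 3]), ([0.0, 1.5], [1, 2])],
    )
    def test_invalid_breakpoints_rejected(self, bp, vals):
        with pytest.raises(ValueError):
            ShollFunction("x", "radial", 1.0, bp, vals)


class TestBranchingPattern:
    def test_t1_steps_default_sign(self, toys):
        f = branching_pattern(toys["t1"])
        np.testing.assert_allclose(f.breakpoints, [0.0, 1 / SQRT5, 1.0], atol=1e-12)
        np.testing.assert_allclose(f.values, [0.0, -1.0, 1.0])
        assert f.value_at(1.0) == 1.0  # number of primary branches

    def test_literal_sign_flips(self, toys):
        f = branching_pattern(toys["t1"], literal_sign=True)
        np.testing.assert_allclose(f.values, [0.0, 1.0, -1.0])

    def test_soma_only_constant_zero(self, soma_only):
        f = branching_pattern(soma_only)
        assert f.value_at(0.3) == 0.0 and f.value_at(1.0) == 0.0

    def test_value_at_one_counts_stems(self):
        # 3 stems, varying degrees: leaves - bifurcations = #stems
        n = generate_neuron(small_params(seed=7, n_stems=3, target_degree=5))
        assert branching_pattern(n).value_at(1.0) == 3.0

    def test_path_domain_uses_longest_path_normalizer(self, toys):
        f = branching_pattern(toys["t1"], domain_kind="path")
        assert f.domain_kind == "path"
        assert f.normalizer == pytest.approx(1 + np.sqrt(2))
        assert f.value_at(1.0) == 1.0


class TestTortuosity:
    def test_straight_branches_are_one(self, toys):
        f = tortuosity(toys["t1"])
        assert f.value_at(0.0) == 1.0 and f.value_at(1.0) == 1.0

    def test_zigzag_ratio_two_once_complete(self, toys):
        f = tortuosity(toys["zigzag"])
        assert f.value_at(0.5) == 1.0  # before the branch is fully inside
        assert f.value_at(1.0) == pytest.approx(2.0, abs=1e-12)

    def test_straight_synthetic_identically_one(self):
        n = generate_neuron(small_params(seed=3, tortuosity_factor=0.0))
        f = tortuosity(n)
        np.testing.assert_allclose(f.values, 1.0, atol=1e-9)


class TestFlux:
    def test_t1_radial_crossing_has_zero_angle(self, toys):
        assert flux_at(toys["t1"], 0.5) == pytest.approx(0.0, abs=1e-12)

    def test_t1_two_symmetric_crossings(self, toys):
        # hand geometry: |(1,0,0) + u(1,1,0)| = 1.5 -> 2u^2+2u-1.25 = 0
        u = (-2 + np.sqrt(4 + 10)) / 4
        x = np.array([1 + u, u, 0.0])
        cos_angle = (x @ np.array([1, 1, 0]) / np.sqrt(2)) / 1.5
        expected = 2 * np.arccos(cos_angle)
        assert flux_at(toys["t1"], 1.5) == pytest.approx(expected, abs=1e-9)

    def test_purely_radial_star_is_zero(self):
        star = build_neuron(rows(
            (1, 1, 0, 0, 0, 1, -1),
            (2, 3, 3, 0, 0, 1, 1),
            (3, 3, 0, 2, 0, 1, 1),
            (4, 3, 0, 0, -4, 1, 1),
        ))
        f = flux(star)
        np.testing.assert_allclose(f.values, 0.0, atol=1e-12)

    def test_grid_size_configurable(self, toys):
        assert len(flux(toys["t1"], n_grid=17).breakpoints) == 17


class TestTaperRate:
    def test_two_bifurcation_staircase(self):
        # bifurcations at path 1 (radius 1.0) and path 2 (radius 0.5), L = 3
        n = build_neuron(rows(
            (1, 1, 0, 0, 0, 1.5, -1),
            (2, 3, 1, 0, 0, 1.0, 1),
            (3, 3, 1, 1, 0, 0.4, 2),
            (4, 3, 1, 0, 1, 0.5, 2),
            (5, 3, 1, 0.6, 1.8, 0.3, 4),
            (6, 3, 1, -0.6, 1.8, 0.3, 4),
        ))
        assert n.longest_path_L == pytest.approx(3.0)
        f = taper_rate(n)
        assert f.domain_kind == "path"
        assert f.value_at(0.2) == pytest.approx(3.0)  # soma diameter
        assert f.value_at(0.5) == pytest.approx(2.0)  # first bifurcation
        assert f.value_at(1.0) == pytest.approx(1.0)  # second bifurcation

    def test_unbranched_is_soma_diameter(self):
        n = build_neuron(rows((1, 1, 0, 0, 0, 2.0, -1), (2, 3, 5, 0, 0, 1.0, 1)))
        f = taper_rate(n)
        assert f.value_at(0.0) == f.value_at(1.0) == 4.0

    def test_all_zero_radii_warns_constant_zero(self):
        n = build_neuron(rows(
            (1, 1, 0, 0, 0, 0, -1),
            (2, 3, 1, 0, 0, 0, 1),
            (3, 3, 2, 1, 0, 0, 2),
            (4, 3, 2, -1, 0, 0, 2),
        ))
        with pytest.warns(UserWarning, match="zero"):
            f = taper_rate(n)
        assert f.value_at(0.5) == 0.0

    def test_monotone_taper_gives_nonincreasing_function(self):
        n = generate_neuron(small_params(seed=11, taper_decay=0.02))
        f = taper_rate(n)
        assert np.all(np.diff(f.values) <= 1e-12)


class TestLeafIndex:
    def test_t1_constant_two(self, toys):
        f = leaf_index(toys["t1"])
        assert f.value_at(0.0) == 2.0 and f.value_at(1.0) == 2.0

    def test_unbranched_dendrite_constant_one(self):
        n = build_neuron(rows((1, 1, 0, 0, 0, 1, -1), (2, 3, 5, 0, 0, 1, 1)))
        f = leaf_index(n)
        assert f.value_at(0.0) == 1.0 and f.value_at(1.0) == 1.0

    def test_caterpillar_staircase_nonincreasing(self):
        # spine along +x; each bifurcation sheds one leaf: sees k, k-1, ..., 2
        recs = [(1, 1, 0.0, 0.0, 0.0, 1.0, -1)]
        nid = 2
        parent = 1
        for i in range(4):
            recs.append((nid, 3, float(i + 1), 0.0, 0.0, 0.5, parent))  # spine node
            recs.append((nid + 1, 3, float(i + 1), 1.0, 0.0, 0.5, nid))  # side leaf
            parent = nid
            nid += 2
        recs.append((nid, 3, 5.0, 0.0, 0.0, 0.5, parent))  # terminal spine tip
        n = build_neuron(rows(*recs))
        f = leaf_index(n)
        assert f.value_at(0.0) == 5.0  # degree
        assert np.all(np.diff(f.values) <= 0)
        assert f.value_at(1.0) == 2.0


class TestEnergy:
    def test_t1_closed_form(self, toys):
        f = energy(toys["t1"])
        assert f.value_at(1.0) == pytest.approx(1 + 4 / (5 * SQRT5), abs=1e-12)
        # before any charge node: 0; after A only: 1
        assert f.value_at(0.0) == 0.0
        assert f.value_at(0.6) == pytest.approx(1.0)

    def test_symmetric_pair_cancels(self):
        n = build_neuron(rows(
            (1, 1, 0, 0, 0, 1, -1),
            (2, 3, 2, 0, 0, 1, 1),
            (3, 3, -2, 0, 0, 1, 1),
        ))
        assert energy(n).value_at(1.0) == pytest.approx(0.0, abs=1e-15)

    def test_inverse_square_scaling_law(self):
        n = generate_neuron(small_params(seed=2))
        s = 3.0
        scaled = n.with_positions(
            {nid: s * v.position for nid, v in n.nodes.items()}
        )
        f, g = energy(n), energy(scaled)
        np.testing.assert_allclose(g.values, f.values / s**2, rtol=1e-9)
        np.testing.assert_allclose(g.breakpoints, f.breakpoints, atol=1e-12)


class TestEnergyPolarity:
    def test_bipolar_fixture_recovers_cones(self, toys):
        res = energy_polarity(toys["bipolar"])
        xs = {nid: toys["bipolar"].nodes[nid].position[0] for nid in res.node_ids}
        side = np.array([1 if xs[nid] > 0 else 2 for nid in res.node_ids])
        same = (res.cluster_labels == side).all() or (
            res.cluster_labels == (3 - side)
        ).all()
        assert same
        assert res.polarity == pytest.approx(np.pi, abs=1e-6)

    def test_single_octant_low_polarity(self):
        n = build_neuron(rows(
            (1, 1, 0, 0, 0, 1, -1),
            (2, 3, 5, 1, 1, 1, 1),
            (3, 3, 6, 3, 1, 1, 2),
            (4, 3, 6, 1, 3, 1, 2),
        ))
        assert energy_polarity(n).polarity < np.pi / 2

    def test_duplicate_direction_zero_angles(self):
        # all charge nodes (one bifurcation, two leaves) lie along +x
        n = build_neuron(rows(
            (1, 1, 0, 0, 0, 1, -1),
            (2, 3, 1, 0, 0, 1, 1),
            (3, 3, 2, 0, 0, 1, 2),
            (4, 3, 3, 0, 0, 1, 2),
        ))
        res = energy_polarity(n)
        np.testing.assert_allclose(res.angle_matrix, 0.0, atol=1e-9)

    def test_too_few_nodes_signaled(self, soma_only):
        with pytest.raises(ValueError):
            energy_polarity(soma_only)


class TestWiring:
    def test_t1_values(self, toys):
        f = wiring(toys["t1"])
        assert f.value_at(0.0) == 0.0
        assert f.value_at(1 / SQRT5) == pytest.approx(1.0, abs=1e-12)
        assert f.value_at(1.0) == pytest.approx(1 + 2 * np.sqrt(2), abs=1e-12)

    def test_halfway_clip_length(self, toys):
        # at r=1.5 each child segment keeps u1 * sqrt(2) of its length
        u = (-2 + np.sqrt(14)) / 4
        assert wiring_at(toys["t1"], 1.5) == pytest.approx(1 + 2 * u * np.sqrt(2))

    @pytest.mark.parametrize("seed", range(3))
    def test_monotone_nondecreasing(self, seed):
        f = wiring(generate_neuron(small_params(seed=seed)))
        assert np.all(np.diff(f.values) >= -1e-9)


class TestTMD:
    def test_s1_path_decomposition(self, toys):
        d = tmd_classical(toys["s1"])
        got = {tuple(p) for p in d.paths}
        assert got == {(5, 4, 2), (3, 2, 1), (8, 6, 1), (7, 6)}

    def test_s1_bar_values(self, toys):
        s1 = toys["s1"]
        d = tmd_classical(s1)
        expected = {
            (round(s1.radial[5], 9), round(s1.radial[2], 9)),
            (round(s1.radial[3], 9), 0.0),
            (round(s1.radial[8], 9), 0.0),
            (round(s1.radial[7], 9), round(s1.radial[6], 9)),
        }
        got = {(round(b[0], 9), round(b[1], 9)) for b in d.bars}
        assert got == expected

    def test_t1_bars(self, toys):
        d = tmd_classical(toys["t1"])
        np.testing.assert_allclose(
            d.sorted_bars(), [[SQRT5, 0.0], [SQRT5, 1.0]], atol=1e-12
        )

    def test_single_dendrite(self):
        n = build_neuron(rows((1, 1, 0, 0, 0, 1, -1), (2, 3, 0, 0, 7, 1, 1)))
        np.testing.assert_allclose(tmd_classical(n).bars, [[7.0, 0.0]])

    def test_one_bar_per_leaf(self):
        n = generate_neuron(small_params(seed=9))
        assert len(tmd_classical(n)) == n.degree


class TestShollTMD:
    def test_t1_interval_structure(self, toys):
        F = sholl_tmd(toys["t1"])
        np.testing.assert_allclose(F.breakpoints, [0.0, 1 / SQRT5, 1.0], atol=1e-12)
        # interval [1/sqrt5, 1): limit from the right at r=1 -> two clipped tips
        mid = F.value_at(0.6)
        np.testing.assert_allclose(mid.sorted_bars(), [[1.0, 0.0], [1.0, 1.0]])
        np.testing.assert_allclose(
            F.value_at(1.0).sorted_bars(), [[SQRT5, 0.0], [SQRT5, 1.0]], atol=1e-12
        )

    def test_soma_only_all_empty(self, soma_only):
        F = sholl_tmd(soma_only)
        assert all(len(d) == 0 for d in F.diagrams)

    @pytest.mark.parametrize("seed", range(5))
    def test_final_diagram_equals_classical(self, seed):
        n = generate_neuron(small_params(seed=seed))
        F = sholl_tmd(n)
        np.testing.assert_allclose(
            F.value_at(1.0).sorted_bars(),
            tmd_classical(n).sorted_bars(),
            atol=1e-9,
        )


def test_compute_descriptor_rejects_unknown(toys):
    with pytest.raises(ValueError, match="unknown descriptor"):
        compute_descriptor(toys["t1"], "nope")
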