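import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from connexel.bundling import (BundlePolyline, BundlingParams,
                               compatibility_matrix, edge_compatibility,
                               bundle, mean_shift_iteration,
                               resample_polyline, segments_for_cycle)
from connexel.model import Connexel, ConnexelSet
from connexel.synthetic import FixtureSpec, make_parallel_bundles


def naive_mean_shift(lines, compat, c_thr, r):
    """Loop-based all-pairs (infinite support) mean-shift oracle."""
    e = len(lines)
    out = [ln.points.copy() for ln in lines]
    for a in range(e):
        for k in range(1, lines[a].n_points - 1):
            x = lines[a].points[k]
            num = np.zeros(3)
            den = 0.0
            for b in range(e):
                if compat[a, b] < c_thr:
                    continue
                for j in range(1, lines[b].n_points - 1):
                    y = lines[b].points[j]
                    w = math.exp(-float((x - y) @ (x - y)) / (2 * r * r))
                    num += w * y
                    den += w
            if den > 0:
                out[a][k] = num / den
    return out


def edge(p, q, v=1.0):
    return Connexel(np.array(p, float), np.array(q, float), v)


class TestEdgeCompatibility:
    def test_identical_edges_fully_compatible(self):
        P = edge((3, 1, -2), (7, 5, 0))
        assert edge_compatibility(P, P) == (1.0, 1.0, 1.0, 1.0, 1.0)

    def test_perpendicular_edges_zero(self):
        P = edge((0, 0, 0), (2, 0, 0))
        Q = edge((0, 0, 0), (0, 2, 0))
        comps = edge_compatibility(P, Q)
        assert comps[0] == 0.0 and comps[4] == 0.0

    def test_parallel_offset_hand_case(self):
        P = edge((0, 0, 0), (2, 0, 0))
        Q = edge((0, 1, 0), (2, 1, 0))
        ca, cs, cp, cv, ce = edge_compatibility(P, Q)
        assert ca == pytest.approx(1.0, abs=1e-9)
        assert cs == pytest.approx(1.0, abs=1e-9)
        assert cp == pytest.approx(2 / 3, abs=1e-9)
        assert cv == pytest.approx(1.0, abs=1e-9)
        assert ce == pytest.approx(2 / 3, abs=1e-9)

    def test_collinear_length_ratio_hand_case(self):
        P = edge((0, 0, 0), (1, 0, 0))
        Q = edge((0, 0, 0), (3, 0, 0))
        cs = edge_compatibility(P, Q)[1]
        assert cs == pytest.approx(4 / 7, abs=1e-9)

    def test_zero_length_edge_is_incompatible(self):
        P = edge((0, 0, 0), (0, 0, 0))
        Q = edge((0, 0, 0), (1, 0, 0))
        assert edge_compatibility(P, Q) == (0.0, 0.0, 0.0, 0.0, 0.0)

    def test_antiparallel_direction_irrelevant(self):
        P = edge((0, 0, 0), (2, 0, 0))
        Q = edge((2, 1, 0), (0, 1, 0))  # reversed direction
        assert edge_compatibility(P, Q)[0] == pytest.approx(1.0)

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 10_000))
    def test_bounds_and_symmetry_random_pairs(self, seed):
        rng = np.random.default_rng(seed)
        P = edge(rng.uniform(-50, 50, 3), rng.uniform(-50, 50, 3))
        Q = edge(rng.uniform(-50, 50, 3), rng.uniform(-50, 50, 3))
        c_pq = edge_compatibility(P, Q)
        c_qp = edge_compatibility(Q, P)
        for a, b in zip(c_pq, c_qp):
            assert 0.0 <= a <= 1.0
            assert a == pytest.approx(b, abs=1e-12)

    def test_rigid_motion_and_scale_invariance(self):
        from scipy.spatial.transform import Rotation
        rng = np.random.default_rng(5)
        P = edge(rng.uniform(-10, 10, 3), rng.uniform(-10, 10, 3))
        Q = edge(rng.uniform(-10, 10, 3), rng.uniform(-10, 10, 3))
        base = edge_compatibility(P, Q)
        rot = Rotation.from_euler("xyz", [31, -54, 12], degrees=True)
        t = np.array([5.0, -3.0, 8.0])
        for s in (1.0, 2.5):
            P2 = edge(rot.apply(s * P.p) + t, rot.apply(s * P.q) + t)
            Q2 = edge(rot.apply(s * Q.p) + t, rot.apply(s * Q.q) + t)
            np.testing.assert_allclose(edge_compatibility(P2, Q2), base,
                                       atol=1e-9)


class TestCompatibilityMatrix:
    def test_single_edge(self):
        cset = ConnexelSet([[0, 0, 0]], [[1, 0, 0]], [1.0])
        cm = compatibility_matrix(cset)
        assert cm.values.shape == (1, 1)
        assert cm.values[0, 0] == 1.0

    def test_matches_pairwise_oracle(self, random_connexels):
        cm = compatibility_matrix(random_connexels).values
        n = len(random_connexels)
        for a in range(n):
            for b in range(n):
                expected = (1.0 if a == b else
                            edge_compatibility(random_connexels[a],
                                               random_connexels[b])[4])
                assert cm[a, b] == pytest.approx(expected, abs=1e-9)

    def test_symmetric_and_bounded(self, random_connexels):
        cm = compatibility_matrix(random_connexels).values
        np.testing.assert_array_equal(cm, cm.T)
        assert cm.min() >= 0.0 and cm.max() <= 1.0


class TestResample:
    def line(self, pts):
        pts = np.asarray(pts, float)
        return BundlePolyline(pts, Connexel(pts[0], pts[-1], 1.0))

    def test_straight_midpoint(self):
        ln = self.line([[0, 0, 0], [2, 0, 0]])
        out = resample_polyline(ln, 2)
        np.testing.assert_allclose(out.points,
                                   [[0, 0, 0], [1, 0, 0], [2, 0, 0]])

    def test_single_segment_keeps_endpoints_only(self):
        ln = self.line([[0, 0, 0], [1, 1, 0], [2, 0, 0]])
        out = resample_polyline(ln, 1)
        assert out.n_points == 2
        np.testing.assert_array_equal(out.points[[0, -1]],
                                      ln.points[[0, -1]])

    def test_curved_arc_length_spacing(self):
        t = np.linspace(0, np.pi, 30)
        pts = np.stack([np.cos(t), np.sin(t), np.zeros_like(t)], axis=1)
        out = resample_polyline(self.line(pts), 7)
        np.testing.assert_array_equal(out.points[0], pts[0])
        np.testing.assert_array_equal(out.points[-1], pts[-1])
        seg = np.linalg.norm(np.diff(out.points, axis=0), axis=1)
        # equal arc-length spacing up to chord discretization
        assert seg.std() / seg.mean() < 0.02
        # cumulative-arc-length oracle: parameters strictly increase
        arcs = np.concatenate([[0], np.cumsum(
            np.linalg.norm(np.diff(pts, axis=0), axis=1))])
        for p in out.points[1:-1]:
            d = np.linalg.norm(pts - p, axis=1)
            assert d.min() < 0.05  # stays on the original curve

    def test_straight_line_length_preserved(self):
        ln = self.line([[0, 0, 0], [3, 4, 0]])
        out = resample_polyline(ln, 13)
        seg = np.linalg.norm(np.diff(out.points, axis=0), axis=1)
        assert seg.sum() == pytest.approx(5.0, abs=1e-9)


def straight_lines(cset, n_segments):
    lines = [BundlePolyline(np.stack([cset.p[i], cset.q[i]]), cset[i])
             for i in range(len(cset))]
    return [resample_polyline(ln, n_segments) for ln in lines]


class TestMeanShift:
    def test_single_interior_point_edge_is_fixed(self):
        cset = ConnexelSet([[0, 0, 0]], [[10, 0, 0]], [1.0])
        lines = straight_lines(cset, 2)
        out = mean_shift_iteration(lines, compatibility_matrix(cset),
                                   BundlingParams())
        np.testing.assert_array_equal(out[0].points, lines[0].points)

    def test_single_edge_stays_on_its_segment(self):
        cset = ConnexelSet([[0, 0, 0]], [[10, 0, 0]], [1.0])
        lines = straight_lines(cset, 6)
        out = mean_shift_iteration(lines, compatibility_matrix(cset),
                                   BundlingParams())
        # interior points may slide along the segment but not leave it
        np.testing.assert_allclose(out[0].points[:, 1:], 0.0, atol=1e-12)
        assert np.all(out[0].points[:, 0] >= 0)
        assert np.all(out[0].points[:, 0] <= 10)

    def test_mirror_symmetric_edges_displace_symmetrically(self):
        cset = ConnexelSet([[0, 1, 0], [0, -1, 0]],
                           [[10, 1, 0], [10, -1, 0]], [1.0, 1.0])
        lines = straight_lines(cset, 4)
        out = mean_shift_iteration(lines, compatibility_matrix(cset),
                                   BundlingParams())
        mirrored = out[1].points * np.array([1, -1, 1])
        np.testing.assert_allclose(out[0].points, mirrored, atol=1e-12)

    def test_parallel_edges_contract_monotonically(self):
        offsets = np.linspace(-1.5, 1.5, 10)
        cset = ConnexelSet([[0, y, 0] for y in offsets],
                           [[20, y, 0] for y in offsets], np.ones(10))
        lines = straight_lines(cset, 6)
        compat = compatibility_matrix(cset)
        params = BundlingParams()
        spread = None
        for _ in range(5):
            lines = mean_shift_iteration(lines, compat, params)
            ys = np.concatenate([ln.points[1:-1, 1] for ln in lines])
            s = ys.std()
            if spread is not None:
                assert s < spread
            spread = s
        assert spread < 0.05  # near-collapse to the common mean plane

    def test_cutoff_equals_naive_reference(self):
        rng = np.random.default_rng(0)
        spec = FixtureSpec(seed=3, bundle_counts=(8, 12),
                           bundle_separation=25.0)
        cset = make_parallel_bundles(spec)
        lines = straight_lines(cset, 5)
        compat = compatibility_matrix(cset)
        # perturb interior points so the test is not trivially symmetric
        for ln in lines:
            ln.points[1:-1] += rng.normal(0, 0.3, ln.points[1:-1].shape)
        diameter = 200.0  # >> domain extent
        params = BundlingParams(neighborhood_cutoff=diameter / 5.0)
        out = mean_shift_iteration(lines, compat, params)
        ref = naive_mean_shift(lines, compat.values, params.c_thr,
                               params.kernel_radius)
        for a in range(len(lines)):
            np.testing.assert_allclose(out[a].points, ref[a], atol=1e-6)

    def test_infinite_support_mode_matches_naive(self):
        cset = ConnexelSet([[0, y, 0] for y in (0.0, 1.0, 2.0)],
                           [[15, y, 0] for y in (0.0, 1.0, 2.0)],
                           np.ones(3))
        lines = straight_lines(cset, 4)
        compat = compatibility_matrix(cset)
        params = BundlingParams(neighborhood_cutoff=None)
        out = mean_shift_iteration(lines, compat, params)
        ref = naive_mean_shift(lines, compat.values, params.c_thr,
                               params.kernel_radius)
        for a in range(len(lines)):
            np.testing.assert_allclose(out[a].points, ref[a], atol=1e-9)


class TestBundle:
    def test_default_parameters(self):
        p = BundlingParams()
        assert p.c_thr == 0.8
        assert p.kernel_radius == 5.0
        assert p.n_cycles == 10

    def test_segment_schedule(self):
        assert [segments_for_cycle(c) for c in range(1, 11)] == \
            [2, 2, 3, 3, 4, 5, 7, 9, 11, 14]

    def test_endpoints_fixed_exactly(self):
        spec = FixtureSpec(seed=1, bundle_counts=(6,))
        cset = make_parallel_bundles(spec)
        lines = bundle(cset, BundlingParams())
        for i, ln in enumerate(lines):
            np.testing.assert_array_equal(ln.points[0], cset.p[i])
            np.testing.assert_array_equal(ln.points[-1], cset.q[i])

    def test_empty_input(self):
        assert bundle(ConnexelSet.empty()) == []

    def test_single_edge_remains_straight(self):
        cset = ConnexelSet([[0, 0, 0]], [[30, 0, 0]], [1.0])
        lines = bundle(cset, BundlingParams())
        np.testing.assert_allclose(lines[0].points[:, 1:], 0.0, atol=1e-9)
        xs = lines[0].points[:, 0]
        assert np.all(np.diff(xs) > 0)

    def test_rigid_motion_equivariance(self):
        from scipy.spatial.transform import Rotation
        spec = FixtureSpec(seed=2, bundle_counts=(7,))
        cset = make_parallel_bundles(spec)
        rot = Rotation.from_euler("zyx", [20, 65, -40], degrees=True)
        t = np.array([12.0, -7.0, 30.0])
        moved = ConnexelSet(rot.apply(cset.p) + t, rot.apply(cset.q) + t,
                            cset.values)
        params = BundlingParams()
        direct = bundle(moved, params)
        then_moved = [rot.apply(ln.points) + t for ln in bundle(cset, params)]
        for a in range(len(cset)):
            np.testing.assert_allclose(direct[a].points, then_moved[a],
                                       atol=1e-6)

    def test_two_density_bundles_contract_equally(self):
        spec = FixtureSpec(seed=0)  # (10, 100) edges
        cset = make_parallel_bundles(spec)
        labels = cset.bundle_labels
        lines = bundle(cset, BundlingParams())
        mid_init = (cset.p + cset.q) / 2
        mid_final = np.array([ln.points[ln.n_points // 2] for ln in lines])
        for b in range(2):
            sel = labels == b
            s0 = np.linalg.norm(
                mid_init[sel] - mid_init[sel].mean(0), axis=1).mean()
            s1 = np.linalg.norm(
                mid_final[sel] - mid_final[sel].mean(0), axis=1).mean()
            assert s1 < 0.5 * s0

    def test_large_input_warns(self):
        from connexel.bundling import CompatibilityMatrix
        rng = np.random.default_rng(9)
        n = 41_000
        cset = ConnexelSet(rng.uniform(0, 1, (n, 3)),
                           rng.uniform(0, 1, (n, 3)), np.ones(n))
        # a single cycle runs no mean-shift iterations, so a dummy
        # compatibility matrix keeps this memory-bound check cheap
        with pytest.warns(UserWarning, match="40000|40,000"):
            bundle(cset, BundlingParams(n_cycles=1),
                   compat=CompatibilityMatrix(np.eye(1)))
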