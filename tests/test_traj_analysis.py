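"""Trajectory analysis: event times, parities, route classification."""

import numpy as np
import pytest

from knotfold.gomodel import Trajectory, build_topology_from_ca
from knotfold.traj_analysis import (
    FoldingEvents,
    KnotTimeSeries,
    _smooth_labels,
    classify_route,
    contact_formation_order,
    folding_time,
    knot_timeseries,
    loop_event_times,
    piercing_parity,
)


# ---------------------------------------------------------------------------
# independent brute-force parity oracle (plane/parametric formulation,
# distinct from the Möller–Trumbore code under test)
# ---------------------------------------------------------------------------

def brute_parity(loop, chain):
    centroid = loop.mean(axis=0)
    count = 0
    m = len(loop)
    for k in range(len(chain) - 1):
        p, q = chain[k], chain[k + 1]
        for i in range(m):
            a, b, c = centroid, loop[i], loop[(i + 1) % m]
            n = np.cross(b - a, c - a)
            nn = np.linalg.norm(n)
            if nn < 1e-12:
                continue
            d = q - p
            denom = n @ d
            if abs(denom) < 1e-12:
                continue
            t = -(n @ (p - a)) / denom
            if not (1e-9 < t < 1 - 1e-9):
                continue
            x = p + t * d
            # barycentric sign test in the triangle plane
            s1 = np.cross(b - a, x - a) @ n
            s2 = np.cross(c - b, x - b) @ n
            s3 = np.cross(a - c, x - c) @ n
            tol = -1e-9 * nn * nn
            if s1 >= tol and s2 >= tol and s3 >= tol:
                count += 1
    return count % 2


def wavy_ring(rng, n=10, radius=5.0):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    r = radius * (1 + rng.uniform(-0.2, 0.2, n))
    z = rng.uniform(-1.0, 1.0, n)
    return np.stack([r * np.cos(t), r * np.sin(t), z], axis=1)


def test_parity_matches_brute_force_on_random_configurations(rng):
    mismatches = 0
    n_cases = 1000
    for _ in range(n_cases):
        loop = wavy_ring(rng)
        start = rng.uniform(-10, 10, 3)
        step = rng.normal(scale=4.0, size=(4, 3))
        chain = start + np.cumsum(step, axis=0)
        got = piercing_parity(loop, chain)
        if got is None:
            continue
        assert got == brute_parity(loop, chain)
    assert mismatches == 0


# ---------------------------------------------------------------------------
# fabricated trajectories
# ---------------------------------------------------------------------------

def make_traj(frames, q=None):
    frames = np.asarray(frames, float)
    n = frames.shape[1]
    coords = frames[0]
    top = build_topology_from_ca(coords, contact_cutoff=0.0)
    top.contacts = np.array([[0, n - 1]])
    top.contact_sigma = np.array([1.0])
    if q is None:
        q = np.zeros(len(frames))
    return Trajectory(frames=frames, times=np.arange(len(frames)),
                      q=np.asarray(q, float), topology=top)


def ring_and_strand_frames(n_frames=16, cross_at=8):
    """Static 10-gon ring in the xy-plane; a straight 5-bead strand descends
    along the axis, its tip passing the ring plane between frames
    cross_at-1 and cross_at, then holding (threaded) as a real terminus
    does once the chain behind it is folded."""
    t = np.linspace(0, 2 * np.pi, 10, endpoint=False)
    ring = np.stack([5 * np.cos(t), 5 * np.sin(t), np.zeros(10)], axis=1)
    side = np.stack([np.full(3, 12.0), 12 + 2 * np.arange(3), np.zeros(3)], axis=1)
    frames = []
    for k in range(n_frames):
        tip_z = max((cross_at - k) * 2.0 - 0.9, -4.9)
        strand = np.stack([np.full(5, 0.01),
                           0.02 * np.arange(5),
                           tip_z + 3.0 * np.arange(5)], axis=1)
        frames.append(np.vstack([ring, side, strand]))
    return np.array(frames)


class TestLoopEvents:
    def test_strand_through_static_ring_sets_tc(self):
        frames = ring_and_strand_frames()
        traj = make_traj(frames)
        t_b, t_c = loop_event_times(traj, s_loop=(0, 10), b_loop=(10, 13),
                                    c_term=(13, 18))
        assert t_c == 8
        assert t_b is None  # side strand never moves, parity never changes

    def test_no_approach_gives_no_events(self):
        frames = ring_and_strand_frames()
        static = np.repeat(frames[:1], 8, axis=0)
        traj = make_traj(static)
        t_b, t_c = loop_event_times(traj, s_loop=(0, 10), b_loop=(10, 13),
                                    c_term=(13, 18))
        assert (t_b, t_c) == (None, None)

    def test_native_threaded_state_has_event_at_first_frame(self):
        frames = ring_and_strand_frames()
        threaded = np.repeat(frames[-1:], 8, axis=0)
        traj = make_traj(threaded)
        _, t_c = loop_event_times(traj, s_loop=(0, 10), b_loop=(10, 13),
                                  c_term=(13, 18))
        assert t_c == 0


class TestFoldingTime:
    def test_monotone_q_crossing(self):
        q = np.linspace(0.0, 1.0, 21)  # crosses 0.9 at frame 18
        traj = make_traj(np.zeros((21, 5, 3)) + np.arange(5)[None, :, None] * 4,
                         q=q)
        assert folding_time(traj) == 18

    def test_never_folding(self):
        q = np.full(30, 0.45)
        traj = make_traj(np.zeros((30, 5, 3)) + np.arange(5)[None, :, None] * 4,
                         q=q)
        assert folding_time(traj) is None

    def test_native_start_folds_at_first_frame(self):
        q = np.ones(10)
        traj = make_traj(np.zeros((10, 5, 3)) + np.arange(5)[None, :, None] * 4,
                         q=q)
        assert folding_time(traj) == 0

    def test_transient_spike_rejected_by_persistence(self):
        q = np.full(20, 0.3)
        q[5] = 0.95  # single-frame artifact
        q[12:] = 0.95
        traj = make_traj(np.zeros((20, 5, 3)) + np.arange(5)[None, :, None] * 4,
                         q=q)
        assert folding_time(traj) == 12


class TestSmoothing:
    def test_single_frame_flicker_suppressed(self):
        raw = ["0_1"] * 8 + ["3_1"] + ["0_1"] * 8
        assert _smooth_labels(raw, 5) == ["0_1"] * 17

    def test_persistent_change_kept(self):
        raw = ["0_1"] * 6 + ["6_1"] * 6
        smoothed = _smooth_labels(raw, 5)
        assert smoothed[-1] == "6_1"
        assert smoothed[0] == "0_1"


class TestKnotTimeseries:
    def test_static_unknotted_curve_all_trivial(self):
        coords = np.zeros((12, 3))
        coords[:, 0] = 3.8 * np.arange(12)
        coords[:, 1] = 0.2 * np.sin(np.arange(12))
        frames = np.repeat(coords[None], 9, axis=0)
        traj = make_traj(frames)
        ts = knot_timeseries(traj, every=1, seed=3)
        assert set(ts.labels) == {"0_1"}

    def test_static_knotted_curve_all_trefoil(self, trefoil_curve):
        from knotfold.synthetic import open_curve_at_max_radius

        pts = open_curve_at_max_radius(trefoil_curve)
        frames = np.repeat(pts[None], 7, axis=0)
        traj = make_traj(frames)
        ts = knot_timeseries(traj, every=1, seed=3)
        assert set(ts.labels) == {"3_1"}


def series(labels):
    return KnotTimeSeries(times=np.arange(len(labels)), labels=list(labels),
                          raw_labels=list(labels))


class TestRouteClassification:
    def test_direct_route_i(self):
        ts = series(["0_1"] * 10 + ["6_1"] * 10)
        ev = FoldingEvents(t_f=15, t_B=12, t_c=9)
        assert classify_route(ts, ev) == "I"

    def test_route_ii_through_figure_eight(self):
        ts = series(["0_1"] * 6 + ["4_1"] * 6 + ["6_1"] * 8)
        ev = FoldingEvents(t_f=16, t_B=7, t_c=13)
        assert classify_route(ts, ev) == "II"

    def test_unfolded(self):
        ts = series(["0_1"] * 20)
        assert classify_route(ts, FoldingEvents(t_f=None)) == "unfolded"

    def test_trapped_in_wrong_knot(self):
        ts = series(["0_1"] * 8 + ["3_1"] * 12)
        assert classify_route(ts, FoldingEvents(t_f=None)) == "trapped"

    def test_route_ii_intermediate_precedes_native(self):
        """Whenever route II is assigned, the 4_1 interval ends no later
        than the first 6_1 frame."""
        ts = series(["0_1"] * 4 + ["4_1"] * 6 + ["6_1"] * 10)
        ev = FoldingEvents(t_f=14, t_B=5, t_c=11)
        assert classify_route(ts, ev) == "II"
        intervals = ts.persistent_intervals()
        end_41 = max(e for s, e, l in intervals if l == "4_1")
        first_61 = min(s for s, e, l in intervals if l == "6_1")
        assert end_41 <= first_61


class TestContactFormationOrder:
    def test_native_start_all_formed_at_first_frame(self):
        rng = np.random.default_rng(4)
        coords = np.cumsum(rng.normal(size=(10, 3)) + [3.0, 0.4, 0], axis=0)
        top = build_topology_from_ca(coords, contact_cutoff=9.0)
        frames = np.repeat(coords[None], 8, axis=0)
        traj = Trajectory(frames=frames, times=np.arange(8),
                          q=np.ones(8), topology=top)
        order = contact_formation_order(traj)
        assert len(order) == top.n_contacts
        assert all(step == 0 for _, step in order)

    def test_never_forming_contacts_omitted(self):
        coords = np.zeros((10, 3))
        coords[:, 0] = 3.8 * np.arange(10)
        coords[0, 1] = 0.4
        top = build_topology_from_ca(coords, contact_cutoff=0.0)
        top.contacts = np.array([[0, 9]])
        top.contact_sigma = np.array([2.0])  # far beyond actual distance
        frames = np.repeat(coords[None], 6, axis=0)
        traj = Trajectory(frames=frames, times=np.arange(6),
                          q=np.zeros(6), topology=top)
        assert contact_formation_order(traj) == []
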