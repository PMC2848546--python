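"""Topological and kinetic analysis of folding trajectories.

Operations here answer the questions one asks of a knotted-protein
folding run: when does the chain reach the folded state (t_f, the first
time 90% of native contacts are formed and stay formed), when does each
topological event happen — the threading of the C-terminal segment
through a loop (t_c) and the flipping of one loop over another (t_B) —
and which route the trajectory took (direct formation of the native
knot, or through a transient simpler knot).

Event times are defined through piercing parities: a loop spans a
surface (fan triangulation of the loop polygon about its centroid,
recomputed every frame), and a chain segment has threaded the loop when
it pierces that surface an odd net number of times.  The loop flip is
the first persistent change of the second loop's piercing parity from
its starting value.  Parity is a topologically faithful observable of
the events described visually in the folding mechanism, and is directly
verifiable against brute-force segment/triangle intersection counting.
All times are integrator step indices; labels and parities are smoothed
over a persistence window because chain closure through a transiently
threading terminus produces single-frame knot flickers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gomodel import NativeTopology, Trajectory, contact_distances
from .knot_core import classify_open_chain
from .knot_detect import close_chain, classify_knot, kmt_reduce

__all__ = [
    "KnotTimeSeries",
    "FoldingEvents",
    "knot_timeseries",
    "folding_time",
    "loop_event_times",
    "classify_route",
    "contact_formation_order",
    "piercing_parity",
    "analyze_trajectory",
]

PERSISTENCE_WINDOW = 5  # analyzed frames


@dataclass
class KnotTimeSeries:
    """Knot label per analyzed frame, raw and persistence-smoothed."""

    times: np.ndarray
    labels: list[str]          # smoothed
    raw_labels: list[str]
    persistence_window: int = PERSISTENCE_WINDOW

    def persistent_intervals(self) -> list[tuple[int, int, str]]:
        """Maximal runs (start_idx, end_idx inclusive, label) of the smoothed series."""
        out = []
        start = 0
        for i in range(1, len(self.labels) + 1):
            if i == len(self.labels) or self.labels[i] != self.labels[start]:
                out.append((start, i - 1, self.labels[start]))
                start = i
        return out


@dataclass
class FoldingEvents:
    """Event times (integrator steps) and the route label of one run."""

    t_f: int | None = None
    t_B: int | None = None
    t_c: int | None = None
    route: str = ""


def _smooth_labels(raw: list[str], window: int) -> list[str]:
    """Carry the last label that persisted >= window frames; flickers vanish."""
    if not raw:
        return []
    smoothed = []
    current = raw[0]
    run_label = raw[0]
    run_len = 0
    for lab in raw:
        if lab == run_label:
            run_len += 1
        else:
            run_label = lab
            run_len = 1
        if run_len >= window:
            current = run_label
        smoothed.append(current)
    return smoothed


def knot_timeseries(traj: Trajectory, every: int = 10, seed: int = 0,
                    persistence_window: int = PERSISTENCE_WINDOW) -> KnotTimeSeries:
    """Close, reduce and classify every ``every``-th saved frame."""
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    idx = list(range(0, len(traj), every))
    if idx[-1] != len(traj) - 1:
        idx.append(len(traj) - 1)
    raw = []
    for k in idx:
        curve = kmt_reduce(close_chain(traj.frames[k]))
        raw.append(classify_knot(curve, seed=seed, reduce_first=False).name)
    return KnotTimeSeries(
        times=traj.times[idx],
        labels=_smooth_labels(raw, persistence_window),
        raw_labels=raw,
        persistence_window=persistence_window,
    )


def folding_time(traj: Trajectory, q_threshold: float = 0.9,
                 persistence_window: int = PERSISTENCE_WINDOW,
                 q_slack: float = 0.05) -> int | None:
    """First step with Q >= threshold, staying >= threshold − slack afterwards."""
    q = traj.q
    n = len(q)
    for k in range(n):
        if q[k] >= q_threshold:
            stop = min(k + persistence_window, n)
            if np.all(q[k:stop] >= q_threshold - q_slack):
                return int(traj.times[k])
    return None


# ---------------------------------------------------------------------------
# piercing parity
# ---------------------------------------------------------------------------

def _fan_triangles(loop: np.ndarray):
    """Fan triangulation of a loop polygon about its centroid.

    Returns (m, 3, 3) triangle array, or None when any triangle is
    degenerate (the loop is too distorted to span a surface this way).
    """
    centroid = loop.mean(axis=0)
    nxt = np.roll(loop, -1, axis=0)
    tris = np.stack([np.broadcast_to(centroid, loop.shape), loop, nxt], axis=1)
    e1 = tris[:, 1] - tris[:, 0]
    e2 = tris[:, 2] - tris[:, 0]
    areas = np.linalg.norm(np.cross(e1, e2), axis=1)
    scale = np.linalg.norm(e1, axis=1) * np.linalg.norm(e2, axis=1)
    if np.any(areas < 1e-9 * np.maximum(scale, 1e-30)):
        return None
    return tris


def _segment_hits_triangle(p, q, tri, tol=1e-9) -> bool:
    """Scalar Möller–Trumbore transversal intersection test."""
    a, b, c = tri
    e1 = b - a
    e2 = c - a
    d = q - p
    h = np.cross(d, e2)
    det = float(h @ e1)
    if abs(det) < 1e-12 * max(np.linalg.norm(e1) * np.linalg.norm(e2), 1e-30):
        return False
    s = p - a
    u = float(s @ h) / det
    qv = np.cross(s, e1)
    v = float(qv @ d) / det
    t = float(qv @ e2) / det
    return (-tol <= u) and (-tol <= v) and (u + v <= 1 + tol) and (tol < t < 1 - tol)


def piercing_parity(loop: np.ndarray, segment_points: np.ndarray) -> int | None:
    """Net parity of piercings of the loop's fan surface by a polyline.

    Counts transverse crossings of every polyline segment with every fan
    triangle, mod 2.  Segments sharing an endpoint with the loop are
    excluded.  Returns None when the fan is degenerate.
    """
    tris = _fan_triangles(loop)
    if tris is None:
        return None
    count = 0
    for k in range(len(segment_points) - 1):
        p, q = segment_points[k], segment_points[k + 1]
        # skip segments touching the loop itself
        if (np.linalg.norm(loop - p, axis=1).min() < 1e-9
                or np.linalg.norm(loop - q, axis=1).min() < 1e-9):
            continue
        for tri in tris:
            if _segment_hits_triangle(p, q, tri):
                count += 1
    return count % 2


def _persistent_first(flags: list[int | None], window: int,
                      times: np.ndarray) -> int | None:
    """First time a True flag holds for >= window frames (None entries carry)."""
    filled: list[bool] = []
    last = False
    for f in flags:
        if f is not None:
            last = bool(f)
        filled.append(last)
    run = 0
    for i, f in enumerate(filled):
        run = run + 1 if f else 0
        if run >= min(window, len(filled)):
            return int(times[i - run + 1])
    # accept a shorter run only if it reaches the end of the series
    if run > 0:
        return int(times[len(filled) - run])
    return None


def loop_event_times(traj: Trajectory, s_loop: tuple[int, int],
                     b_loop: tuple[int, int], c_term: tuple[int, int] | None = None,
                     every: int = 1,
                     persistence_window: int = PERSISTENCE_WINDOW):
    """(t_B, t_c) from piercing parities; ranges are positional, end-exclusive.

    t_c: first persistent time the C-terminal segment pierces the
    S-loop's spanning surface an odd net number of times.  t_B: first
    persistent time the B-loop's piercing parity differs from its value
    in the first analyzed frame.  Frames whose S-loop cannot span a fan
    surface are skipped, carrying the previous parity.
    """
    s0, s1 = s_loop
    b0, b1 = b_loop
    n = traj.frames.shape[1]
    if c_term is None:
        c_term = (b1 - 1, n)
    c0, c1 = c_term
    idx = list(range(0, len(traj), every))
    c_flags: list[int | None] = []
    b_changed: list[int | None] = []
    b_initial: int | None = None
    for k in idx:
        frame = traj.frames[k]
        loop = frame[s0:s1]
        pc = piercing_parity(loop, frame[c0:c1])
        pb = piercing_parity(loop, frame[b0:b1])
        c_flags.append(pc)
        if pb is not None and b_initial is None:
            b_initial = pb
        b_changed.append(None if (pb is None or b_initial is None)
                         else int(pb != b_initial))
    times = traj.times[idx]
    t_c = _persistent_first(c_flags, persistence_window, times)
    t_b = _persistent_first(b_changed, persistence_window, times)
    return t_b, t_c


# ---------------------------------------------------------------------------
# route classification
# ---------------------------------------------------------------------------

def classify_route(ts: KnotTimeSeries, events: FoldingEvents,
                   native_knot: str = "6_1",
                   intermediate_knot: str = "4_1") -> str:
    """Route label of one trajectory.

    Route I: folded, native knot formed with no persistent intermediate
    knot before it.  Route II: a persistent intermediate (figure-eight
    when folding the Stevedore knot) precedes the native knot.
    "unfolded": never reached the folded state and ends unknotted.
    "trapped": anything else — e.g. a persistent wrong knot.
    """
    intervals = ts.persistent_intervals()
    first_native = None
    first_intermediate = None
    for start, _end, lab in intervals:
        if lab == native_knot and first_native is None:
            first_native = start
        if lab == intermediate_knot and first_intermediate is None:
            first_intermediate = start
    folded = events.t_f is not None and ts.labels and ts.labels[-1] == native_knot
    if folded:
        if first_intermediate is not None and (
                first_native is None or first_intermediate < first_native):
            return "II"
        return "I"
    if events.t_f is None and (not ts.labels or ts.labels[-1] == "0_1"):
        return "unfolded"
    return "trapped"


def contact_formation_order(traj: Trajectory, topology: NativeTopology | None = None,
                            tolerance_factor: float = 1.2,
                            persistence_window: int = PERSISTENCE_WINDOW):
    """First persistent formation step per native contact, sorted by step.

    A contact is formed when its distance is below ``tolerance_factor``
    times its native value for at least ``persistence_window``
    consecutive saved frames (or through the final frame).  Contacts
    that never form persistently are omitted.
    """
    top = topology if topology is not None else traj.topology
    n_frames = len(traj)
    formed = np.zeros((n_frames, top.n_contacts), dtype=bool)
    for k in range(n_frames):
        d = contact_distances(top, traj.frames[k])
        formed[k] = d < tolerance_factor * top.contact_sigma
    out = []
    for c in range(top.n_contacts):
        col = formed[:, c]
        first = None
        for k in range(n_frames):
            w = min(persistence_window, n_frames - k)
            if col[k:k + w].all():
                first = k
                break
        if first is not None:
            out.append(((int(top.contacts[c, 0]), int(top.contacts[c, 1])),
                        int(traj.times[first])))
    out.sort(key=lambda x: x[1])
    return out


def analyze_trajectory(traj: Trajectory, every: int = 10, seed: int = 0,
                       q_threshold: float = 0.9,
                       s_loop: tuple[int, int] | None = None,
                       b_loop: tuple[int, int] | None = None,
                       native_knot: str | None = None) -> dict:
    """One-stop report: knot series, t_f, loop events, route."""
    ts = knot_timeseries(traj, every=every, seed=seed)
    t_f = folding_time(traj, q_threshold=q_threshold)
    events = FoldingEvents(t_f=t_f)
    if s_loop is not None and b_loop is not None:
        events.t_B, events.t_c = loop_event_times(traj, s_loop, b_loop,
                                                  every=every)
    if native_knot is None:
        native_knot = classify_open_chain(traj.topology.native_coords,
                                          [seed, seed + 1, seed + 2]).name
    events.route = classify_route(ts, events, native_knot=native_knot)
    rle = [(str(lab), int(a), int(b)) for a, b, lab in
           [(s, e, l) for s, e, l in ts.persistent_intervals()]]
    return {
        "t_f": events.t_f,
        "t_B": events.t_B,
        "t_c": events.t_c,
        "route": events.route,
        "final_q": float(traj.q[-1]),
        "final_knot": ts.labels[-1] if ts.labels else None,
        "knot_series_rle": rle,
    }
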