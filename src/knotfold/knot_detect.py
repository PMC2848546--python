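"""Knot type identification for open protein backbones and closed curves.

The pipeline follows the standard computational-topology route for
proteins: (1) close the open Cα trace through a loop far outside the
structure, (2) simplify the closed polygon by triangle elimination
(KMT reduction), which preserves the knot type while shrinking the
curve to a handful of vertices, (3) project onto a generic plane and
enumerate crossings, and (4) evaluate the Alexander polynomial of the
crossing diagram at t = −1 and t = −2 with exact integer arithmetic.
The pair of determinant values identifies every knot type through six
crossings; in particular |Δ(−1)| alone cannot separate the figure-eight
knot 4_1 from the (2,5) torus knot 5_1 (both have determinant 5), which
is why the second evaluation exists.

A knot is only defined on a closed loop, so the chain is closed by
extending both termini radially away from the backbone's centre of mass
far beyond the structure and joining the two far points on a distant
sphere — the "pull both ends outward" definition of knottedness in an
open string.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structures import BackboneChain

__all__ = [
    "ClosedCurve",
    "CrossingDiagram",
    "KnotLabel",
    "close_chain",
    "kmt_reduce",
    "project_crossings",
    "alexander_determinant",
    "classify_knot",
    "KNOT_TABLE",
    "DegenerateProjectionError",
]


class DegenerateProjectionError(RuntimeError):
    """Projection direction produced a non-generic diagram; retry."""


@dataclass
class ClosedCurve:
    """Closed polygonal space curve (protein plus closure arc, or synthetic knot)."""

    vertices: np.ndarray  # (n, 3)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if len(self.vertices) < 3:
            raise ValueError("closed curve needs >= 3 vertices")
        nxt = np.roll(self.vertices, -1, axis=0)
        if np.any(np.linalg.norm(nxt - self.vertices, axis=1) == 0.0):
            raise ValueError("consecutive vertices coincide")

    def __len__(self) -> int:
        return len(self.vertices)


@dataclass
class CrossingDiagram:
    """Planar knot diagram: crossings with over/under arcs and signs.

    Arcs are the pieces of the curve between consecutive underpasses,
    numbered along the curve; arc ``k`` ends at underpass ``k``.  For a
    one-component diagram the number of arcs equals the number of
    crossings.
    """

    n_arcs: int
    crossings: list[tuple[int, int, int]] = field(default_factory=list)
    # each crossing: (over_arc, under_incoming_arc, sign)

    @property
    def n_crossings(self) -> int:
        return len(self.crossings)


# (name, minimal crossing number, |Δ(−1)|, odd part of |Δ(−2)|) for every
# prime knot through six crossings.  The third value is the t = −2
# evaluation with all factors of two removed, which makes it immune to
# the ±t^k ambiguity of the Alexander matrix determinant.
KNOT_TABLE: dict[tuple[int, int], tuple[str, int]] = {
    (1, 1): ("0_1", 0),
    (3, 7): ("3_1", 3),
    (5, 11): ("4_1", 4),
    (5, 31): ("5_1", 5),
    (7, 1): ("5_2", 5),
    (9, 5): ("6_1", 6),
    (11, 59): ("6_2", 6),
    (13, 67): ("6_3", 6),
}


@dataclass(frozen=True)
class KnotLabel:
    """Classification result: knot name and its Alexander determinants."""

    name: str
    crossing_number: int
    det_minus1: int
    det_minus2: int

    @property
    def is_knotted(self) -> bool:
        return self.name != "0_1"

    def __str__(self) -> str:
        return self.name


# ---------------------------------------------------------------------------
# chain closure
# ---------------------------------------------------------------------------

def close_chain(chain_or_coords, n_arc_points: int = 12) -> ClosedCurve:
    """Close an open backbone through a loop far outside the structure.

    Each terminus is extended along the ray from the backbone centre of
    mass through that terminus, out to a sphere of radius ten times the
    maximal pairwise extent of the chain; the two far points are joined
    by a great-circle arc on that sphere.  The added segments stay
    outside the chain's convex hull, so the closure cannot thread the
    structure and the detected knot is the knot "pulled tight" from the
    ends.
    """
    if isinstance(chain_or_coords, BackboneChain):
        coords = chain_or_coords.coords
    else:
        coords = np.asarray(chain_or_coords, dtype=float)
    if len(coords) < 2:
        raise ValueError("need >= 2 points to close")

    com = coords.mean(axis=0)
    # max pairwise extent; O(n^2) is fine at protein sizes
    if len(coords) > 1500:
        lo, hi = coords.min(axis=0), coords.max(axis=0)
        extent = float(np.linalg.norm(hi - lo))
    else:
        diff = coords[:, None, :] - coords[None, :, :]
        extent = float(np.sqrt((diff**2).sum(-1)).max())
    if extent == 0.0:
        raise ValueError("degenerate chain: zero extent")
    radius = 10.0 * extent

    def far_point(p: np.ndarray) -> np.ndarray:
        ray = p - com
        norm = np.linalg.norm(ray)
        if norm < 1e-9 * extent:
            # terminus sits on the centre of mass: perturb the ray
            rng = np.random.default_rng(0)
            ray = rng.normal(size=3)
            ray *= 1e-6 * extent / np.linalg.norm(ray)
            norm = np.linalg.norm(ray)
        return com + ray / norm * radius

    f_start = far_point(coords[0])
    f_end = far_point(coords[-1])

    # great-circle arc from f_end around to f_start, on the far sphere
    u0 = (f_end - com) / radius
    u1 = (f_start - com) / radius
    dot = float(np.clip(u0 @ u1, -1.0, 1.0))
    angle = np.arccos(dot)
    arc = []
    if angle < 1e-8:
        mid = None
    else:
        if angle > np.pi - 1e-6:
            # antipodal: route through an arbitrary perpendicular waypoint
            perp = np.cross(u0, [1.0, 0.0, 0.0])
            if np.linalg.norm(perp) < 1e-6:
                perp = np.cross(u0, [0.0, 1.0, 0.0])
            perp /= np.linalg.norm(perp)
            mid = perp
        else:
            mid = None
        def slerp(a, b, ts):
            ang = np.arccos(np.clip(a @ b, -1.0, 1.0))
            s = np.sin(ang)
            return np.array(
                [(np.sin((1 - t) * ang) * a + np.sin(t * ang) * b) / s for t in ts]
            )
        interior = np.linspace(0, 1, n_arc_points + 2)[1:-1]
        if mid is None:
            pts = slerp(u0, u1, interior)
        else:
            half = max(n_arc_points // 2, 1)
            pts = np.vstack(
                [
                    slerp(u0, mid, np.linspace(0, 1, half + 1)[1:]),
                    slerp(mid, u1, np.linspace(0, 1, half + 1)[1:-1]),
                ]
            )
        arc = [com + radius * p for p in pts]

    vertices = np.vstack([coords, [f_end], arc, [f_start]])
    return ClosedCurve(vertices)


# ---------------------------------------------------------------------------
# KMT reduction
# ---------------------------------------------------------------------------

def _segments_cross_triangle(tri: np.ndarray, p: np.ndarray, q: np.ndarray,
                             eps: float = 1e-10) -> np.ndarray:
    """Vectorized segment/triangle intersection (Möller–Trumbore).

    ``p``, ``q``: (m, 3) segment endpoints; returns boolean mask of
    segments meeting the closed triangle transversally.  Segments lying
    (almost) in the triangle's plane are tested in 2D and treated
    conservatively: any overlap with the triangle blocks elimination.
    """
    a, b, c = tri
    e1 = b - a
    e2 = c - a
    d = q - p  # (m, 3)
    h = np.cross(d, e2)
    det = h @ e1  # (m,)
    scale = np.linalg.norm(e1) * np.linalg.norm(e2)
    ok = np.abs(det) > eps * np.maximum(scale, 1e-30)

    hit = np.zeros(len(p), dtype=bool)
    if np.any(ok):
        dd = det[ok]
        s = p[ok] - a
        u = np.einsum("ij,ij->i", s, h[ok]) / dd
        qv = np.cross(s, e1)
        v = np.einsum("ij,ij->i", qv, d[ok]) / dd
        t = (qv @ e2) / dd
        tol = 1e-9
        inside = (
            (u >= -tol) & (v >= -tol) & (u + v <= 1 + tol)
            & (t >= -tol) & (t <= 1 + tol)
        )
        hit[np.flatnonzero(ok)[inside]] = True

    # coplanar segments: conservative 2D overlap test
    n = np.cross(e1, e2)
    nn = np.linalg.norm(n)
    if nn > 0:
        n = n / nn
        dist_p = np.abs((p - a) @ n)
        dist_q = np.abs((q - a) @ n)
        plane_tol = 1e-9 * max(np.linalg.norm(e1), np.linalg.norm(e2), 1e-30)
        coplanar = (~ok) & (dist_p < plane_tol) & (dist_q < plane_tol)
        if np.any(coplanar):
            # project to the triangle plane's 2D frame
            f1 = e1 / np.linalg.norm(e1)
            f2 = np.cross(n, f1)
            tri2 = np.array([[0.0, 0.0], [e1 @ f1, e1 @ f2], [e2 @ f1, e2 @ f2]])
            for idx in np.flatnonzero(coplanar):
                p2 = np.array([(p[idx] - a) @ f1, (p[idx] - a) @ f2])
                q2 = np.array([(q[idx] - a) @ f1, (q[idx] - a) @ f2])
                if _segment_overlaps_triangle_2d(p2, q2, tri2):
                    hit[idx] = True
    return hit


def _segment_overlaps_triangle_2d(p, q, tri, tol=1e-12) -> bool:
    def cross2(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    def inside(x):
        s0 = cross2(tri[0], tri[1], x)
        s1 = cross2(tri[1], tri[2], x)
        s2 = cross2(tri[2], tri[0], x)
        return (s0 >= -tol and s1 >= -tol and s2 >= -tol) or (
            s0 <= tol and s1 <= tol and s2 <= tol
        )

    if inside(p) or inside(q):
        return True
    edges = [(tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])]
    for a, b in edges:
        d1 = cross2(p, q, a)
        d2 = cross2(p, q, b)
        d3 = cross2(a, b, p)
        d4 = cross2(a, b, q)
        if ((d1 > tol) != (d2 > tol)) and ((d3 > tol) != (d4 > tol)):
            return True
    return False


def kmt_reduce(curve: ClosedCurve, min_vertices: int = 3) -> ClosedCurve:
    """Simplify a closed polygon by triangle elimination, preserving topology.

    A vertex ``i`` is deleted whenever the triangle spanned by its two
    neighbours is pierced by no other segment of the curve: the chain
    can then be deformed across that empty triangle without passing
    through itself.  Passes run in ascending index order until a full
    pass removes nothing.  Worst case the input is returned unchanged.
    """
    verts = list(map(np.asarray, curve.vertices))
    changed = True
    while changed and len(verts) > min_vertices:
        changed = False
        i = 0
        while i < len(verts) and len(verts) > min_vertices:
            n = len(verts)
            a = verts[(i - 1) % n]
            v = verts[i]
            b = verts[(i + 1) % n]
            area2 = np.linalg.norm(np.cross(v - a, b - a))
            base = np.linalg.norm(b - a)
            if base < 1e-12:
                # neighbours coincide: vertex and duplicate both removable
                del verts[i]
                changed = True
                continue
            if area2 < 1e-9 * base:
                # collinear: removable only if v lies between its neighbours
                t = (v - a) @ (b - a) / (base * base)
                if -1e-9 <= t <= 1 + 1e-9:
                    del verts[i]
                    changed = True
                    continue
                i += 1
                continue
            # all segments except (i-1,i) and (i,i+1)
            arr = np.array(verts)
            nxt = np.roll(arr, -1, axis=0)
            mask = np.ones(n, dtype=bool)
            mask[(i - 1) % n] = False
            mask[i] = False
            p = arr[mask]
            q = nxt[mask]
            # segments sharing a triangle vertex: shrink away from it
            tri = np.array([a, v, b])
            p = p.copy()
            q = q.copy()
            for tv in (a, b):
                share_p = np.linalg.norm(p - tv, axis=1) < 1e-12
                share_q = np.linalg.norm(q - tv, axis=1) < 1e-12
                p[share_p] = p[share_p] + 1e-7 * (q[share_p] - p[share_p])
                q[share_q] = q[share_q] + 1e-7 * (p[share_q] - q[share_q])
            if not _segments_cross_triangle(tri, p, q).any():
                del verts[i]
                changed = True
            else:
                i += 1
    return ClosedCurve(np.array(verts))


# ---------------------------------------------------------------------------
# planar projection
# ---------------------------------------------------------------------------

def project_crossings(curve: ClosedCurve, direction: np.ndarray) -> CrossingDiagram:
    """Enumerate crossings of the curve projected along ``direction``.

    Raises :class:`DegenerateProjectionError` when the projection is not
    generic (a segment parallel to the direction, a crossing too close
    to a vertex image, or coincident crossings); the caller retries with
    a fresh direction.
    """
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    # orthonormal frame
    tmp = np.array([1.0, 0.0, 0.0])
    if abs(d @ tmp) > 0.9:
        tmp = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, tmp)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)

    verts = curve.vertices
    n = len(verts)
    xy = np.stack([verts @ e1, verts @ e2], axis=1)
    depth = verts @ d
    nxt = np.arange(1, n + 1) % n

    seg_vec = xy[nxt] - xy
    seg_len3 = np.linalg.norm(verts[nxt] - verts, axis=1)
    if np.any(np.linalg.norm(seg_vec, axis=1) < 1e-9 * seg_len3):
        raise DegenerateProjectionError("segment parallel to projection direction")

    crossings_raw = []  # (pos_over, pos_under, sign); pos = i + t along curve
    scale = max(float(np.abs(xy).max()), 1e-30)
    tol = 1e-9
    for i in range(n):
        pi, vi = xy[i], seg_vec[i]
        for j in range(i + 1, n):
            if j == i or (j + 1) % n == i or (i + 1) % n == j:
                continue  # adjacent segments share a vertex
            pj, vj = xy[j], seg_vec[j]
            denom = vi[0] * vj[1] - vi[1] * vj[0]
            if abs(denom) < tol * max(
                np.linalg.norm(vi) * np.linalg.norm(vj), 1e-30
            ):
                # parallel in projection: degenerate only if the images
                # are collinear AND overlap (distinct collinear 3D
                # segments project to disjoint collinear images in any
                # generic direction, which is harmless)
                r = pj - pi
                if abs(r[0] * vi[1] - r[1] * vi[0]) < tol * scale:
                    li = vi @ vi
                    t0 = (pj - pi) @ vi / li
                    t1 = (pj + vj - pi) @ vi / li
                    lo, hi = min(t0, t1), max(t0, t1)
                    if hi > tol and lo < 1 - tol:
                        raise DegenerateProjectionError("overlapping collinear images")
                continue
            r = pj - pi
            s = (r[0] * vj[1] - r[1] * vj[0]) / denom
            t = (r[0] * vi[1] - r[1] * vi[0]) / denom
            if -tol < s < 1 + tol and -tol < t < 1 + tol:
                if s < tol or s > 1 - tol or t < tol or t > 1 - tol:
                    raise DegenerateProjectionError("crossing at a vertex image")
                zi = depth[i] + s * (depth[nxt[i]] - depth[i])
                zj = depth[j] + t * (depth[nxt[j]] - depth[j])
                if abs(zi - zj) < 1e-9 * max(abs(zi), abs(zj), 1e-30):
                    raise DegenerateProjectionError("equal depth at crossing")
                cross = float(np.sign(vi[0] * vj[1] - vi[1] * vj[0]))
                if zi > zj:
                    over_dir, under_dir = vi, vj
                    pos_over, pos_under = i + s, j + t
                else:
                    over_dir, under_dir = vj, vi
                    pos_over, pos_under = j + t, i + s
                sign = 1 if over_dir[0] * under_dir[1] - over_dir[1] * under_dir[0] > 0 else -1
                crossings_raw.append((pos_over, pos_under, sign))

    if not crossings_raw:
        return CrossingDiagram(n_arcs=1, crossings=[])

    under_pos = sorted(c[1] for c in crossings_raw)
    for a, b in zip(under_pos, under_pos[1:]):
        if b - a < 1e-12:
            raise DegenerateProjectionError("coincident underpasses")
    m = len(under_pos)
    u = np.array(under_pos)

    def arc_of(pos: float) -> int:
        # arc k ends at underpass u[k]; positions in (u[k-1], u[k]) -> arc k
        return int(np.searchsorted(u, pos)) % m

    crossings = []
    for pos_over, pos_under, sign in crossings_raw:
        k = int(np.searchsorted(u, pos_under - 1e-12))  # index of this underpass
        crossings.append((arc_of(pos_over), k, sign))
    crossings.sort(key=lambda c: c[1])
    return CrossingDiagram(n_arcs=m, crossings=crossings)


# ---------------------------------------------------------------------------
# Alexander determinant
# ---------------------------------------------------------------------------

def _bareiss_det(mat: list[list[int]]) -> int:
    """Fraction-free integer determinant (Bareiss algorithm)."""
    a = [row[:] for row in mat]
    n = len(a)
    if n == 0:
        return 1
    sign = 1
    prev = 1
    for k in range(n - 1):
        if a[k][k] == 0:
            for r in range(k + 1, n):
                if a[r][k] != 0:
                    a[k], a[r] = a[r], a[k]
                    sign = -sign
                    break
            else:
                return 0
        for i in range(k + 1, n):
            for j in range(k + 1, n):
                a[i][j] = (a[i][j] * a[k][k] - a[i][k] * a[k][j]) // prev
            a[i][k] = 0
        prev = a[k][k]
    return sign * a[n - 1][n - 1]


def alexander_determinant(diagram: CrossingDiagram, t_value: int) -> int:
    """|Δ(t)| at an integer ``t``, exactly, normalized to an invariant.

    Builds the crossing/arc Alexander matrix (one row per crossing: the
    overpass arc receives ``t − 1`` and the underpass arcs ``−t`` and
    ``1``, swapped for negative crossings; coincident arcs accumulate),
    deletes one row and one column, and evaluates the integer
    determinant by fraction-free elimination.  The matrix determinant
    carries a ±t^k ambiguity, so for |t| > 1 all factors of |t| are
    divided out; the returned value is a positive integer invariant of
    the knot (for t = −2, the odd part of |Δ(−2)|).
    """
    m = diagram.n_crossings
    if m == 0:
        return 1
    if m != diagram.n_arcs:
        raise ValueError("arc count must equal crossing count for one component")
    t = int(t_value)
    mat = [[0] * m for _ in range(m)]
    for row, (over, under_in, sign) in enumerate(diagram.crossings):
        under_out = (under_in + 1) % m
        mat[row][over] += t - 1
        if sign > 0:
            mat[row][under_in] += -t
            mat[row][under_out] += 1
        else:
            mat[row][under_in] += 1
            mat[row][under_out] += -t
    minor = [row[:-1] for row in mat[:-1]]
    det = abs(_bareiss_det(minor))
    if det == 0:
        return 0
    base = abs(t)
    if base > 1:
        while det % base == 0:
            det //= base
    return det


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_knot(curve: ClosedCurve, seed: int = 0, max_attempts: int = 100,
                  reduce_first: bool = True) -> KnotLabel:
    """Assign a knot type to a closed curve.

    KMT-reduces the curve, then draws seeded random projection
    directions until one is generic, computes |Δ(−1)| and the
    normalized |Δ(−2)|, and looks the pair up in the table of prime
    knots through six crossings.  Unmatched pairs are reported as
    ``"unclassified"`` with the determinants preserved.  Chirality is
    not resolved (the Alexander polynomial cannot distinguish mirror
    images), matching the achiral naming 3_1, 4_1, ...
    """
    reduced = kmt_reduce(curve) if reduce_first else curve
    if len(reduced) <= 3:
        return KnotLabel("0_1", 0, 1, 1)
    rng = np.random.default_rng(seed)
    last_err: Exception | None = None
    for _ in range(max_attempts):
        d = rng.normal(size=3)
        norm = np.linalg.norm(d)
        if norm < 1e-12:
            continue
        try:
            diagram = project_crossings(reduced, d / norm)
        except DegenerateProjectionError as exc:
            last_err = exc
            continue
        det1 = alexander_determinant(diagram, -1)
        det2 = alexander_determinant(diagram, -2)
        name, ncross = KNOT_TABLE.get((det1, det2), ("unclassified", -1))
        return KnotLabel(name, ncross, det1, det2)
    raise DegenerateProjectionError(
        f"cannot find generic projection after {max_attempts} attempts: {last_err}"
    )
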