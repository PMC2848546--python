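"""Synthetic knotted curves and toy backbones for testing the full pipeline.

Every knot type that occurs in known protein structures through six
crossings can be generated here without touching any external file:
torus knots from their closed-form parametrization, and the remaining
types (figure-eight 4_1, 5_2, Stevedore 6_1) from the closure of their
braid words, rendered as 3D polylines with distinct over/under depths.
Open-chain analogs (knot plus straight flanks, slipknot fixtures) and a
small foldable knotted mini-protein support the closure, knotted-core
and folding-simulation machinery.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .knot_detect import ClosedCurve, classify_knot
from .structures import BackboneChain

__all__ = [
    "CurveSpec",
    "make_curve",
    "make_open_knotted_chain",
    "make_slipknot_chain",
    "make_toy_knotted_protein",
    "random_self_avoiding_walk",
    "BRAID_WORDS",
    "TOY_FOLDING_TEMPERATURE",
    "TOY_CONTACT_CUTOFF",
]

CA_SPACING = 3.8  # Å, trans-peptide Cα–Cα distance

# Braid words (Artin generators; positive = lower-index strand passes
# over) whose trace closures give each knot type.  Validated against
# the Alexander-determinant oracle in the test suite.
BRAID_WORDS: dict[str, tuple[int, list[int]]] = {
    "3_1": (2, [1, 1, 1]),
    "4_1": (3, [1, -2, 1, -2]),
    "5_1": (2, [1, 1, 1, 1, 1]),
    "5_2": (3, [1, 1, 1, 2, -1, 2]),
    "6_1": (4, [1, 1, 2, -1, -3, 2, -3]),
}

KINDS = (
    "circle",
    "trefoil",
    "figure_eight",
    "five_one",
    "five_two",
    "six_one",
    "random_walk",
    "slipknot_fixture",
)

_KIND_TO_NAME = {
    "trefoil": "3_1",
    "figure_eight": "4_1",
    "five_one": "5_1",
    "five_two": "5_2",
    "six_one": "6_1",
    "circle": "0_1",
}


@dataclass
class CurveSpec:
    """Recipe for one synthetic closed curve."""

    kind: str
    n_vertices: int = 200
    seed: int = 0
    noise: float = 0.0
    torus_pq: tuple[int, int] = (2, 3)

    def __post_init__(self) -> None:
        if self.kind not in KINDS and self.kind != "torus_knot":
            raise ValueError(f"unknown curve kind {self.kind!r}")
        if self.n_vertices < 3:
            raise ValueError("n_vertices >= 3 required")
        if self.noise < 0:
            raise ValueError("noise must be >= 0")


def torus_knot(p: int, q: int, n_vertices: int = 200,
               major: float = 10.0, minor: float = 4.0) -> ClosedCurve:
    """(p, q) torus knot from the standard toroidal parametrization.

    (2, 3) is the trefoil, (2, 5) the 5_1 torus knot.  ``major`` and
    ``minor`` are the torus radii; defaults give protein-like scale.
    """
    t = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    r = major + minor * np.cos(q * t)
    x = r * np.cos(p * t)
    y = r * np.sin(p * t)
    z = minor * np.sin(q * t)
    return ClosedCurve(np.stack([x, y, z], axis=1))


def circle(n_vertices: int = 20, radius: float = 10.0) -> ClosedCurve:
    t = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    return ClosedCurve(
        np.stack([radius * np.cos(t), radius * np.sin(t), np.zeros_like(t)], axis=1)
    )


# ---------------------------------------------------------------------------
# braid closure rendering
# ---------------------------------------------------------------------------

def braid_closure(n_strands: int, word: list[int], scale: float = 10.0) -> ClosedCurve:
    """Render the trace closure of a braid word as a 3D polyline.

    Strands run along x at integer y positions; each braid letter swaps
    two neighbouring strands with the over strand bumped to positive z
    and the under strand to negative z.  The closure connects the end
    of position j back to its start through a return arc lifted to its
    own z level above everything — an embedding isotopic to the
    standard trace closure.  The braid permutation must be a single
    cycle (otherwise the closure is a link, not a knot).
    """
    for letter in word:
        if letter == 0 or abs(letter) >= n_strands:
            raise ValueError(f"letter {letter} invalid for {n_strands} strands")

    n_steps = len(word)
    # paths[s] = list of 3D points for the strand that STARTS at position s+1
    pos = list(range(n_strands))  # pos[slot] = strand occupying slot
    paths: list[list[np.ndarray]] = [
        [np.array([0.0, float(s), 0.0])] for s in range(n_strands)
    ]
    for step, letter in enumerate(word):
        i = abs(letter) - 1  # slots i, i+1 swap
        x0, x1 = float(step), float(step + 1)
        xm = x0 + 0.5
        s_lo, s_hi = pos[i], pos[i + 1]
        over_first = letter > 0  # positive: lower slot passes over
        z_lo = 0.55 if over_first else -0.55
        paths[s_lo].append(np.array([xm, i + 0.5, z_lo]))
        paths[s_lo].append(np.array([x1, float(i + 1), 0.0]))
        paths[s_hi].append(np.array([xm, i + 0.5, -z_lo]))
        paths[s_hi].append(np.array([x1, float(i), 0.0]))
        for slot in range(n_strands):
            if slot not in (i, i + 1):
                paths[pos[slot]].append(np.array([x1, float(slot), 0.0]))
        pos[i], pos[i + 1] = pos[i + 1], pos[i]

    # permutation: strand starting at slot s ends at slot end_slot[s]
    end_slot = {pos[slot]: slot for slot in range(n_strands)}
    perm = {s: end_slot[s] for s in range(n_strands)}
    # single-cycle check
    seen, s = {0}, perm[0]
    while s not in seen:
        seen.add(s)
        s = perm[s]
    if len(seen) != n_strands:
        raise ValueError("braid closure is a link, not a knot")

    x_end = float(n_steps)
    points: list[np.ndarray] = []
    strand = 0
    for _ in range(n_strands):
        points.extend(paths[strand])
        j = perm[strand]  # closing slot: end of this strand sits at slot j
        z_j = 2.0 + 0.7 * j
        margin = 1.0 + 0.3 * j
        points.append(np.array([x_end + margin, float(j), 0.0]))
        points.append(np.array([x_end + margin, float(j), z_j]))
        points.append(np.array([-margin, float(j), z_j]))
        points.append(np.array([-margin, float(j), 0.0]))
        strand = j  # continue with the strand that starts at slot j
    pts = np.array(points)
    # drop consecutive duplicates (straight-run bookkeeping)
    keep = [0]
    for k in range(1, len(pts)):
        if np.linalg.norm(pts[k] - pts[keep[-1]]) > 1e-9:
            keep.append(k)
    if np.linalg.norm(pts[keep[-1]] - pts[keep[0]]) < 1e-9:
        keep.pop()
    pts = pts[keep]
    return ClosedCurve(pts * scale / max(n_steps, 1))


def _subdivide(vertices: np.ndarray, n_target: int) -> np.ndarray:
    """Insert midpoints into the longest segments until n_target vertices.

    Keeps every original vertex, so the polygon (and its knot type) is
    geometrically unchanged.
    """
    verts = list(map(np.asarray, vertices))
    while len(verts) < n_target:
        nxt = verts[1:] + verts[:1]
        lengths = [np.linalg.norm(b - a) for a, b in zip(verts, nxt)]
        i = int(np.argmax(lengths))
        mid = (verts[i] + verts[(i + 1) % len(verts)]) / 2
        verts.insert(i + 1, mid)
    return np.array(verts)


class NoiseDestroyedTopologyError(RuntimeError):
    """Requested vertex noise changed the curve's knot type."""


def make_curve(spec: CurveSpec) -> ClosedCurve:
    """Generate the closed curve described by ``spec``.

    With ``noise > 0``, seeded Gaussian displacement is added to every
    vertex and the result re-classified; if the perturbation changed
    the knot type the generation fails loudly rather than returning a
    mislabeled fixture.
    """
    kind = spec.kind
    if kind == "torus_knot":
        base = torus_knot(*spec.torus_pq, n_vertices=spec.n_vertices)
        p, q = spec.torus_pq
        nominal = {(2, 3): "3_1", (3, 2): "3_1", (2, 5): "5_1", (5, 2): "5_1"}.get(
            (p, q), None
        )
    elif kind == "circle":
        base = circle(n_vertices=spec.n_vertices)
        nominal = "0_1"
    elif kind == "trefoil":
        base = torus_knot(2, 3, n_vertices=spec.n_vertices)
        nominal = "3_1"
    elif kind == "random_walk":
        walk = random_self_avoiding_walk(max(spec.n_vertices, 10), spec.seed)
        from .knot_detect import close_chain

        base = close_chain(walk)
        nominal = None
    elif kind == "slipknot_fixture":
        raise ValueError("slipknot_fixture is an open chain: use make_slipknot_chain")
    else:
        n_strands, word = BRAID_WORDS[_KIND_TO_NAME[kind]]
        rendered = braid_closure(n_strands, word)
        base = ClosedCurve(_subdivide(rendered.vertices, spec.n_vertices))
        nominal = _KIND_TO_NAME[kind]

    if spec.noise > 0:
        rng = np.random.default_rng(spec.seed)
        noisy = base.vertices + rng.normal(scale=spec.noise, size=base.vertices.shape)
        curve = ClosedCurve(noisy)
        if nominal is not None:
            got = classify_knot(curve, seed=spec.seed).name
            if got != nominal:
                raise NoiseDestroyedTopologyError(
                    f"noise {spec.noise} changed {nominal} into {got}"
                )
        return curve
    return base


# ---------------------------------------------------------------------------
# open-chain fixtures
# ---------------------------------------------------------------------------

def _rescale_spacing(points: np.ndarray, spacing: float) -> np.ndarray:
    """Uniformly scale an open polyline so mean vertex spacing = spacing."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return points * (spacing / seg.mean())


def open_curve_at_max_radius(curve: ClosedCurve) -> np.ndarray:
    """Open a closed curve at its maximum-radius vertex.

    The cut point is farthest from the centroid, i.e. on the outside of
    the structure, so the two new termini are surface-exposed — the
    analog of protein termini — and closure re-finds the original knot.
    """
    verts = curve.vertices
    centroid = verts.mean(axis=0)
    k = int(np.argmax(np.linalg.norm(verts - centroid, axis=1)))
    rolled = np.roll(verts, -k, axis=0)
    return rolled  # open chain: the segment rolled[-1] -> rolled[0] is removed


def _as_backbone(points: np.ndarray, chain_id: str = "A") -> BackboneChain:
    return BackboneChain(
        chain_id=chain_id,
        residues=[(i + 1, "") for i in range(len(points))],
        coords=np.asarray(points, dtype=float),
    )


def make_open_knotted_chain(kind: str, flank_residues: int = 0,
                            seed: int = 0, n_vertices: int = 120) -> BackboneChain:
    """Open-chain analog of a synthetic knot, with straight flanks.

    The closed curve is cut at its maximum-radius vertex, rescaled to
    Cα spacing (3.8 Å), and straight flanks of ``flank_residues`` beads
    are appended at both ends pointing radially outward.  Author
    numbering runs 1..n.  Used to exercise chain closure and the
    knotted-core scan: the core must exclude all flank residues.
    """
    if kind == "slipknot_fixture":
        return make_slipknot_chain(seed=seed)
    spec = CurveSpec(kind=kind, n_vertices=n_vertices, seed=seed)
    curve = make_curve(spec)
    pts = open_curve_at_max_radius(curve)
    pts = _rescale_spacing(pts, CA_SPACING)
    centroid = pts.mean(axis=0)

    def flank(end_point: np.ndarray, n: int) -> np.ndarray:
        if n == 0:
            return np.zeros((0, 3))
        d = end_point - centroid
        d = d / np.linalg.norm(d)
        return end_point + d * CA_SPACING * np.arange(1, n + 1)[:, None]

    head = flank(pts[0], flank_residues)[::-1]
    tail = flank(pts[-1], flank_residues)
    return _as_backbone(np.vstack([head, pts, tail]))


def make_slipknot_chain(seed: int = 0, n_vertices: int = 90) -> BackboneChain:
    """Open chain that is unknotted as a whole but has a knotted subchain.

    Construction: take an open trefoil, then retrace the final third of
    the chain backwards alongside itself (offset ~1 Å) and escape
    radially — the terminus is pulled back out of the loop it had
    threaded, so closure of the whole chain is trivial while the
    subchain that stops before the retrace still closes to a trefoil.
    """
    curve = torus_knot(2, 3, n_vertices=n_vertices)
    pts = open_curve_at_max_radius(curve)
    pts = _rescale_spacing(pts, CA_SPACING)
    n = len(pts)
    k = n // 3  # how far the end retraces
    centroid = pts.mean(axis=0)

    rng = np.random.default_rng(seed)
    retrace = []
    for i in range(n - 2, n - 2 - k, -1):
        tangent = pts[i + 1] - pts[i - 1]
        radial = pts[i] - centroid
        offset = np.cross(tangent, radial)
        norm = np.linalg.norm(offset)
        if norm < 1e-9:
            offset = rng.normal(size=3)
            norm = np.linalg.norm(offset)
        retrace.append(pts[i] + offset / norm * 1.2)
    retrace = np.array(retrace)
    exit_start = retrace[-1]
    d = exit_start - centroid
    d /= np.linalg.norm(d)
    escape = exit_start + d * CA_SPACING * np.arange(1, 9)[:, None]
    return _as_backbone(np.vstack([pts, retrace, escape]))


def random_self_avoiding_walk(n: int, seed: int, step: float = CA_SPACING,
                              min_dist: float = 3.0) -> np.ndarray:
    """Random open chain with excluded volume (rejection sampling)."""
    rng = np.random.default_rng(seed)
    pts = [np.zeros(3)]
    attempts = 0
    while len(pts) < n:
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        cand = pts[-1] + step * d
        arr = np.array(pts[:-1]) if len(pts) > 1 else None
        if arr is None or np.min(np.linalg.norm(arr - cand, axis=1)) > min_dist:
            pts.append(cand)
            attempts = 0
        else:
            attempts += 1
            if attempts > 200:  # back up one step and retry
                pts.pop()
                attempts = 0
    return np.array(pts)


# ---------------------------------------------------------------------------
# toy knotted mini-protein
# ---------------------------------------------------------------------------

# Reduced temperature for toy-protein folding/stability runs, located by a
# temperature scan (native basin stable, Q ~ 1; compact states form from
# extended starts within ~1e6 steps) and pinned here for reproducibility.
TOY_FOLDING_TEMPERATURE = 0.5
# Cα contact cutoff calibrated for the toy: captures the ring/pin/groove
# packing shells (~4-6 Å) without second-shell noise.
TOY_CONTACT_CUTOFF = 6.5


def _chaikin(points: np.ndarray, iterations: int = 1) -> np.ndarray:
    """Chaikin corner cutting: rounds sharp polyline corners so that a
    fixed-arc-length resample produces near-uniform chord lengths."""
    pts = points
    for _ in range(iterations):
        out = [pts[0]]
        for a, b in zip(pts[:-1], pts[1:]):
            out.append(0.75 * a + 0.25 * b)
            out.append(0.25 * a + 0.75 * b)
        out.append(pts[-1])
        pts = np.array(out)
    return pts


def _resample_arclength(points: np.ndarray, spacing: float) -> np.ndarray:
    """Resample an open polyline at (near-)equal arc-length spacing.

    The count is rounded so the spacing divides the total length evenly;
    no short trailing segment is produced.
    """
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    n_out = max(2, int(round(s[-1] / spacing)) + 1)
    targets = np.linspace(0.0, s[-1], n_out)
    out = np.stack([np.interp(targets, s, points[:, c]) for c in range(3)], axis=1)
    return out


def make_toy_knotted_protein(seed: int = 0, n_residues: int = 35) -> BackboneChain:
    """Designed ~35-bead knotted mini-protein (see :func:`_toy_native_coords`).

    Results are cached per (seed, n_residues); a fresh chain object is
    returned each call.  ``n_residues`` is the approximate target; the
    actual count is fixed by the construction (35 for the default).
    """
    coords = _toy_native_coords(seed)
    return _as_backbone(coords.copy())


@lru_cache(maxsize=8)
def _toy_native_coords(seed: int) -> np.ndarray:
    """Ring-and-pin open trefoil mini-protein at Cα geometry.

    Architecture, mimicking how small knotted proteins arrange the knot:
    an N-terminal tail runs into a flat ~8-bead ring; the chain exits the
    ring through a "neck" that dips back under the tail (the locking
    crossing of the knot); an excursion arcs over the structure and a
    C-terminal pin descends through the ring, exits along the ring's
    underside and finally passes beneath the neck, so that tail, neck
    and exit stack into a three-layer sandwich.  Every crossing of the
    trefoil is supported by tight (4-6 Å) contacts.  The construction is
    validated by re-classification (must close to 3_1) and has no pair
    of non-bonded beads closer than ~3.6 Å.  A sub-Å seeded jitter
    breaks the exact symmetries of the parametric build.
    """
    a = 5.3          # ring radius, Å
    dip = -4.6       # neck depth below the ring plane
    tail_z = 0.8
    d2r = np.deg2rad
    W = []
    for r in (21.0, 17.0, 13.0, 9.0):
        W.append((r * np.cos(d2r(-20)), r * np.sin(d2r(-20)), tail_z))
    for t in np.linspace(-20, 310, 40):
        W.append((a * np.cos(d2r(t)), a * np.sin(d2r(t)), 0.0))
    W.append((6.0 * np.cos(d2r(325)), 6.0 * np.sin(d2r(325)), dip))
    W.append((8.0 * np.cos(d2r(-20)), 8.0 * np.sin(d2r(-20)), dip))
    W.append((12 * np.cos(d2r(10)), 12 * np.sin(d2r(10)), dip * 0.5))
    W.append((10 * np.cos(d2r(10)), 10 * np.sin(d2r(10)), 7.0))
    W.append((0.6, -0.4, 8.2))
    for z in (4.4, 0.6, -3.4):
        W.append((0.3 * np.cos(z), 0.3 * np.sin(2 * z), z))
    for t, zz in ((80, -4.6), (130, -4.4), (180, -4.3), (240, -4.5), (300, -6.5)):
        W.append((a * np.cos(d2r(t)), a * np.sin(d2r(t)), zz))
    W.append((7.2 * np.cos(d2r(-25)), 7.2 * np.sin(d2r(-25)), -8.5))
    W.append((10.5 * np.cos(d2r(-18)), 10.5 * np.sin(d2r(-18)), -8.7))
    W.append((15.0 * np.cos(d2r(-15)), 15.0 * np.sin(d2r(-15)), -8.8))
    smooth = _chaikin(np.array(W, float), 2)
    pts = _resample_arclength(smooth, CA_SPACING)

    rng = np.random.default_rng(seed)
    for _ in range(10):
        jittered = pts + rng.normal(scale=0.04, size=pts.shape)
        from .knot_detect import close_chain

        if classify_knot(close_chain(jittered), seed=seed).name == "3_1":
            return jittered
    raise RuntimeError("seeded jitter destroyed the designed trefoil")
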