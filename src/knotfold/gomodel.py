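"""Structure-based Cα model with only native contacts, and Langevin dynamics.

The force field is the classic minimally frustrated Gō-type model:
harmonic bonds and angles, a two-term backbone dihedral, a 10–12
attraction for every pair of residues in contact in the native
structure, and a purely repulsive r⁻¹² core for every other pair.
Energies are in units of the contact depth ε, lengths in Å, and the
reduced temperature is k_BT/ε; time is the natural unit
τ = sqrt(m Å²/ε) with all bead masses set to 1.

    V = Σ_bonds  K_r (r − r₀)²
      + Σ_angles K_θ (θ − θ₀)²
      + Σ_dihedrals K_φ [(1 − cos(φ − φ₀)) + ½ (1 − cos 3(φ − φ₀))]
      + Σ_native  ε [5 (σ_ij/r)¹² − 6 (σ_ij/r)¹⁰]
      + Σ_non-native ε (σ_rep/r)¹²

with the community-standard constants K_r = 100 ε/Å², K_θ = 20 ε/rad²,
K_φ = 1 ε and ½ ε, σ_rep = 4 Å.  Each native 10–12 term is minimized
at the native pair distance σ_ij with depth exactly −ε, so the native
state is the global minimum by construction: the model cannot bias any
non-native route, which is what makes it suitable for asking whether a
knotted topology can form at all.

Integration is Langevin velocity-Verlet (BAOAB splitting); with the
friction set to zero it reduces to plain velocity Verlet, which the
tests exploit for energy-conservation checks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numba
import numpy as np

from .structures import BackboneChain, read_backbone

__all__ = [
    "NativeTopology",
    "SimParams",
    "Trajectory",
    "build_topology",
    "build_topology_from_ca",
    "potential_energy",
    "fraction_native_contacts",
    "run_trajectory",
    "extended_conformation",
]

K_BOND = 100.0      # ε/Å²
K_ANGLE = 20.0      # ε/rad²
K_DIHEDRAL_1 = 1.0  # ε
K_DIHEDRAL_3 = 0.5  # ε
SIGMA_REP = 4.0     # Å


class SingularConfigurationError(ValueError):
    """Two beads (nearly) coincide; forces are undefined."""


class NoContactsError(ValueError):
    """Topology defines no native contacts."""


@dataclass
class NativeTopology:
    """Bonded terms and native-contact list of a Cα structure-based model."""

    n_residues: int
    native_coords: np.ndarray                 # (n, 3) Å
    bonds: np.ndarray                         # (nb, 2) int; r0 from bond_r0
    bond_r0: np.ndarray
    angles: np.ndarray                        # (na, 3) int
    angle_theta0: np.ndarray
    dihedrals: np.ndarray                     # (nd, 4) int
    dihedral_phi0: np.ndarray
    contacts: np.ndarray                      # (nc, 2) int, i < j, |i-j| >= 3
    contact_sigma: np.ndarray                 # native Cα distance per contact
    epsilon: float = 1.0
    repulsive_sigma: float = SIGMA_REP
    # cached nonbonded pair arrays (built lazily)
    _pairs: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.native_coords = np.asarray(self.native_coords, float)
        cs = {tuple(c) for c in np.asarray(self.contacts).reshape(-1, 2)}
        if any((j, i) in cs for i, j in cs):
            raise ValueError("contact list contains symmetric duplicates")
        if any(abs(i - j) < 3 for i, j in cs):
            raise ValueError("contacts must have |i-j| >= 3")
        bad = [(r,) for r in self.bond_r0 if not (2.5 <= r <= 4.5)]
        if bad:
            warnings.warn(
                f"{len(bad)} bond length(s) outside the trans-peptide range "
                "[2.5, 4.5] Å", stacklevel=2,
            )

    @property
    def n_contacts(self) -> int:
        return len(self.contacts)

    def nonbonded_pairs(self):
        """All pairs |i-j| >= 3 with their sigma and native flag."""
        if self._pairs is None:
            n = self.n_residues
            ii, jj = np.triu_indices(n, k=3)
            native = {tuple(sorted(c)): s
                      for c, s in zip(self.contacts, self.contact_sigma)}
            is_native = np.zeros(len(ii), dtype=np.int8)
            sigma = np.full(len(ii), self.repulsive_sigma)
            for k, (i, j) in enumerate(zip(ii, jj)):
                s = native.get((int(i), int(j)))
                if s is not None:
                    is_native[k] = 1
                    sigma[k] = s
            self._pairs = (ii.astype(np.int64), jj.astype(np.int64),
                           sigma, is_native)
        return self._pairs


@dataclass
class SimParams:
    """Langevin dynamics parameters, reduced units."""

    temperature: float
    n_steps: int
    friction: float = 1.0   # 1/τ
    dt: float = 0.005       # τ
    save_every: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")
        if self.dt > 0.01:
            raise ValueError("dt must be <= 0.01 τ for stability")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")


@dataclass
class Trajectory:
    """Saved frames of one run, with per-frame fraction of native contacts Q."""

    frames: np.ndarray            # (n_frames, n, 3)
    times: np.ndarray             # integrator step index per frame
    q: np.ndarray                 # (n_frames,)
    topology: NativeTopology
    diverged: bool = False
    final_velocities: np.ndarray | None = None
    kinetic: np.ndarray | None = None   # per saved frame, ε

    def __len__(self) -> int:
        return len(self.frames)


# ---------------------------------------------------------------------------
# topology construction
# ---------------------------------------------------------------------------

def _bonded_terms(coords: np.ndarray):
    n = len(coords)
    bonds = np.stack([np.arange(n - 1), np.arange(1, n)], axis=1)
    bond_r0 = np.linalg.norm(np.diff(coords, axis=0), axis=1)
    angles = np.stack([np.arange(n - 2), np.arange(1, n - 1), np.arange(2, n)], axis=1)
    theta0 = np.array([_angle(coords[i], coords[j], coords[k]) for i, j, k in angles])
    dihedrals = np.stack([np.arange(n - 3), np.arange(1, n - 2),
                          np.arange(2, n - 1), np.arange(3, n)], axis=1)
    phi0 = np.array([_dihedral(coords[i], coords[j], coords[k], coords[l])
                     for i, j, k, l in dihedrals])
    return bonds, bond_r0, angles, theta0, dihedrals, phi0


def _angle(a, b, c) -> float:
    u = a - b
    v = c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.arccos(np.clip(cosang, -1, 1)))


def _dihedral(p0, p1, p2, p3) -> float:
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    return float(np.arctan2(np.dot(m1, n2), np.dot(n1, n2)))


def build_topology(pdb_source, chain_id: str, contact_cutoff: float = 4.5,
                   bridge_gaps: bool = False) -> NativeTopology:
    """Build the Cα model from a PDB structure with heavy atoms.

    A native contact (i, j), |i−j| ≥ 3, is declared when any heavy-atom
    pair between the two residues lies closer than ``contact_cutoff``
    (default 4.5 Å); its σ_ij is the native Cα–Cα distance.  Bonded
    geometry comes from consecutive Cα positions.  Chains with gaps are
    refused unless ``bridge_gaps``: bridged bonded terms use the
    straight-segment geometry, which is fictitious — hence the warning.
    """
    import gemmi

    from .structures import _coerce_structure

    chain = read_backbone(pdb_source, chain_id)
    if chain.has_gaps:
        if not bridge_gaps:
            raise ValueError(
                "chain has gaps in author numbering; pass bridge_gaps=True "
                "to build bonded terms across bridged segments"
            )
        warnings.warn("bridging chain gaps: bonded terms across gaps are "
                      "fictitious", stacklevel=2)

    structure = _coerce_structure(pdb_source)
    model = structure[0]
    gchain = model.find_chain(chain_id)
    heavy: dict[tuple[int, str], np.ndarray] = {}
    for res in gchain:
        if res.het_flag == "H":
            continue
        key = (res.seqid.num, res.seqid.icode.strip())
        pts = [[a.pos.x, a.pos.y, a.pos.z] for a in res if a.element.name != "H"]
        if pts:
            heavy.setdefault(key, np.array(pts))

    coords = chain.coords
    n = len(chain)
    contacts, sigmas = [], []
    atom_sets = [heavy.get(r) for r in chain.residues]
    for i in range(n):
        ai = atom_sets[i]
        if ai is None:
            continue
        for j in range(i + 3, n):
            aj = atom_sets[j]
            if aj is None:
                continue
            d2 = ((ai[:, None, :] - aj[None, :, :]) ** 2).sum(-1)
            if d2.min() < contact_cutoff**2:
                contacts.append((i, j))
                sigmas.append(np.linalg.norm(coords[i] - coords[j]))
    return _assemble(coords, contacts, sigmas)


def build_topology_from_ca(chain_or_coords, contact_cutoff: float = 7.5) -> NativeTopology:
    """Build the Cα model from a Cα-only trace.

    Without side-chain atoms a larger cutoff on Cα–Cα distance stands
    in for the heavy-atom criterion; 7.5 Å captures helix (i, i+3/4)
    and sheet cross-strand packing distances.  Used for synthetic
    mini-proteins and Cα-only PDB fixtures.
    """
    if isinstance(chain_or_coords, BackboneChain):
        coords = chain_or_coords.coords
    else:
        coords = np.asarray(chain_or_coords, float)
    n = len(coords)
    ii, jj = np.triu_indices(n, k=3)
    d = np.linalg.norm(coords[ii] - coords[jj], axis=1)
    mask = d < contact_cutoff
    contacts = list(zip(ii[mask].tolist(), jj[mask].tolist()))
    sigmas = d[mask].tolist()
    return _assemble(coords, contacts, sigmas)


def _assemble(coords, contacts, sigmas) -> NativeTopology:
    bonds, bond_r0, angles, theta0, dihedrals, phi0 = _bonded_terms(coords)
    return NativeTopology(
        n_residues=len(coords),
        native_coords=np.asarray(coords, float),
        bonds=bonds, bond_r0=bond_r0,
        angles=angles, angle_theta0=theta0,
        dihedrals=dihedrals, dihedral_phi0=phi0,
        contacts=np.array(contacts, int).reshape(-1, 2),
        contact_sigma=np.array(sigmas, float),
    )


# ---------------------------------------------------------------------------
# forces (numba kernels)
# ---------------------------------------------------------------------------

@numba.njit(cache=True)
def _forces(coords, bonds, bond_r0, angles, theta0, dihedrals, phi0,
            pair_i, pair_j, pair_sigma, pair_native, eps, forces):
    n = coords.shape[0]
    for i in range(n):
        forces[i, 0] = 0.0
        forces[i, 1] = 0.0
        forces[i, 2] = 0.0
    energy = 0.0

    for b in range(bonds.shape[0]):
        i, j = bonds[b, 0], bonds[b, 1]
        dx = coords[j, 0] - coords[i, 0]
        dy = coords[j, 1] - coords[i, 1]
        dz = coords[j, 2] - coords[i, 2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - bond_r0[b]
        energy += K_BOND * dr * dr
        f = 2.0 * K_BOND * dr / r
        forces[i, 0] += f * dx
        forces[i, 1] += f * dy
        forces[i, 2] += f * dz
        forces[j, 0] -= f * dx
        forces[j, 1] -= f * dy
        forces[j, 2] -= f * dz

    for a in range(angles.shape[0]):
        i, j, k = angles[a, 0], angles[a, 1], angles[a, 2]
        ux = coords[i, 0] - coords[j, 0]
        uy = coords[i, 1] - coords[j, 1]
        uz = coords[i, 2] - coords[j, 2]
        vx = coords[k, 0] - coords[j, 0]
        vy = coords[k, 1] - coords[j, 1]
        vz = coords[k, 2] - coords[j, 2]
        nu = math.sqrt(ux * ux + uy * uy + uz * uz)
        nv = math.sqrt(vx * vx + vy * vy + vz * vz)
        cost = (ux * vx + uy * vy + uz * vz) / (nu * nv)
        if cost > 1.0:
            cost = 1.0
        elif cost < -1.0:
            cost = -1.0
        theta = math.acos(cost)
        dtheta = theta - theta0[a]
        energy += K_ANGLE * dtheta * dtheta
        # the 1/sin(theta) in the gradient diverges at collinear bends;
        # floor it so a rare straightened angle cannot blow up the step
        sint = math.sqrt(max(1.0 - cost * cost, 2.5e-3))
        coef = -2.0 * K_ANGLE * dtheta / sint
        inunv = 1.0 / (nu * nv)
        inu2 = cost / (nu * nu)
        inv2 = cost / (nv * nv)
        dix = coef * (vx * inunv - ux * inu2)
        diy = coef * (vy * inunv - uy * inu2)
        diz = coef * (vz * inunv - uz * inu2)
        dkx = coef * (ux * inunv - vx * inv2)
        dky = coef * (uy * inunv - vy * inv2)
        dkz = coef * (uz * inunv - vz * inv2)
        forces[i, 0] -= dix
        forces[i, 1] -= diy
        forces[i, 2] -= diz
        forces[k, 0] -= dkx
        forces[k, 1] -= dky
        forces[k, 2] -= dkz
        forces[j, 0] += dix + dkx
        forces[j, 1] += diy + dky
        forces[j, 2] += diz + dkz

    for d in range(dihedrals.shape[0]):
        i, j, k, l = dihedrals[d, 0], dihedrals[d, 1], dihedrals[d, 2], dihedrals[d, 3]
        b1x = coords[j, 0] - coords[i, 0]
        b1y = coords[j, 1] - coords[i, 1]
        b1z = coords[j, 2] - coords[i, 2]
        b2x = coords[k, 0] - coords[j, 0]
        b2y = coords[k, 1] - coords[j, 1]
        b2z = coords[k, 2] - coords[j, 2]
        b3x = coords[l, 0] - coords[k, 0]
        b3y = coords[l, 1] - coords[k, 1]
        b3z = coords[l, 2] - coords[k, 2]
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        nb2 = math.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        # phi = atan2((n1 x b2hat) . n2, n1 . n2)
        cxx = n2y * n1z - n2z * n1y
        cxy = n2z * n1x - n2x * n1z
        cxz = n2x * n1y - n2y * n1x
        sinp = (cxx * b2x + cxy * b2y + cxz * b2z) / nb2
        cosp = n1x * n2x + n1y * n2y + n1z * n2z
        phi = math.atan2(sinp, cosp)
        dphi = phi - phi0[d]
        energy += K_DIHEDRAL_1 * (1.0 - math.cos(dphi)) \
            + K_DIHEDRAL_3 * (1.0 - math.cos(3.0 * dphi))
        dV = K_DIHEDRAL_1 * math.sin(dphi) + 3.0 * K_DIHEDRAL_3 * math.sin(3.0 * dphi)
        n1sq = n1x * n1x + n1y * n1y + n1z * n1z
        n2sq = n2x * n2x + n2y * n2y + n2z * n2z
        if n1sq < 1e-12 or n2sq < 1e-12:
            continue
        # dphi/dri = |b2|/|n1|^2 n1 ; dphi/drl = -|b2|/|n2|^2 n2
        # (verified against central differences; see tests)
        gi = nb2 / n1sq
        gl = -nb2 / n2sq
        dpix = gi * n1x
        dpiy = gi * n1y
        dpiz = gi * n1z
        dplx = gl * n2x
        dply = gl * n2y
        dplz = gl * n2z
        s12 = (b1x * b2x + b1y * b2y + b1z * b2z) / (nb2 * nb2)
        s32 = (b3x * b2x + b3y * b2y + b3z * b2z) / (nb2 * nb2)
        dpjx = -dpix - s12 * dpix + s32 * dplx
        dpjy = -dpiy - s12 * dpiy + s32 * dply
        dpjz = -dpiz - s12 * dpiz + s32 * dplz
        dpkx = -dplx + s12 * dpix - s32 * dplx
        dpky = -dply + s12 * dpiy - s32 * dply
        dpkz = -dplz + s12 * dpiz - s32 * dplz
        forces[i, 0] -= dV * dpix
        forces[i, 1] -= dV * dpiy
        forces[i, 2] -= dV * dpiz
        forces[j, 0] -= dV * dpjx
        forces[j, 1] -= dV * dpjy
        forces[j, 2] -= dV * dpjz
        forces[k, 0] -= dV * dpkx
        forces[k, 1] -= dV * dpky
        forces[k, 2] -= dV * dpkz
        forces[l, 0] -= dV * dplx
        forces[l, 1] -= dV * dply
        forces[l, 2] -= dV * dplz

    for p in range(pair_i.shape[0]):
        i, j = pair_i[p], pair_j[p]
        dx = coords[j, 0] - coords[i, 0]
        dy = coords[j, 1] - coords[i, 1]
        dz = coords[j, 2] - coords[i, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < 1e-12:
            return np.inf  # singular configuration
        sig = pair_sigma[p]
        s2 = sig * sig / r2
        s6 = s2 * s2 * s2
        s12 = s6 * s6
        if pair_native[p] == 1:
            s10 = s6 * s2 * s2
            energy += eps * (5.0 * s12 - 6.0 * s10)
            # dV/dr / r: d/dr [5 s^12 - 6 s^10] = (-60 s^12 + 60 s^10)/r
            f = eps * 60.0 * (s12 - s10) / r2
        else:
            energy += eps * s12
            f = eps * 12.0 * s12 / r2
        forces[i, 0] -= f * dx
        forces[i, 1] -= f * dy
        forces[i, 2] -= f * dz
        forces[j, 0] += f * dx
        forces[j, 1] += f * dy
        forces[j, 2] += f * dz
    return energy


@numba.njit(cache=True)
def _integrate_chunk(coords, vels, dt, c1, c2, noise,
                     bonds, bond_r0, angles, theta0, dihedrals, phi0,
                     pair_i, pair_j, pair_sigma, pair_native, eps, forces):
    """BAOAB Langevin steps; noise is (n_steps, n, 3) standard normals
    pre-scaled by sqrt(T).  Returns the potential energy after the
    chunk, or inf on singular configurations."""
    n_steps = noise.shape[0]
    half = 0.5 * dt
    energy = 0.0
    for s in range(n_steps):
        for i in range(coords.shape[0]):
            for c in range(3):
                vels[i, c] += half * forces[i, c]
                coords[i, c] += half * vels[i, c]
                vels[i, c] = c1 * vels[i, c] + c2 * noise[s, i, c]
                coords[i, c] += half * vels[i, c]
        energy = _forces(coords, bonds, bond_r0, angles, theta0, dihedrals,
                         phi0, pair_i, pair_j, pair_sigma, pair_native, eps,
                         forces)
        if not math.isfinite(energy):
            return energy
        for i in range(coords.shape[0]):
            for c in range(3):
                vels[i, c] += half * forces[i, c]
    return energy


def _force_args(top: NativeTopology):
    pi, pj, sig, nat = top.nonbonded_pairs()
    return (top.bonds.astype(np.int64), top.bond_r0.astype(float),
            top.angles.astype(np.int64), top.angle_theta0.astype(float),
            top.dihedrals.astype(np.int64), top.dihedral_phi0.astype(float),
            pi, pj, sig, nat, float(top.epsilon))


def potential_energy(topology: NativeTopology, coords: np.ndarray):
    """Total potential energy (ε) and analytic forces (ε/Å)."""
    coords = np.ascontiguousarray(coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates")
    forces = np.empty_like(coords)
    e = _forces(coords, *_force_args(topology), forces)
    if not np.isfinite(e):
        raise SingularConfigurationError("overlapping beads")
    return float(e), forces


def fraction_native_contacts(topology: NativeTopology, coords: np.ndarray,
                             tolerance_factor: float = 1.2) -> float:
    """Q: fraction of native contacts with r_ij < tolerance_factor × σ_ij."""
    if topology.n_contacts == 0:
        raise NoContactsError("no contacts defined")
    coords = np.asarray(coords, float)
    i = topology.contacts[:, 0]
    j = topology.contacts[:, 1]
    r = np.linalg.norm(coords[i] - coords[j], axis=1)
    return float(np.mean(r < tolerance_factor * topology.contact_sigma))


def contact_distances(topology: NativeTopology, coords: np.ndarray) -> np.ndarray:
    i = topology.contacts[:, 0]
    j = topology.contacts[:, 1]
    return np.linalg.norm(np.asarray(coords, float)[i] - coords[j], axis=1)


def extended_conformation(topology: NativeTopology, seed: int = 0) -> np.ndarray:
    """Near-straight self-avoiding start: beads along x with seeded jitter."""
    rng = np.random.default_rng(seed)
    n = topology.n_residues
    spacing = float(topology.bond_r0.mean())
    coords = np.zeros((n, 3))
    coords[:, 0] = spacing * np.arange(n)
    coords[:, 1:] = rng.normal(scale=0.3, size=(n, 2))
    return coords


def run_trajectory(topology: NativeTopology, params: SimParams,
                   initial="native") -> Trajectory:
    """Run seeded Langevin dynamics and record frames with Q online.

    ``initial`` may be ``"native"``, ``"extended"`` (seeded near-straight
    self-avoiding conformation), or an explicit (n, 3) array.  On
    numerical blow-up (non-finite energy or coordinates beyond 1e6 Å)
    the run aborts and returns the frames collected so far with
    ``diverged=True``.
    """
    if isinstance(initial, str):
        if initial == "native":
            coords = topology.native_coords.copy()
        elif initial == "extended":
            coords = extended_conformation(topology, seed=params.seed)
        else:
            raise ValueError(f"unknown initial conformation {initial!r}")
    else:
        coords = np.array(initial, dtype=float)
        if coords.shape != (topology.n_residues, 3):
            raise ValueError("initial coordinates have wrong shape")
    coords = np.ascontiguousarray(coords)

    rng = np.random.default_rng(params.seed)
    n = topology.n_residues
    vels = rng.normal(scale=math.sqrt(max(params.temperature, 0.0)), size=(n, 3))
    c1 = math.exp(-params.friction * params.dt)
    c2 = math.sqrt((1.0 - c1 * c1) * max(params.temperature, 0.0))

    args = _force_args(topology)
    forces = np.empty_like(coords)
    e0 = _forces(coords, *args, forces)
    if not np.isfinite(e0):
        raise SingularConfigurationError("initial configuration singular")

    def q_of(x):
        # contact-less topologies (e.g. a dimer used for integrator checks)
        # have no defined Q
        if topology.n_contacts == 0:
            return math.nan
        return fraction_native_contacts(topology, x)

    frames = [coords.copy()]
    times = [0]
    qs = [q_of(coords)]
    kin = [0.5 * float((vels**2).sum())]
    diverged = False
    step = 0
    while step < params.n_steps:
        chunk = min(params.save_every, params.n_steps - step)
        noise = rng.standard_normal((chunk, n, 3))
        e = _integrate_chunk(coords, vels, params.dt, c1, c2, noise, *args,
                             forces)
        step += chunk
        if not np.isfinite(e) or np.abs(coords).max() > 1e6:
            warnings.warn(f"integration diverged at step {step}", stacklevel=2)
            diverged = True
            break
        frames.append(coords.copy())
        times.append(step)
        qs.append(q_of(coords))
        kin.append(0.5 * float((vels**2).sum()))
    return Trajectory(
        frames=np.array(frames), times=np.array(times), q=np.array(qs),
        topology=topology, diverged=diverged, final_velocities=vels.copy(),
        kinetic=np.array(kin),
    )
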