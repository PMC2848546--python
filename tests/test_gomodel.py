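"""Structure-based Cα model: topology construction, forces, dynamics."""

import math

import numpy as np
import pytest

from knotfold.gomodel import (
    K_BOND,
    NativeTopology,
    NoContactsError,
    SimParams,
    SingularConfigurationError,
    build_topology,
    build_topology_from_ca,
    extended_conformation,
    fraction_native_contacts,
    potential_energy,
    run_trajectory,
)

TWO_RESIDUE_PDB = """\
ATOM      1  N   ALA A   1       0.000   1.200   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       1.400   0.000   0.600  1.00  0.00           C
ATOM      4  N   ALA A   2       2.500   0.100   0.100  1.00  0.00           N
ATOM      5  CA  ALA A   2       3.800   0.000   0.000  1.00  0.00           C
END
"""


def ideal_ca_helix(n=20, radius=2.3, rise=1.5, turn_deg=100.0):
    t = np.deg2rad(turn_deg) * np.arange(n)
    return np.stack([radius * np.cos(t), radius * np.sin(t), rise * np.arange(n)],
                    axis=1)


class TestBuildTopology:
    def test_two_residue_fixture(self):
        top = build_topology(TWO_RESIDUE_PDB, "A")
        assert top.n_residues == 2
        assert len(top.bonds) == 1
        assert len(top.angles) == 0
        assert len(top.dihedrals) == 0
        assert top.n_contacts == 0

    def test_heavy_atom_contact_rule(self):
        # residues 1 and 4 share a close side-chain pair; 1 and 3 are near
        # in Cα distance but |i-j| >= 3 excludes nothing here except the
        # bonded neighbourhood.  The CB of residue 4 is placed 4.0 Å from
        # the CB of residue 1.
        lines = []
        serial = 1
        ca = [(0, 0, 0), (3.8, 0, 0), (7.6, 0, 0), (11.4, 0, 0), (15.2, 0, 0)]
        cb = [(0, 3, 0), (3.8, 3, 0), (7.6, 3, 0), (0.0, 7.0, 0), (15.2, 3, 0)]
        for i, (cai, cbi) in enumerate(zip(ca, cb), start=1):
            for name, xyz in (("CA", cai), ("CB", cbi)):
                lines.append(
                    f"ATOM  {serial:5d}  {name:<3s} ALA A{i:4d}    "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00           C"
                )
                serial += 1
        pdb = "\n".join(lines) + "\nEND\n"
        top = build_topology(pdb, "A", contact_cutoff=4.5)
        assert [tuple(c) for c in top.contacts] == [(0, 3)]
        # sigma is the native Cα–Cα distance, not the heavy-atom distance
        np.testing.assert_allclose(top.contact_sigma, [11.4])

    def test_ca_helix_contacts_are_i3_i4(self):
        top = build_topology_from_ca(ideal_ca_helix(), contact_cutoff=7.5)
        offsets = {j - i for i, j in top.contacts}
        assert offsets == {3, 4}

    def test_gapped_chain_refused_without_bridge(self):
        from conftest import ALTLOC_GAP_PDB

        with pytest.raises(ValueError, match="gap"), pytest.warns(UserWarning):
            build_topology(ALTLOC_GAP_PDB, "A")


@pytest.fixture(scope="module")
def small_top():
    rng = np.random.default_rng(8)
    walk = np.cumsum(
        rng.normal(size=(14, 3)) * [1.0, 1.0, 1.0]
        + np.array([3.0, 0.5, 0.0]), axis=0)
    return build_topology_from_ca(walk, contact_cutoff=9.0)


class TestPotentialEnergy:
    def test_native_contact_energy_is_minus_n_contacts(self, small_top):
        e, _ = potential_energy(small_top, small_top.native_coords)
        # bonded terms vanish at native geometry; each 10-12 term sits at -ε;
        # only the non-native repulsion adds a small positive tail
        pi, pj, sigma, is_native = small_top.nonbonded_pairs()
        d = np.linalg.norm(
            small_top.native_coords[pi] - small_top.native_coords[pj], axis=1)
        repulsion = np.sum((sigma[is_native == 0] / d[is_native == 0]) ** 12)
        np.testing.assert_allclose(e, -small_top.n_contacts + repulsion,
                                   atol=1e-9)

    def test_single_bond_stretch_closed_form(self):
        native = np.array([[0.0, 0, 0], [3.8, 0, 0]])
        top = build_topology_from_ca(native)
        delta = 0.37
        stretched = np.array([[0.0, 0, 0], [3.8 + delta, 0, 0]])
        e, f = potential_energy(top, stretched)
        np.testing.assert_allclose(e, K_BOND * delta**2, rtol=1e-12)
        np.testing.assert_allclose(f[1, 0], -2 * K_BOND * delta, rtol=1e-12)

    def test_forces_match_central_differences(self, small_top):
        rng = np.random.default_rng(0)
        x = small_top.native_coords + rng.normal(scale=0.25,
                                                 size=(small_top.n_residues, 3))
        _, analytic = potential_energy(small_top, x)
        h = 1e-6
        numeric = np.zeros_like(analytic)
        for i in range(small_top.n_residues):
            for c in range(3):
                xp, xm = x.copy(), x.copy()
                xp[i, c] += h
                xm[i, c] -= h
                numeric[i, c] = -(potential_energy(small_top, xp)[0]
                                  - potential_energy(small_top, xm)[0]) / (2 * h)
        err = np.abs(analytic - numeric).max() / np.abs(numeric).max()
        assert err < 1e-5

    def test_overlapping_beads_rejected(self, small_top):
        x = small_top.native_coords.copy()
        x[5] = x[9]
        with pytest.raises(SingularConfigurationError):
            potential_energy(small_top, x)


class TestFractionNativeContacts:
    def test_native_is_one_extended_is_zero(self, small_top):
        assert fraction_native_contacts(small_top, small_top.native_coords) == 1.0
        ext = extended_conformation(small_top, seed=1)
        assert fraction_native_contacts(small_top, ext) == 0.0

    def test_half_formed_constructed(self):
        # 8-bead chain with exactly two contacts; place one at its native
        # distance and push the other to three sigma
        coords = np.zeros((8, 3))
        coords[:, 0] = 3.8 * np.arange(8)
        coords[0, 1] = 0.3
        top = build_topology_from_ca(coords, contact_cutoff=0.0)
        top.contacts = np.array([[0, 4], [2, 7]])
        top.contact_sigma = np.array([
            np.linalg.norm(coords[0] - coords[4]),
            np.linalg.norm(coords[2] - coords[7]) / 3.0,  # native dist = 3 sigma
        ])
        assert fraction_native_contacts(top, coords) == 0.5

    def test_no_contacts_error(self):
        coords = np.zeros((5, 3))
        coords[:, 0] = 3.8 * np.arange(5)
        top = build_topology_from_ca(coords, contact_cutoff=0.0)
        with pytest.raises(NoContactsError):
            fraction_native_contacts(top, coords)


class TestDynamics:
    def test_seed_determinism_bitwise(self, small_top):
        p = SimParams(temperature=0.5, n_steps=20_000, save_every=5_000, seed=7)
        t1 = run_trajectory(small_top, p, initial="native")
        t2 = run_trajectory(small_top, p, initial="native")
        assert np.array_equal(t1.frames, t2.frames)
        assert np.array_equal(t1.q, t2.q)

    def test_energy_conservation_without_thermostat(self, small_top):
        """γ=0, thermostat off: the integrator is plain velocity Verlet and
        total energy drift stays small over 1e5 steps."""
        p = SimParams(temperature=0.2, n_steps=100_000, friction=0.0,
                      dt=0.001, save_every=100_000, seed=3)
        traj = run_trajectory(small_top, p, initial="native")
        assert not traj.diverged
        e_start, _ = potential_energy(small_top, traj.frames[0])
        e_end, _ = potential_energy(small_top, traj.frames[-1])
        total_start = e_start + traj.kinetic[0]
        total_end = e_end + traj.kinetic[-1]
        scale = max(abs(total_start), traj.kinetic[0], 1.0)
        assert abs(total_end - total_start) / scale < 1e-4

    def test_equipartition_in_native_basin(self, small_top):
        T = 0.4
        p = SimParams(temperature=T, n_steps=400_000, save_every=1_000, seed=11)
        traj = run_trajectory(small_top, p, initial="native")
        dof = 3 * small_top.n_residues
        ke_per_dof = traj.kinetic[10:] / dof
        assert np.mean(ke_per_dof) == pytest.approx(T / 2, rel=0.05)

    def test_harmonic_bond_fluctuation_closed_form(self):
        """⟨(r-r0)²⟩ = k_BT / (2 K_r) for a thermostatted dimer."""
        native = np.array([[0.0, 0, 0], [3.8, 0, 0]])
        top = build_topology_from_ca(native)
        T = 0.5
        p = SimParams(temperature=T, n_steps=4_000_000, friction=2.0,
                      dt=0.002, save_every=200, seed=5)
        traj = run_trajectory(top, p, initial="native")
        r = np.linalg.norm(traj.frames[:, 1] - traj.frames[:, 0], axis=1)
        x2 = np.mean((r[50:] - 3.8) ** 2)
        assert x2 == pytest.approx(T / (2 * K_BOND), rel=0.02)

    def test_divergence_aborts_with_partial_frames(self, small_top):
        # absurd temperature with the maximum time step blows up quickly
        p = SimParams(temperature=20000.0, n_steps=50_000, dt=0.01,
                      save_every=1_000, seed=2)
        with pytest.warns(UserWarning, match="diverged"):
            traj = run_trajectory(small_top, p, initial="extended")
        assert traj.diverged
        assert len(traj) >= 1

    def test_native_basin_stable_at_folding_temperature(self):
        from knotfold.synthetic import (
            TOY_CONTACT_CUTOFF,
            TOY_FOLDING_TEMPERATURE,
            make_toy_knotted_protein,
        )

        toy = make_toy_knotted_protein(seed=0)
        top = build_topology_from_ca(toy, contact_cutoff=TOY_CONTACT_CUTOFF)
        p = SimParams(temperature=TOY_FOLDING_TEMPERATURE, n_steps=300_000,
                      save_every=30_000, seed=9)
        traj = run_trajectory(top, p, initial="native")
        assert np.all(traj.q > 0.8)
        assert traj.q[-1] > 0.85
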