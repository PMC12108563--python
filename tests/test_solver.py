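"""FE solver: element kernels, closed-form oracles, ties, contact."""

import numpy as np
import pytest

from tmjfem.core import LabelVolume
from tmjfem.materials import ElementMaterialField
from tmjfem.meshing import (EDGES, define_node_sets, interface_facets,
                            mesh_from_labels, part_boundary_facets,
                            split_interface)
from tmjfem.solver import (ContactPair, LoadCase, apply_bonded_mpc,
                           distribute_load, element_stiffness, solve_contact,
                           solve_linear)

from conftest import end_sets, make_block_mesh, uniform_material


def reference_tet10():
    n4 = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
    return np.vstack([n4] + [0.5 * (n4[a] + n4[b]) for a, b in EDGES])


class TestElementStiffness:
    def test_symmetric(self):
        K = element_stiffness(reference_tet10(), 1000.0, 0.3)
        assert np.abs(K - K.T).max() < 1e-9 * np.abs(K).max()

    def test_rigid_translation_gives_zero_force(self):
        K = element_stiffness(reference_tet10(), 1000.0, 0.3)
        u = np.tile([1.0, -2.0, 0.5], 10)
        assert np.abs(K @ u).max() < 1e-9 * np.abs(K).max()

    def test_exactly_six_zero_energy_modes(self):
        K = element_stiffness(reference_tet10(), 1000.0, 0.3)
        w = np.linalg.eigvalsh(K)
        assert (w < 1e-9 * w[-1]).sum() == 6
        assert w[6] > 1e-9 * w[-1]

    def test_inverted_element_rejected(self):
        n10 = reference_tet10() * np.array([-1.0, 1.0, 1.0])  # mirrored
        with pytest.raises(ValueError, match="Jacobian"):
            element_stiffness(n10, 1000.0, 0.3)


class TestDistributeLoad:
    def test_node_set_equal_split(self):
        m = make_block_mesh(2, 2, 2)
        m.node_sets["ten"] = np.arange(10)
        f = distribute_load(m, "ten", (0, 0, -450.0))
        assert np.allclose(f[np.arange(10)], (0, 0, -45.0))
        assert np.allclose(f.sum(axis=0), (0, 0, -450.0), atol=1e-12)

    def test_sum_conserved_for_surface_sets(self):
        m = make_block_mesh(3, 3, 4)
        end_sets(m, "block")
        f = distribute_load(m, "tip", (3.0, -2.0, 7.0))
        assert np.allclose(f.sum(axis=0), (3.0, -2.0, 7.0), atol=1e-12)

    def test_facet_shares_proportional_to_area(self):
        # two facets, one with twice the area: shares 1/3 and 2/3
        nodes = np.array([
            [0, 0, 0], [1, 0, 0], [0, 1, 0],       # area 1/2
            [5, 0, 0], [7, 0, 0], [5, 1, 0],       # area 1
            [0.5, 0, 0], [0.5, 0.5, 0], [0, 0.5, 0],
            [6, 0, 0], [6, 0.5, 0], [5, 0.5, 0]])
        facets = np.array([[0, 1, 2, 6, 7, 8], [3, 4, 5, 9, 10, 11]])
        m = make_block_mesh(1, 1, 1)
        m.nodes = nodes
        m.surface_sets = {"s": facets}
        m.node_sets = {}
        f = distribute_load(m, "s", (0, 0, 9.0))
        small = f[[6, 7, 8], 2].sum()
        large = f[[9, 10, 11], 2].sum()
        assert small == pytest.approx(3.0, rel=1e-12)
        assert large == pytest.approx(6.0, rel=1e-12)

    def test_empty_set_rejected(self):
        m = make_block_mesh(1, 1, 1)
        with pytest.raises(ValueError):
            distribute_load(m, "nope", (1, 0, 0))


class TestClosedFormBars:
    def test_uniaxial_bar_tip_displacement(self):
        # delta = FL/(EA): L=10, A=4, E=1000, F=40 -> 0.1
        m = make_block_mesh(2, 2, 10)
        end_sets(m, "block")
        mat = uniform_material(m, E=1000.0, nu=0.0)
        lc = LoadCase(dirichlet=[dict(set="base", components=(0, 1, 2))],
                      loads=[dict(set="tip", total=(0, 0, 40.0))])
        sol = solve_linear(m, mat, lc)
        tip = np.unique(m.surface_sets["tip"])
        assert sol.displacements[tip, 2].mean() == pytest.approx(0.1, rel=1e-6)
        assert np.allclose(sol.stress[:, :, 2], 10.0, rtol=1e-6)

    def test_two_segment_bar_series_compliance(self):
        # E1 for z<5, E2 for z>=5: delta = F(L1/E1A + L2/E2A)
        lab = np.ones((2, 2, 10), np.int16)
        lab[:, :, 5:] = 2
        m = mesh_from_labels(LabelVolume(lab, {1: "soft", 2: "stiff"},
                                         spacing=1.0))
        end_sets(m, "soft")
        fb = part_boundary_facets(m, "stiff")
        m.surface_sets["tip"] = fb[m.nodes[fb[:, :3]].mean(axis=1)[:, 2] > 9.4]
        E1, E2, F, A = 1000.0, 4000.0, 40.0, 4.0
        mat = ElementMaterialField(
            E=np.where(m.part_ids == 1, E1, E2), nu=np.zeros(m.n_elements))
        lc = LoadCase(dirichlet=[dict(set="base", components=(0, 1, 2))],
                      loads=[dict(set="tip", total=(0, 0, F))])
        sol = solve_linear(m, mat, lc)
        tip = np.unique(m.surface_sets["tip"])
        expected = F * (5.0 / (E1 * A) + 5.0 / (E2 * A))
        assert sol.displacements[tip, 2].mean() == pytest.approx(expected, rel=1e-6)
        # interface stress is uniform F/A in both materials
        assert np.allclose(sol.stress[:, :, 2], F / A, rtol=1e-6)

    def test_zero_load_zero_displacement(self):
        m = make_block_mesh(2, 2, 4)
        end_sets(m, "block")
        m.node_sets["one"] = np.array([int(np.unique(m.surface_sets["tip"])[0])])
        lc = LoadCase(dirichlet=[dict(set="base", components=(0, 1, 2))],
                      loads=[dict(set="one", total=(0.0, 0.0, 0.0))])
        sol = solve_linear(m, uniform_material(m), lc)
        assert np.abs(sol.displacements).max() == 0.0

    def test_insufficient_constraints_rejected(self):
        m = make_block_mesh(2, 2, 2)
        m.node_sets["pt"] = np.array([0])
        lc = LoadCase(dirichlet=[dict(set="pt", components=(0,))],
                      loads=[dict(set="pt", total=(1, 0, 0))])
        with pytest.raises(ValueError, match="constrained"):
            solve_linear(m, uniform_material(m), lc)


class TestPatchTest:
    def test_affine_boundary_displacement_gives_constant_stress(self):
        """Three-part conforming mesh reproduces a constant strain state."""
        lab = np.ones((3, 3, 3), np.int16)
        lab[:, :, 1] = 2
        lab[:, :, 2] = 3
        m = mesh_from_labels(LabelVolume(lab, {1: "a", 2: "b", 3: "c"},
                                         spacing=1.0))
        A = np.array([[1e-3, 4e-4, -2e-4],
                      [4e-4, -5e-4, 3e-4],
                      [-2e-4, 3e-4, 8e-4]])
        coords = m.nodes
        on_boundary = np.any((coords <= coords.min(0) + 1e-9)
                             | (coords >= coords.max(0) - 1e-9), axis=1)
        ids = np.nonzero(on_boundary)[0]
        m.node_sets["bnd"] = ids
        u_pre = coords[ids] @ A.T
        lc = LoadCase(dirichlet=[dict(set="bnd", components=(0, 1, 2),
                                      value=u_pre)])
        sol = solve_linear(m, uniform_material(m, E=2000.0, nu=0.3), lc)
        # interior displacement continues the affine field
        expect = coords @ A.T
        err = np.abs(sol.displacements - expect).max() / np.abs(expect).max()
        assert err < 1e-8
        s = sol.stress.reshape(-1, 6)
        spread = np.abs(s - s.mean(axis=0)).max() / np.abs(s).max()
        assert spread < 1e-8


class TestEquilibriumAndObjectivity:
    def test_reactions_balance_applied_loads(self):
        m = make_block_mesh(2, 2, 6)
        end_sets(m, "block")
        lc = LoadCase(dirichlet=[dict(set="base", components=(0, 1, 2))],
                      loads=[dict(set="tip", total=(5.0, -3.0, 11.0))])
        sol = solve_linear(m, uniform_material(m), lc)
        gap = sol.equilibrium_gap()
        assert np.abs(gap).max() < 1e-8 * np.abs(sol.applied).sum()

    def test_frame_objectivity_under_rigid_rotation(self):
        ang = 0.6
        R = np.array([[np.cos(ang), -np.sin(ang), 0],
                      [np.sin(ang), np.cos(ang), 0], [0, 0, 1.0]])
        m1 = make_block_mesh(2, 2, 5)
        end_sets(m1, "block")
        lc1 = LoadCase(dirichlet=[dict(set="base", components=(0, 1, 2))],
                       loads=[dict(set="tip", total=(3.0, 1.0, 8.0))])
        sol1 = solve_linear(m1, uniform_material(m1), lc1)

        m2 = make_block_mesh(2, 2, 5)
        end_sets(m2, "block")
        m2.nodes = m2.nodes @ R.T
        lc2 = LoadCase(dirichlet=[dict(set="base", components=(0, 1, 2))],
                       loads=[dict(set="tip", total=R @ (3.0, 1.0, 8.0))])
        sol2 = solve_linear(m2, uniform_material(m2), lc2)
        expect = sol1.displacements @ R.T
        err = np.abs(sol2.displacements - expect).max()
        assert err < 1e-8 * np.abs(expect).max()


class TestBondedTies:
    def _column(self, split=True):
        lab = np.ones((2, 2, 6), np.int16)
        lab[:, :, 3:] = 2
        m = mesh_from_labels(LabelVolume(lab, {1: "lo", 2: "hi"}, spacing=1.0))
        iface = interface_facets(m, "lo", "hi")
        if split:
            m, pairs = split_interface(m, "lo", "hi")
        else:
            pairs = None
        end_sets(m, "lo")
        fb = part_boundary_facets(m, "hi")
        m.surface_sets["tip"] = fb[m.nodes[fb[:, :3]].mean(axis=1)[:, 2] > 5.4]
        return m, iface, pairs

    def test_conforming_interface_emits_no_equations(self):
        m, iface, _ = self._column(split=False)
        slaves = np.unique(iface)
        cons = apply_bonded_mpc(m, slaves, iface)
        assert cons == []

    def test_tied_column_matches_merged_column(self):
        ms, iface, pairs = self._column(split=True)
        cons = apply_bonded_mpc(ms, pairs[:, 1], iface)
        assert len(cons) == len(pairs)
        lc = LoadCase(dirichlet=[dict(set="base", components=(0, 1, 2))],
                      loads=[dict(set="tip", total=(0, 0, -36.0))], ties=cons)
        sol_tied = solve_contact(ms, uniform_material(ms, nu=0.0), lc)

        mm, _, _ = self._column(split=False)
        lcm = LoadCase(dirichlet=[dict(set="base", components=(0, 1, 2))],
                       loads=[dict(set="tip", total=(0, 0, -36.0))])
        sol_merged = solve_linear(mm, uniform_material(mm, nu=0.0), lcm)
        ref = np.abs(sol_merged.stress).max()
        assert np.abs(sol_tied.stress - sol_merged.stress).max() < 1e-8 * ref

    def test_rigid_translation_of_tied_assembly_has_zero_violation(self):
        ms, iface, pairs = self._column(split=True)
        cons = apply_bonded_mpc(ms, pairs[:, 1], iface)
        shift = np.array([0.3, -0.2, 0.7])
        for c in cons:
            # slave displacement interpolated from masters equals the rigid
            # shift exactly
            interp = np.sum(c["weights"][:, None] * np.tile(shift, (len(c["weights"]), 1)), axis=0)
            assert np.allclose(interp, shift, atol=1e-12)

    def test_far_slave_rejected_with_location(self):
        m, iface, pairs = self._column(split=True)
        far = m.nodes.shape[0] - 1
        m.nodes[far] = (100.0, 100.0, 100.0)
        with pytest.raises(ValueError, match="capture"):
            apply_bonded_mpc(m, np.array([far]), iface, capture_distance=1.0)


class TestContact:
    def _stack(self, gap_voxels=0):
        nz = 6 + gap_voxels
        lab = np.zeros((3, 3, nz), np.int16)
        lab[:, :, :3] = 1
        lab[:, :, 3 + gap_voxels:] = 2
        m0 = mesh_from_labels(LabelVolume(lab, {1: "lower", 2: "upper"},
                                          spacing=1.0))
        if gap_voxels == 0:
            iface = interface_facets(m0, "lower", "upper")
            m, pairs = split_interface(m0, "lower", "upper")
        else:
            fb = part_boundary_facets(m0, "lower")
            iface = fb[m0.nodes[fb[:, :3]].mean(axis=1)[:, 2] > 2.4]
            m = m0
            pairs = np.stack([np.unique(iface), m0.part_nodes("upper")[:len(np.unique(iface))]], axis=1)
        define_node_sets(m, {
            "bot": dict(type="box", lo=(-9, -9, -0.6), hi=(9, 9, -0.4)),
            "top_xy": dict(type="box", lo=(-9, -9, nz - 0.6), hi=(9, 9, nz))})
        fb = part_boundary_facets(m, "upper")
        m.surface_sets["top"] = fb[m.nodes[fb[:, :3]].mean(axis=1)[:, 2] > nz - 0.6]
        return m, iface, pairs

    def test_separated_bodies_no_contact_force(self):
        # upper body fully fixed, lower loaded sideways: gap never closes
        m, iface, _ = self._stack(gap_voxels=2)
        define_node_sets(m, {"upper_all": dict(type="box", lo=(-9, -9, 4.4),
                                               hi=(9, 9, 99))})
        slaves = m.part_nodes("upper")
        slaves = slaves[m.nodes[slaves, 2] < 4.6]
        lc = LoadCase(
            dirichlet=[dict(set="bot", components=(0, 1, 2)),
                       dict(set="upper_all", components=(0, 1, 2))],
            loads=[dict(set="top", total=(0.0, 0.0, 5.0))],
            contact=[ContactPair(slave_nodes=slaves, master_facets=iface,
                                 friction=0.3)])
        sol = solve_contact(m, uniform_material(m), lc)
        assert sol.diagnostics["active_nodes"] == 0

    def test_flat_on_flat_uniform_pressure(self):
        m, iface, pairs = self._stack()
        lc = LoadCase(
            dirichlet=[dict(set="bot", components=(0, 1, 2)),
                       dict(set="top_xy", components=(0, 1))],
            loads=[dict(set="top", total=(0, 0, -90.0))],  # 10 MPa on 3x3
            contact=[ContactPair(slave_nodes=pairs[:, 1], master_facets=iface,
                                 friction=0.0)])
        sol = solve_contact(m, uniform_material(m, nu=0.0), lc)
        szz = sol.stress[:, :, 2]
        assert np.allclose(szz, -10.0, rtol=0.05)
        assert np.abs(sol.equilibrium_gap()).max() < 1e-8 * 90.0
        assert sol.diagnostics["max_penetration"] <= 1e-3  # gap tolerance

    def test_stuck_interface_does_not_slide(self):
        # tangential load below mu * normal load: slip below tolerance
        m, iface, pairs = self._stack()
        lc = LoadCase(
            dirichlet=[dict(set="bot", components=(0, 1, 2))],
            # |T| well below mu*N even after the overturning moment
            # redistributes the normal pressure across the interface
            loads=[dict(set="top", total=(4.0, 0.0, -90.0))],
            contact=[ContactPair(slave_nodes=pairs[:, 1], master_facets=iface,
                                 friction=0.3)])
        sol = solve_contact(m, uniform_material(m, nu=0.0), lc)
        # the interface as a whole sticks: relative tangential motion stays
        # below tolerance everywhere (a few corner nodes may report "slip"
        # because quadratic facets route normal force through the midside
        # nodes, but they carry no load and do not move)
        slip = sol.displacements[pairs[:, 1], 0] - sol.displacements[pairs[:, 0], 0]
        assert np.abs(slip).max() < 1e-3
        assert sol.diagnostics["slipping_nodes"] <= len(pairs) // 4
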