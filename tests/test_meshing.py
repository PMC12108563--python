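"""Voxel-to-C3D10 meshing, node sets, downsampling and file writers."""

import numpy as np
import pytest

from tmjfem.core import LabelVolume
from tmjfem.materials import ElementMaterialField
from tmjfem.meshing import (define_node_sets, downsample_labels,
                            interface_facets, mesh_from_labels,
                            part_boundary_facets, read_inp, split_interface,
                            write_mesh)

from conftest import make_block_mesh


class TestMeshFromLabels:
    def test_single_voxel_gives_6_tets_27_nodes(self):
        lab = np.zeros((3, 3, 3), np.int16)
        lab[1, 1, 1] = 1
        m = mesh_from_labels(LabelVolume(lab, {1: "a"}, spacing=0.5))
        m.validate()
        assert m.n_elements == 6
        assert m.n_nodes == 27  # 8 corners + 19 unique edge midpoints

    def test_element_volumes_sum_to_voxel_volume_exactly(self):
        rng = np.random.default_rng(0)
        lab = (rng.random((6, 5, 4)) > 0.5).astype(np.int16)
        lv = LabelVolume(lab, {1: "a"}, spacing=0.7)
        m = mesh_from_labels(lv)
        expected = lab.sum() * 0.7 ** 3
        assert m.corner_volumes().sum() == pytest.approx(expected, rel=1e-12)

    def test_adjacent_voxels_of_different_parts_share_interface_nodes(self):
        lab = np.zeros((2, 1, 1), np.int16)
        lab[0] = 1
        lab[1] = 2
        m = mesh_from_labels(LabelVolume(lab, {1: "a", 2: "b"}, spacing=1.0))
        # conforming: 27 + 27 - 9 shared face nodes
        assert m.n_nodes == 45
        # node coordinates are unique (deduplicated by lattice key)
        assert len(np.unique(np.round(m.nodes, 9), axis=0)) == m.n_nodes

    def test_no_orphan_nodes(self):
        m = make_block_mesh(3, 3, 3)
        m.validate()

    def test_all_jacobians_positive(self):
        m = make_block_mesh(2, 2, 2, spacing=0.3)
        assert np.all(m.corner_volumes() > 0)

    def test_empty_labels_rejected(self):
        with pytest.raises(ValueError):
            mesh_from_labels(LabelVolume(np.zeros((2, 2, 2), np.int16),
                                         {1: "a"}))


class TestDownsample:
    def test_uniform_block_downsamples_to_same_label(self):
        lab = np.ones((8, 8, 8), np.int16)
        lv = LabelVolume(lab, {1: "a"}, spacing=0.5)
        out = downsample_labels(lv, 2)
        assert out.data.shape == (4, 4, 4)
        assert np.all(out.data == 1)
        assert np.allclose(out.spacing, 1.0)

    def test_weight_lets_minority_part_survive(self):
        lab = np.ones((4, 4, 4), np.int16)
        lab[0, 0, :2] = 2  # 2 of 64 voxels in the block
        lv = LabelVolume(lab, {1: "bone", 2: "screw"}, spacing=1.0)
        plain = downsample_labels(lv, 4)
        weighted = downsample_labels(lv, 4, weights={2: 40.0})
        assert np.all(plain.data == 1)
        assert np.all(weighted.data == 2)

    def test_majority_vote_without_weights(self):
        lab = np.ones((2, 2, 2), np.int16)
        lab[0, 0, 0] = 2
        lv = LabelVolume(lab, {1: "a", 2: "b"}, spacing=1.0)
        assert np.all(downsample_labels(lv, 2).data == 1)


class TestNodeSets:
    def test_sphere_predicate_members_inside(self):
        m = make_block_mesh(4, 4, 4)
        define_node_sets(m, {"s": dict(type="sphere", center=(1.5, 1.5, 1.5),
                                       radius=1.0)})
        ids = m.node_sets["s"]
        assert len(ids) > 0
        assert np.all(np.linalg.norm(m.nodes[ids] - 1.5, axis=1) <= 1.0)

    def test_off_volume_predicate_gives_empty_set(self):
        m = make_block_mesh(3, 3, 3)
        define_node_sets(m, {"far": dict(type="sphere", center=(99, 99, 99),
                                         radius=1.0)})
        assert len(m.node_sets["far"]) == 0

    def test_union_of_disjoint_predicates_adds(self):
        m = make_block_mesh(6, 2, 2)
        define_node_sets(m, {
            "a": dict(type="box", lo=(-1, -1, -1), hi=(1.0, 3, 3)),
            "b": dict(type="box", lo=(3.0, -1, -1), hi=(9, 3, 3)),
            "ab": dict(type="box", lo=(-1, -1, -1), hi=(9, 3, 3)),
        })
        a, b, ab = (m.node_sets[k] for k in ("a", "b", "ab"))
        # brute-force scan oracle
        inside = lambda lo, hi: np.nonzero(
            np.all((m.nodes >= lo) & (m.nodes <= hi), axis=1))[0]
        assert np.array_equal(np.sort(a), inside((-1, -1, -1), (1.0, 3, 3)))
        gap = inside((1.0 + 1e-9, -1, -1), (3.0 - 1e-9, 3, 3))
        assert len(a) + len(b) + len(gap) == len(ab)


class TestBoundaryFacets:
    def test_cube_boundary_face_count(self):
        m = make_block_mesh(2, 2, 2)
        f = part_boundary_facets(m, "block")
        # 6 faces x 4 voxel-faces x 2 triangles
        assert len(f) == 48

    def test_interface_facets_between_parts(self):
        lab = np.zeros((2, 2, 2), np.int16)
        lab[0] = 1
        lab[1] = 2
        m = mesh_from_labels(LabelVolume(lab, {1: "a", 2: "b"}, spacing=1.0))
        f = interface_facets(m, "a", "b")
        assert len(f) == 8  # 4 voxel faces x 2 triangles
        # all facet nodes lie on the interface plane x = 0.5
        assert np.allclose(m.nodes[np.unique(f)][:, 0], 0.5)


class TestSplitInterface:
    def test_split_duplicates_only_shared_nodes(self):
        lab = np.zeros((2, 1, 1), np.int16)
        lab[0], lab[1] = 1, 2
        m = mesh_from_labels(LabelVolume(lab, {1: "a", 2: "b"}, spacing=1.0))
        m2, pairs = split_interface(m, "a", "b")
        assert len(pairs) == 9
        assert m2.n_nodes == m.n_nodes + 9
        assert np.allclose(m2.nodes[pairs[:, 0]], m2.nodes[pairs[:, 1]])
        # parts no longer share nodes
        assert len(np.intersect1d(m2.part_nodes("a"), m2.part_nodes("b"))) == 0


class TestWriters:
    def test_inp_round_trip_reproduces_mesh(self, tmp_path):
        m = make_block_mesh(2, 2, 3, spacing=0.4)
        define_node_sets(m, {"top": dict(type="box", lo=(-1, -1, 0.7),
                                         hi=(2, 2, 2))})
        mat = ElementMaterialField(E=np.full(m.n_elements, 5000.0),
                                   nu=np.full(m.n_elements, 0.3))
        path = tmp_path / "mesh.inp"
        write_mesh(m, mat, path, dialect="abaqus-inp")
        back = read_inp(path)
        assert np.array_equal(back.elements, m.elements)
        assert np.allclose(back.nodes, m.nodes, atol=1e-9)
        assert np.array_equal(np.sort(back.node_sets["top"]),
                              np.sort(m.node_sets["top"]))

    def test_single_element_inp_has_one_c3d10_record(self):
        lab = np.zeros((1, 1, 1), np.int16)
        lab[0, 0, 0] = 1
        m = mesh_from_labels(LabelVolume(lab, {1: "a"}, spacing=1.0))
        m.elements = m.elements[:1]
        m.part_ids = m.part_ids[:1]
        used = np.unique(m.elements)
        remap = -np.ones(m.n_nodes, np.int64)
        remap[used] = np.arange(len(used))
        m.elements = remap[m.elements]
        m.nodes = m.nodes[used]
        text = write_mesh(m, None, dialect="abaqus-inp")
        elem_lines = [ln for ln in text.splitlines()
                      if ln and ln[0].isdigit() and ln.count(",") == 10]
        assert len(elem_lines) == 1

    def test_binning_error_below_half_bin_width(self):
        m = make_block_mesh(3, 3, 3)
        rng = np.random.default_rng(2)
        E = rng.uniform(100.0, 10000.0, m.n_elements)
        mat = ElementMaterialField(E=E, nu=np.full(m.n_elements, 0.3))
        n_bins = 100
        text = write_mesh(m, mat, dialect="abaqus-inp", n_bins=n_bins)
        # parse written per-group moduli and group membership
        import re
        groups = {}
        current = None
        for ln in text.splitlines():
            mm = re.match(r"\*ELSET, ELSET=MAT-(\d+)", ln)
            if mm:
                current = int(mm.group(1))
                groups.setdefault(current, [])
            elif ln.startswith("*"):
                current = None
            elif current is not None and ln and ln[0].isdigit():
                groups[current].extend(int(v) - 1 for v in ln.split(","))
        mods = {}
        lines = text.splitlines()
        for i, ln in enumerate(lines):
            mm = re.match(r"\*MATERIAL, NAME=MAT-(\d+)", ln)
            if mm:
                mods[int(mm.group(1))] = float(lines[i + 2].split(",")[0])
        half_bin = (E.max() - E.min()) / (2 * n_bins)
        for g, elems in groups.items():
            for e in elems:
                assert abs(mods[g] - E[e]) <= half_bin + 1e-9

    def test_vtk_output_carries_exact_moduli(self):
        m = make_block_mesh(2, 2, 2)
        E = np.linspace(100, 200, m.n_elements)
        mat = ElementMaterialField(E=E, nu=np.full(m.n_elements, 0.3))
        text = write_mesh(m, mat, dialect="vtk")
        assert "SCALARS youngs_modulus" in text
        tail = text.split("LOOKUP_TABLE default")[2].split("SCALARS")[0].split()
        assert np.allclose([float(v) for v in tail], E, rtol=1e-8)


class TestModelReduction:
    def test_coarse_merged_mesh_has_far_fewer_nodes(self, small_phantom):
        _, truth = small_phantom
        fine = mesh_from_labels(truth.labels, coarseness=2)
        coarse = mesh_from_labels(truth.labels, coarseness=4,
                                  weights={truth.labels.id_of("prosthesis"): 6.0,
                                           truth.labels.id_of("screws"): 6.0})
        assert fine.n_nodes >= 5 * coarse.n_nodes
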