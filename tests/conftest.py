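"""Shared fixtures: a small noise-free phantom and block-mesh helpers."""

import numpy as np
import pytest

from tmjfem.core import LabelVolume
from tmjfem.materials import ElementMaterialField
from tmjfem.meshing import define_node_sets, mesh_from_labels, part_boundary_facets
from tmjfem.phantom import PhantomConfig, build_phantom

SMALL_SHAPE = (60, 60, 45)
SMALL_SPACING = 0.6  # same physical extent as the default grid


@pytest.fixture(scope="session")
def small_config():
    return PhantomConfig(shape=SMALL_SHAPE, spacing=SMALL_SPACING, noise_sd=0.0)


@pytest.fixture(scope="session")
def small_phantom(small_config):
    """Noise-free half-resolution phantom shared across the suite."""
    return build_phantom(small_config)


def make_block_mesh(nx, ny, nz, spacing=1.0, parts=None):
    """Voxel block mesh; ``parts`` optionally assigns per-voxel labels."""
    lab = np.ones((nx, ny, nz), np.int16) if parts is None else parts
    names = {int(i): f"part_{i}" for i in np.unique(lab) if i > 0}
    if parts is None:
        names = {1: "block"}
    mesh = mesh_from_labels(LabelVolume(lab, names, spacing=spacing))
    return mesh


def uniform_material(mesh, E=1000.0, nu=0.3):
    return ElementMaterialField(E=np.full(mesh.n_elements, float(E)),
                                nu=np.full(mesh.n_elements, float(nu)))


def end_sets(mesh, part, axis=2):
    """Add 'base' node set and 'tip' surface set at the ends of a block."""
    lo = mesh.nodes[:, axis].min()
    hi = mesh.nodes[:, axis].max()
    box_lo = np.full(3, -1e9)
    box_hi = np.full(3, 1e9)
    box_hi[axis] = lo + 1e-9
    define_node_sets(mesh, {"base": dict(type="box", lo=tuple(box_lo),
                                         hi=tuple(box_hi))})
    fb = part_boundary_facets(mesh, part)
    c = mesh.nodes[fb[:, :3]].mean(axis=1)[:, axis]
    mesh.surface_sets["tip"] = fb[c > hi - 1e-9]
    return mesh
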