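"""Core data containers shared across the pipeline.

Conventions
-----------
* Volumes are indexed ``[i, j, k]`` and the world position of voxel centre
  ``(i, j, k)`` is ``origin + (i, j, k) * spacing`` (millimetres).  The axis
  order tag ``"xyz"`` records this identification of array axes with the
  anatomical x/y/z axes.
* Units are fixed at mm / N / MPa throughout; mass densities appear only in
  the material-mapping law, in kg/m^3 as tabulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ImageVolume",
    "Mask",
    "LabelVolume",
    "TriSurface",
    "RigidTransform",
]


def _as_vec3(x, name: str) -> np.ndarray:
    v = np.atleast_1d(np.asarray(x, dtype=float))
    if v.size == 1:
        v = np.repeat(v, 3)
    if v.shape != (3,):
        raise ValueError(f"{name} must be a scalar or length-3 vector, got {x!r}")
    return v


@dataclass
class ImageVolume:
    """Scalar voxel grid, either raw scanner units or calibrated HU."""

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    axis_order: str = "xyz"
    calibrated: bool = False

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("ImageVolume.data must be a 3D array")
        self.spacing = _as_vec3(self.spacing, "spacing")
        self.origin = _as_vec3(self.origin, "origin")
        if np.any(self.spacing <= 0):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("ImageVolume.data contains non-finite values")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of every voxel centre, shape ``(*shape, 3)``."""
        axes = [self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
                for a in range(3)]
        grid = np.meshgrid(*axes, indexing="ij")
        return np.stack(grid, axis=-1)

    def with_data(self, data: np.ndarray, calibrated: bool | None = None) -> "ImageVolume":
        return replace(self, data=np.asarray(data, dtype=float),
                       calibrated=self.calibrated if calibrated is None else calibrated)


@dataclass
class Mask:
    """Boolean voxel mask congruent with its source volume."""

    data: np.ndarray
    name: str = ""
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("Mask.data must be a 3D boolean array")
        self.spacing = _as_vec3(self.spacing, "spacing")
        self.origin = _as_vec3(self.origin, "origin")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def count(self) -> int:
        return int(self.data.sum())


@dataclass
class LabelVolume:
    """Integer per-voxel part labels; 0 is background."""

    data: np.ndarray
    names: dict
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("LabelVolume.data must be integer-typed")
        self.spacing = _as_vec3(self.spacing, "spacing")
        self.origin = _as_vec3(self.origin, "origin")
        ids = list(self.names)
        if len(set(ids)) != len(ids) or len(set(self.names.values())) != len(ids):
            raise ValueError("label ids must map one-to-one to part names")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def id_of(self, name: str) -> int:
        for k, v in self.names.items():
            if v == name:
                return int(k)
        raise KeyError(f"no part named {name!r}")

    def mask(self, name: str) -> Mask:
        return Mask(self.data == self.id_of(name), name=name,
                    spacing=self.spacing, origin=self.origin)


@dataclass
class TriSurface:
    """Triangulated surface: vertices in mm, faces as vertex-index triplets."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.faces.size and (self.faces.min() < 0 or
                                self.faces.max() >= len(self.vertices)):
            raise ValueError("face indices out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def triangles(self) -> np.ndarray:
        """Corner coordinates per face, shape (n_faces, 3, 3)."""
        return self.vertices[self.faces]

    def areas(self) -> np.ndarray:
        t = self.triangles()
        c = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
        return 0.5 * np.linalg.norm(c, axis=1)

    def area(self) -> float:
        return float(self.areas().sum())

    def enclosed_volume(self) -> float:
        """Signed volume by the divergence theorem (outward orientation > 0)."""
        t = self.triangles()
        return float(np.einsum("ij,ij->i", t[:, 0],
                               np.cross(t[:, 1], t[:, 2])).sum() / 6.0)

    def remove_degenerate(self, eps: float = 0.0) -> "TriSurface":
        keep = self.areas() > eps
        return TriSurface(self.vertices, self.faces[keep])

    def transformed(self, transform: "RigidTransform") -> "TriSurface":
        return TriSurface(transform.apply(self.vertices), self.faces.copy())

    def to_trimesh(self):
        import trimesh
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces,
                               process=False)

    @classmethod
    def from_trimesh(cls, mesh) -> "TriSurface":
        return cls(np.asarray(mesh.vertices, dtype=float),
                   np.asarray(mesh.faces, dtype=np.int64))


@dataclass
class RigidTransform:
    """Proper rigid transform x -> R x + t."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = _as_vec3(self.translation, "translation")
        err = np.abs(self.rotation @ self.rotation.T - np.eye(3)).max()
        if err > 1e-9:
            raise ValueError(f"rotation not orthonormal (|R R^T - I| = {err:.2e})")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation must be proper (det = +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_translation(cls, t) -> "RigidTransform":
        return cls(np.eye(3), t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self after other: x -> self(other(x))."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)
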