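"""CT-value -> density -> Young's-modulus mapping and element materials.

Mandibular bone is mapped element by element: the calibrated HU value is
converted linearly to an apparent density per regime (trabecular HU
[-1000, 500] -> rho [0, 1000] kg/m^3; cortical HU [501, 1500] ->
rho [1001, 2000]) and the regime's power law E = c * rho^2.01 gives the
modulus in MPa.  The tabulated intervals are implemented exactly as printed,
half-open in density with rho in [1000, 1001) assigned to the cortical law;
the resulting discontinuity at the regime boundary is a property of the
published table and is documented rather than smoothed.  Outside the printed
CT intervals, bone-mask values clamp to the nearest density endpoint (0 or
2000) since the table defines no behaviour there.  A small modulus floor
keeps stiffness matrices positive definite where the law evaluates to ~0.

Teeth are split into dentin (HU <= 2000, E = 24,535 MPa) and enamel
(HU > 2000, E = 39,605 MPa); prosthesis and screws carry Ti-6Al-4V constants
(113,800 MPa, nu = 0.342); the simplified merged-bone variant uses a uniform
10 GPa / 0.3.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy import ndimage

from .core import ImageVolume, LabelVolume

__all__ = [
    "MaterialTable",
    "ElementMaterialField",
    "load_material_table",
    "hu_to_density",
    "density_to_E",
    "classify_tooth_tissue",
    "assign_element_materials",
]


@dataclass
class MaterialTable:
    """Bone mapping regimes plus homogeneous material constants."""

    bone_regimes: list
    constants: dict
    tooth_split_hu: float = 2000.0
    modulus_floor: float = 0.01
    version: int = 1

    def __post_init__(self):
        prev_hi = -np.inf
        for reg in self.bone_regimes:
            if reg["law_coefficient"] <= 0:
                raise ValueError("power-law coefficients must be positive")
            if not 0 < reg["poisson"] < 0.5:
                raise ValueError("Poisson ratio must lie in (0, 0.5)")
            if reg["hu"][0] < prev_hi:
                raise ValueError("bone CT intervals overlap")
            prev_hi = reg["hu"][1]
        for name, c in self.constants.items():
            if c["E"] <= 0 or not 0 < c["poisson"] < 0.5:
                raise ValueError(f"invalid constants for {name}")

    def constant(self, name: str):
        c = self.constants[name]
        return c["E"], c["poisson"]


def load_material_table() -> MaterialTable:
    """Load the packaged material table asset."""
    text = resources.files("tmjfem.data").joinpath("material_table.json").read_text()
    raw = json.loads(text)
    return MaterialTable(bone_regimes=raw["bone_regimes"],
                         constants=raw["constants"],
                         tooth_split_hu=raw["tooth_split_hu"],
                         modulus_floor=raw["modulus_floor_MPa"],
                         version=raw["version"])


def hu_to_density(hu, table: MaterialTable | None = None):
    """Piecewise-linear map from calibrated HU to apparent density (kg/m^3).

    Each regime's CT interval endpoints map to its density interval
    endpoints.  Values between the printed intervals (HU in (500, 501))
    bridge linearly between the adjacent endpoints; values outside clamp.
    Monotone nondecreasing over the whole axis.
    """
    table = table or load_material_table()
    hu = np.asarray(hu, dtype=float)
    # knots built from the printed interval endpoints
    xs, ys = [], []
    for reg in table.bone_regimes:
        xs.extend(reg["hu"])
        ys.extend(reg["density"])
    rho = np.interp(hu, xs, ys)  # np.interp clamps outside the knot range
    return rho if rho.ndim else float(rho)


def density_to_E(rho, table: MaterialTable | None = None):
    """Power-law modulus E(rho) in MPa with regime selection by density.

    rho < 1000 uses the trabecular law, rho >= 1000 the cortical law (the
    half-open gap [1000, 1001) is assigned to the cortical side).  The
    configured floor is applied so E > 0 always.
    """
    table = table or load_material_table()
    rho_arr = np.asarray(rho, dtype=float)
    if np.any(rho_arr < 0):
        raise ValueError("density must be non-negative")
    trab, cort = table.bone_regimes[0], table.bone_regimes[1]
    boundary = cort["density"][0] - 1.0  # 1000: start of the cortical side
    with np.errstate(invalid="ignore"):
        e_trab = trab["law_coefficient"] * rho_arr ** trab["law_exponent"]
        e_cort = cort["law_coefficient"] * rho_arr ** cort["law_exponent"]
    E = np.where(rho_arr < boundary, e_trab, e_cort)
    E = np.maximum(E, table.modulus_floor)
    return E if E.ndim else float(E)


def classify_tooth_tissue(hu, table: MaterialTable | None = None):
    """Dentin/enamel split of tooth voxels by HU.

    HU <= 2000 -> dentin (the boundary is inclusive); HU > 2000 -> enamel.
    Returns ``(tissue_name_or_array, E, nu)``.
    """
    table = table or load_material_table()
    hu_arr = np.asarray(hu, dtype=float)
    e_den, nu = table.constant("dentin")
    e_ena, _ = table.constant("enamel")
    is_enamel = hu_arr > table.tooth_split_hu
    E = np.where(is_enamel, e_ena, e_den)
    if hu_arr.ndim == 0:
        return ("enamel" if is_enamel else "dentin"), float(E), nu
    names = np.where(is_enamel, "enamel", "dentin")
    return names, E, nu


@dataclass
class ElementMaterialField:
    """Per-element Young's modulus (MPa), Poisson ratio and provenance."""

    E: np.ndarray
    nu: np.ndarray
    provenance: np.ndarray = None  # "mapped" | "homogeneous" per element

    def __post_init__(self):
        self.E = np.asarray(self.E, dtype=float)
        self.nu = np.asarray(self.nu, dtype=float)
        if self.provenance is None:
            self.provenance = np.full(len(self.E), "homogeneous", dtype=object)
        if np.any(self.E <= 0):
            raise ValueError("every element must have E > 0")
        if len(self.E) != len(self.nu):
            raise ValueError("E and nu must have equal length")


# barycentric coordinates of the 4-point Gauss rule of the tetrahedron
_GAUSS_A = 0.5854101966249685
_GAUSS_B = 0.13819660112501052
_GAUSS_BARY = np.full((4, 4), _GAUSS_B)
np.fill_diagonal(_GAUSS_BARY, _GAUSS_A)


def _sample_hu(vol: ImageVolume, points: np.ndarray) -> np.ndarray:
    """Trilinear samples of the HU field at world points."""
    idx = (points - vol.origin) / vol.spacing
    lo = idx.min(axis=0)
    hi = idx.max(axis=0)
    limits = np.asarray(vol.shape) - 1
    if np.any(lo < -0.5) or np.any(hi > limits + 0.5):
        raise ValueError("sample points fall outside the image volume")
    coords = np.clip(idx, 0, limits).T
    return ndimage.map_coordinates(vol.data, coords, order=1, mode="nearest")


def assign_element_materials(mesh, vol: ImageVolume, labels: LabelVolume,
                             table: MaterialTable | None = None,
                             part_modes: dict | None = None,
                             aggregation: str = "quadrature") -> ElementMaterialField:
    """Per-element material assignment for a tetrahedral mesh.

    ``part_modes`` maps part name -> mode: ``"mapped"`` (HU -> density ->
    power law, for bone), ``"tooth"`` (dentin/enamel split by element HU),
    or the name of a constant in the table (``"titanium"``,
    ``"uniform_bone"``, ...).  Mapped and tooth elements sample the HU field
    trilinearly at the element's 4 quadrature points (``aggregation=
    "quadrature"``, matching where stiffness is integrated) or at the
    centroid (``aggregation="centroid"``) and aggregate by mean.
    """
    table = table or load_material_table()
    part_modes = part_modes or {}
    nel = len(mesh.elements)
    E = np.empty(nel)
    nu = np.empty(nel)
    prov = np.empty(nel, dtype=object)

    corner_xyz = mesh.nodes[mesh.elements[:, :4]]  # (nel, 4, 3)
    if aggregation == "quadrature":
        sample_pts = np.einsum("ga,nad->ngd", _GAUSS_BARY, corner_xyz)
    elif aggregation == "centroid":
        sample_pts = corner_xyz.mean(axis=1)[:, None, :]
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")

    hu_needed = any(mode in ("mapped", "tooth") for mode in part_modes.values())
    if hu_needed:
        flat = sample_pts.reshape(-1, 3)
        try:
            hu_samples = _sample_hu(vol, flat).reshape(sample_pts.shape[:2])
        except ValueError as exc:
            bad = _first_outside(vol, sample_pts)
            raise ValueError(f"element {bad} samples outside the volume") from exc
        elem_hu = hu_samples.mean(axis=1)

    for part_id, part_name in mesh.part_names.items():
        sel = mesh.part_ids == part_id
        if not sel.any():
            continue
        mode = part_modes.get(part_name, "mapped")
        if mode == "mapped":
            rho = hu_to_density(elem_hu[sel], table)
            E[sel] = density_to_E(rho, table)
            nu[sel] = table.bone_regimes[0]["poisson"]
            prov[sel] = "mapped"
        elif mode == "tooth":
            _, e_vals, nu_t = classify_tooth_tissue(elem_hu[sel], table)
            E[sel] = e_vals
            nu[sel] = nu_t
            prov[sel] = "mapped"
        else:
            e_c, nu_c = table.constant(mode)
            E[sel] = e_c
            nu[sel] = nu_c
            prov[sel] = "homogeneous"
    return ElementMaterialField(E=E, nu=nu, provenance=prov)


def _first_outside(vol, sample_pts):
    idx = (sample_pts.reshape(len(sample_pts), -1, 3) - vol.origin) / vol.spacing
    limits = np.asarray(vol.shape) - 1
    bad = np.any((idx < -0.5) | (idx > limits + 0.5), axis=(1, 2))
    hits = np.nonzero(bad)[0]
    return int(hits[0]) if hits.size else -1
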