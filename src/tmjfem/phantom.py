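"""Synthetic CT phantom of an implanted mandible.

Every downstream stage (calibration, segmentation, material mapping, meshing,
solving) is exercised on this seeded generator, so the whole pipeline is
testable without patient data.  The geometry is parametric, not anatomical: a
horseshoe (torus-sector) mandible body with a cortical shell over a
trabecular core, two rami with a natural condyle on the contralateral side
and a resected stump on the treated side, a few teeth (dentin with an enamel
cap), and a titanium prosthesis plate with a condylar head fixed by
cylindrical screws (plus two optional "dummy" screws that exist only in the
planning-stage geometry and do not reach bone).

The prosthesis and screws are rasterized from exact triangulated "CAD"
surfaces; those same surfaces are emitted as ground truth so the CAD-based
model variants and the surface-deviation stage have an exact reference.

Raw voxel values are an affine transform of Hounsfield units,
``raw = g * HU + h`` plus optional seeded Gaussian noise, so the calibration
stage has a real transform to invert; ``g`` and ``h`` are stored in the
truth record.

All geometric dimensions are fractions of the physical volume extent, so the
phantom scales consistently when a test shrinks the grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ImageVolume, LabelVolume, RigidTransform, TriSurface
from .geometry import voxelize_surface
from .wear import WearSeries

__all__ = [
    "PhantomConfig",
    "PhantomTruth",
    "PhantomError",
    "build_phantom",
    "simulate_wear_series",
    "write_volume_slices",
    "read_volume_slices",
]

# part label ids; ids map one-to-one to part names
PART_NAMES = {
    1: "mandible",
    2: "tooth_31",
    3: "tooth_33",
    4: "tooth_47",
    5: "prosthesis",
    6: "screws",
    7: "dummy_screws",
}

DEFAULT_HU = {
    "air": -1000.0,
    "soft_tissue": 0.0,   # water-equivalent, doubles as the calibration water reference
    "trabecular": 300.0,
    "cortical": 1400.0,
    "dentin": 1700.0,
    "enamel": 2500.0,
    "titanium": 3100.0,
}

_HU_ORDER = ["air", "soft_tissue", "trabecular", "cortical", "dentin",
             "enamel", "titanium"]


class PhantomError(ValueError):
    """Invalid phantom specification."""


@dataclass
class PhantomConfig:
    """Parameters of the synthetic CT volume.

    ``shape`` voxels per axis; ``spacing`` in mm (0.3 isotropic by default,
    matching a modern high-resolution mandible CT); nominal HU per tissue;
    ``noise_sd`` additive Gaussian noise in HU; ``raw_gain``/``raw_offset``
    define the raw-value affine ``raw = gain * HU + offset``.
    """

    shape: tuple = (120, 120, 90)
    spacing: float = 0.3
    hu: dict = field(default_factory=lambda: dict(DEFAULT_HU))
    noise_sd: float = 0.0
    metal_artifacts: bool = False
    seed: int = 0
    prosthesis_pose: RigidTransform = field(default_factory=RigidTransform.identity)
    dummy_screws: bool = True
    raw_gain: float = 0.5
    raw_offset: float = 1024.0
    tooth_angles: dict = None  # degrees on the dental arch; None: defaults

    def validate(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 8 for s in self.shape):
            raise PhantomError(f"grid shape must be 3 axes of >= 8 voxels, got {self.shape}")
        if not np.all(np.atleast_1d(self.spacing) > 0):
            raise PhantomError(f"voxel spacing must be positive, got {self.spacing}")
        missing = [k for k in _HU_ORDER if k not in self.hu]
        if missing:
            raise PhantomError(f"missing nominal HU for tissues: {missing}")
        vals = [self.hu[k] for k in _HU_ORDER]
        # air < soft < trabecular < cortical <= dentin < enamel < titanium
        strict = [(0, 1), (1, 2), (2, 3), (4, 5), (5, 6)]
        if any(vals[i] >= vals[j] for i, j in strict) or vals[3] > vals[4]:
            raise PhantomError(
                "tissue HU must satisfy air < soft tissue < trabecular < "
                f"cortical <= dentin < enamel < titanium, got {dict(zip(_HU_ORDER, vals))}")
        if self.noise_sd < 0:
            raise PhantomError("noise_sd must be >= 0")
        if self.raw_gain == 0:
            raise PhantomError("raw_gain must be nonzero")


@dataclass
class PhantomTruth:
    """Ground truth emitted alongside the raw volume."""

    labels: LabelVolume
    surfaces: dict                 # part name -> list of exact TriSurface
    nominal_hu: dict               # tissue name -> HU
    nominal_hu_volume: np.ndarray  # noise-free HU per voxel
    tissue: np.ndarray             # per-voxel tissue name index into _HU_ORDER
    muscles: pd.DataFrame          # name, x, y, z, Fx, Fy, Fz (N)
    regions: dict                  # region name -> predicate spec dict
    raw_gain: float
    raw_offset: float
    water_box: tuple               # world-coordinate (lo, hi) sample box
    air_box: tuple
    config: PhantomConfig = None

    def part_mask(self, name):
        return self.labels.mask(name)


def _depth_cyl_z(x, y, z, cx, cy, r, z0, z1):
    """Inside-depth of a vertical cylinder (positive inside)."""
    radial = r - np.hypot(x - cx, y - cy)
    return np.minimum(radial, np.minimum(z - z0, z1 - z))


def _depth_sphere(x, y, z, c, r):
    return r - np.sqrt((x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2)


def _geometry(config: PhantomConfig) -> dict:
    """Absolute world-frame geometry, scaled from the volume extent."""
    spacing = np.atleast_1d(np.asarray(config.spacing, dtype=float))
    if spacing.size == 1:
        spacing = np.repeat(spacing, 3)
    ex, ey, ez = np.asarray(config.shape) * spacing
    g = {}
    g["extent"] = (ex, ey, ez)
    g["body_z"] = 0.222 * ez
    g["body_r"] = 0.089 * ex
    g["arch_R"] = 0.306 * ex
    g["arch_cx"], g["arch_cy"] = 0.5 * ex, 0.611 * ey
    g["shell"] = max(0.025 * ex, 2.0 * float(spacing.max()))
    g["ramus_r"] = 0.078 * ex
    g["ramus_left"] = (g["arch_cx"] + g["arch_R"] * np.cos(np.deg2rad(135)),
                       g["arch_cy"] + g["arch_R"] * np.sin(np.deg2rad(135)))
    g["ramus_right"] = (g["arch_cx"] + g["arch_R"] * np.cos(np.deg2rad(45)),
                        g["arch_cy"] + g["arch_R"] * np.sin(np.deg2rad(45)))
    g["ramus_top"] = 0.741 * ez
    g["condyle_r"] = 0.083 * ex
    g["stump_top"] = 0.407 * ez
    g["tooth_r"] = 0.0417 * ex
    g["tooth_z"] = (0.304 * ez, 0.5 * ez)
    g["enamel_z"] = 0.444 * ez
    ang = config.tooth_angles or {"tooth_31": -90.0, "tooth_33": -135.0,
                                  "tooth_47": -20.0}
    g["teeth"] = {name: (g["arch_cx"] + g["arch_R"] * np.cos(np.deg2rad(a)),
                         g["arch_cy"] + g["arch_R"] * np.sin(np.deg2rad(a)))
                  for name, a in ang.items()}
    g["plate_lo"] = np.array([0.794 * ex, 0.758 * ey, 0.222 * ez])
    g["plate_hi"] = np.array([0.836 * ex, 0.897 * ey, 0.778 * ez])
    g["head_c"] = np.array([0.764 * ex, 0.828 * ey, 0.796 * ez])
    g["head_r"] = 0.0694 * ex
    g["screw_r"] = 0.025 * ex
    g["screw_x"] = (0.644 * ex, 0.811 * ex)
    g["screw_yz"] = [(0.828 * ey, 0.267 * ez),
                     (0.786 * ey, 0.344 * ez),
                     (0.869 * ey, 0.344 * ez)]
    g["dummy_x"] = (0.833 * ex, 0.889 * ex)
    g["dummy_yz"] = [(0.786 * ey, 0.481 * ez), (0.869 * ey, 0.481 * ez)]
    g["soft_c"] = np.array([0.5 * ex, 0.556 * ey, 0.444 * ez])
    g["soft_semi"] = np.array([0.444 * ex, 0.417 * ey, 0.444 * ez])
    wb = np.array([0.5 * ex, 0.333 * ey, 0.741 * ez])
    g["water_box"] = (wb - 0.028 * ex, wb + 0.028 * ex)
    g["air_box"] = (0.01 * np.array([ex, ey, ez]), 0.07 * np.array([ex, ey, ez]))
    return g


def _x_cylinder(radius, x0, x1, y, z, sections=24):
    """Triangulated cylinder with its axis along x."""
    import trimesh
    cyl = trimesh.creation.cylinder(radius=radius, height=x1 - x0,
                                    sections=sections)
    rot = trimesh.transformations.rotation_matrix(np.pi / 2, [0, 1, 0])
    cyl.apply_transform(rot)
    cyl.apply_translation([(x0 + x1) / 2.0, y, z])
    return TriSurface.from_trimesh(cyl)


def _prosthesis_surfaces(geom: dict, pose: RigidTransform,
                         dummy: bool) -> dict:
    """Exact CAD surfaces: plate + condylar head, screws, dummy screws."""
    import trimesh
    lo, hi = geom["plate_lo"], geom["plate_hi"]
    plate = trimesh.creation.box(extents=hi - lo)
    plate.apply_translation((lo + hi) / 2.0)
    head = trimesh.creation.icosphere(subdivisions=3, radius=geom["head_r"])
    head.apply_translation(geom["head_c"])
    surfaces = {
        "prosthesis": [TriSurface.from_trimesh(plate),
                       TriSurface.from_trimesh(head)],
        "screws": [_x_cylinder(geom["screw_r"], *geom["screw_x"], y, z)
                   for (y, z) in geom["screw_yz"]],
    }
    if dummy:
        surfaces["dummy_screws"] = [
            _x_cylinder(geom["screw_r"], *geom["dummy_x"], y, z)
            for (y, z) in geom["dummy_yz"]]
    return {name: [s.transformed(pose) for s in parts]
            for name, parts in surfaces.items()}


def _segmentation_regions(geom: dict, surfaces: dict) -> dict:
    """Bounding-box restrictions for threshold masks.

    These play the role of the operator's per-mask bounding region: teeth
    boxes follow the tooth cylinders; metal-part boxes follow the posed CAD
    surfaces, so they stay valid under a prosthesis pose change.
    """
    regions = {}
    z0, z1 = geom["tooth_z"]
    r = geom["tooth_r"] + 1.0
    for name, (tx, ty) in geom["teeth"].items():
        regions[f"seg_{name}"] = dict(type="box",
                                      lo=(tx - r, ty - r, z0 - 1.0),
                                      hi=(tx + r, ty + r, z1 + 1.0))
    for part, surfs in surfaces.items():
        # union of per-component boxes, kept tight: every voxel centre
        # inside a component is inside its CAD bounding box, and
        # neighbouring metal parts are not claimed
        margin = 0.05
        boxes = [(tuple(s.vertices.min(axis=0) - margin),
                  tuple(s.vertices.max(axis=0) + margin)) for s in surfs]
        regions[f"seg_{part}"] = dict(type="boxes", boxes=boxes)
    return regions


def _region_specs(geom: dict, pose: RigidTransform) -> dict:
    """Named world-coordinate regions for node sets (fixation, bite, muscles)."""
    lx, ly = geom["ramus_left"]
    rx, ry = geom["ramus_right"]
    ez = geom["extent"][2]
    x47, y47 = geom["teeth"]["tooth_47"]
    head_c = pose.apply(geom["head_c"])
    return {
        "prosthesis_condyle": dict(type="sphere", center=tuple(head_c),
                                   radius=geom["head_r"] + 1.0,
                                   part="prosthesis"),
        "contralateral_condyle": dict(type="sphere",
                                      center=(lx, ly, geom["ramus_top"]),
                                      radius=geom["condyle_r"] + 1.0,
                                      part="mandible"),
        "bite_tooth_47": dict(type="sphere",
                              center=(x47, y47, geom["tooth_z"][1]),
                              radius=geom["tooth_r"] + 0.8, part="tooth_47"),
        "masseter_left": dict(type="sphere", center=(lx, ly, 0.444 * ez),
                              radius=3.0, part="mandible"),
        "masseter_right": dict(type="sphere", center=(rx, ry, 0.593 * ez),
                               radius=2.0, part="mandible"),
        "temporalis_left": dict(type="sphere", center=(lx, ly, 0.667 * ez),
                                radius=2.5, part="mandible"),
        "temporalis_right": dict(type="sphere", center=(rx, ry, 0.63 * ez),
                                 radius=2.0, part="mandible"),
        "pterygoid_left": dict(type="sphere", center=(lx, ly, 0.296 * ez),
                               radius=2.8, part="mandible"),
        "pterygoid_right": dict(type="sphere", center=(rx, ry, 0.296 * ez),
                                radius=2.8, part="mandible"),
    }


def _muscle_table(regions: dict) -> pd.DataFrame:
    """Placeholder muscle-force table (N).

    Magnitudes are plausible for a 450 N unilateral molar bite but are NOT
    patient data; users substitute their own musculoskeletal results.
    Muscles whose attachment region lies on resected bone resolve to empty
    node sets and are dropped at load-case assembly.
    """
    rows = []
    forces = {
        "masseter_left": (10.0, -30.0, 150.0),
        "masseter_right": (-10.0, -30.0, 150.0),
        "temporalis_left": (0.0, 25.0, 100.0),
        "temporalis_right": (0.0, 25.0, 100.0),
        "pterygoid_left": (35.0, -15.0, 80.0),
        "pterygoid_right": (-35.0, -15.0, 80.0),
    }
    for name, f in forces.items():
        c = regions[name]["center"]
        rows.append(dict(name=name, x=c[0], y=c[1], z=c[2],
                         Fx=f[0], Fy=f[1], Fz=f[2]))
    return pd.DataFrame(rows)


def build_phantom(config: PhantomConfig | None = None):
    """Build the raw (uncalibrated) volume and its ground truth.

    Returns ``(ImageVolume, PhantomTruth)``.  Identical config + seed gives
    bit-identical outputs.
    """
    config = config or PhantomConfig()
    config.validate()
    geom = _geometry(config)

    spacing = np.atleast_1d(np.asarray(config.spacing, dtype=float))
    if spacing.size == 1:
        spacing = np.repeat(spacing, 3)
    shape = tuple(int(s) for s in config.shape)
    origin = np.zeros(3)

    ax = [origin[a] + spacing[a] * np.arange(shape[a]) for a in range(3)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")

    # ---- bone (mandible) implicit ------------------------------------
    rho = np.hypot(X - geom["arch_cx"], Y - geom["arch_cy"])
    torus = geom["body_r"] - np.sqrt((rho - geom["arch_R"]) ** 2
                                     + (Z - geom["body_z"]) ** 2)
    phi = np.degrees(np.arctan2(Y - geom["arch_cy"], X - geom["arch_cx"]))
    torus = np.where((phi > 45.0) & (phi < 135.0), -np.inf, torus)

    lx, ly = geom["ramus_left"]
    rx, ry = geom["ramus_right"]
    lramus = _depth_cyl_z(X, Y, Z, lx, ly, geom["ramus_r"],
                          geom["body_z"], geom["ramus_top"])
    lcond = _depth_sphere(X, Y, Z, (lx, ly, geom["ramus_top"]),
                          geom["condyle_r"])
    stump = _depth_cyl_z(X, Y, Z, rx, ry, geom["ramus_r"],
                         geom["body_z"], geom["stump_top"])
    bone_depth = np.maximum.reduce([torus, lramus, lcond, stump])
    bone = bone_depth > 0

    # ---- teeth --------------------------------------------------------
    teeth_masks = {}
    z0, z1 = geom["tooth_z"]
    for name, (tx, ty) in geom["teeth"].items():
        depth = _depth_cyl_z(X, Y, Z, tx, ty, geom["tooth_r"], z0, z1)
        teeth_masks[name] = depth > 0
    names = list(teeth_masks)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if (teeth_masks[names[i]] & teeth_masks[names[j]]).any():
                raise PhantomError(
                    f"overlapping part specification: {names[i]} and {names[j]}")

    # ---- prosthesis: rasterized from the exact CAD surfaces ----------
    surfaces = _prosthesis_surfaces(geom, config.prosthesis_pose,
                                    config.dummy_screws)
    metal_masks = {}
    for part, surfs in surfaces.items():
        m = np.zeros(shape, dtype=bool)
        for s in surfs:
            m |= voxelize_surface(s, shape, spacing, origin).data
        metal_masks[part] = m

    # ---- labels with fixed priority (metal > teeth > bone) ------------
    labels = np.zeros(shape, dtype=np.int16)
    labels[bone] = 1
    for lid, name in ((2, "tooth_31"), (3, "tooth_33"), (4, "tooth_47")):
        labels[teeth_masks[name]] = lid
    for lid, name in ((7, "dummy_screws"), (6, "screws"), (5, "prosthesis")):
        if name in metal_masks:
            labels[metal_masks[name]] = lid

    # ---- tissue field and nominal HU ----------------------------------
    tissue = np.zeros(shape, dtype=np.int8)  # index into _HU_ORDER; 0 = air
    soft = (((X - geom["soft_c"][0]) / geom["soft_semi"][0]) ** 2
            + ((Y - geom["soft_c"][1]) / geom["soft_semi"][1]) ** 2
            + ((Z - geom["soft_c"][2]) / geom["soft_semi"][2]) ** 2) <= 1.0
    tissue[soft] = _HU_ORDER.index("soft_tissue")
    is_bone = labels == 1
    cortical = is_bone & (bone_depth < geom["shell"])
    tissue[is_bone] = _HU_ORDER.index("trabecular")
    tissue[cortical] = _HU_ORDER.index("cortical")
    is_tooth = (labels >= 2) & (labels <= 4)
    tissue[is_tooth] = _HU_ORDER.index("dentin")
    tissue[is_tooth & (Z > geom["enamel_z"])] = _HU_ORDER.index("enamel")
    tissue[labels >= 5] = _HU_ORDER.index("titanium")

    hu_values = np.array([config.hu[k] for k in _HU_ORDER])
    hu = hu_values[tissue]

    # ---- raw transform + noise ----------------------------------------
    rng = np.random.default_rng(config.seed)
    noisy = hu if config.noise_sd == 0 else hu + rng.normal(
        0.0, config.noise_sd, size=shape)
    if config.metal_artifacts:
        noisy = noisy + _metal_streaks(labels, X, Y, rng)
    raw = config.raw_gain * noisy + config.raw_offset

    label_names = {lid: n for lid, n in PART_NAMES.items()
                   if (labels == lid).any() or lid <= 6}
    if not config.dummy_screws:
        label_names.pop(7, None)

    regions = _region_specs(geom, config.prosthesis_pose)
    regions.update(_segmentation_regions(geom, surfaces))
    truth = PhantomTruth(
        labels=LabelVolume(labels, label_names, spacing=spacing, origin=origin),
        surfaces=surfaces,
        nominal_hu=dict(config.hu),
        nominal_hu_volume=hu,
        tissue=tissue,
        muscles=_muscle_table(regions),
        regions=regions,
        raw_gain=config.raw_gain,
        raw_offset=config.raw_offset,
        water_box=geom["water_box"],
        air_box=geom["air_box"],
        config=config,
    )
    vol = ImageVolume(raw, spacing=spacing, origin=origin, calibrated=False)
    return vol, truth


def _metal_streaks(labels, X, Y, rng, amplitude: float = 150.0):
    """Angular streak noise confined to slices that intersect titanium."""
    streak = np.zeros(labels.shape)
    metal_slices = np.nonzero((labels >= 5).any(axis=(0, 1)))[0]
    if metal_slices.size == 0:
        return streak
    for k in metal_slices:
        mx = X[:, :, 0][labels[:, :, k] >= 5].mean()
        my = Y[:, :, 0][labels[:, :, k] >= 5].mean()
        theta = np.arctan2(Y[:, :, 0] - my, X[:, :, 0] - mx)
        r = np.hypot(X[:, :, 0] - mx, Y[:, :, 0] - my)
        phase = rng.uniform(0, 2 * np.pi)
        streak[:, :, k] = amplitude * np.cos(8 * theta + phase) * np.exp(-r / 20.0)
    return streak


def simulate_wear_series(true_rate: float, intercept: float,
                         soak_drift: float = 0.0, n_points: int = 10,
                         step: float = 500_000.0, noise_sd: float = 0.0,
                         seed: int = 0) -> WearSeries:
    """Simulate a gravimetric wear test read out every ``step`` cycles.

    ``true_rate`` is the true net mass loss per cycle (mg/cycle),
    ``intercept`` the running-in offset (mg), ``soak_drift`` the apparent
    mass-loss rate (mg/cycle) that affects specimen and soak control alike
    (e.g. fluid exchange).  The measured specimen loss is
    ``true_rate*n + intercept + soak_drift*n + noise`` and the soak control
    records ``soak_drift*n + noise``; subtracting the control recovers the
    net loss W_n = true_rate*n + intercept.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2 (regression impossible otherwise)")
    if step <= 0:
        raise ValueError("cycle step must be positive")
    rng = np.random.default_rng(seed)
    n = step * np.arange(1, n_points + 1, dtype=float)
    specimen = true_rate * n + intercept + soak_drift * n
    soak = soak_drift * n
    if noise_sd > 0:
        specimen = specimen + rng.normal(0.0, noise_sd, n_points)
        soak = soak + rng.normal(0.0, noise_sd, n_points)
    return WearSeries(cycles=n, specimen_loss=specimen, soak_change=soak)


# ---------------------------------------------------------------------------
# volume writers: per-slice 16-bit TIFF stack with a JSON sidecar
# ---------------------------------------------------------------------------

def write_volume_slices(vol: ImageVolume, truth: PhantomTruth, outdir) -> Path:
    """Write the raw volume as per-slice 16-bit TIFFs plus a JSON sidecar."""
    import tifffile
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data = np.clip(np.rint(vol.data), 0, 65535).astype(np.uint16)
    for k in range(data.shape[2]):
        tifffile.imwrite(outdir / f"slice_{k:04d}.tif", data[:, :, k].T)
    sidecar = dict(shape=list(vol.shape), spacing=list(map(float, vol.spacing)),
                   origin=list(map(float, vol.origin)), axis_order=vol.axis_order,
                   raw_gain=truth.raw_gain, raw_offset=truth.raw_offset)
    (outdir / "volume.json").write_text(json.dumps(sidecar, indent=2))
    return outdir


def read_volume_slices(indir) -> ImageVolume:
    import tifffile
    indir = Path(indir)
    meta = json.loads((indir / "volume.json").read_text())
    slices = sorted(indir.glob("slice_*.tif"))
    data = np.stack([tifffile.imread(p).T for p in slices], axis=2)
    return ImageVolume(data.astype(float), spacing=meta["spacing"],
                       origin=meta["origin"], axis_order=meta["axis_order"])
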