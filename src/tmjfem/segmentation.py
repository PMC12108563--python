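"""CT calibration, mask segmentation, surface extraction and comparison.

The stage mirrors a clinical image-processing chain: two-point HU
calibration (water -> 0 HU, air -> -1000 HU), per-part threshold masks with
morphological cleanup (island removal, cavity fill, gap closing, applied in
that priority order), combination of masks into a label volume, surface
extraction, rigid CAD-to-segmentation alignment, and closest-point surface
deviation mapping.

Connectivity conventions: 26-neighbourhood for foreground islands,
6-neighbourhood for background cavities (the standard dual pair).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import ImageVolume, LabelVolume, Mask, RigidTransform, TriSurface
from .geometry import closest_point_on_surface

__all__ = [
    "calibrate",
    "threshold_mask",
    "morph_clean",
    "resolve_priority",
    "extract_surface",
    "smooth_surface",
    "align_surface",
    "surface_deviation",
    "dice",
    "DeviationMap",
]

FOREGROUND_CONNECTIVITY = 26
CAVITY_CONNECTIVITY = 6

_STRUCT_26 = ndimage.generate_binary_structure(3, 3)
_STRUCT_6 = ndimage.generate_binary_structure(3, 1)


def calibrate(raw: ImageVolume, mean_water: float, mean_air: float) -> ImageVolume:
    """Two-point linear calibration of raw values to Hounsfield units.

    The affine map sends ``mean_water -> 0 HU`` and ``mean_air -> -1000 HU``.
    """
    if mean_water == mean_air:
        raise ValueError("water and air reference means are equal; "
                         "calibration line is degenerate")
    hu = 1000.0 * (raw.data - mean_water) / (mean_water - mean_air)
    out = raw.with_data(hu, calibrated=True)
    return out


def threshold_mask(vol: ImageVolume, method: str = "fixed",
                   lo: float = None, hi: float = None,
                   region=None, name: str = "") -> Mask:
    """Range-select a mask, with a fixed or adaptively chosen threshold.

    ``method="fixed"``: voxels with value in ``[lo, hi]``.
    ``method="adaptive"``: an Otsu split of the (optionally region-restricted)
    histogram supplies the missing bound — the lower bound if ``lo`` is None,
    the upper if ``hi`` is None; explicit bounds are kept.
    ``region`` is a boolean array restricting both the histogram and the mask.
    """
    data = vol.data
    restrict = np.ones(data.shape, dtype=bool) if region is None else np.asarray(region, dtype=bool)
    if method == "adaptive":
        sample = data[restrict]
        if sample.size == 0 or np.ptp(sample) == 0:
            split = sample[0] if sample.size else 0.0
        else:
            from skimage.filters import threshold_otsu
            split = float(threshold_otsu(sample))
        if lo is None:
            lo = split
        elif hi is None:
            hi = split
    elif method != "fixed":
        raise ValueError(f"unknown threshold method {method!r}")
    lo = -np.inf if lo is None else lo
    hi = np.inf if hi is None else hi
    m = (data >= lo) & (data <= hi) & restrict
    if not m.any():
        warnings.warn(f"threshold produced an empty mask ({name or 'unnamed'})",
                      stacklevel=2)
    return Mask(m, name=name, spacing=vol.spacing, origin=vol.origin)


def _remove_islands(m: np.ndarray, min_island: int) -> np.ndarray:
    if min_island <= 1 or not m.any():
        return m
    lab, n = ndimage.label(m, structure=_STRUCT_26)
    if n == 0:
        return m
    sizes = np.bincount(lab.ravel())
    keep = sizes >= min_island
    keep[0] = False
    return keep[lab]


def _fill_cavities(m: np.ndarray) -> np.ndarray:
    if not m.any():
        return m
    bg, n = ndimage.label(~m, structure=_STRUCT_6)
    if n == 0:
        return m
    border_labels = np.unique(np.concatenate([
        bg[0].ravel(), bg[-1].ravel(), bg[:, 0].ravel(), bg[:, -1].ravel(),
        bg[:, :, 0].ravel(), bg[:, :, -1].ravel()]))
    enclosed = np.ones(n + 1, dtype=bool)
    enclosed[border_labels] = False
    enclosed[0] = False
    return m | enclosed[bg]


def _ball(radius: int) -> np.ndarray:
    r = int(radius)
    g = np.mgrid[-r:r + 1, -r:r + 1, -r:r + 1]
    return (g ** 2).sum(axis=0) <= r * r


def morph_clean(m: Mask, min_island: int = 0, closing_radius: int = 0) -> Mask:
    """Island removal, then cavity fill, then gap closing — in that order.

    Islands are 26-connected components smaller than ``min_island`` voxels;
    cavities are 6-connected background components with no path to the
    volume border; gap closing is a morphological closing with a ball of the
    given voxel radius.
    """
    data = _remove_islands(m.data, min_island)
    data = _fill_cavities(data)
    if closing_radius > 0:
        data = ndimage.binary_closing(data, structure=_ball(closing_radius))
        data = _fill_cavities(data)
    return Mask(data, name=m.name, spacing=m.spacing, origin=m.origin)


def resolve_priority(masks: list) -> LabelVolume:
    """Combine masks into a label volume; earlier masks take priority.

    Voxel labels are the 1-based index of the first (highest-priority) mask
    containing the voxel; 0 is background.
    """
    if not masks:
        raise ValueError("no masks given")
    shape = masks[0].shape
    for m in masks:
        if m.shape != shape:
            raise ValueError("masks are not congruent")
    labels = np.zeros(shape, dtype=np.int16)
    for i, m in enumerate(reversed(masks)):
        labels[m.data] = len(masks) - i
    names = {i + 1: (m.name or f"part_{i + 1}") for i, m in enumerate(masks)}
    return LabelVolume(labels, names, spacing=masks[0].spacing,
                       origin=masks[0].origin)


def extract_surface(m: Mask, spacing=None, origin=None) -> TriSurface:
    """Triangulated boundary of a voxel mask.

    Emits the 0.5 level set of the binary field under nearest-neighbour
    interpolation: the set of voxel faces separating inside from outside.
    Faces on the volume border are not capped, so a mask with no border
    contact yields a closed, watertight surface whose enclosed volume equals
    the voxel count times the voxel volume exactly.
    """
    if not m.data.any():
        raise ValueError("cannot extract a surface from an empty mask")
    spacing = m.spacing if spacing is None else np.broadcast_to(
        np.atleast_1d(np.asarray(spacing, float)), (3,)).copy()
    origin = m.origin if origin is None else np.asarray(origin, float)
    data = m.data

    quads = []  # (corner lattice point, axis, orientation)
    for axis in range(3):
        diff = np.diff(data.astype(np.int8), axis=axis)
        # val=+1: solid on the + side, outward normal points along -axis
        for sign, val in ((-1, 1), (1, -1)):
            idx = np.argwhere(diff == val)
            if idx.size == 0:
                continue
            # face sits between voxel idx and idx+1 along `axis`
            base = idx.astype(np.int64)
            base[:, axis] += 1  # lattice coordinate of the face plane
            quads.append((base, axis, sign))

    verts = {}
    faces = []

    def vid(key):
        if key not in verts:
            verts[key] = len(verts)
        return verts[key]

    for base, axis, sign in quads:
        a1, a2 = [a for a in range(3) if a != axis]
        for b in base:
            c = [tuple(b + d1 * _unit(a1) + d2 * _unit(a2))
                 for (d1, d2) in ((0, 0), (1, 0), (1, 1), (0, 1))]
            ids = [vid(k) for k in c]
            if sign > 0:  # outward normal along +axis
                tris = ([ids[0], ids[1], ids[2]], [ids[0], ids[2], ids[3]])
            else:
                tris = ([ids[0], ids[2], ids[1]], [ids[0], ids[3], ids[2]])
            # axis-pair handedness: (a1, a2, axis) may be a negative
            # permutation of (x, y, z); flip to keep normals outward
            if (a1, a2) != _pos_pair(axis):
                tris = ([t[0], t[2], t[1]] for t in tris)
            faces.extend(tris)

    keys = np.array(list(verts.keys()), dtype=float)
    # lattice point (i, j, k) sits at the corner between voxel centres:
    # world = origin + (index - 0.5) * spacing
    vertices = origin + (keys - 0.5) * spacing
    return TriSurface(vertices, np.asarray(faces, dtype=np.int64))


def _unit(axis):
    e = np.zeros(3, dtype=np.int64)
    e[axis] = 1
    return e


def _pos_pair(axis):
    # in-plane axis pair forming a right-handed frame with `axis`
    return {0: (1, 2), 1: (2, 0), 2: (0, 1)}[axis]


def smooth_surface(m: Mask, sigma: float) -> Mask:
    """Gaussian-smoothed binary field re-thresholded at 0.5.

    ``sigma`` is in voxels; ``sigma=0`` is the identity.  Thin structures of
    about one voxel (e.g. segmented screws) erode or vanish under smoothing,
    which is why screw-bearing masks are left unsmoothed by default in the
    pipeline.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return Mask(m.data.copy(), name=m.name, spacing=m.spacing, origin=m.origin)
    field = ndimage.gaussian_filter(m.data.astype(float), sigma)
    return Mask(field >= 0.5, name=m.name, spacing=m.spacing, origin=m.origin)


def align_surface(cad: TriSurface, target: TriSurface,
                  init: RigidTransform | None = None,
                  refine: bool = False, max_iter: int = 50,
                  tol: float = 1e-8) -> RigidTransform:
    """Rigidly align a CAD surface with a segmented target surface.

    With ``refine=False`` the initial transform is returned verbatim — the
    reproducible stand-in for interactive manual placement.  With
    ``refine=True`` a point-to-surface ICP refines it; the mean closest-point
    distance never increases relative to the initial transform.
    """
    init = init or RigidTransform.identity()
    if cad.n_faces == 0 or target.n_faces == 0:
        raise ValueError("both surfaces must be non-empty")
    if not refine:
        return init

    pts0 = cad.vertices
    current = init

    def mean_dist(tf):
        d, _, _ = closest_point_on_surface(tf.apply(pts0), target)
        return d.mean()

    best = current
    best_d = mean_dist(current)
    prev_d = best_d
    for _ in range(max_iter):
        moved = current.apply(pts0)
        _, matched, _ = closest_point_on_surface(moved, target)
        # Kabsch: best rigid map of pts0 onto matched points
        mu_p = pts0.mean(axis=0)
        mu_q = matched.mean(axis=0)
        H = (pts0 - mu_p).T @ (matched - mu_q)
        U, _, Vt = np.linalg.svd(H)
        D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
        R = Vt.T @ D @ U.T
        current = RigidTransform(R, mu_q - R @ mu_p)
        d = mean_dist(current)
        if d < best_d:
            best, best_d = current, d
        if abs(prev_d - d) < tol:
            break
        prev_d = d
    return best


@dataclass
class DeviationMap:
    """Per-sample unsigned closest-point distances between two surfaces."""

    distances: np.ndarray
    points: np.ndarray

    @property
    def max(self) -> float:
        return float(self.distances.max())

    @property
    def mean(self) -> float:
        return float(self.distances.mean())

    def fraction_below(self, threshold_mm: float = 1.0) -> float:
        return float((self.distances < threshold_mm).mean())

    def summary(self) -> dict:
        return dict(max_mm=self.max, mean_mm=self.mean,
                    fraction_below_1mm=self.fraction_below(1.0))


def surface_deviation(reference: TriSurface, target: TriSurface) -> DeviationMap:
    """Unsigned distance from each reference vertex to the target surface.

    Sampling points are the reference vertices; each is measured against the
    nearest point on any target triangle (point-to-triangle, not
    point-to-vertex).
    """
    if target.n_faces == 0:
        raise ValueError("target surface is empty")
    d, _, _ = closest_point_on_surface(reference.vertices, target)
    return DeviationMap(distances=d, points=reference.vertices.copy())


def dice(a: Mask, b: Mask) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    na, nb = a.count(), b.count()
    if na + nb == 0:
        return 1.0
    inter = int((a.data & b.data).sum())
    return 2.0 * inter / (na + nb)
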