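"""Stress invariants, per-part peaks and cross-variant comparison.

Peaks are taken at element quadrature points (not nodal extrapolations,
which inflate maxima mesh-dependently) and normalized against a
user-supplied reference stress — the stand-in for a proprietary material
limit; by default the baseline run's own peak serves as reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .meshing import TetMesh
from .solver import Solution

__all__ = ["von_mises", "peak_stress", "compare_variants", "StressSummary"]


def von_mises(stress, check_symmetry: bool = True):
    """Von Mises equivalent stress of 3x3 tensors or Voigt-6 vectors.

    Accepts shape ``(..., 3, 3)`` (symmetric tensors) or ``(..., 6)`` in
    Voigt order (xx, yy, zz, xy, yz, zx); returns shape ``(...)``.
    """
    s = np.asarray(stress, dtype=float)
    if s.shape[-2:] == (3, 3):
        if check_symmetry:
            asym = np.abs(s - np.swapaxes(s, -1, -2)).max()
            scale = max(np.abs(s).max(), 1.0)
            if asym > 1e-9 * scale:
                raise ValueError(f"stress tensor not symmetric (|s-s^T| = {asym:.2e})")
        sxx, syy, szz = s[..., 0, 0], s[..., 1, 1], s[..., 2, 2]
        sxy, syz, szx = s[..., 0, 1], s[..., 1, 2], s[..., 2, 0]
    elif s.shape[-1] == 6:
        sxx, syy, szz, sxy, syz, szx = (s[..., i] for i in range(6))
    else:
        raise ValueError("expected (..., 3, 3) tensors or (..., 6) Voigt vectors")
    return np.sqrt(0.5 * ((sxx - syy) ** 2 + (syy - szz) ** 2 + (szz - sxx) ** 2)
                   + 3.0 * (sxy ** 2 + syz ** 2 + szx ** 2))


@dataclass
class StressSummary:
    """Per-part peak von Mises stress of one model variant."""

    part: str
    variant: str
    peak_MPa: float
    normalized_peak: float
    reference_MPa: float
    location: np.ndarray      # world coordinates of the peak element centroid
    element: int

    def as_dict(self) -> dict:
        return dict(part=self.part, variant=self.variant,
                    peak_MPa=self.peak_MPa,
                    normalized_peak=self.normalized_peak,
                    reference_MPa=self.reference_MPa,
                    location=list(map(float, self.location)),
                    element=int(self.element))


def peak_stress(solution: Solution, mesh: TetMesh, part: str,
                reference: float, variant: str = "") -> StressSummary:
    """Peak quadrature-point von Mises stress over one part, normalized.

    ``reference`` is the normalization stress in MPa (> 0).
    """
    if reference <= 0:
        raise ValueError("reference stress must be positive")
    elems = mesh.part_elements(part)
    if len(elems) == 0:
        raise ValueError(f"unknown or empty part {part!r}")
    vm = von_mises(solution.stress[elems])      # (n_part, 4)
    flat = int(np.argmax(vm))
    eid = int(elems[flat // 4])
    peak = float(vm.ravel()[flat])
    centroid = mesh.nodes[mesh.elements[eid, :4]].mean(axis=0)
    return StressSummary(part=part, variant=variant, peak_MPa=peak,
                         normalized_peak=peak / reference,
                         reference_MPa=reference,
                         location=centroid, element=eid)


def compare_variants(runs: list, location_radius_mm: float = 2.0) -> pd.DataFrame:
    """Tabulate normalized peaks and pairwise differences across variants.

    All runs must share the same reference stress.  The table lists the
    normalized peak of each run, the percentage difference of each pair
    (relative to the second run of the pair), and whether the peak locations
    coincide within the given radius.  Magnitudes are reported, not
    asserted — peak values depend on the (patient) geometry.
    """
    if len(runs) < 2:
        raise ValueError("need at least two runs to compare")
    refs = {round(r.reference_MPa, 12) for r in runs}
    if len(refs) != 1:
        raise ValueError("runs use different reference stresses; "
                         "renormalize before comparing")
    rows = []
    for i, a in enumerate(runs):
        for j, b in enumerate(runs):
            if j <= i:
                continue
            diff = (a.normalized_peak - b.normalized_peak) / b.normalized_peak
            dist = float(np.linalg.norm(np.asarray(a.location)
                                        - np.asarray(b.location)))
            rows.append(dict(
                variant_a=a.variant, variant_b=b.variant,
                peak_a=a.normalized_peak, peak_b=b.normalized_peak,
                difference_pct=100.0 * diff,
                location_distance_mm=dist,
                locations_coincide=dist <= location_radius_mm))
    return pd.DataFrame(rows)
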