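"""End-to-end orchestration of the model variants on one phantom.

The four variants mirror a gradual transition from a purely image-based
model toward a CAD-driven industrial-style model:

* Model 1 — fully segmented geometry (bone, teeth, prosthesis, screws),
  HU-mapped bone stiffness, no dummy screws, plate-bone contact ignored.
* Model 2 — segmented bone/teeth, prosthesis and screws taken from the
  exact CAD surfaces instead of the segmentation.
* Model 3 — Model 2 plus the two planning-stage "dummy" screws.
* Model 4 — simplified contact model: CAD prosthesis with dummy screws,
  mandible and teeth merged into one part with a uniform 10 GPa modulus,
  coarser mesh, and plate-bone contact configurable (ignored, bonded or
  frictional with mu = 0.3).

The "industrial-style" run is Model 4 with bonded screw constraints and the
plate-bone contact left out — the frozen-workflow choice.  Its peak stress
serves as the default normalization reference for every variant.

The prosthesis-mandible interface is always split into separate bodies
(connected through the bonded screws), so "contact ignored" genuinely means
the plate can separate from the bone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .core import ImageVolume, LabelVolume, Mask
from .materials import assign_element_materials, load_material_table
from .meshing import (TetMesh, define_node_sets, interface_facets,
                      mesh_from_labels, split_interface, write_mesh)
from .phantom import PhantomConfig, PhantomTruth, build_phantom
from .postpro import StressSummary, compare_variants, peak_stress
from .segmentation import (align_surface, calibrate, morph_clean,
                           resolve_priority, threshold_mask)
from .geometry import voxelize_surface
from .solver import ContactPair, LoadCase, apply_bonded_mpc, solve_contact, solve_linear

__all__ = ["VariantSpec", "WorkflowConfig", "VariantRun", "run_variant", "run_all"]

# label-downsampling weights by part name: thin metal parts must survive
# coarsening, teeth get a mild boost over bone
_DOWNSAMPLE_WEIGHTS = {"prosthesis": 6.0, "screws": 6.0, "dummy_screws": 6.0,
                       "tooth_31": 2.0, "tooth_33": 2.0, "tooth_47": 2.0}


@dataclass(frozen=True)
class VariantSpec:
    """Configuration of one model variant."""

    number: int
    name: str
    prosthesis_source: str = "segmented"   # "segmented" | "cad"
    dummy_screws: bool = False
    bone_material: str = "mapped"          # "mapped" | "uniform"
    teeth: str = "individual"              # "individual" | "merged"
    contact: str = "ignored"               # "ignored" | "bonded" | "frictional"

    @classmethod
    def model(cls, number: int, contact: str = None) -> "VariantSpec":
        presets = {
            1: cls(1, "model_1", "segmented", False, "mapped", "individual", "ignored"),
            2: cls(2, "model_2", "cad", False, "mapped", "individual", "ignored"),
            3: cls(3, "model_3", "cad", True, "mapped", "individual", "ignored"),
            4: cls(4, "model_4", "cad", True, "uniform", "merged", "ignored"),
        }
        spec = presets[number]
        if contact is not None:
            spec = replace(spec, contact=contact,
                           name=f"{spec.name}_{contact}" if number == 4 else spec.name)
        return spec


@dataclass
class WorkflowConfig:
    """Study conditions for a full variant comparison on one phantom."""

    phantom: PhantomConfig = None
    noise_sd: float = 30.0            # HU; realistic CT noise level
    coarseness_fine: int = 4          # mesh downsampling, Models 1-3
    coarseness_simplified: int = 8    # Model 4 / industrial-style
    bite_force_N: float = 450.0
    bite_direction: tuple = (0.0, 0.0, 1.0)   # superior axis surrogate
    friction: float = 0.3
    reference_stress: float = None    # None: industrial-style run's own peak
    # the phantom has no partial-volume blur, so midpoint thresholds are
    # already exact; gap closing stays available for real data but defaults
    # off (it would fill staircase concavities of the clean masks)
    min_island_voxels: int = 8
    closing_radius: int = 0
    seed: int = 0

    def phantom_config(self, dummy_screws: bool) -> PhantomConfig:
        base = self.phantom or PhantomConfig()
        return replace(base, noise_sd=self.noise_sd, seed=self.seed,
                       dummy_screws=dummy_screws)


@dataclass
class VariantRun:
    """Artifacts of one executed variant."""

    spec: VariantSpec
    summary: StressSummary
    solution: object
    mesh: TetMesh
    labels: LabelVolume
    truth: PhantomTruth
    dropped_muscles: list
    n_nodes: int
    n_elements: int

    def manifest(self) -> dict:
        return dict(variant=self.spec.name,
                    spec=self.spec.__dict__,
                    n_nodes=self.n_nodes, n_elements=self.n_elements,
                    dropped_muscles=self.dropped_muscles,
                    summary=self.summary.as_dict(),
                    residual=float(self.solution.residual),
                    diagnostics={k: (float(v) if isinstance(v, (int, float)) else v)
                                 for k, v in self.solution.diagnostics.items()})


def _midpoint(truth: PhantomTruth, a: str, b: str) -> float:
    return 0.5 * (truth.nominal_hu[a] + truth.nominal_hu[b])


def _region_array(vol: ImageVolume, spec: dict) -> np.ndarray:
    centers = vol.voxel_centers()
    if spec.get("type") == "boxes":
        out = np.zeros(vol.shape, dtype=bool)
        for lo, hi in spec["boxes"]:
            out |= np.all((centers >= np.asarray(lo))
                          & (centers <= np.asarray(hi)), axis=-1)
        return out
    lo = np.asarray(spec["lo"])
    hi = np.asarray(spec["hi"])
    return np.all((centers >= lo) & (centers <= hi), axis=-1)


def segment_phantom(hu_vol: ImageVolume, truth: PhantomTruth,
                    prosthesis_source: str = "segmented",
                    dummy_screws: bool = False,
                    min_island: int = 8, closing_radius: int = 0) -> LabelVolume:
    """Threshold + cleanup segmentation of the calibrated phantom volume.

    Thresholds sit at the midpoints between the nominal tissue HU values
    (the reproducible stand-in for an operator-tuned adaptive threshold);
    each mask is restricted to its configured bounding region and cleaned
    morphologically.  Screw masks skip the closing step, mirroring the
    decision not to smooth screw-scale structures.  With
    ``prosthesis_source="cad"`` the metal parts are rasterized from the
    exact CAD surfaces (aligned with the configured transform) instead.
    """
    bone_lo = _midpoint(truth, "soft_tissue", "trabecular")
    bone_hi = _midpoint(truth, "cortical", "dentin")
    teeth_hi = _midpoint(truth, "enamel", "titanium")

    masks = []
    if prosthesis_source == "cad":
        pose = align_surface(truth.surfaces["prosthesis"][0],
                             truth.surfaces["prosthesis"][0],
                             init=None, refine=False)  # explicit "manual" placement
        part_order = ["prosthesis", "screws"] + (
            ["dummy_screws"] if dummy_screws else [])
        for part in part_order:
            m = np.zeros(hu_vol.shape, dtype=bool)
            for s in truth.surfaces.get(part, []):
                m |= voxelize_surface(s.transformed(pose), hu_vol.shape,
                                      hu_vol.spacing, hu_vol.origin).data
            masks.append(Mask(m, name=part, spacing=hu_vol.spacing,
                              origin=hu_vol.origin))
    else:
        for part in ["prosthesis", "screws"] + (
                ["dummy_screws"] if dummy_screws else []):
            region = _region_array(hu_vol, truth.regions[f"seg_{part}"])
            m = threshold_mask(hu_vol, lo=teeth_hi, hi=None, region=region,
                               name=part)
            masks.append(morph_clean(m, min_island=max(2, min_island // 2),
                                     closing_radius=0))

    for tooth in ("tooth_31", "tooth_33", "tooth_47"):
        region = _region_array(hu_vol, truth.regions[f"seg_{tooth}"])
        m = threshold_mask(hu_vol, lo=bone_hi, hi=teeth_hi, region=region,
                           name=tooth)
        masks.append(morph_clean(m, min_island=min_island,
                                 closing_radius=closing_radius))

    m = threshold_mask(hu_vol, lo=bone_lo, hi=bone_hi, name="mandible")
    masks.append(morph_clean(m, min_island=min_island,
                             closing_radius=closing_radius))

    # priority: prosthesis > screws (> dummy screws) > teeth > mandible
    return resolve_priority(masks)


def _merge_teeth(labels: LabelVolume) -> LabelVolume:
    """Merge all tooth parts into the mandible label (Model-4 simplification)."""
    data = labels.data.copy()
    names = dict(labels.names)
    mand = labels.id_of("mandible")
    for name in list(names.values()):
        if name.startswith("tooth"):
            tid = labels.id_of(name)
            data[data == tid] = mand
            names.pop(tid)
    return LabelVolume(data, names, spacing=labels.spacing, origin=labels.origin)


def run_variant(spec: VariantSpec, config: WorkflowConfig | None = None,
                reference: float = None, workdir=None) -> VariantRun:
    """Execute one variant end to end on the phantom.

    phantom -> calibrate -> segment (or CAD rasterize) -> materials ->
    mesh -> node sets -> interface split -> solve -> peak stress.
    ``reference`` normalizes the peak (defaults to the run's own peak).
    """
    config = config or WorkflowConfig()
    pconf = config.phantom_config(dummy_screws=spec.dummy_screws)
    raw, truth = build_phantom(pconf)

    # two-point calibration from the water and air sample regions
    water = raw.data[_region_array(raw, dict(lo=truth.water_box[0],
                                             hi=truth.water_box[1]))].mean()
    air = raw.data[_region_array(raw, dict(lo=truth.air_box[0],
                                           hi=truth.air_box[1]))].mean()
    hu_vol = calibrate(raw, mean_water=water, mean_air=air)

    labels = segment_phantom(hu_vol, truth,
                             prosthesis_source=spec.prosthesis_source,
                             dummy_screws=spec.dummy_screws,
                             min_island=config.min_island_voxels,
                             closing_radius=config.closing_radius)
    if spec.teeth == "merged":
        labels = _merge_teeth(labels)

    coarseness = (config.coarseness_simplified if spec.bone_material == "uniform"
                  else config.coarseness_fine)
    pid_weights = {labels.id_of(name): w
                   for name, w in _DOWNSAMPLE_WEIGHTS.items()
                   if name in labels.names.values()}
    mesh = mesh_from_labels(labels, coarseness=coarseness, weights=pid_weights)

    # separate the prosthesis from the mandible (screws stay bonded to both)
    iface = interface_facets(mesh, "mandible", "prosthesis")
    keep = tuple(p for p in ("screws", "dummy_screws")
                 if p in labels.names.values())
    mesh, pairs = split_interface(mesh, "mandible", "prosthesis",
                                  keep_bonded_parts=keep)

    regions = {k: v for k, v in truth.regions.items()
               if not k.startswith("seg_")}
    if spec.teeth == "merged":
        regions["bite_tooth_47"] = dict(regions["bite_tooth_47"], part="mandible")
    define_node_sets(mesh, regions)

    table = load_material_table()
    part_modes = {"prosthesis": "titanium", "screws": "titanium",
                  "dummy_screws": "titanium"}
    part_modes["mandible"] = ("uniform_bone" if spec.bone_material == "uniform"
                              else "mapped")
    for name in labels.names.values():
        if name.startswith("tooth"):
            part_modes[name] = "tooth"
    materials = assign_element_materials(mesh, hu_vol, labels, table,
                                         part_modes=part_modes)

    loadcase = LoadCase(
        dirichlet=[dict(set="prosthesis_condyle", components=(0, 1, 2)),
                   dict(set="contralateral_condyle", components=(0, 1, 2))])
    bite = np.asarray(config.bite_direction, dtype=float)
    bite = bite / np.linalg.norm(bite) * config.bite_force_N
    loadcase.loads.append(dict(set="bite_tooth_47", total=bite))

    dropped = []
    for _, row in truth.muscles.iterrows():
        name = row["name"]
        if len(mesh.node_sets.get(name, ())) == 0:
            dropped.append(name)  # attachment on resected bone: removed
            continue
        loadcase.loads.append(dict(set=name,
                                   total=(row["Fx"], row["Fy"], row["Fz"])))

    if spec.contact == "frictional" and len(pairs):
        loadcase.contact.append(ContactPair(
            slave_nodes=pairs[:, 1], master_facets=iface,
            mode="frictional", friction=config.friction))
        solution = solve_contact(mesh, materials, loadcase)
    elif spec.contact == "bonded" and len(pairs):
        loadcase.ties.extend(apply_bonded_mpc(mesh, pairs[:, 1], iface))
        solution = solve_linear(mesh, materials, loadcase)
    else:
        solution = solve_linear(mesh, materials, loadcase)

    peak = peak_stress(solution, mesh, "prosthesis",
                       reference=reference or 1.0, variant=spec.name)
    if reference is None:
        peak = peak_stress(solution, mesh, "prosthesis",
                           reference=peak.peak_MPa, variant=spec.name)

    run = VariantRun(spec=spec, summary=peak, solution=solution, mesh=mesh,
                     labels=labels, truth=truth, dropped_muscles=dropped,
                     n_nodes=mesh.n_nodes, n_elements=mesh.n_elements)
    if workdir is not None:
        _persist(run, materials, Path(workdir))
    return run


def _persist(run: VariantRun, materials, workdir: Path) -> None:
    out = workdir / run.spec.name
    out.mkdir(parents=True, exist_ok=True)
    (out / "summary.json").write_text(json.dumps(run.manifest(), indent=2))
    write_mesh(run.mesh, materials, out / "mesh.vtk", dialect="vtk")
    np.savez_compressed(out / "labels.npz", labels=run.labels.data,
                        spacing=run.labels.spacing, origin=run.labels.origin)


def run_all(config: WorkflowConfig | None = None, workdir=None) -> dict:
    """Run Models 1-4, Model 4 with contact, and the industrial-style model.

    Returns a dict with the six stress summaries, the pairwise comparison
    table and a reproducibility manifest.  All normalized peaks use the
    industrial-style run's peak stress as reference (unless the config
    supplies one).
    """
    config = config or WorkflowConfig()

    # industrial-style: Model-4 geometry, bonded screws, plate-bone contact
    # left out of the frozen workflow
    industrial = run_variant(VariantSpec.model(4), config,
                             reference=config.reference_stress,
                             workdir=workdir)
    reference = config.reference_stress or industrial.summary.peak_MPa
    industrial.summary = peak_stress(industrial.solution, industrial.mesh,
                                     "prosthesis", reference, "industrial")

    runs = {"industrial": industrial}
    for number in (1, 2, 3):
        spec = VariantSpec.model(number)
        runs[spec.name] = run_variant(spec, config, reference=reference,
                                      workdir=workdir)
    # Model 4 without contact shares the industrial-style computation
    m4 = VariantRun(spec=VariantSpec.model(4), summary=peak_stress(
        industrial.solution, industrial.mesh, "prosthesis", reference,
        "model_4"), solution=industrial.solution, mesh=industrial.mesh,
        labels=industrial.labels, truth=industrial.truth,
        dropped_muscles=industrial.dropped_muscles,
        n_nodes=industrial.n_nodes, n_elements=industrial.n_elements)
    runs["model_4"] = m4
    spec4c = VariantSpec.model(4, contact="frictional")
    runs[spec4c.name] = run_variant(spec4c, config, reference=reference,
                                    workdir=workdir)

    summaries = [r.summary for r in runs.values()]
    report = compare_variants(summaries)
    manifest = dict(seed=config.seed, noise_sd=config.noise_sd,
                    coarseness_fine=config.coarseness_fine,
                    coarseness_simplified=config.coarseness_simplified,
                    bite_force_N=config.bite_force_N,
                    friction=config.friction,
                    reference_MPa=reference,
                    runs={k: r.manifest() for k, r in runs.items()})
    if workdir is not None:
        out = Path(workdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        report.to_csv(out / "comparison.csv", index=False)
    return dict(runs=runs, summaries=summaries, report=report,
                manifest=manifest, reference_MPa=reference)
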