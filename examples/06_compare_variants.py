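"""Full variant comparison: segmented vs CAD geometry, contact vs none.

Runs all four model variants plus the industrial-style reference on one
reduced phantom and prints the normalized peak-stress table.
"""

from tmjfem import PhantomConfig
from tmjfem.workflow import WorkflowConfig, run_all

config = WorkflowConfig(phantom=PhantomConfig(shape=(60, 60, 45), spacing=0.6),
                        noise_sd=30.0, coarseness_fine=2,
                        coarseness_simplified=4, seed=4)
result = run_all(config)

print(f"reference stress (industrial-style peak): "
      f"{result['reference_MPa']:.1f} MPa\n")
for s in result["summaries"]:
    print(f"  {s.variant:20s} normalized peak {s.normalized_peak:.3f} "
          f"({s.peak_MPa:8.1f} MPa), {result['runs'][s.variant].n_nodes} nodes")

print("\npairwise comparison:")
cols = ["variant_a", "variant_b", "difference_pct", "locations_coincide"]
print(result["report"][cols].to_string(index=False))
print("\nPeaks are normalized by the industrial-style run, so 1.0 means "
      "'same peak as the frozen reference workflow'.  The fine HU-mapped "
      "models read higher than the coarse uniform-bone model; the dummy "
      "screws barely move the peak; and on this phantom the segmented and "
      "CAD prosthesis coincide (segmentation recovers the truth exactly), "
      "so Models 1 and 2 agree.")
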