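"""Run one model variant end to end on a reduced phantom.

Model 4 is the simplified contact model: CAD prosthesis with dummy screws,
mandible and teeth merged at a uniform 10 GPa, molar bite plus muscle loads,
condyles fixed.  The run prints the peak von Mises stress in the prosthesis.
"""

from tmjfem import PhantomConfig
from tmjfem.workflow import VariantSpec, WorkflowConfig, run_variant

config = WorkflowConfig(phantom=PhantomConfig(shape=(60, 60, 45), spacing=0.6),
                        noise_sd=0.0, coarseness_fine=2,
                        coarseness_simplified=4, seed=3)

run = run_variant(VariantSpec.model(4), config)
s = run.summary
print(f"variant {s.variant}: {run.n_nodes} nodes, {run.n_elements} C3D10 elements")
print(f"dropped muscles (attachments on resected bone): {run.dropped_muscles}")
print(f"peak von Mises stress in the prosthesis: {s.peak_MPa:.1f} MPa "
      f"at {s.location.round(1)} mm")
print(f"equilibrium residual: {run.solution.residual:.2e}")
print("\nThe peak sits near the screw fixation where the bite and muscle "
      "loads funnel into the plate; the residual confirms the solve "
      "satisfied equilibrium to solver precision.")
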