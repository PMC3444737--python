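"""Activation of a synthetic left-ventricle shell from endocardial patches.

Builds a truncated-ellipsoid shell with a rule-based transmural fiber helix
(3164 blue-noise nodes), stimulates six endocardial patches standing in for
Purkinje exit sites, and reports the activation sequence. Writes a VTK point
cloud with per-node activation times for visualization.
"""

from pathlib import Path

import numpy as np

from efgmep.experiments import run_ventricle
from efgmep.vtkio import write_vtk_points

rep = run_ventricle(n=3164, seed=3)
act = rep["activation"]

print(f"nodes: {rep['cloud'].n_nodes}, stimulated: {len(rep['stim_nodes'])}")
print(f"all nodes activated: {rep['all_activated']}")
print(f"activation time range: {act.times.min():.1f} .. {act.times.max():.1f} ms")
print(f"mean endocardial activation: {rep['endo_mean_activation']:.1f} ms")
print(f"mean epicardial activation:  {rep['epi_mean_activation']:.1f} ms")
print("\nThe endocardium activates before the epicardium at matched wall")
print("locations: the wave enters at the inner wall and crosses the ~10 mm")
print("wall against the slower cross-fiber diffusivity.")

out = Path("scratch") if Path("scratch").is_dir() else Path(".")
path = out / "ventricle_activation.vtk"
write_vtk_points(path, rep["cloud"].positions,
                 scalars={"activation_time_ms": act.times},
                 vectors={"fiber": rep["fibers"].vectors})
print(f"\nwrote {path} (legacy VTK point cloud; open in ParaView)")
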