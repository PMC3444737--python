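"""Heat-conduction convergence: meshfree Galerkin vs bilinear FEM.

Runs the diffusion benchmark (analytic radial kernel from t = 1 to t = 2 on
a 20x20 mm square) for two node spacings and prints the nodal RMS errors.
The meshfree solver with a moderate influence-domain size (d_max = 2) is far
more accurate than linear finite elements on the identical lattice and
quadrature; with a minimal influence domain (d_max = 1.1) it behaves like
FEM.
"""

from efgmep.experiments import run_heat2d

hs = (1.0, 0.5)
fem = run_heat2d(h_values=hs, method="fem")
efgm_small = run_heat2d(h_values=hs, method="efgm", d_max=1.1)
efgm = run_heat2d(h_values=hs, method="efgm", d_max=2.0)

print(f"{'h (mm)':>8} {'FEM':>12} {'EFGM d_max=1.1':>16} {'EFGM d_max=2':>14}")
for rf, r1, r2 in zip(fem.rows, efgm_small.rows, efgm.rows):
    print(f"{rf.h:>8} {rf.rms:>12.3e} {r1.rms:>16.3e} {r2.rms:>14.3e}")

print("\nRMS is the nodal root-mean-square error against the analytic kernel")
print("at t = 2. The d_max=1.1 column tracks FEM (minimal influence domains");
print("recover a linear-element-like approximation); d_max=2 gains roughly")
print("two orders of magnitude from the wider, smoother MLS fit.")
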