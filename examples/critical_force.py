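"""Critical-force workflow: FEM sweep, then live monitoring of a force trace.

Solves a desk-scale cantilever bar (the verification stand-in for instrument-
on-bone loading), finds the smallest load whose peak von Mises stress reaches
a yield threshold, and then replays a force ramp through the warning monitor:
one warning per excursion above the critical force, stamped at the first
exceeding sample.
"""

import numpy as np

from mrsim import Material, critical_force_sweep, monitor_force, solve_static
from mrsim.fem import face_traction_loads
from mrsim.motion import ForceTrace
from mrsim.synthetic import gen_block_tetmesh

# 60 x 10 x 10 mm bar (metres here), clamped at one end, pulled at the other
E, L, side = 12e9, 0.06, 0.01
mesh = gen_block_tetmesh(6, 2, 2, (L, side, side))
mesh.material = Material(E, 0.0)
mesh.constrained_nodes = {i for i, p in enumerate(mesh.nodes) if p[0] < 1e-12}
tip = mesh.nodes[:, 0] > L - 1e-12
force = 100.0  # N resultant of the unit load pattern
mesh.loads = face_traction_loads(mesh, tip, np.array([force / side**2, 0, 0]))

result = solve_static(mesh)
print(f"max von Mises at {force:g} N: {result.max_von_mises:.4g} Pa "
      f"(analytic F/A = {force / side**2:.4g} Pa)")

yield_stress = 1e8  # Pa, illustrative threshold
f_crit = critical_force_sweep(mesh, mesh.loads, yield_stress) * force
print(f"critical force: {f_crit:.4g} N (analytic Y*A = {yield_stress * side**2:.4g} N)")

# monitor a 0 -> 40 N instrument force ramp against the 20 N default threshold
trace = ForceTrace(np.arange(41.0) * 0.05, np.arange(41.0))
for ev in monitor_force(trace):
    print(f"warning at t={ev.timestamp:.2f}s: {ev.message}")
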