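"""Analytic benchmark: minimum-time thrust steering.

A vehicle accelerates at a constant 100 m/s^2 in a direction chosen by
the steering-angle control, and must reach altitude 5 m with horizontal
speed 45 m/s and zero vertical speed as fast as possible.  The optimal
control satisfies tan(theta) linear in time, and the whole trajectory
has a closed form — an independent oracle for the collocation stack.
The printed RMS error compares every state and the control on the mesh.
"""
from collosim.verify import solve_linear_tangent

report, solution, oracle = solve_linear_tangent(num_mesh_intervals=100)
print(f"status:          {solution.status}")
print(f"final time:      {solution.duration:.7f} s "
      f"(analytic {oracle.tf:.7f} s)")
print(report)
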