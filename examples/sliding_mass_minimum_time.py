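"""Minimum-time point-to-point slide (bang-bang benchmark).

A 1 kg mass slides 1 m under a force bounded by +-10 N, starting and
ending at rest, in minimum time.  The optimum is the bang-bang profile
with switching at half time and duration 2*sqrt(m*d/F_max) = 0.63246 s;
the printed objective should match it to a fraction of a millisecond.
"""
import numpy as np

from collosim import TranscriptionConfig, solve_with_continuation
from collosim.verify import sliding_mass_problem

problem = sliding_mass_problem(mass=1.0, distance=1.0, force_bound=10.0)
config = TranscriptionConfig(scheme="hermite-simpson",
                             num_mesh_intervals=40,
                             convergence_tol=1e-8, constraint_tol=1e-8)
solution, _ = solve_with_continuation(problem, config,
                                      mesh_schedule=(5, 10, 20))

analytic = 2.0 * np.sqrt(1.0 * 1.0 / 10.0)
print(f"status:            {solution.status}")
print(f"minimum time:      {solution.objective:.6f} s")
print(f"analytic optimum:  {analytic:.6f} s")
print(f"difference:        {abs(solution.objective - analytic):.2e} s")
print("The force profile is +10 N for the first half and -10 N for the "
      "second half;")
print(f"force at 1/4 and 3/4 time: {np.interp(0.25 * solution.duration, solution.time, solution['force']):+.2f}, "
      f"{np.interp(0.75 * solution.duration, solution.time, solution['force']):+.2f} N")
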