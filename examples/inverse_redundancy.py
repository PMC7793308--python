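"""Muscle redundancy: which activations produced an observed motion?

A motion of the suspended mass is synthesized by forward simulation with
known muscle activity; the inverse tool then receives only the
kinematics (positions and speeds over time) and solves for excitations,
activations, and small bounded reserve forces that reproduce the
inverse-dynamics loads.  The printed RMS difference shows how well the
known activity is recovered; the reserve peak shows how little of the
motion the muscles could not explain.
"""
import numpy as np

from collosim import MuscularSystem, solve_inverse
from collosim.verify import (forward_shooting, predict_suspended_mass,
                             suspended_mass_fixture)

model = suspended_mass_fixture()
system = MuscularSystem(model)
prediction = predict_suspended_mass(num_mesh_intervals=25,
                                    mesh_schedule=(10,))
x0 = np.array([prediction[nm][0] for nm in system.state_names])
dense = np.linspace(prediction.time[0], prediction.time[-1], 201)
synth = forward_shooting(system, prediction, x0,
                         (prediction.time[0], prediction.time[-1]),
                         t_eval=dense, rtol=1e-10)

inverse = solve_inverse(model, synth, num_mesh_intervals=25)
names = [f"{m}_activation" for m in ("left", "middle", "right")]
a_ref = np.stack([np.interp(inverse.time, synth.time, synth[nm])
                  for nm in names])
a_inv = np.stack([inverse[nm] for nm in names])
rms = np.sqrt(np.mean((a_inv - a_ref) ** 2))
print(f"inverse status:      {inverse.status}")
print(f"activation RMS:      {100 * rms / np.abs(a_ref).max():.2f}% "
      "of peak (recovery of the known activity)")
reserves = np.stack([inverse[f"reserve_{c}"] for c in ("x", "y")])
print(f"peak reserve force:  {np.abs(reserves).max():.3f} N "
      "(unexplained load; should be near zero)")
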