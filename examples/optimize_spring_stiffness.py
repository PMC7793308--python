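"""Optimize the stiffness of an assistive torsional spring.

A single-joint sit-to-stand model (torso pendulum with an extensor and a
flexor muscle) stands up while minimizing squared excitations plus
duration.  Re-solving with the spring stiffness as a free optimization
variable finds the assistance level that minimizes the same cost; the
objective can only improve (zero stiffness remains feasible) and the
extensor works less on average.
"""
from collosim.verify import spring_assist_experiment

unassisted, assisted, k_opt, bound_limited = spring_assist_experiment()
print(f"unassisted objective: {unassisted.objective:.4f} "
      f"(duration {unassisted.duration:.3f} s)")
print(f"assisted objective:   {assisted.objective:.4f} "
      f"(duration {assisted.duration:.3f} s)")
print(f"optimal stiffness:    {k_opt:.1f} N m/rad"
      + ("  [at a bound!]" if bound_limited else ""))
print(f"mean extensor activation: "
      f"{unassisted['extensor_activation'].mean():.3f} -> "
      f"{assisted['extensor_activation'].mean():.3f}")
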