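model:
  name: sliding_mass
  gravity:
  - 0.0
  - 0.0
  bodies:
  - name: mass
    mass: 1.0
    inertia: 0.0
    com:
    - 0.0
    - 0.0
  joints:
  - kind: slider
    child: mass
    parent: ground
    parent_point:
    - 0.0
    - 0.0
    child_point:
    - 0.0
    - 0.0
    axis:
    - 1.0
    - 0.0
    coordinates:
    - name: x
      unit: m
      bounds:
      - -5.0
      - 5.0
  muscles: []
  springs: []
  contacts: []
  actuators:
  - name: force
    coordinate: x
    gain: 1.0
  constraints: []
problem:
  duration:
  - 0.05
  - 2.0
  state_initial:
    x: 0.0
    x_u: 0.0
  state_final:
    x: 1.0
    x_u: 0.0
  control_bounds:
    force:
    - -10.0
    - 10.0
  goals:
  - kind: final_time
    weight: 1.0
solver:
  scheme: hermite-simpson
  num_mesh_intervals: 20
  convergence_tol: 1.0e-08
  constraint_tol: 1.0e-08
  mesh_continuation:
  - 5
  - 10
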