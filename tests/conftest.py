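"""Shared (session-scoped) fixtures.

The expensive nonlinear-program solves are computed once per session:
the Hermite-Simpson N=50 suspended-mass prediction (used by the
time-stepping, tracking-recovery, and inverse-tool tests) and the
sliding-mass minimum-time mesh ladder (used by the convergence and
bang-bang tests).
"""

import warnings

import numpy as np
import pytest

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def suspended_prediction():
    from collosim.verify import predict_suspended_mass
    return predict_suspended_mass(num_mesh_intervals=50,
                                  mesh_schedule=(10, 25))


@pytest.fixture(scope="session")
def sliding_mass_ladder():
    """Minimum-time solutions over N in {5,10,20,40} with guess chaining,
    per scheme."""
    from collosim.verify import sliding_mass_problem
    from collosim.problem import solve_problem
    from collosim.transcription import TranscriptionConfig
    out = {}
    for scheme in ("trapezoidal", "hermite-simpson"):
        prob = sliding_mass_problem()
        guess, sols = None, {}
        for N in (5, 10, 20, 40):
            cfg = TranscriptionConfig(scheme=scheme, num_mesh_intervals=N,
                                      convergence_tol=1e-8,
                                      constraint_tol=1e-8)
            sol, _ = solve_problem(prob, cfg, guess=guess)
            sols[N] = sol
            guess = sol
        out[scheme] = sols
    return out
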