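"""Transcription layer: grids, defect operators, NLP layout, and small
solves."""

import numpy as np
import pytest

from collosim import model as md
from collosim.system import MuscularSystem
from collosim.problem import (ProblemDef, ControlEffortGoal, FinalTimeGoal,
                              solve_problem)
from collosim.transcription import (TranscriptionConfig, build_grid,
                                    trapezoidal_defect,
                                    hermite_simpson_defect, assemble_nlp,
                                    solve_nlp, check_gradient)


def sliding_mass_model():
    return md.ModelSpec(
        name="sliding_mass",
        bodies=[md.Body("mass", mass=1.0)],
        joints=[md.Joint("slider", child="mass",
                         coordinates=[md.Coordinate("x", "m",
                                                    (-5.0, 5.0))])],
        actuators=[md.CoordinateActuator("force", "x")],
        gravity=(0.0, 0.0))


def sliding_mass_problem(F_max=10.0):
    sys_ = MuscularSystem(sliding_mass_model())
    return ProblemDef(system=sys_, duration=(0.05, 2.0),
                      state_initial={"x": 0.0, "x_u": 0.0},
                      state_final={"x": 1.0, "x_u": 0.0},
                      control_bounds={"force": (-F_max, F_max)},
                      goals=[FinalTimeGoal(1.0)])


class TestGrid:
    @pytest.mark.parametrize("N,expect", [(2, 5), (25, 51), (40, 81)])
    def test_hermite_simpson_point_count(self, N, expect):
        cfg = TranscriptionConfig(scheme="hermite-simpson",
                                  num_mesh_intervals=N)
        assert build_grid(cfg, 0.0, 1.0).size == expect

    def test_trapezoidal_points(self):
        cfg = TranscriptionConfig(scheme="trapezoidal",
                                  num_mesh_intervals=2)
        np.testing.assert_allclose(build_grid(cfg, 0.0, 1.0),
                                   [0.0, 0.5, 1.0])

    def test_too_few_intervals(self):
        with pytest.raises(ValueError):
            TranscriptionConfig(num_mesh_intervals=1)

    def test_reversed_span(self):
        cfg = TranscriptionConfig(num_mesh_intervals=4)
        with pytest.raises(ValueError):
            build_grid(cfg, 1.0, 0.0)


class TestDefectOperators:
    def test_trapezoid_exact_for_linear_rate(self):
        # xdot = t on [0,1] with exact endpoint values
        assert trapezoidal_defect(0.0, 0.5, 0.0, 1.0, 1.0) \
            == pytest.approx(0.0)

    def test_trapezoid_quadratic_rate_error(self):
        # xdot = t^2: exact endpoints give defect 1/3 - 1/2 = -1/6
        d = trapezoidal_defect(0.0, 1.0 / 3.0, 0.0, 1.0, 1.0)
        assert d == pytest.approx(-1.0 / 6.0)

    def test_hs_exact_through_cubics(self):
        # x = t^3 on [0,1], xdot = 3 t^2, consistent midpoint values
        interp, integ = hermite_simpson_defect(
            0.0, 0.125, 1.0, 0.0, 0.75, 3.0, 1.0)
        assert interp == pytest.approx(0.0, abs=1e-15)
        assert integ == pytest.approx(0.0, abs=1e-15)

    def test_hs_quartic_rate_error(self):
        # xdot = t^4: Simpson integrates 5/24, true integral 1/5
        _, integ = hermite_simpson_defect(
            0.0, 1.0 / 5.0 / 32.0, 1.0 / 5.0, 0.0, 1.0 / 16.0, 1.0, 1.0)
        assert integ == pytest.approx(1.0 / 5.0 - 5.0 / 24.0)

    def test_constant_rate_both_schemes(self):
        f = 2.0
        assert trapezoidal_defect(1.0, 1.0 + 0.5 * f, f, f, 0.5) \
            == pytest.approx(0.0)
        interp, integ = hermite_simpson_defect(
            1.0, 1.0 + 0.25 * f, 1.0 + 0.5 * f, f, f, f, 0.5)
        assert interp == pytest.approx(0.0)
        assert integ == pytest.approx(0.0)

    def test_nonpositive_spacing_rejected(self):
        with pytest.raises(ValueError):
            trapezoidal_defect(0.0, 1.0, 1.0, 1.0, 0.0)

    @pytest.mark.parametrize("deg", range(5))
    def test_exactness_degrees_on_monomials(self, deg):
        """Trapezoid integrates rate polynomials exactly up to degree 1,
        Simpson up to degree 3; the first failing degree has the known
        quadrature error."""
        h = 1.0
        # exact increment of x for xdot = t^deg over [0,1]
        inc = 1.0 / (deg + 1)
        f0 = 1.0 if deg == 0 else 0.0
        trap = trapezoidal_defect(0.0, inc, f0, 1.0, h)
        x_mid = 0.5 ** (deg + 1) / (deg + 1)
        _, simp = hermite_simpson_defect(0.0, x_mid, inc, f0,
                                         0.5 ** deg, 1.0, h)
        if deg <= 1:
            assert trap == pytest.approx(0.0, abs=1e-15)
        else:
            assert abs(trap) > 1e-3
        if deg <= 3:
            assert simp == pytest.approx(0.0, abs=1e-15)
        else:
            assert abs(simp) > 1e-3


class TestLayout:
    def test_sliding_mass_trapezoidal_variable_count(self):
        # 11 points x (2 states + 1 control) + 1 free-duration slot
        nlp = assemble_nlp(sliding_mass_problem(),
                           TranscriptionConfig(scheme="trapezoidal",
                                               num_mesh_intervals=10))
        assert nlp.n_vars == 34

    def test_hs_point_mass_variable_count(self):
        # 21 points x (2 + 1) + 1 free-duration slot
        nlp = assemble_nlp(sliding_mass_problem(),
                           TranscriptionConfig(scheme="hermite-simpson",
                                               num_mesh_intervals=10))
        assert nlp.n_vars == 64

    def test_parameter_adds_one_variable(self):
        from collosim.problem import register_parameter
        spec = sliding_mass_model()
        spec.springs = [md.TorsionalSpring("x", stiffness=5.0)]
        prob = ProblemDef(system=MuscularSystem(spec), duration=1.0,
                          goals=[ControlEffortGoal(1.0)])
        cfg = TranscriptionConfig(num_mesh_intervals=5)
        base = assemble_nlp(prob, cfg).n_vars
        register_parameter(prob, "springs/x/stiffness", (0.0, 300.0))
        assert assemble_nlp(prob, cfg).n_vars == base + 1

    def test_layout_is_bijective(self):
        nlp = assemble_nlp(sliding_mass_problem(),
                           TranscriptionConfig(scheme="hermite-simpson",
                                               num_mesh_intervals=4))
        z = np.arange(nlp.n_vars, dtype=float)
        dt, X, C, GAM, P = nlp.unpack(z)
        repacked = nlp.pack(dt, X, C, GAM, P)
        np.testing.assert_array_equal(repacked, z)

    def test_default_guess_is_bound_midpoint(self):
        nlp = assemble_nlp(sliding_mass_problem(),
                           TranscriptionConfig(scheme="trapezoidal",
                                               num_mesh_intervals=4))
        z = nlp.default_guess()
        both = np.isfinite(nlp.lb) & np.isfinite(nlp.ub)
        np.testing.assert_allclose(z[both],
                                   0.5 * (nlp.lb + nlp.ub)[both])
        assert np.all(z[~both] == 0.0)


class TestSolveValidation:
    def test_nan_guess_rejected_before_solver(self):
        nlp = assemble_nlp(sliding_mass_problem(),
                           TranscriptionConfig(num_mesh_intervals=4))
        bad = nlp.default_guess()
        bad[3] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            solve_nlp(nlp, guess=bad)

    def test_crossed_bounds_rejected(self):
        prob = sliding_mass_problem()
        prob.control_bounds = {"force": (10.0, -10.0)}
        with pytest.raises(ValueError, match="lower > upper"):
            assemble_nlp(prob, TranscriptionConfig(num_mesh_intervals=4))

    def test_unbounded_free_time_rejected(self):
        prob = sliding_mass_problem()
        prob.duration = (0.1, np.inf)
        with pytest.raises(ValueError):
            assemble_nlp(prob, TranscriptionConfig(num_mesh_intervals=4))


class TestSmallSolves:
    def test_quadratic_program(self):
        """min (c-3)^2 posed as an effort goal on a dynamically inert
        control (zero-gain actuator), exercising the bare solver path."""
        spec = sliding_mass_model()
        spec.actuators = [md.CoordinateActuator("force", "x", gain=0.0)]
        prob = ProblemDef(system=MuscularSystem(spec), duration=1.0,
                          state_bounds={"x": (0.0, 0.0), "x_u": (0.0, 0.0)},
                          control_bounds={"force": (-10.0, 10.0)},
                          goals=[ControlEffortGoal(1.0)])

        class Shifted(ControlEffortGoal):
            def integrand(self, x, c, t, p):
                g, gx, gc, gt, gp = super().integrand(x - 0, c - 3.0, t, p)
                return g, gx, gc, gt, gp
        prob.goals = [Shifted(1.0)]
        cfg = TranscriptionConfig(scheme="trapezoidal",
                                  num_mesh_intervals=4,
                                  convergence_tol=1e-8,
                                  constraint_tol=1e-8)
        nlp = assemble_nlp(prob, cfg)
        raw = solve_nlp(nlp)
        assert raw.status == "converged"
        _, _, C, _, _ = nlp.unpack(raw.z)
        np.testing.assert_allclose(C[:, 0], 3.0, atol=1e-3)

    def test_objective_gradient_matches_fd(self):
        nlp = assemble_nlp(sliding_mass_problem(),
                           TranscriptionConfig(scheme="hermite-simpson",
                                               num_mesh_intervals=4))
        rng = np.random.default_rng(3)
        z = np.clip(nlp.default_guess()
                    + 0.1 * rng.standard_normal(nlp.n_vars),
                    nlp.lb, nlp.ub)
        assert check_gradient(nlp, z) < 1e-4


@pytest.fixture()
def sliding_mass_solutions(sliding_mass_ladder):
    return sliding_mass_ladder


class TestDynamicsModes:
    def test_implicit_residual_vanishes_at_forward_dynamics_accel(self):
        """Setting the acceleration variables to the explicit
        forward-dynamics output zeroes the implicit residual."""
        from collosim.verify import suspended_mass_fixture
        sys_ = MuscularSystem(suspended_mass_fixture())
        rng = np.random.default_rng(5)
        T = 7
        x = np.vstack([rng.uniform(-0.1, 0.1, T),
                       rng.uniform(-0.22, -0.1, T),
                       rng.uniform(-1, 1, (2, T)),
                       rng.uniform(0.05, 0.9, (3, T))])
        c = rng.uniform(0.05, 0.9, (3, T))
        lam = np.zeros((0, T))
        t = np.linspace(0, 1, T)
        xdot = sys_.rate(x, c, lam, t, ())
        w = xdot[2:4]
        res = sys_.implicit_residual(x, c, lam, w, t, ())
        assert np.max(np.abs(res)) < 1e-9
        np.testing.assert_array_equal(
            sys_.implicit_rate(x, c, lam, w, t, ()), xdot)

    def test_equilibrium_pendulum_rate_is_zero(self):
        """An unactuated pendulum hanging at rest has a zero state
        derivative."""
        spec = md.ModelSpec(
            name="pend",
            bodies=[md.Body("rod", mass=1.0, com=(0.0, -0.5))],
            joints=[md.Joint("pin", child="rod",
                             coordinates=[md.Coordinate("theta")])])
        sys_ = MuscularSystem(spec)
        xdot = sys_.rate(np.zeros((2, 1)), np.zeros((0, 1)),
                         np.zeros((0, 1)), np.zeros(1), ())
        np.testing.assert_allclose(xdot, 0.0, atol=1e-14)


class TestSlidingMassMinimumTime:
    analytic = 2.0 * np.sqrt(1.0 * 1.0 / 10.0)

    def test_bang_bang_objective(self, sliding_mass_solutions):
        sol = sliding_mass_solutions["hermite-simpson"][40]
        assert sol.success
        assert abs(sol.objective - self.analytic) < 1e-4

    def test_mesh_error_decreases(self, sliding_mass_solutions):
        # trapezoidal errors decay cleanly (O(h^2)); Hermite-Simpson errors
        # sit at the solver-tolerance floor, so monotonicity is asserted up
        # to that floor
        for scheme, floor in (("trapezoidal", 0.0),
                              ("hermite-simpson", 2e-5)):
            errs = [abs(sliding_mass_solutions[scheme][N].objective
                        - self.analytic) for N in (5, 10, 20, 40)]
            for a, b in zip(errs, errs[1:]):
                assert b <= a + floor

    def test_all_converged_and_audited(self, sliding_mass_solutions):
        for scheme, sols in sliding_mass_solutions.items():
            for N, sol in sols.items():
                assert sol.success, (scheme, N, sol.status)
                assert sol.residuals["max"] <= 1e-8
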