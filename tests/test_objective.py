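"""Objective worked values, termination rule, and the CMA-ES harness."""

import math

import numpy as np
import pytest

import balancesim as bs
from balancesim import cmaes
from balancesim.objective import (DOFLimits, ObjectiveWeights,
                                  check_termination, dof_penalty_rate,
                                  evaluate_objective)
from balancesim.optimize import (OptimizerConfig, default_initial_params,
                                 optimize_condition, restart_seeds,
                                 warm_start_sweep)
from balancesim.perturbation import Condition, Protocol
from balancesim.trajectory import Trajectory


def synthetic_traj(duration=10.0, dt=1e-2, act=0.0, knee_deg=0.0,
                   tilt_deg=0.0, tx=0.0, t_term=None, fell=False):
    n = int(round(duration / dt)) + 1
    q = np.zeros((n, 9))
    q[:, 4] = q[:, 7] = math.radians(knee_deg)
    q[:, 2] = math.radians(tilt_deg)
    q[:, 0] = tx
    zeros2 = np.zeros((n, 2))
    return Trajectory(
        t=np.arange(n) * dt, q=q, qdot=np.zeros((n, 9)),
        act=np.full((n, 18), act), exc=np.zeros((n, 18)),
        muscle_force=np.zeros((n, 18)), contact_normal=np.zeros((n, 4)),
        contact_tangential=np.zeros((n, 4)), com=zeros2, com_vel=zeros2,
        foot_com=zeros2, cop=np.zeros(n), platform=zeros2, grf=zeros2,
        dt=dt, t_term=duration if t_term is None else t_term, fell=fell,
        effort_integral=0.0, dof_integral=0.0,
        muscle_names=tuple(f"m{i}" for i in range(18)))


class TestDofPenalty:
    def test_within_limits_zero(self):
        assert dof_penalty_rate(np.zeros(9)) == 0.0

    def test_knee_violation_is_ten(self):
        q = np.zeros(9)
        q[4] = math.radians(35.0)
        assert dof_penalty_rate(q) == 10.0

    def test_all_three_violated_is_thirty(self):
        q = np.zeros(9)
        q[7] = math.radians(31.0)
        q[2] = math.radians(-16.0)
        q[0] = 0.25
        assert dof_penalty_rate(q) == 30.0

    def test_limits_are_exclusive(self):
        q = np.zeros(9)
        q[4] = math.radians(30.0)
        assert dof_penalty_rate(q) == 0.0


class TestEvaluateObjective:
    def test_perfect_run_scores_zero(self):
        assert evaluate_objective(synthetic_traj()) == 0.0

    def test_fall_at_five_seconds_scores_fifty(self):
        traj = synthetic_traj(duration=5.0, t_term=5.0, fell=True)
        assert evaluate_objective(traj) == pytest.approx(50.0)

    def test_persistent_knee_violation_scores_hundred(self):
        traj = synthetic_traj(knee_deg=35.0)
        assert evaluate_objective(traj) == pytest.approx(100.0)

    def test_effort_term(self):
        # constant a=0.5 in all 18 muscles for 10 s: 18 * 0.25 * 10 = 45
        traj = synthetic_traj(act=0.5)
        assert evaluate_objective(traj) == pytest.approx(45.0)

    def test_matches_kernel_accumulators(self, model, short_closed_loop):
        params, traj = short_closed_loop
        w = ObjectiveWeights(t_end=2.0)
        J = evaluate_objective(traj, w)
        J_kernel = (traj.effort_integral
                    + 100.0 * (1 - traj.t_term / 2.0) + traj.dof_integral)
        assert J == pytest.approx(J_kernel, abs=1e-9)

    def test_empty_rejected(self):
        traj = synthetic_traj()
        traj.t = traj.t[:0]
        traj.act = traj.act[:0]
        traj.q = traj.q[:0]
        with pytest.raises(ValueError):
            evaluate_objective(traj)


class TestTermination:
    def test_at_initial_height_not_falling(self):
        assert not check_termination(1.0, 1.0)

    def test_below_ninety_percent_falls(self):
        assert check_termination(0.89, 1.0)

    def test_exactly_ninety_percent_is_not_a_fall(self):
        assert not check_termination(0.90, 1.0)

    def test_invalid_height(self):
        with pytest.raises(ValueError):
            check_termination(1.0, 0.0)


class TestCMAES:
    def test_sphere_recovered(self):
        res = cmaes.minimize(lambda x: float(np.sum((x - 0.3) ** 2)),
                             np.zeros(5), 0.3, seed=1, max_generations=300)
        assert res.f_best < 1e-9
        assert np.allclose(res.x_best, 0.3, atol=1e-4)

    def test_rosenbrock_4d_recovered(self):
        def rosen(x):
            return float(np.sum(100 * (x[1:] - x[:-1] ** 2) ** 2
                                + (1 - x[:-1]) ** 2))
        res = cmaes.minimize(rosen, np.zeros(4), 0.3, seed=1,
                             max_generations=1000)
        assert res.f_best < 1e-8
        assert np.allclose(res.x_best, 1.0, atol=1e-3)

    def test_bounds_respected(self):
        res = cmaes.minimize(lambda x: float(np.sum((x + 1.0) ** 2)),
                             np.full(3, 0.5), 0.3,
                             bounds=(np.zeros(3), np.ones(3)),
                             seed=2, max_generations=200)
        assert np.all(res.x_best >= 0.0) and np.all(res.x_best <= 1.0)
        assert np.allclose(res.x_best, 0.0, atol=1e-3)  # box corner optimum

    def test_seeded_determinism(self):
        f = lambda x: float(np.sum(x ** 2))
        a = cmaes.minimize(f, np.ones(4), 0.2, seed=9, max_generations=50)
        b = cmaes.minimize(f, np.ones(4), 0.2, seed=9, max_generations=50)
        assert a.f_best == b.f_best
        assert np.array_equal(a.x_best, b.x_best)

    def test_ftarget_stops_early(self):
        res = cmaes.minimize(lambda x: float(np.sum(x ** 2)), np.ones(4),
                             0.2, seed=3, max_generations=500, ftarget=1e-3)
        assert res.stop_reason == "ftarget"
        assert res.f_best <= 1e-3


class TestOptimizeCondition:
    def test_injected_toy_objective_recovered(self, model):
        """The restart harness recovers (3, -1) of an injected quadratic."""
        def toy(x):
            return float((x[0] - 3.0) ** 2 + (x[1] + 1.0) ** 2)
        cfg = OptimizerConfig(restarts=2, max_generations=300, seed=5,
                              population=8)
        res = optimize_condition(
            model, Condition(100.0, 0.0), cfg, objective=toy, n_params=2,
            bounds=(np.array([-5.0, -5.0]), np.array([5.0, 5.0])))
        assert abs(res.best_vector[0] - 3.0) < 1e-3
        assert abs(res.best_vector[1] + 1.0) < 1e-3
        assert res.best_J == min(res.restart_J)
        assert len(res.restart_J) == 2

    def test_same_seeds_identical_result(self, model):
        def toy(x):
            return float(np.sum(x ** 2))
        cfg = OptimizerConfig(restarts=2, max_generations=30, seed=8,
                              population=6)
        kw = dict(objective=toy, n_params=3,
                  bounds=(np.full(3, -2.0), np.full(3, 2.0)))
        r1 = optimize_condition(model, Condition(100.0, 0.0), cfg, **kw)
        r2 = optimize_condition(model, Condition(100.0, 0.0), cfg, **kw)
        assert r1.best_J == r2.best_J
        assert np.array_equal(r1.best_vector, r2.best_vector)
        assert r1.seeds == r2.seeds

    def test_restart_seeds_distinct_and_bounded(self):
        seeds = restart_seeds(123, 8)
        assert len(set(seeds)) == 8
        assert all(0 <= s < 2 ** 31 for s in seeds)


class TestWarmStartSweep:
    def test_warm_start_chains_within_delay(self, model, monkeypatch):
        """Magnitude k's search starts from magnitude k-1's winner; the
        first magnitude starts from the config default."""
        from balancesim import optimize as opt
        calls = []

        def fake_optimize(model_, cond, cfg, **kw):
            calls.append((cond, cfg.warm_start))
            marker = default_initial_params(cond.delay_ms * 1e-3)
            marker = bs.ReflexParams(
                K_L=np.full(9, cond.magnitude_mm + cond.delay_ms),
                com_delay=cond.delay_ms * 1e-3)
            return opt.OptimResult(marker, cond.magnitude_mm,
                                   [cond.magnitude_mm], [0], 1, 10.0, False)

        monkeypatch.setattr(opt, "optimize_condition", fake_optimize)
        protocol = Protocol(magnitudes_mm=(0, 2, 4), delays_ms=(100, 150))
        out = opt.warm_start_sweep(model, protocol,
                                   OptimizerConfig(seed=0))
        assert len(out) == 6
        by_cond = {c: w for c, w in calls}
        for d in (100, 150):
            assert by_cond[Condition(d, 0)] is None
            assert by_cond[Condition(d, 2)].K_L[0] == 0 + d
            assert by_cond[Condition(d, 4)].K_L[0] == 2 + d
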