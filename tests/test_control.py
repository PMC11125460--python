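"""Delay lines, the three feedback laws, genome round-trips, and the
reference-vs-kernel closed-loop cross-check."""

import math

import numpy as np
import pytest

import balancesim as bs
from balancesim.control import (ControlHistory, DelayLine, FORCE_GROUPS,
                                ReflexParams, com_feedback, controller_step,
                                force_feedback, length_reflex,
                                total_excitation)
from balancesim.muscle import UNIQUE_MUSCLES, musculotendon_geometry


class TestDelayLine:
    def test_exact_on_sinusoid(self):
        dt, delay = 1e-3, 0.087
        line = DelayLine(delay, dt)
        ts = np.arange(0, 0.5, dt)
        sig = np.sin(2 * math.pi * 3.0 * ts)
        for k, s in enumerate(sig):
            line.push(s)
            if k * dt >= delay:
                expected = sig[k - line.steps]
                assert line.delayed() == expected  # machine-exact

    def test_prefill_before_delay_elapses(self):
        line = DelayLine(0.05, 1e-3)
        line.push(7.0)
        line.push(3.0)
        assert line.delayed() == 7.0  # first sample serves as prefill

    def test_zero_delay_passthrough(self):
        line = DelayLine(0.0, 1e-3)
        line.push(1.5)
        assert line.delayed() == 1.5

    def test_non_multiple_delay_rejected(self):
        with pytest.raises(ValueError):
            DelayLine(0.0505, 1e-3 * 3)


class TestFeedbackLaws:
    def test_length_reflex(self):
        assert length_reflex(2.0, 1.1, 1.0) == pytest.approx(0.2)
        assert length_reflex(5.0, 0.9, 0.9) == 0.0
        assert length_reflex(0.0, 1.4, 1.0) == 0.0
        with pytest.raises(ValueError):
            length_reflex(1.0, -0.1, 1.0)

    def test_force_feedback(self):
        assert force_feedback(0.5, 0.4) == pytest.approx(0.2)
        assert force_feedback(1.0, [0.1, 0.3]) == pytest.approx(0.4)
        assert force_feedback(3.0, 0.0) == 0.0
        with pytest.raises(ValueError):
            force_feedback(1.0, -0.2)

    def test_com_feedback(self):
        assert com_feedback(2.0, 0.0, -0.05, 0.0) == pytest.approx(-0.1)
        assert com_feedback(0.0, 3.0, 0.0, 0.02) == pytest.approx(0.06)
        assert com_feedback(5.0, 5.0, 0.0, 0.0) == 0.0

    def test_total_excitation_clipping(self):
        assert total_excitation(0.0, 0.0, 0.0, 0.01) == pytest.approx(0.01)
        assert total_excitation(1.0, 0.5, 0.2, 0.0) == 1.0
        assert total_excitation(-0.2, -0.1, 0.0, 0.0) == 0.0


class TestReflexParams:
    def test_vector_round_trip(self):
        rng = np.random.default_rng(0)
        lo, hi = ReflexParams.vector_bounds()
        x = rng.uniform(lo, hi)
        p = ReflexParams.from_vector(x, com_delay=0.15)
        assert np.allclose(p.to_vector(), x)
        assert p.com_delay == 0.15

    def test_text_round_trip_exact(self):
        rng = np.random.default_rng(1)
        lo, hi = ReflexParams.vector_bounds()
        p = ReflexParams.from_vector(rng.uniform(lo, hi), com_delay=0.2)
        q = ReflexParams.from_text(p.to_text())
        assert np.array_equal(p.to_vector(), q.to_vector())
        assert q.com_delay == p.com_delay and q.u_base == p.u_base

    def test_force_matrix_wiring(self):
        p = ReflexParams(K_F=np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0]))
        G = p.force_gain_matrix()
        i = {m: k for k, m in enumerate(UNIQUE_MUSCLES)}
        # IL <- GM + HM with the first gain, same side only
        assert G[i["IL"], i["GM"]] == 1.0 and G[i["IL"], i["HM"]] == 1.0
        assert G[i["IL"], i["GM"] + 9] == 0.0
        # reverse mapping carries its own gain
        assert G[i["GM"], i["IL"]] == 2.0 and G[i["HM"], i["IL"]] == 2.0
        # left leg mirrors the right
        assert G[i["TA"] + 9, i["SOL"] + 9] == 5.0
        # non-paired muscles receive nothing
        assert np.all(G[i["VAS"], [i["GM"], i["IL"], i["TA"]]] == 0.0)

    def test_pairing_is_mutual(self):
        drives = {(s, r) for recv, srcs in FORCE_GROUPS
                  for r in recv for s in srcs}
        for s, r in drives:
            assert (r, s) in drives

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            ReflexParams(K_L=np.full(9, -1.0))
        with pytest.raises(ValueError):
            ReflexParams(K_F=np.zeros(5))


class TestControllerStep:
    def _history(self, dt=1e-3, n=400):
        ls = np.ones((n, 18))
        fs = np.zeros((n, 18))
        dps = np.zeros(n)
        dvs = np.zeros(n)
        return ControlHistory(dt, ls, fs, dps, dvs)

    def test_hand_evaluated_three_laws(self, model):
        """Three-sample history with known delays matches a hand
        evaluation of the stretch, force, and COM terms."""
        dt = 0.05
        # SOL (index 7) has a 100 ms reflex delay = 2 samples here
        l_hist = np.ones((3, 18))
        l_hist[0, 7] = 1.08
        l_hist[2, 7] = 1.20
        f_hist = np.zeros((3, 18))
        f_hist[0, 8] = 0.5    # TA force at t0 (SOL's antagonist)
        dp = np.array([0.00, 0.01, 0.02])
        dv = np.array([0.00, 0.10, 0.20])
        hist = ControlHistory(dt, l_hist, f_hist, dp, dv)
        params = ReflexParams(
            K_L=np.full(9, 2.0), l_0=np.full(9, 1.0),
            K_CP=np.full(9, 1.0), K_CV=np.full(9, 0.5),
            K_F=np.array([0.0, 0.0, 0.0, 0.0, 0.0, 0.4]),
            com_delay=0.05, u_base=0.01)
        exc = controller_step(model, hist, params, t=0.10)
        # SOL: u_L = 2*(1.08-1) = 0.16 (100 ms delay -> sample 0)
        #      u_F = 0.4*0.5 = 0.2 (TA force, sample 0)
        #      u_COM = 1*0.01 + 0.5*0.10 = 0.06 (50 ms delay -> sample 1)
        assert exc[7] == pytest.approx(0.16 + 0.2 + 0.06 + 0.01, abs=1e-12)
        # GM (35 ms delay rounds to sample 1): all signals neutral there
        assert exc[0] == pytest.approx(0.0 + 0.06 + 0.01, abs=1e-12)

    def test_before_delays_elapse_uses_prefill(self, model):
        hist = self._history()
        hist.l_norm[0, :] = 1.05
        hist.l_norm[1:, :] = 1.0
        params = ReflexParams(K_L=np.full(9, 1.0), l_0=np.full(9, 1.0),
                              com_delay=0.1, u_base=0.0)
        exc = controller_step(model, hist, params, t=0.01)
        assert np.allclose(exc, 0.05)  # every delay reaches back to t = 0

    def test_constant_history_steady_output(self, model):
        hist = self._history()
        hist.l_norm[:] = 1.02
        params = ReflexParams(K_L=np.full(9, 1.0), l_0=np.full(9, 1.0),
                              com_delay=0.1, u_base=0.0)
        e1 = controller_step(model, hist, params, t=0.15)
        e2 = controller_step(model, hist, params, t=0.35)
        assert np.allclose(e1, e2)
        assert np.allclose(e1, 0.02)

    def test_kernel_matches_reference_implementation(self, model,
                                                     short_closed_loop):
        """Dual route: recompute excitations from the recorded histories
        with the Python controller and compare with the kernel's."""
        from balancesim.msk_model import muscle_reference_angles
        params, traj = short_closed_loop
        qref = muscle_reference_angles(model)
        coords = ("pelvis_tx", "pelvis_ty", "pelvis_tilt",
                  "hip_r", "knee_r", "ankle_r", "hip_l", "knee_l", "ankle_l")
        n = traj.n
        l_hist = np.empty((n, 18))
        for k in range(n):
            qd_ = dict(zip(coords, traj.qdot[k]))
            q_ = dict(zip(coords, traj.q[k]))
            for mi, spec in enumerate(model.muscles):
                kin = musculotendon_geometry(spec, q_, qd_, qref)
                l_hist[k, mi] = kin.l_norm
        fmax = np.array([m.f_max for m in model.muscles])
        hist = ControlHistory(traj.dt, l_hist, traj.muscle_force / fmax,
                              traj.foot_com[:, 0] - traj.com[:, 0],
                              traj.foot_com[:, 1] - traj.com_vel[:, 0])
        for k in (0, 137, n // 2, 3 * n // 4, n - 1):
            exc_ref = controller_step(model, hist, params, t=k * traj.dt)
            assert np.allclose(exc_ref, traj.exc[k], atol=1e-10), f"step {k}"

    def test_zero_gain_controller_collapses_under_perturbation(self, model):
        """Baseline tone alone cannot balance: the uncontrolled model falls
        and the termination rule fires."""
        params = ReflexParams(com_delay=0.1)  # all gains zero
        s = bs.simulate(model, params,
                        bs.PerturbationSpec(amplitude=0.08, duration=10.0),
                        record=False)
        assert s["fell"] and s["t_term"] < 10.0
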