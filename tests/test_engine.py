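import numpy as np
import pytest

from osteochemo import cohort, engine
from osteochemo.engine import (
    Trajectory,
    nondimensionalize,
    redimensionalize,
    scale_vector,
    scaling_from,
    simulate,
    untreated_steady_state,
)
from osteochemo.model import IDX
from osteochemo.regimens import InfusionEvent, Regimen, build_map
from osteochemo.units import dose_bsa_to_concentration


class TestSteadyState:
    def test_residual_below_tolerance(self, cluster1):
        ss = untreated_steady_state(cluster1.params, cluster1.steady_state * 1.1,
                                    settle_days=500.0)
        scale = np.maximum(np.abs(cluster1.steady_state), 1.0)
        res = np.abs(engine.rhs_untreated(ss, cluster1.params)) / scale
        assert res.max() < 1e-8

    def test_recovers_backsolved_target(self, cluster1):
        ss = untreated_steady_state(cluster1.params, cluster1.steady_state * 1.1,
                                    settle_days=500.0)
        np.testing.assert_allclose(ss[:14], cluster1.steady_state[:14], rtol=1e-6)

    def test_locally_stable_under_perturbation(self, cluster1):
        x0 = cluster1.steady_state.copy()
        x0[:14] *= 1.01
        traj = simulate(x0, cluster1.params, cluster1.chemo, None, horizon=500.0,
                        scaling=scaling_from(cluster1.steady_state, None, cluster1.chemo),
                        output_dt=10.0)
        np.testing.assert_allclose(traj.final[:14], cluster1.steady_state[:14],
                                   rtol=1e-3)

    def test_fixed_point_stays_put(self, cluster1):
        traj = simulate(cluster1.steady_state, cluster1.params, cluster1.chemo,
                        None, horizon=200.0, output_dt=5.0)
        rel = np.abs(traj.states[:, :14] / cluster1.steady_state[:14] - 1.0)
        assert rel.max() < 1e-3


class TestDrugPK:
    def test_single_infusion_matches_closed_form(self, cluster1):
        """A 4-h infusion then decay: A(t) follows the linear-ODE solution."""
        chemo = cluster1.chemo
        dur = 4.0 / 24.0
        reg = Regimen("one-mtx", 35.0, 1,
                      (InfusionEvent("methotrexate", 0.0, dur, 12000.0),),
                      treatment_start=1.0)
        traj = simulate(cluster1.steady_state, cluster1.params, chemo, reg,
                        horizon=6.0, rtol=1e-10, atol=1e-13, output_dt=0.02)
        v = dose_bsa_to_concentration(12000.0) / dur
        delta = chemo.delta_A1
        t0, t1 = 1.0, 1.0 + dur
        t = traj.times
        exact = np.where(
            t < t0, 0.0,
            np.where(t <= t1,
                     (v / delta) * (1 - np.exp(-delta * (t - t0))),
                     (v / delta) * (1 - np.exp(-delta * dur))
                     * np.exp(-delta * np.clip(t - t1, 0, None))))
        sim = traj["A1"]
        mask = exact > 1e-9 * exact.max()
        rel = np.abs(sim[mask] - exact[mask]) / exact[mask]
        assert rel.max() < 1e-6

    def test_other_drugs_stay_zero(self, cluster1):
        reg = Regimen("one-mtx", 35.0, 1,
                      (InfusionEvent("methotrexate", 0.0, 4 / 24, 12000.0),),
                      treatment_start=1.0)
        traj = simulate(cluster1.steady_state, cluster1.params, cluster1.chemo,
                        reg, horizon=6.0, output_dt=0.5)
        assert np.all(traj["A2"] == 0.0) and np.all(traj["A3"] == 0.0)


class TestNondimensionalization:
    def test_steady_state_maps_to_ones(self, cluster1, map_regimen):
        scaling = scaling_from(cluster1.steady_state, map_regimen, cluster1.chemo)
        xbar = nondimensionalize(cluster1.steady_state, scaling, cluster1.chemo)
        np.testing.assert_allclose(xbar[:14], 1.0, rtol=1e-12)

    def test_round_trip_identity(self, cluster1, map_regimen, rng):
        scaling = scaling_from(cluster1.steady_state, map_regimen, cluster1.chemo)
        x = rng.uniform(0.5, 2.0, 17) * np.maximum(cluster1.steady_state, 1.0)
        back = redimensionalize(nondimensionalize(x, scaling, cluster1.chemo),
                                scaling, cluster1.chemo)
        np.testing.assert_allclose(back, x, rtol=1e-12)

    def test_scaled_and_dimensional_simulations_agree(self, cluster1, map_regimen):
        kw = dict(horizon=80.0, rtol=1e-10, atol=1e-13, output_dt=1.0)
        scaling = scaling_from(cluster1.steady_state, map_regimen, cluster1.chemo)
        a = simulate(cluster1.steady_state, cluster1.params, cluster1.chemo,
                     map_regimen, scaling=scaling, scaled=True, **kw)
        b = simulate(cluster1.steady_state, cluster1.params, cluster1.chemo,
                     map_regimen, scaled=False, **kw)
        ref = np.abs(a.states).max(axis=0)
        assert np.max(np.abs(a.states - b.states) / ref) < 1e-6

    def test_trajectory_scaling_round_trip(self, cluster1, map_regimen):
        scaling = scaling_from(cluster1.steady_state, map_regimen, cluster1.chemo)
        traj = simulate(cluster1.steady_state, cluster1.params, cluster1.chemo,
                        map_regimen, horizon=10.0, output_dt=1.0)
        scaled = nondimensionalize(traj, scaling, cluster1.chemo)
        back = redimensionalize(scaled, scaling, cluster1.chemo)
        np.testing.assert_allclose(back.states, traj.states, rtol=1e-12)


class TestSimulateContract:
    def test_first_state_is_initial_condition(self, cluster1, map_regimen):
        traj = simulate(cluster1.steady_state, cluster1.params, cluster1.chemo,
                        map_regimen, horizon=5.0, output_dt=1.0)
        np.testing.assert_allclose(traj.states[0], cluster1.steady_state, rtol=1e-12)

    def test_tolerance_halving_convergence(self, cluster1, map_regimen):
        common = dict(horizon=80.0, output_dt=5.0)
        c_vals = []
        for rtol in (1e-6, 5e-7):
            traj = simulate(cluster1.steady_state, cluster1.params, cluster1.chemo,
                            map_regimen, rtol=rtol, atol=rtol * 1e-3, **common)
            c_vals.append(traj.value("C", 80.0))
        assert abs(c_vals[0] / c_vals[1] - 1.0) < 1e-4

    def test_negative_initial_state_rejected(self, cluster1, map_regimen):
        bad = cluster1.steady_state.copy()
        bad[0] = -1.0
        with pytest.raises(ValueError):
            simulate(bad, cluster1.params, cluster1.chemo, map_regimen, horizon=5.0)

    def test_states_stay_nonnegative(self, map_trajectories):
        for traj in map_trajectories.values():
            assert traj.states.min() >= 0.0

    def test_trajectory_validation(self):
        with pytest.raises(ValueError):
            Trajectory(times=[0.0, 0.0], states=np.zeros((2, 17)))
        with pytest.raises(ValueError):
            Trajectory(times=[0.0, 1.0], states=np.zeros((2, 5)))


class TestAlphaDimInvariance:
    def test_scaled_trajectories_invariant_under_joint_rescaling(self, map_regimen):
        """Rescaling all populations with alpha_dim (back-solved rates adapt)
        leaves non-dimensional trajectories identical."""
        a = cohort.build_scenario(1)
        b = cohort.build_scenario(1, alpha_dim=10 * a.alpha_dim)
        np.testing.assert_allclose(b.steady_state[:13], 10 * a.steady_state[:13],
                                   rtol=1e-12)
        kw = dict(horizon=50.0, output_dt=1.0, rtol=1e-8, atol=1e-11)
        ta = simulate(a.steady_state, a.params, a.chemo, map_regimen,
                      scaling=scaling_from(a.steady_state, map_regimen, a.chemo), **kw)
        tb = simulate(b.steady_state, b.params, b.chemo, map_regimen,
                      scaling=scaling_from(b.steady_state, map_regimen, b.chemo), **kw)
        sa = ta.states / scale_vector(
            scaling_from(a.steady_state, map_regimen, a.chemo), a.chemo)
        sb = tb.states / scale_vector(
            scaling_from(b.steady_state, map_regimen, b.chemo), b.chemo)
        np.testing.assert_allclose(sa, sb, rtol=2e-6, atol=1e-9)


class TestDynamicsSignatures:
    """Qualitative treatment-response patterns on the synthetic clusters."""

    def test_necrotic_hmgb1_dendritic_peak_in_drug_windows(self, suite,
                                                           map_trajectories,
                                                           map_regimen):
        windows = engine.drug_administration_windows(map_regimen)
        for cid, traj in map_trajectories.items():
            t = traj.times
            for name in ("N", "H", "D"):
                y = traj[name]
                for i, (s, e) in enumerate(windows):
                    nxt = windows[i + 1][0] if i + 1 < len(windows) else t[-1]
                    seg = (t >= s) & (t <= nxt)
                    peak_t = t[seg][np.argmax(y[seg])]
                    assert s <= peak_t <= e, (cid, name, s, peak_t)
                    assert y[seg][-1] < y[seg].max(), (cid, name, s)

    def test_terminal_population_shifts(self, map_trajectories):
        for traj in map_trajectories.values():
            day80 = {n: traj.value(n, 80.0) for n in
                     ("C", "T_h", "T_c", "I_g", "M", "T_r", "mu1", "mu2")}
            base = {n: traj[n][0] for n in day80}
            assert day80["C"] < base["C"]
            for n in ("T_h", "T_c", "I_g"):
                assert day80[n] >= base[n], n
            for n in ("M", "T_r", "mu1", "mu2"):
                assert day80[n] <= base[n], n

    def test_fast_cluster_retains_more_cancer_than_slow(self, suite, map_regimen):
        """Equal initial cancer load, equal dosing: the faster-growing cluster
        ends treatment with strictly more cancer cells."""
        fast, slow = suite[1], suite[3]
        assert fast.steady_state[IDX["C"]] == slow.steady_state[IDX["C"]]
        kw = dict(horizon=85.0, output_dt=1.0)
        cf = simulate(fast.steady_state, fast.params, fast.chemo, map_regimen,
                      **kw).value("C", 80.0)
        cs = simulate(slow.steady_state, slow.params, slow.chemo, map_regimen,
                      **kw).value("C", 80.0)
        assert cf > cs
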