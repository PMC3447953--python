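"""Coupled integration: light forcing, coupling terms, entrainment
classification, convergence and the topology-switch protocol."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_network, make_trajectory, single_cell_network
from scnsim.core_models import PoincareParams, sample_poincare_population
from scnsim.measures import activity_width_height, mean_field
from scnsim.network import NetworkConfig, build_network
from scnsim.simulate import (
    LightSchedule,
    SimConfig,
    entrainment_region,
    free_run,
    is_entrained,
    light_signal,
    measure_periods,
    mean_field_peaks,
    simulate_network,
    topology_switch_experiment,
)
from scnsim.simulate import _PoincareSystem


class TestLightSignal:
    def test_square_wave_values(self):
        sched = LightSchedule(T=24.0, sigma_L=8.0, b=0.1, phase0=0.0)
        assert light_signal(1.0, sched) == 0.1
        assert light_signal(9.0, sched) == 0.0

    @given(t=st.floats(-100.0, 1000.0))
    def test_exact_periodicity(self, t):
        sched = LightSchedule(T=24.0, sigma_L=10.0, b=0.3, phase0=2.0)
        assert light_signal(t, sched) == light_signal(t + 24.0, sched)

    def test_invalid_width_rejected(self):
        with pytest.raises(ValueError):
            LightSchedule(T=24.0, sigma_L=30.0)

    def test_none_schedule_is_dark(self):
        assert light_signal(5.0, None) == 0.0


class TestSimulateNetwork:
    def test_uncoupled_cells_keep_their_tau(self):
        """g = 0: every rhythmic cell free-runs at its own intrinsic period."""
        with pytest.warns(UserWarning):  # k_mean = 0: edgeless network
            net = build_network(NetworkConfig(N=40, f_VL=0.0, k_mean=0.0, delta=0.0, seed=3))
        params = sample_poincare_population(40, 0.0, seed=3)
        sim = SimConfig(g=0.0, cycles_total=25, cycles_transient=5, seed=3)
        traj = free_run(net, params, sim)
        periods = measure_periods(traj)
        taus = np.array([p.tau for p in params])
        assert np.nanmax(np.abs(periods - taus)) < 0.05

    def test_two_cells_lock_in_phase(self):
        """Two identical coupled cells started near antiphase converge to
        in-phase locking (phase difference -> 0)."""
        net = make_network([[0.5, 0.5], [0.5, 0.6]], ["DM", "DM"], [(0, 1)])
        params = [PoincareParams(1.0, 0.03, 24.0, 2.0)] * 2
        sim = SimConfig(g=0.1, cycles_total=40, cycles_transient=30, seed=0)
        y0 = np.array([1.0, -0.95, 0.0, 0.1])  # (x0, x1, y0, y1): near antiphase
        traj = simulate_network(net, params, None, sim, y0=y0)
        x = traj.activity[:, traj.post_mask]
        y = traj.states[1][:, traj.post_mask]
        dphi = np.angle(np.exp(1j * (np.arctan2(y[0], x[0]) - np.arctan2(y[1], x[1]))))
        assert np.abs(dphi[-100:]).max() < 0.1

    def test_coupling_term_is_neighbor_mean(self):
        """Unit-weight oracle on a 3-cell path: the coupling contribution to
        each derivative equals g times the plain mean of neighbor states."""
        net = make_network([[0.1, 0.5], [0.5, 0.5], [0.9, 0.5]], ["DM"] * 3, [(0, 1), (1, 2)])
        params = [PoincareParams(1.0, 0.03, 24.0, 2.0)] * 3
        g = 0.17
        coupled = _PoincareSystem(net, params, SimConfig(g=g, seed=0), None)
        uncoupled = _PoincareSystem(net, params, SimConfig(g=0.0, seed=0), None)
        rng = np.random.default_rng(5)
        yv = rng.normal(size=6)
        diff = coupled.rhs(0.0, yv) - uncoupled.rhs(0.0, yv)
        x, y = yv[:3], yv[3:]
        expect_x = g * np.array([x[1], (x[0] + x[2]) / 2, x[1]])
        expect_y = g * np.array([y[1], (y[0] + y[2]) / 2, y[1]])
        assert np.allclose(diff, np.concatenate([expect_x, expect_y]), atol=1e-12)

    def test_isolated_cell_receives_no_coupling(self):
        net = make_network([[0.1, 0.5], [0.5, 0.5]], ["DM", "DM"], [])
        params = [PoincareParams(1.0, 0.03, 24.0, 2.0)] * 2
        sys_g = _PoincareSystem(net, params, SimConfig(g=5.0, seed=0), None)
        sys_0 = _PoincareSystem(net, params, SimConfig(g=0.0, seed=0), None)
        yv = np.array([1.0, -0.3, 0.2, 0.8])
        assert np.allclose(sys_g.rhs(0.0, yv), sys_0.rhs(0.0, yv))

    def test_param_length_mismatch_rejected(self):
        net = single_cell_network()
        with pytest.raises(ValueError):
            simulate_network(net, [], None, SimConfig(seed=0))

    def test_damped_cell_amplitude_decays_monotonically(self):
        net = single_cell_network()
        params = [PoincareParams(0.0, 2.0, 24.0, 2.0)]  # A=0: algebraic radial decay
        sim = SimConfig(g=0.0, cycles_total=40, cycles_transient=0, seed=0)
        traj = free_run(net, params, sim)
        r = np.hypot(traj.activity[0], traj.states[1][0])
        assert (np.diff(r) <= 1e-12).all()
        assert r[-1] < 1e-3

    def test_transient_flagged_not_dropped(self):
        net = single_cell_network()
        sim = SimConfig(cycles_total=12, cycles_transient=4, seed=0)
        traj = free_run(net, [PoincareParams(1.0, 0.03, 24.0)], sim)
        assert traj.times[0] == 0.0
        assert traj.transient_until == 96.0
        assert traj.post_mask.sum() < len(traj.times)

    def test_invalid_sim_config_rejected_before_compute(self):
        with pytest.raises(ValueError):
            SimConfig(cycles_total=10, cycles_transient=10)


class TestConvergence:
    def test_halving_tolerances_stable_peaks(self):
        """Integrator accuracy: halving rtol/atol moves post-transient
        mean-field peak values by < 1e-3."""
        net = build_network(NetworkConfig(N=60, delta=0.05, seed=2))
        params = sample_poincare_population(60, 1 / 3, seed=2)
        sched = LightSchedule(sigma_L=12.0)
        sim = SimConfig(cycles_total=20, cycles_transient=8, seed=2)
        t1 = simulate_network(net, params, sched, sim)
        sim2 = dataclasses.replace(sim, rtol=sim.rtol / 2, atol=sim.atol / 2)
        t2 = simulate_network(net, params, sched, sim2)
        mf1 = t1.activity[:, t1.post_mask].mean(axis=0)
        mf2 = t2.activity[:, t2.post_mask].mean(axis=0)
        assert np.abs(mf1.max() - mf2.max()) < 1e-3

    def test_settles_after_a_few_periods(self, winter_entrained):
        """Summary statistics on cycles 16-40 and 21-40 differ by < 2 %."""
        def shape_from(cycle0):
            sliced = dataclasses.replace(winter_entrained, transient_until=cycle0 * 24.0)
            return activity_width_height(mean_field(sliced))

        a, b = shape_from(16), shape_from(21)
        assert abs(a.w - b.w) / b.w < 0.02
        assert abs(a.h - b.h) / b.h < 0.02


class TestIsEntrained:
    def test_synthetic_periodic_mean_field(self):
        t = np.arange(0.0, 24.0 * 30, 0.1)
        traj = make_trajectory(t, [np.cos(2 * np.pi * t / 24.0)], transient_until=24.0 * 10)
        assert is_entrained(traj, 24.0)

    def test_detuned_rhythm_not_entrained(self):
        t = np.arange(0.0, 25.0 * 30, 0.1)
        traj = make_trajectory(t, [np.cos(2 * np.pi * t / 25.0)], transient_until=25.0 * 10)
        assert not is_entrained(traj, 24.0)

    def test_short_trajectory_rejected(self):
        t = np.arange(0.0, 24.0 * 5, 0.1)
        traj = make_trajectory(t, [np.cos(2 * np.pi * t / 24.0)])
        with pytest.raises(ValueError):
            is_entrained(traj, 24.0)

    def test_single_cell_locks_to_strong_forcing(self):
        """tau = 25 h cell under strong 24 h light: 1:1 locking."""
        net = single_cell_network()
        # make the lone DM cell light-sensitive for this single-oscillator run
        net = dataclasses.replace(net, cells=dataclasses.replace(net.cells, region=np.array(["VL"])))
        params = [PoincareParams(1.0, 0.03, 25.0, 2.0)]
        sched = LightSchedule(T=24.0, sigma_L=12.0, b=0.3)
        traj = simulate_network(net, params, sched, SimConfig(g=0.0, seed=1))
        assert is_entrained(traj, 24.0)

    def test_no_forcing_free_run_not_at_T_ext(self):
        net = single_cell_network()
        params = [PoincareParams(1.0, 0.03, 25.0, 2.0)]
        traj = free_run(net, params, SimConfig(g=0.0, seed=1))
        assert not is_entrained(traj, 24.0)

    def test_stride_invariant_classification(self):
        net = build_network(NetworkConfig(N=60, delta=0.05, seed=2))
        params = sample_poincare_population(60, 1 / 3, seed=2)
        sched = LightSchedule(sigma_L=12.0)
        flags = []
        for dt_out in (0.1, 2.5):  # output stride 1 vs 25
            sim = SimConfig(seed=2, dt_out=dt_out)
            flags.append(is_entrained(simulate_network(net, params, sched, sim), 24.0))
        assert flags[0] == flags[1]


class TestEntrainmentRegion:
    def test_zero_amplitude_column_all_false(self):
        net = build_network(NetworkConfig(N=40, delta=0.05, seed=4))
        params = sample_poincare_population(40, 1 / 3, seed=4)
        sim = SimConfig(cycles_total=26, cycles_transient=12, seed=4)
        emap = entrainment_region(net, params, [23.0, 25.0], [0.0], sim)
        assert not emap.entrained.any()


@pytest.fixture(scope="module")
def nets300():
    winter = build_network(NetworkConfig(N=300, delta=0.02, seed=6))
    summer = build_network(NetworkConfig(N=300, delta=0.01, seed=6))
    params = sample_poincare_population(300, 1 / 3, seed=6)
    return winter, summer, params


class TestTopologySwitch:
    def test_identity_switch_no_transient(self, nets300):
        winter, _, params = nets300
        sim = SimConfig(cycles_total=28, cycles_transient=10, seed=6)
        _, cycles = topology_switch_experiment(winter, winter, params, sim, switch_cycle=14,
                                               schedule=LightSchedule(sigma_L=12.0))
        assert cycles == 0

    def test_winter_to_summer_fast_and_broadens(self, nets300):
        """Switching to the summer topology broadens the mean-field peak and
        re-stabilizes within a few cycles."""
        winter, summer, params = nets300
        sim = SimConfig(cycles_total=40, cycles_transient=10, seed=6)
        post, cycles = topology_switch_experiment(winter, summer, params, sim, switch_cycle=20,
                                                  schedule=LightSchedule(sigma_L=12.0))
        assert cycles <= 10
        w_late = activity_width_height(mean_field(post, post_only=False)).w_per_cycle[-5:]
        pre = simulate_network(winter, params, LightSchedule(sigma_L=12.0),
                               dataclasses.replace(sim, cycles_total=20, cycles_transient=10))
        w_winter = activity_width_height(mean_field(pre)).w
        assert np.nanmean(w_late) > w_winter

    def test_mismatched_cells_rejected(self, nets300):
        winter, _, params = nets300
        other = build_network(NetworkConfig(N=200, delta=0.02, seed=1))
        with pytest.raises(ValueError):
            topology_switch_experiment(winter, other, params, SimConfig(seed=0), 10)
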