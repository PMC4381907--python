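"""Master-equation integration and macroscopic observables."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from iksgate.params import default_kcnq1
from iksgate.protocols import VoltageProtocol, preset_protocol, step_protocol
from iksgate.ratematrix import build_rate_matrix, equilibrium_distribution, open_probability
from iksgate.simulate import observables, simulate_protocol, steady_state_curves
from iksgate.states import ChannelState, enumerate_states
from iksgate.analysis import compare_exponential_models
from iksgate.kcne1 import apply_perturbation, kcne1_default_perturbation

from conftest import draw_random_params
from _microstate import micro_observables, micro_simulate, micro_states


class TestProtocols:
    def test_sample_grid_and_voltage_lookup(self):
        prot = VoltageProtocol([(10.0, 0.0), (5.0, 60.0)], sample_interval_ms=1.0)
        t = prot.times_ms()
        assert len(t) == 16 and t[0] == 0.0 and t[-1] == 15.0
        v = prot.voltage_at(t)
        assert v[0] == 0.0 and v[9] == 0.0
        # boundary sample carries the incoming segment's command
        assert v[10] == 60.0 and v[-1] == 60.0

    def test_invalid_protocols_rejected(self):
        with pytest.raises(ValueError):
            VoltageProtocol([])
        with pytest.raises(ValueError):
            VoltageProtocol([(-5.0, 0.0)])
        with pytest.raises(ValueError):
            VoltageProtocol([(10.5, 0.0)], sample_interval_ms=1.0)

    def test_presets_match_published_protocols(self):
        vcf = preset_protocol("vcf_family", test_mv=-20.0)
        assert vcf.segments == ((4000.0, -20.0), (1000.0, 60.0))
        perm = preset_protocol("permeability")
        assert perm.segments == ((5000.0, 60.0), (3000.0, -60.0))
        xe = preset_protocol("xe991", test_mv=40.0)
        assert xe.segments[-1][1] == -40.0
        assert vcf.holding_voltage_mv == -80.0


class TestSimulateProtocol:
    def test_stationary_at_holding(self, baseline_params):
        prot = VoltageProtocol([(500.0, -80.0)])
        traj = simulate_protocol(baseline_params, prot)
        assert np.abs(traj.occupancy - traj.occupancy[0]).max() < 1e-9

    @pytest.mark.parametrize("seed", range(3))
    def test_occupancy_conservation_random_protocols(self, seed):
        rng = np.random.default_rng(500 + seed)
        params = draw_random_params(rng)
        segs = [
            (float(rng.integers(5, 50)), float(rng.uniform(-100, 100)))
            for _ in range(4)
        ]
        traj = simulate_protocol(params, VoltageProtocol(segs))
        assert np.abs(traj.occupancy.sum(axis=1) - 1.0).max() < 1e-9
        assert traj.occupancy.min() >= 0.0

    def test_matrix_exponential_agrees_with_fine_ode(self, baseline_params):
        prot = VoltageProtocol([(40.0, 0.0), (20.0, 60.0)])
        traj = simulate_protocol(baseline_params, prot)
        p0 = equilibrium_distribution(baseline_params, -80.0)
        sol_parts, p = [], p0
        t_offset = 0.0
        for dur, v in prot.segments:
            Q = build_rate_matrix(baseline_params, v)
            tgrid = np.arange(1, int(dur) + 1) * 1e-3
            sol = solve_ivp(
                lambda t, y: y @ Q,
                (0.0, dur / 1000.0),
                p,
                t_eval=tgrid,
                max_step=1e-6,
                rtol=1e-10,
                atol=1e-12,
            )
            sol_parts.append(sol.y.T)
            p = sol.y[:, -1]
            t_offset += dur
        ode = np.vstack([p0[None, :], *sol_parts])
        assert np.abs(ode - traj.occupancy).max() < 1e-6

    def test_explicit_initial_vector_validated(self, baseline_params):
        prot = VoltageProtocol([(10.0, 0.0)])
        bad = np.ones(30)
        with pytest.raises(ValueError):
            simulate_protocol(baseline_params, prot, initial=bad)
        with pytest.raises(ValueError):
            simulate_protocol(baseline_params, prot, initial="nonsense")


class TestObservables:
    def test_fully_resting_closed_has_no_signal(self, baseline_params):
        prot = VoltageProtocol([(5.0, -80.0)])
        states = enumerate_states()
        p0 = np.zeros(30)
        p0[states.index(ChannelState("C", 4, 0, 0))] = 1.0
        # freeze dynamics so occupancy stays put
        frozen = baseline_params.replace(
            k_ri=baseline_params.k_ri.__class__(1e-12, 0.0),
            k_ia=baseline_params.k_ia.__class__(1e-12, 0.0),
            k_co=1e-12,
        )
        traj = simulate_protocol(frozen, prot, initial=p0)
        obs = observables(traj, frozen)
        assert np.abs(obs.fluorescence_raw).max() < 1e-9
        assert np.abs(obs.current).max() < 1e-6

    def test_current_vanishes_at_reversal_potential(self, baseline_params):
        e_rev = baseline_params.ions["K"].e_rev_mv
        prot = VoltageProtocol([(50.0, e_rev)])
        traj = simulate_protocol(baseline_params, prot)
        obs = observables(traj, baseline_params)
        assert np.abs(obs.current).max() < 1e-9

    def test_equal_fluorophore_weights_report_one_minus_resting_fraction(
        self, baseline_params
    ):
        p = baseline_params.replace(f_i=1.0, f_a=1.0)
        prot = VoltageProtocol([(200.0, 0.0)])
        traj = simulate_protocol(p, prot)
        obs = observables(traj, p)
        states = enumerate_states()
        resting_frac = traj.occupancy @ np.array([s.n_R / 4.0 for s in states])
        assert np.abs(obs.fluorescence_raw - (1.0 - resting_frac)).max() < 1e-12

    def test_unknown_ion_rejected(self, baseline_params):
        prot = VoltageProtocol([(5.0, 0.0)])
        traj = simulate_protocol(baseline_params, prot)
        with pytest.raises(ValueError):
            observables(traj, baseline_params, ion="Cs")


class TestSteadyStateCurves:
    def test_decoupled_pore_gives_flat_gv(self, baseline_params):
        p = baseline_params.replace(theta_io=1.0, theta_ao=1.0)
        df = steady_state_curves(p, [-80.0, -40.0, 0.0, 40.0], 60.0, 2000.0)
        assert np.abs(df["gv_norm"] - 1.0).max() < 1e-6

    def test_long_pulse_gv_matches_equilibrium_open_probability(self, baseline_params):
        volts = [-60.0, -20.0, 20.0, 60.0]
        df = steady_state_curves(baseline_params, volts, 60.0, 60_000.0)
        po = np.array([open_probability(baseline_params, v) for v in volts])
        assert np.abs(df["gv_norm"].to_numpy() - po / po[-1]).max() < 1e-8
        assert df["equilibrated"].all()

    def test_fv_is_nondecreasing_for_positive_gating_charge(self, baseline_params):
        volts = list(range(-120, 101, 20))
        df = steady_state_curves(baseline_params, volts, 60.0, 4000.0)
        assert (np.diff(df["fv_raw"].to_numpy()) > -1e-12).all()

    def test_short_pulse_flagged_unequilibrated(self, baseline_params):
        df = steady_state_curves(baseline_params, [0.0], 60.0, 50.0)
        assert not df["equilibrated"].iloc[0]

    def test_zero_driving_force_rejected(self, baseline_params):
        e_rev = baseline_params.ions["K"].e_rev_mv
        with pytest.raises(ValueError):
            steady_state_curves(baseline_params, [0.0], e_rev, 1000.0)
        with pytest.raises(ValueError):
            steady_state_curves(baseline_params, [], 60.0, 1000.0)


class TestMicrostateCrossCheck:
    def test_observables_match_labelled_vsd_simulator(self, baseline_params):
        prot = VoltageProtocol([(100.0, -20.0), (50.0, 60.0)], sample_interval_ms=5.0)
        traj = simulate_protocol(baseline_params, prot)
        obs = observables(traj, baseline_params)
        # microstate initial: equilibrium at holding, built microscopically
        from _microstate import micro_equilibrium

        p0 = micro_equilibrium(baseline_params, -80.0)
        times, occ = micro_simulate(baseline_params, prot, p0)
        p_open, current, fluor = micro_observables(
            baseline_params, occ, prot.voltage_at(times)
        )
        assert np.abs(p_open - obs.open_probability).max() < 1e-8
        assert np.abs(fluor - obs.fluorescence_raw).max() < 1e-8
        scale = np.abs(current).max()
        assert np.abs(current - obs.current).max() < 1e-8 * scale


class TestOnsetPhenotype:
    def test_baseline_onset_biphasic_and_kcne1_onset_delayed(self, baseline_params):
        """Homomeric-like onset is bi-exponential; the perturbed model shows a
        sigmoid delay.  Checked at +40 mV, where both VSD steps move the
        current."""
        prot40 = VoltageProtocol([(4000.0, 40.0)])
        traj = simulate_protocol(baseline_params, prot40)
        obs = observables(traj, baseline_params)
        mono, bi, p_val, bi_preferred = compare_exponential_models(
            obs.times_ms[1:], obs.current[1:]
        )
        assert bi_preferred and p_val < 0.01
        # genuinely two time scales with same-sign amplitudes, not a
        # degenerate equal-tau pair
        assert bi.tau_slow_ms > 1.5 * bi.tau_fast_ms
        assert all(c.amplitude > 0 for c in bi.components)

        # the perturbed model's current stays a tiny fraction of its final
        # value for hundreds of ms (sigmoid delay), unlike the baseline
        perturbed = apply_perturbation(baseline_params, kcne1_default_perturbation())
        obs_p40 = observables(simulate_protocol(perturbed, prot40), perturbed)
        frac_200 = obs_p40.current[200] / obs_p40.current[-1]
        frac_200_base = obs.current[200] / obs.current[-1]
        assert frac_200 < 0.05 < frac_200_base
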