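"""Simulator invariants: exchange kinetics, conservation, photophysics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ssb_recycling.config import (
    SimulationConfig,
    EXCHANGE_TIME_TABLE,
    calibrate_exchange_constants,
    interp_okazaki_mean,
)
from ssb_recycling import sim_core as sc


class TestEffectiveExchangeRate:
    def test_zero_concentration_zero_intrinsic_gives_pure_retention(self):
        cfg = SimulationConfig(c_ssb=0.0, k_intr=0.0, L_mean_knt=1.4)
        assert sc.effective_exchange_rate(cfg) == 0.0

    def test_linear_in_concentration(self):
        cfg = SimulationConfig(c_ssb=100.0, k_intr=0.01, k_fac=0.0033)
        assert sc.effective_exchange_rate(cfg) == pytest.approx(0.34)
        # tau ~ 2.9 s at 100 nM for these constants
        assert 1.0 / sc.effective_exchange_rate(cfg) == pytest.approx(2.9, abs=0.1)

    def test_strictly_increasing_in_concentration(self):
        rates = [
            sc.effective_exchange_rate(SimulationConfig(c_ssb=c))
            for c in (2.0, 10.0, 20.0, 100.0)
        ]
        assert np.all(np.diff(rates) > 0)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(c_ssb=-1.0)

    def test_calibrated_defaults_reproduce_measured_exchange_times(self):
        """The least-squares calibration reproduces the measured (c, tau)
        pairs to within ~25% at every concentration."""
        k_intr, k_fac = calibrate_exchange_constants()
        for c, tau in EXCHANGE_TIME_TABLE.items():
            tau_model = 1.0 / (k_intr + k_fac * c)
            assert tau_model == pytest.approx(tau, rel=0.25)


class TestOkazakiTable:
    def test_tabulated_concentrations_exact(self):
        table = {2.0: 1.4, 10.0: 1.5, 20.0: 2.0, 100.0: 2.8}
        for c, L in table.items():
            assert interp_okazaki_mean(c, table) == pytest.approx(L)

    def test_log_interpolation_between_entries(self):
        table = {10.0: 1.0, 1000.0: 3.0}
        assert interp_okazaki_mean(100.0, table) == pytest.approx(2.0)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            interp_okazaki_mean(10.0, {})


class TestChaseConservation:
    def test_no_solution_exchange_and_complement_conserved(self, chase_run):
        _, ledger, _ = chase_run
        fates = ledger.fates()
        assert fates["solution_exchange"] == 0
        assert set(r.fate for r in ledger.records) <= {
            "internal_transfer",
            "retained_at_end",
            "bleached_in_place",
        }
        # the initial complement is the whole population
        assert len(ledger) == 40
        assert all(r.origin == "initial" for r in ledger.records)

    @settings(max_examples=10, deadline=None)
    @given(seed=st.integers(0, 10_000), n0=st.integers(5, 60))
    def test_conservation_holds_across_seeds(self, seed, n0):
        cfg = SimulationConfig(
            c_ssb=0.0, k_intr=0.0, L_mean_knt=1.4, initial_tetramers=n0,
            duration=20.0, seed=seed,
        )
        _, ledger, _ = sc.simulate_replisome(cfg)
        assert len(ledger) == n0
        assert ledger.fates()["solution_exchange"] == 0

    def test_stalled_fork_initiates_no_fragments(self):
        cfg = SimulationConfig(v_mean=0.0, v_sd=0.0, c_ssb=10.0, duration=20.0, seed=1)
        traj, ledger, _ = sc.simulate_replisome(cfg)
        assert len(traj.fragment_lengths_nt) == 0
        assert np.all(traj.position_bp == 0.0)


class TestExchangeStatistics:
    def test_replacement_rate_matches_effective_exchange_rate(self):
        """Empirical solution-replacement count over at-fork exposure time
        converges to k_ex (count-rate oracle, ~10^3 events)."""
        cfg = SimulationConfig(c_ssb=10.0, k_intr=0.0, k_fac=0.01, duration=200.0)
        events = 0.0
        exposure = 0.0
        for s in range(12):
            _, ledger, gt = sc.simulate_replisome(cfg.replace(seed=s))
            for r in ledger.records:
                t_end = r.release_time if r.release_time is not None else cfg.duration
                exposure += t_end - r.bind_time
            events += sum(
                1 for r in ledger.records if r.fate == "solution_exchange"
            )
        k_emp = events / exposure
        assert events > 1000
        assert k_emp == pytest.approx(0.1, rel=0.05)

    def test_tau_true_is_inverse_rate_exactly(self, frap_run):
        *_, gt = frap_run
        assert gt.tau_true == pytest.approx(1.0 / gt.k_ex)
        assert gt.k_ex == pytest.approx(0.1)

    def test_post_pulse_recovery_follows_exponential_saturation(self):
        """Expected bright fraction Delta after the pulse follows
        1 - exp(-k_ex * t) (analytic recovery oracle, ensemble average)."""
        tau = 5.0
        t_pulse = 40.0  # past the fork-population burn-in
        cfg = SimulationConfig(
            c_ssb=100.0, k_intr=0.0, k_fac=1.0 / (tau * 100.0), tau_b=1e6,
            pulse_times=[t_pulse], duration=60.0, noise_sd=0.0,
        )
        t_probe = np.array([1.0, 2.5, 5.0, 10.0, 17.5])
        num = np.zeros_like(t_probe)
        den = np.zeros_like(t_probe)
        for s in range(60):
            cfgi = cfg.replace(seed=s)
            _, ledger, _ = sc.simulate_replisome(cfgi)
            trace = sc.emit_intensity_trace(ledger, cfgi)
            pre = np.mean(trace.I[(trace.t > t_pulse - 15.0) & (trace.t < t_pulse)])
            for k, dt in enumerate(t_probe):
                num[k] += np.interp(t_pulse + dt, trace.t, trace.I)
                den[k] += pre
        frac = num / den
        expected = 1.0 - np.exp(-t_probe / tau)
        assert np.allclose(frac, expected, atol=0.06)


class TestDeterminism:
    def test_identical_config_gives_identical_ledger_and_trace(self, frap_cfg):
        out = []
        for _ in range(2):
            _, ledger, _ = sc.simulate_replisome(frap_cfg)
            trace = sc.emit_intensity_trace(ledger, frap_cfg)
            out.append((ledger.to_dataframe(), trace.I.copy()))
        assert out[0][0].equals(out[1][0])
        assert np.array_equal(out[0][1], out[1][1])


class TestFrapPulse:
    def test_bright_count_zero_immediately_after_pulse(self, frap_run, frap_cfg):
        _, ledger, _ = frap_run
        t_pulse = frap_cfg.pulse_times[0]
        eps = 1e-9
        bright = sum(r.bright_dyes(t_pulse + eps) for r in ledger.records)
        assert bright == 0

    def test_pulse_on_empty_fork_is_noop(self):
        cfg = SimulationConfig(
            c_ssb=0.0, k_intr=0.0, L_mean_knt=1.4, initial_tetramers=0,
            duration=10.0, seed=2,
        )
        _, ledger, _ = sc.simulate_replisome(cfg)
        assert len(ledger) == 0
        before = ledger.to_dataframe()
        sc.apply_frap_pulse(ledger, 5.0)
        assert ledger.to_dataframe().equals(before)

    def test_pulse_outside_window_rejected(self, chase_run):
        _, ledger, _ = chase_run
        with pytest.raises(ValueError):
            sc.apply_frap_pulse(ledger, ledger.duration + 1.0)


class TestSteadyStateTetramers:
    def test_stalled_fork_has_zero_coverage(self):
        cfg = SimulationConfig(v_mean=0.0, v_sd=0.0, c_ssb=10.0, duration=20.0, seed=1)
        assert sc.steady_state_tetramers(cfg) == 0.0

    def test_coverage_matches_renewal_oracle(self):
        """Sawtooth ssDNA exposure with exponential fragment lengths:
        simulated time-average coverage equals the renewal Monte-Carlo
        average of (remaining ssDNA)/footprint within 5%."""
        cfg = SimulationConfig(c_ssb=2.0, v_sd=0.0, duration=2000.0, frame_interval=0.25)
        covs = [
            sc.steady_state_tetramers(cfg.replace(seed=s)) for s in range(6)
        ]
        sim_cov = float(np.mean(covs))
        rng = np.random.default_rng(1234)
        L = rng.exponential(1400.0, size=40_000)
        # time-average of the 0 -> L ramp over cycles, duration-weighted
        oracle = np.sum(L**2 / 2.0) / np.sum(L) / 35.0
        assert sim_cov == pytest.approx(oracle, rel=0.05)


class TestIntensityTrace:
    def test_constant_trace_for_one_everlasting_dye(self):
        cfg = SimulationConfig(
            c_ssb=0.0, k_intr=0.0, L_mean_knt=1.4, initial_tetramers=1,
            labeled_fraction=1.0, dyes_mean=1.0, tau_b=1e12, duration=20.0,
            noise_sd=0.0, seed=5,
        )
        _, ledger, _ = sc.simulate_replisome(cfg)
        trace = sc.emit_intensity_trace(ledger, cfg)
        assert np.all(trace.I == trace.I[0])
        assert trace.I[0] == 1.0

    def test_ensemble_decay_at_imaging_bleach_lifetime(self, chase_cfg):
        """With exchange disabled the ensemble-mean trace decays as
        exp(-t/tau_b) with tau_b = 9.5 s."""
        stack = []
        for s in range(30):
            cfgi = chase_cfg.replace(seed=s)
            _, ledger, _ = sc.simulate_replisome(cfgi)
            tr = sc.emit_intensity_trace(ledger, cfgi)
            stack.append(tr.I / tr.I[0])
        mean = np.vstack(stack).mean(axis=0)
        t = np.arange(len(mean)) * chase_cfg.frame_interval
        expected = np.exp(-t / 9.5)
        assert np.allclose(mean[t <= 20.0], expected[t <= 20.0], atol=0.05)

    def test_trace_integral_matches_ledger_tally(self, frap_run, frap_cfg):
        """Bookkeeping oracle: noise-free trace equals a direct per-frame
        count of bright dyes from the ledger."""
        _, ledger, _ = frap_run
        cfg0 = frap_cfg.replace(noise_sd=0.0, baseline=0.0)
        trace = sc.emit_intensity_trace(ledger, cfg0)
        direct = np.array(
            [sum(r.bright_dyes(t) for r in ledger.records) for t in trace.t]
        )
        assert np.array_equal(trace.I, direct.astype(float))


class TestInVivoScene:
    def test_zero_energy_pulse_is_identity(self):
        cfg = SimulationConfig(
            c_ssb=450.0, k_intr=0.0, k_fac=1.0 / (2.5 * 450.0), tau_b=10.0,
            pulse_times=[5.0], duration=20.0, noise_sd=0.2, seed=4,
        )
        s1 = sc.simulate_in_vivo_scene(cfg, n_cells=4, n_pulsed=2, pulse_dose=0.0)
        cfg2 = cfg.replace(pulse_times=[15.0])
        s2 = sc.simulate_in_vivo_scene(cfg2, n_cells=4, n_pulsed=2, pulse_dose=0.0)
        for a, b in zip(s1.focus_traces, s2.focus_traces):
            assert np.array_equal(a.I, b.I)

    def test_pulse_darkens_focus_but_spares_cytosol(self):
        cfg = SimulationConfig(
            c_ssb=450.0, k_intr=0.0, k_fac=1.0 / (2.5 * 450.0), tau_b=10.0,
            pulse_times=[5.0], duration=20.0, noise_sd=0.0, seed=8,
        )
        scene = sc.simulate_in_vivo_scene(cfg, n_cells=10, n_pulsed=5)
        post_over_pre = []
        for tr in scene.focus_traces:
            pre = np.mean(tr.I[(tr.t > 2.0) & (tr.t < 5.0)])
            post = np.interp(5.0 + cfg.frame_interval, tr.t, tr.I)
            post_over_pre.append(post / pre)
        assert np.mean(post_over_pre) < 0.15
        retained = [
            1.0 - c.cytosol_bleach_fraction for c in scene.cells if not c.is_control
        ]
        assert np.mean(retained) > 0.90

    def test_target_outside_cells_rejected(self):
        cfg = SimulationConfig(c_ssb=450.0, duration=20.0, pulse_times=[5.0], seed=1)
        with pytest.raises(ValueError):
            sc.simulate_in_vivo_scene(cfg, n_cells=4, frap_target=(1e3, 1e3))

    def test_needs_a_control_cell(self):
        cfg = SimulationConfig(c_ssb=450.0, duration=20.0, pulse_times=[5.0], seed=1)
        with pytest.raises(ValueError):
            sc.simulate_in_vivo_scene(cfg, n_cells=1)

    def test_recovery_asymptote_tracks_pool_bright_fraction(self):
        """Compartment-model oracle: corrected for imaging decay, the
        post-pulse focus recovery tends to pool-bright-fraction x occupancy."""
        cfg = SimulationConfig(
            c_ssb=450.0, k_intr=0.0, k_fac=1.0 / (1.0 * 450.0), tau_b=30.0,
            pulse_times=[4.0], duration=24.0, noise_sd=0.0, seed=6,
            labeled_fraction=1.0, dyes_mean=1.0,
        )
        acc = np.zeros(1)
        n_rep = 40
        t_late = 20.0
        vals = []
        for s in range(n_rep):
            scene = sc.simulate_in_vivo_scene(
                cfg.replace(seed=s), n_cells=3, n_pulsed=1, focus_tetramers=12
            )
            tr = scene.focus_traces[0]
            vals.append(np.interp(t_late, tr.t, tr.I))
        # expectation: occupancy * exp(-t/tau_b) * (1 - exp(-k_ex (t-t_pulse)))
        expected = 12.0 * math.exp(-t_late / 30.0) * (1.0 - math.exp(-(t_late - 4.0) / 1.0))
        assert np.mean(vals) == pytest.approx(expected, rel=0.15)
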